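import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pairscreen as ps
from pairscreen.lm import conditional_effects, huber_rlm, normalize_additive
from pairscreen.screen_io import ScreenTable


def _grid_table(scores: np.ndarray, reps: int = 1) -> ScreenTable:
    """Wrap an A x B (x replicate) score array as a screen table."""
    if scores.ndim == 2:
        scores = scores[:, :, None]
    n_a, n_b, n_r = scores.shape
    ai, bi, ri = np.meshgrid(
        np.arange(n_a), np.arange(n_b), np.arange(n_r), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "pert_a": [f"a{i:02d}" for i in ai.ravel()],
            "pert_b": [f"b{j:02d}" for j in bi.ravel()],
            "score": scores.ravel(),
            "rep1": "1",
            "rep2": ri.ravel() + 1,
        }
    )
    return ScreenTable(df)


class TestHuberRlm:
    def test_exact_linear_data_interpolated(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 3.0 + 2.0 * np.arange(10.0)
        fit = huber_rlm(x, y)
        assert fit.coefficients == pytest.approx([3.0, 2.0], abs=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.converged

    def test_outlier_resistance_vs_ols(self):
        rng = np.random.default_rng(8)
        xv = np.linspace(0, 10, 20)
        sigma = 0.2
        y = 2.0 * xv + rng.normal(0, sigma, 20)
        y[10] += 10 * sigma  # gross outlier
        x = np.column_stack([np.ones(20), xv])
        huber_slope = huber_rlm(x, y).coefficients[1]
        ols_slope = np.linalg.lstsq(x, y, rcond=None)[0][1]
        assert abs(huber_slope - 2.0) < 0.05 * 2.0
        assert abs(ols_slope - 2.0) > abs(huber_slope - 2.0)

    def test_constant_response_intercept_only(self):
        fit = huber_rlm(np.ones((12, 1)), np.full(12, 4.2))
        assert fit.coefficients[0] == pytest.approx(4.2)

    def test_large_tuning_k_matches_ols(self):
        rng = np.random.default_rng(3)
        x = np.column_stack([np.ones(30), rng.normal(size=30), rng.normal(size=30)])
        y = x @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 1.0, 30)
        fit = huber_rlm(x, y, tuning_k=1e9)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        assert np.allclose(fit.coefficients, ols, atol=1e-6)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12)
        x = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = x @ np.array([0.5, 1.5]) + rng.standard_t(3, 60)
        mine = huber_rlm(x, y).coefficients
        theirs = sm.RLM(y, x, M=sm.robust.norms.HuberT(t=1.345)).fit().params
        assert np.allclose(mine, theirs, atol=1e-3)

    def test_rank_deficient_design_names_columns(self):
        x = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(np.linalg.LinAlgError, match="aliased"):
            huber_rlm(x, np.arange(10.0), names=["int", "x", "x2"])


class TestNormalizeAdditive:
    def test_purely_additive_log_structure_zero_residuals(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 9)
        scores = np.exp(5 + a[:, None] + b[None, :])
        resid = normalize_additive(_grid_table(scores))
        assert np.allclose(resid, 0.0, atol=1e-8)

    def test_single_spiked_cell_recovers_delta(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 0.5, 10), rng.normal(0, 0.5, 10)
        scores = np.exp(5 + a[:, None] + b[None, :])
        delta = 1.0
        scores[3, 4] *= np.exp(delta)
        resid = normalize_additive(_grid_table(scores))
        table = _grid_table(scores)
        idx = (table.data.pert_a == "a03") & (table.data.pert_b == "b04")
        assert resid[idx.to_numpy()][0] == pytest.approx(delta, rel=0.10)

    def test_global_rescaling_absorbed_by_intercept(self, small_screen):
        r1 = normalize_additive(small_screen)
        scaled = ScreenTable(small_screen.data.assign(score=small_screen.data.score * 37.5))
        r2 = normalize_additive(scaled)
        assert np.allclose(r1, r2, atol=1e-8)


class TestConditionalEffects:
    def test_spiked_cell_has_smallest_p_in_context(self):
        rng = np.random.default_rng(21)
        n_a, n_b, n_r = 8, 8, 4
        resid = rng.normal(0, 0.01, (n_a, n_b, n_r))
        resid[2, 5, :] += 1.0
        table = _grid_table(np.exp(resid))  # scores unused by the test
        eff = conditional_effects(resid.ravel(), table, fix="A")
        ctx = eff[eff.context == "a02"].set_index("target")
        assert ctx.p.idxmin() == "b05"

    def test_null_p_values_uniform(self):
        # 2500 p-values keep the KS sampling noise (~0.017) well below the
        # bound, so the check discriminates miscalibration from seed luck
        rng = np.random.default_rng(33)
        n_a, n_b, n_r = 50, 50, 4
        resid = rng.normal(0, 1, n_a * n_b * n_r)
        table = _grid_table(np.ones((n_a, n_b, n_r)))
        eff = conditional_effects(resid, table, fix="A")
        ks = stats.kstest(eff.p.dropna(), "uniform").statistic
        assert ks < 0.05

    def test_single_replicate_context_reports_beta_without_p(self):
        table = _grid_table(np.exp(np.random.default_rng(1).normal(size=(4, 4))))
        resid = np.arange(16.0)
        eff = conditional_effects(resid, table, fix="A")
        assert eff.p.isna().all()
        assert np.allclose(eff.beta, resid)  # one observation per target

    def test_directed_tail_is_half_two_sided(self):
        rng = np.random.default_rng(2)
        resid = rng.normal(0, 1, 5 * 6 * 3)
        table = _grid_table(np.ones((5, 6, 3)))
        two = conditional_effects(resid, table, fix="B", tail="two-sided")
        one = conditional_effects(resid, table, fix="B", tail="directed")
        assert np.allclose(one.p, two.p / 2.0, equal_nan=True)


class TestLmAnalyze:
    def test_spiked_pair_ranks_top(self, small_screen):
        cfg = ps.SimulationConfig(
            n_a=20, n_b=20, n_replicates=4, n_true_positives=1,
            fold=0.5, replicate_cv=0.10, seed=77,
        )
        table, truth = ps.generate_screen(cfg)
        res = ps.lm_analyze(table)
        df = res.data.sort_values("p_combined")
        top = int(np.ceil(0.01 * len(df)))
        top_pairs = set(zip(df.pertA.head(top), df.pertB.head(top)))
        assert truth.spiked_pairs <= top_pairs

    def test_one_row_per_observed_pair(self, small_screen):
        res = ps.lm_analyze(small_screen)
        pairs = small_screen.data.groupby(["pert_a", "pert_b"]).ngroups
        assert len(res) == pairs
        assert not res.data.duplicated(["pertA", "pertB"]).any()

    def test_scale_equivariance_of_p_values(self, small_screen):
        res1 = ps.lm_analyze(small_screen)
        scaled = ScreenTable(small_screen.data.assign(score=small_screen.data.score * 11.0))
        res2 = ps.lm_analyze(scaled)
        for col in ("p_a", "p_b", "p_combined"):
            assert np.allclose(res1.data[col], res2.data[col], atol=1e-8)

    def test_spike_recovery_monotone_in_fold(self):
        def median_neglog(fold):
            cfg = ps.SimulationConfig(
                n_a=20, n_b=20, n_replicates=4, n_true_positives=8,
                fold=fold, seed=55,
            )
            table, truth = ps.generate_screen(cfg)
            res = ps.lm_analyze(table)
            hit = res.data.set_index(["pertA", "pertB"]).loc[list(truth.spiked_pairs)]
            return np.median(-np.log10(hit.p_combined))

        assert median_neglog(0.5) > median_neglog(0.7)
        assert median_neglog(1.5) > median_neglog(1.3)


class TestLmSplitAnalyze:
    def test_single_block_identical_to_full(self, small_screen):
        full = ps.lm_analyze(small_screen)
        split = ps.lm_split_analyze(small_screen, group_size=100)
        num = full.data.columns[2:]
        assert np.allclose(
            full.data[num].to_numpy(), split.data[num].to_numpy(),
            atol=1e-10, equal_nan=True,
        )

    def test_pairs_never_split_across_blocks(self, small_screen):
        res = ps.lm_split_analyze(small_screen, group_size=4)
        blocks = res.meta["blocks"]
        # every pair's replicates share one (A-block, B-block) assignment
        df = small_screen.data
        assign = df.apply(
            lambda r: (blocks["A"][r.pert_a], blocks["B"][r.pert_b]), axis=1
        )
        per_pair = assign.groupby([df.pert_a, df.pert_b]).nunique()
        assert (per_pair == 1).all()
        assert len(res) == df.groupby(["pert_a", "pert_b"]).ngroups

    def test_small_group_size_rejected(self, small_screen):
        with pytest.raises(ValueError, match="group_size"):
            ps.lm_split_analyze(small_screen, group_size=1)
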