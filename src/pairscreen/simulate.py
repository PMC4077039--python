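"""Synthetic spike-in screens and ROC benchmarking of the analysis models.

The generator emulates a barcode-abundance screen: a log-normal baseline
with additive log-scale row and column effects (every perturbation shifts
fitness marginally) and multiplicative replicate noise.  A small set of
randomly chosen pairs -- the spike-ins, the ground-truth "true positives"
-- has its expected signal multiplied by a fold factor (0.5 and 0.7 for
reduced fitness, 1.3 and 1.5 for increased fitness are the conventional
benchmark points).  Expected score of pair (i, j)::

    E[score_ij] = exp(baseline_log_mean + a_i + b_j) * fold^{spiked(i,j)}
    a_i ~ N(0, row_effect_sd^2),  b_j ~ N(0, col_effect_sd^2)

Each replicate is drawn log-normally around its expectation with a given
coefficient of variation (mean-one noise, so the expectation is exact).
An optional raw-scale Gaussian noise model (``noise="raw"``) makes the
noise symmetric on the raw scale instead, which renders decreased-fitness
spikes easier to detect than their mirrored increased-fitness
counterparts -- the asymmetry seen in real barcode data.

ROC evaluation sweeps a ranking statistic (typically the combined
p-value, ascending: smaller = more hit-like) over all thresholds and
reports the trapezoidal area under the curve; pairs with a missing
statistic rank worst.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from pairscreen.screen_io import ResultTable, ScreenTable

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "RocCurve",
    "generate_screen",
    "roc",
    "benchmark",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic spike-in screen.

    Defaults reproduce the benchmark scale of a 100 x 100 quadruplicate
    screen with 100 spiked pairs; see :func:`benchmark` for the desk-scale
    grid.  ``baseline_log_mean`` is on the natural-log scale (e^7 ~ 1100,
    a typical bead intensity / read count magnitude); marginal row and
    column effect standard deviations of 0.3 give ~35% perturbation-level
    fitness spread; ``replicate_cv`` is the coefficient of variation of
    the replicate noise.
    """

    n_a: int = 100
    n_b: int = 100
    n_replicates: int = 4
    n_true_positives: int = 100
    fold: float = 0.5
    baseline_log_mean: float = 7.0
    row_effect_sd: float = 0.3
    col_effect_sd: float = 0.3
    replicate_cv: float = 0.15
    noise: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_replicates) < 1:
            raise ValueError("screen dimensions must be positive")
        if not 0 <= self.n_true_positives <= self.n_a * self.n_b:
            raise ValueError("n_true_positives must fit in the screen")
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.row_effect_sd <= 0 or self.col_effect_sd <= 0:
            raise ValueError("effect standard deviations must be positive")
        if self.replicate_cv <= 0:
            raise ValueError("replicate_cv must be positive")
        if self.noise not in ("lognormal", "raw"):
            raise ValueError("noise must be 'lognormal' or 'raw'")


@dataclass
class TruthSet:
    """Ground-truth spike-in labels of a simulated screen."""

    spiked_pairs: set[tuple[str, str]]
    fold: float

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"fold": self.fold, "spiked_pairs": sorted(self.spiked_pairs)}, fh
            )

    @classmethod
    def from_json(cls, path: str) -> "TruthSet":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls({tuple(p) for p in obj["spiked_pairs"]}, obj["fold"])


@dataclass
class RocCurve:
    """Threshold sweep of a ranking statistic against spike-in truth."""

    points: np.ndarray  # ordered (FPR, TPR), from (0,0) to (1,1)
    auc: float
    n_pos: int
    n_neg: int

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.points[:, 0], self.points[:, 1], label=label)
        ax.plot([0, 1], [0, 1], ls=":", color="0.6", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        if label:
            ax.legend()
        return ax


def generate_screen(config: SimulationConfig) -> tuple[ScreenTable, TruthSet]:
    """Draw a synthetic screen and its spike-in truth, reproducibly.

    All randomness derives from ``config.seed``; the same configuration
    always produces an identical table.
    """
    rng = np.random.default_rng(config.seed)
    na, nb, nr = config.n_a, config.n_b, config.n_replicates
    width = max(3, len(str(max(na, nb))))
    names_a = [f"A{i+1:0{width}d}" for i in range(na)]
    names_b = [f"B{j+1:0{width}d}" for j in range(nb)]
    a = rng.normal(0.0, config.row_effect_sd, size=na)
    b = rng.normal(0.0, config.col_effect_sd, size=nb)
    log_expect = config.baseline_log_mean + a[:, None] + b[None, :]
    flat = rng.choice(na * nb, size=config.n_true_positives, replace=False)
    spike_mask = np.zeros(na * nb, dtype=bool)
    spike_mask[flat] = True
    spike_mask = spike_mask.reshape(na, nb)
    expect = np.exp(log_expect)
    expect[spike_mask] *= config.fold

    cv = config.replicate_cv
    if config.noise == "lognormal":
        # mean-one log-normal noise: E[score] stays exactly `expect`
        sigma2 = math.log1p(cv**2)
        noise = rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), size=(na, nb, nr))
        scores = expect[:, :, None] * np.exp(noise)
    else:  # raw-scale Gaussian noise, asymmetric after the log transform
        scores = expect[:, :, None] * (
            1.0 + cv * rng.standard_normal(size=(na, nb, nr))
        )
        scores = np.maximum(scores, 0.0)

    ai, bi, ri = np.meshgrid(
        np.arange(na), np.arange(nb), np.arange(nr), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "pert_a": np.asarray(names_a, dtype=object)[ai.ravel()],
            "pert_b": np.asarray(names_b, dtype=object)[bi.ravel()],
            "score": scores.ravel(),
            "rep1": "1",
            "rep2": ri.ravel() + 1,
        }
    )
    truth = TruthSet(
        {
            (names_a[i], names_b[j])
            for i, j in zip(*np.nonzero(spike_mask))
        },
        config.fold,
    )
    meta = {"importer": "generate_screen", "config": asdict(config)}
    return ScreenTable(df, meta).validate(), truth


def roc(
    results: ResultTable, truth: TruthSet, statistic: str = "p_combined"
) -> RocCurve:
    """ROC of a ranking statistic (ascending = hit-like) vs spike-in truth.

    All distinct thresholds are swept; tied scores share a threshold, so
    the trapezoidal area equals the Mann-Whitney two-sample probability
    that a random spiked pair out-ranks a random null pair.  Pairs with a
    missing statistic are ranked worst.
    """
    if not truth.spiked_pairs:
        raise ValueError("truth set is empty")
    df = results.data
    pairs = set(zip(df["pertA"], df["pertB"]))
    missing = truth.spiked_pairs - pairs
    if missing:
        raise ValueError(f"truth pairs absent from results: {sorted(missing)[:5]}")
    score = df[statistic].to_numpy(dtype=float)
    score = np.where(np.isnan(score), np.inf, score)  # missing ranks worst
    is_pos = np.fromiter(
        ((a, b) in truth.spiked_pairs for a, b in zip(df["pertA"], df["pertB"])),
        dtype=bool,
        count=len(df),
    )
    n_pos = int(is_pos.sum())
    n_neg = len(df) - n_pos
    if n_neg == 0:
        raise ValueError("no null pairs to rank against")
    order = np.argsort(score, kind="stable")
    s_sorted = score[order]
    pos_sorted = is_pos[order]
    # group tied scores: cumulative counts at the end of each tie block
    boundary = np.nonzero(np.diff(s_sorted))[0]
    ends = np.concatenate([boundary, [len(s_sorted) - 1]])
    tp = np.cumsum(pos_sorted)[ends]
    fp = (ends + 1) - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocCurve(points=points, auc=auc, n_pos=n_pos, n_neg=n_neg)


def benchmark(
    folds=(0.5, 0.7, 1.3, 1.5),
    methods=("lm", "slm", "ut"),
    n_a: int = 30,
    n_b: int = 30,
    n_replicates: int = 4,
    n_true_positives: int = 25,
    replicate_cv: float = 0.15,
    noise: str = "lognormal",
    seed: int = 0,
    group_size: int = 15,
    statistic: str = "p_combined",
    out_csv: str | None = None,
    plot_prefix: str | None = None,
) -> pd.DataFrame:
    """AUC of each analysis method at each spike-in fold.

    One screen is generated per fold (shared seed, so all methods see the
    same data) and scored by the requested methods; the ROC is computed on
    ``statistic``.  Returns a tidy frame of (fold, method, auc) and
    optionally writes it as CSV and one ROC figure per fold.
    """
    from pairscreen.lm import lm_analyze, lm_split_analyze
    from pairscreen.ut import ut_analyze

    rows = []
    curves: dict[float, dict[str, RocCurve]] = {}
    for fold in folds:
        config = SimulationConfig(
            n_a=n_a,
            n_b=n_b,
            n_replicates=n_replicates,
            n_true_positives=n_true_positives,
            fold=fold,
            replicate_cv=replicate_cv,
            noise=noise,
            seed=seed,
        )
        table, truth = generate_screen(config)
        curves[fold] = {}
        for method in methods:
            if method == "lm":
                res = lm_analyze(table)
            elif method == "slm":
                res = lm_split_analyze(table, group_size=group_size)
            elif method == "ut":
                res = ut_analyze(table)
            else:
                raise ValueError(f"unknown method {method!r}")
            curve = roc(res, truth, statistic=statistic)
            curves[fold][method] = curve
            rows.append({"fold": fold, "method": method, "auc": curve.auc})
    out = pd.DataFrame(rows)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    if plot_prefix is not None:
        import matplotlib.pyplot as plt

        for fold, by_method in curves.items():
            fig, ax = plt.subplots()
            for method, curve in by_method.items():
                curve.plot(ax=ax, label=f"{method} (AUC {curve.auc:.3f})")
            ax.set_title(f"spike-in fold {fold}")
            fig.savefig(f"{plot_prefix}_fold{fold}.png", dpi=120)
            plt.close(fig)
    return out
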