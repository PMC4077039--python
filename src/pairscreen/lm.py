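"""Two-stage robust linear model for interaction scoring.

Barcode-abundance fitness scores from a double perturbation screen are
assumed, on the log scale, to decompose additively into (1) the systematic
effect of perturbation A, (2) the systematic effect of perturbation B,
(3) a pair-specific signal consistent across replicates -- the interaction
of biological interest -- and (4) replicate noise::

    log intensity_i = beta_A[A_i] + beta_B[B_i] + s_i

The first stage estimates the two marginal effects by robust regression
(iteratively reweighted least squares with a Huber M-estimator, resistant
to the rare true interactions, which are outliers under the additive
model) and returns the residual signal ``s_i`` per measurement.

The second stage dissects ``s_i`` twice.  Fixing each level of A in turn,
the residuals of that context are regressed on the dummy-coded B levels
(one coefficient per B, no intercept)::

    for each A:  s_(i|A) = beta_(B|A)[B_i] + eps

and symmetrically with B fixed.  Each coefficient pools the replicates of
one pair within its context; its t statistic (coefficient over robust
standard error, residual degrees of freedom of the context fit) yields the
directional p-value of the pair.  Because both increased- and
decreased-fitness interactions are of interest and the combined score must
be uniformly distributed for null pairs, the default p-value is the
two-sided tail ``2 P(T_dof > |t|)``; ``tail="directed"`` gives the halved
anti-conservative variant ``P(T_dof > |t|)``.

Working on log scores makes the additive coefficients model multiplicative
fitness effects, and leaves every p-value invariant under global rescaling
of the raw scores.

A memory-saving split variant partitions both perturbation axes into
blocks (default 50 levels) and runs the full normalization and testing
independently per block pair, at some cost in statistical power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
from scipy import stats

from pairscreen._common import assemble_results
from pairscreen.screen_io import ResultTable, ScreenTable, ScreenValidationError

__all__ = [
    "RobustFit",
    "ConditionalEffect",
    "huber_rlm",
    "normalize_additive",
    "conditional_effects",
    "iter_effects",
    "lm_analyze",
    "lm_split_analyze",
    "DEFAULT_TUNING_K",
]

#: Huber tuning constant giving 95% efficiency at the Gaussian model.
DEFAULT_TUNING_K = 1.345

#: MAD-to-sigma consistency factor for Gaussian residuals.
_MAD_SCALE = 0.6745


@dataclass
class RobustFit:
    """Result of a Huber IRLS regression.

    ``standard_errors`` come from Huber's asymptotic M-estimator
    covariance (psi-squared scale with the finite-sample correction
    factor); ``dof`` is observations minus estimated parameters.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    residuals: np.ndarray
    dof: int
    converged: bool
    iterations: int
    scale: float
    names: list[str] | None = None


@dataclass(frozen=True)
class ConditionalEffect:
    """Effect of ``target`` within the context of one fixed perturbation."""

    context: str
    target: str
    beta: float
    se: float
    t: float
    p: float


def _solve_normal(xtwx: np.ndarray, xtwy: np.ndarray, names: list[str] | None):
    try:
        chol = scipy.linalg.cho_factor(xtwx)
    except scipy.linalg.LinAlgError:
        aliased = _aliased_columns(xtwx, names)
        raise np.linalg.LinAlgError(
            f"rank-deficient design; aliased columns: {aliased}"
        ) from None
    return scipy.linalg.cho_solve(chol, xtwy), chol


def _aliased_columns(xtx: np.ndarray, names: list[str] | None) -> list[str]:
    _, r = np.linalg.qr(xtx)
    diag = np.abs(np.diag(r))
    bad = np.nonzero(diag <= 1e-10 * max(diag.max(), 1.0))[0]
    if names is None:
        return [f"column {i}" for i in bad]
    return [names[i] for i in bad]


def huber_rlm(
    design,
    response: np.ndarray,
    tuning_k: float = DEFAULT_TUNING_K,
    max_iter: int = 50,
    tol: float = 1e-6,
    names: list[str] | None = None,
) -> RobustFit:
    """Huber M-estimation by iteratively reweighted least squares.

    Parameters
    ----------
    design : ndarray or scipy sparse matrix, observations x parameters
        Must have full column rank.
    response : ndarray
    tuning_k : float
        Huber constant; observations with ``|r| > k * scale`` are
        down-weighted by ``k * scale / |r|``.  As ``tuning_k`` grows the
        fit converges to ordinary least squares.
    max_iter, tol : int, float
        Iteration stops when the largest coefficient change drops below
        ``tol``; non-convergence is reported via ``converged=False``.

    Notes
    -----
    The residual scale is re-estimated each iteration as
    ``median(|r|) / 0.6745`` (MAD about zero, the convention for
    regression residuals).  If the scale collapses to zero the data are
    fit exactly and iteration stops.
    """
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    if sp.issparse(design):
        x = sp.csr_matrix(design).astype(float)
    else:
        x = np.asarray(design, dtype=float)
    p = x.shape[1]
    if n < p:
        raise ValueError(f"need at least as many observations ({n}) as parameters ({p})")

    def wls(w: np.ndarray):
        if sp.issparse(x):
            xw = x.multiply(w[:, None]).tocsr()
            xtwx = (x.T @ xw).toarray()
            xtwy = x.T @ (w * y)
        else:
            xw = x * w[:, None]
            xtwx = x.T @ xw
            xtwy = x.T @ (w * y)
        beta, _ = _solve_normal(xtwx, xtwy, names)
        return beta, xtwx

    weights = np.ones(n)
    beta, xtwx = wls(weights)
    converged = False
    iterations = 0
    scale = 0.0
    for iterations in range(1, max_iter + 1):
        resid = y - x @ beta
        scale = float(np.median(np.abs(resid))) / _MAD_SCALE
        if scale <= np.finfo(float).eps * max(1.0, float(np.abs(y).max())):
            converged = True  # exact fit
            break
        with np.errstate(divide="ignore"):
            weights = np.minimum(1.0, tuning_k * scale / np.abs(resid))
        weights[~np.isfinite(weights)] = 1.0  # zero residual -> full weight
        beta_new, xtwx = wls(weights)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged:
        import warnings

        warnings.warn(
            f"Huber IRLS did not converge in {max_iter} iterations", stacklevel=2
        )
    resid = y - x @ beta
    dof = n - p
    if scale > 0 and dof > 0:
        # Huber's asymptotic covariance of an M-estimator,
        #   K^2 * [s^2 sum(psi(u)^2)/(n-p)] / (mean psi')^2 * (X'X)^{-1}
        # with u = r/s, psi the Huber function, psi' its (indicator)
        # derivative and K = 1 + (p/n) var(psi')/mean(psi')^2; this keeps
        # the t statistics calibrated where the naive MAD-scale plug-in
        # does not
        u = resid / scale
        psi = np.clip(u, -tuning_k, tuning_k)
        dpsi = (np.abs(u) < tuning_k).astype(float)
        m = dpsi.mean()
        if m > 0:
            kcorr = 1.0 + (p / n) * dpsi.var() / m**2
            s2 = kcorr**2 * (scale**2 * np.sum(psi**2) / dof) / m**2
            if sp.issparse(x):
                xtx = (x.T @ x).toarray()
            else:
                xtx = x.T @ x
            cov = s2 * np.linalg.inv(xtx)
        else:
            cov = np.full((p, p), np.inf)
    else:
        cov = np.zeros((p, p))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return RobustFit(
        coefficients=beta,
        standard_errors=se,
        residuals=resid,
        dof=dof,
        converged=converged,
        iterations=iterations,
        scale=scale,
        names=names,
    )


# ---------------------------------------------------------------------------
# stage 1: additive normalization


def default_pseudocount(table: ScreenTable) -> float:
    """1 for data containing zeros (counts), 0 for strictly positive scores."""
    return 1.0 if (table.data["score"] <= 0).any() else 0.0


def _dummy_design(table: ScreenTable):
    """Sparse design: intercept + A dummies + B dummies (first level = reference)."""
    df = table.data
    la, lb = table.levels_a, table.levels_b
    a = pd.Categorical(df["pert_a"], categories=la).codes.astype(np.int64)
    b = pd.Categorical(df["pert_b"], categories=lb).codes.astype(np.int64)
    n = len(df)
    ncols = 1 + (len(la) - 1) + (len(lb) - 1)
    rows, cols = [np.arange(n)], [np.zeros(n, dtype=int)]  # intercept
    mask_a = a > 0
    rows.append(np.nonzero(mask_a)[0])
    cols.append(a[mask_a])  # columns 1..len(la)-1
    mask_b = b > 0
    rows.append(np.nonzero(mask_b)[0])
    cols.append(len(la) - 1 + b[mask_b])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    x = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(n, ncols))
    names = (
        ["(intercept)"]
        + [f"A[{lvl}]" for lvl in la[1:]]
        + [f"B[{lvl}]" for lvl in lb[1:]]
    )
    return x, names


def normalize_additive(
    table: ScreenTable,
    pseudocount: float | None = None,
    tuning_k: float = DEFAULT_TUNING_K,
    return_fit: bool = False,
):
    """Remove the marginal A and B effects from log scores.

    Fits ``ln(score + pseudocount) ~ A + B`` by Huber regression and
    returns the residual signal ``s_i``, one value per measurement,
    aligned with ``table.data``.  With ``return_fit=True`` the full
    :class:`RobustFit` is returned alongside.
    """
    table.validate()
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    scores = table.data["score"].to_numpy(dtype=float) + pseudocount
    if (scores <= 0).any():
        raise ScreenValidationError(
            "scores plus pseudocount must be positive for the log transform"
        )
    y = np.log(scores)
    x, names = _dummy_design(table)
    fit = huber_rlm(x, y, tuning_k=tuning_k, names=names)
    if return_fit:
        return fit.residuals, fit
    return fit.residuals


# ---------------------------------------------------------------------------
# stage 2: conditional effects


def conditional_effects(
    residuals: np.ndarray,
    table: ScreenTable,
    fix: str = "A",
    tuning_k: float = DEFAULT_TUNING_K,
    tail: str = "two-sided",
) -> pd.DataFrame:
    """Per-context robust effect of every level of the other factor.

    For each level of the fixed factor, the residual signals of that
    context are regressed on the dummy-coded other factor (no intercept;
    every target level gets a coefficient, pooling the context's
    replicates).  Returns a frame with columns ``context, target, beta,
    se, t, p``.  Contexts without a spare residual degree of freedom
    report the coefficient with a missing p-value.

    ``tail="two-sided"`` (default) gives ``2 P(T > |t|)``, uniform for
    null pairs; ``tail="directed"`` gives ``P(T > |t|)``, one-sided in the
    direction of the estimated sign.
    """
    if fix not in ("A", "B"):
        raise ValueError("fix must be 'A' or 'B'")
    if tail not in ("two-sided", "directed"):
        raise ValueError("tail must be 'two-sided' or 'directed'")
    df = table.data
    s = np.asarray(residuals, dtype=float)
    if len(s) != len(df):
        raise ValueError("residual vector must align with the screen table")
    ctx_col, tgt_col = ("pert_a", "pert_b") if fix == "A" else ("pert_b", "pert_a")

    records = []
    for ctx, idx in df.groupby(ctx_col, sort=True).indices.items():
        sub = df.iloc[idx]
        y = s[idx]
        targets = sorted(sub[tgt_col].unique())
        if len(targets) < 2:
            for tgt in targets:
                records.append((ctx, tgt, np.nan, np.nan, np.nan, np.nan))
            continue
        codes = pd.Categorical(sub[tgt_col], categories=targets).codes
        n, p = len(y), len(targets)
        if n - p < 1:
            # one observation per target: coefficients are the values
            for tgt, code in zip(targets, range(p)):
                beta = float(np.mean(y[codes == code]))
                records.append((ctx, tgt, beta, np.nan, np.nan, np.nan))
            continue
        x = sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, p)
        )
        fit = huber_rlm(x, y, tuning_k=tuning_k, names=[str(t) for t in targets])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = fit.coefficients / fit.standard_errors
        p_two = 2.0 * stats.t.sf(np.abs(t_stat), fit.dof)
        p_val = p_two / 2.0 if tail == "directed" else np.minimum(p_two, 1.0)
        for j, tgt in enumerate(targets):
            records.append(
                (ctx, tgt, fit.coefficients[j], fit.standard_errors[j],
                 t_stat[j], p_val[j])
            )
    return pd.DataFrame(
        records, columns=["context", "target", "beta", "se", "t", "p"]
    )


def iter_effects(frame: pd.DataFrame) -> Iterator[ConditionalEffect]:
    """View the rows of a :func:`conditional_effects` frame as records."""
    for row in frame.itertuples(index=False):
        yield ConditionalEffect(row.context, row.target, row.beta, row.se, row.t, row.p)


# ---------------------------------------------------------------------------
# full pipelines


def lm_analyze(
    table: ScreenTable,
    pseudocount: float | None = None,
    tuning_k: float = DEFAULT_TUNING_K,
    combine_method: str = "brown",
    tail: str = "two-sided",
) -> ResultTable:
    """Full linear-model pipeline: normalize, test both directions, combine.

    ``p_b`` of a pair tests the B-coefficient within its fixed-A context
    (how unusual is B's effect among B's given this A); ``p_a`` tests the
    A-coefficient within the fixed-B context.  Magnitudes are computed from
    raw scores and the two directional p-values are combined by Brown's
    method (default).
    """
    table.validate()
    resid = normalize_additive(table, pseudocount=pseudocount, tuning_k=tuning_k)
    fix_a = conditional_effects(resid, table, fix="A", tuning_k=tuning_k, tail=tail)
    fix_b = conditional_effects(resid, table, fix="B", tuning_k=tuning_k, tail=tail)
    p_b = fix_a.rename(columns={"context": "pertA", "target": "pertB"})[
        ["pertA", "pertB", "p"]
    ]
    p_a = fix_b.rename(columns={"context": "pertB", "target": "pertA"})[
        ["pertA", "pertB", "p"]
    ]
    meta = {
        "method": "lm",
        "pseudocount": pseudocount,
        "tuning_k": tuning_k,
        "combine_method": combine_method,
        "tail": tail,
    }
    return assemble_results(table, p_a, p_b, combine_method=combine_method, meta=meta)


def _partition(levels: list[str], group_size: int, rng: np.random.Generator | None):
    levels = list(levels)
    if rng is not None:
        order = rng.permutation(len(levels))
        levels = [levels[i] for i in order]
    n_blocks = max(1, -(-len(levels) // group_size))
    blocks = [list(b) for b in np.array_split(np.asarray(levels, dtype=object), n_blocks)]
    # avoid degenerate single-level blocks (normalization needs >= 2 levels)
    while len(blocks) > 1 and len(blocks[-1]) < 2:
        blocks[-2].extend(blocks[-1])
        blocks.pop()
    return blocks


def lm_split_analyze(
    table: ScreenTable,
    group_size: int = 50,
    shuffle_seed: int | None = None,
    pseudocount: float | None = None,
    tuning_k: float = DEFAULT_TUNING_K,
    combine_method: str = "brown",
    tail: str = "two-sided",
) -> ResultTable:
    """Split linear model: blockwise normalization and testing.

    Both axes are partitioned into contiguous blocks of roughly
    ``group_size`` levels (sorted identifier order, or a seeded shuffle),
    and the full :func:`lm_analyze` pipeline runs independently on each
    A-block x B-block sub-table.  Results are concatenated; the block
    assignment is recorded in ``meta``.  With ``group_size`` at least both
    axis sizes this reduces exactly to :func:`lm_analyze`.
    """
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    table.validate()
    rng = None if shuffle_seed is None else np.random.default_rng(shuffle_seed)
    blocks_a = _partition(table.levels_a, group_size, rng)
    blocks_b = _partition(table.levels_b, group_size, rng)
    df = table.data
    parts = []
    assignment = {"A": {}, "B": {}}
    for ia, ba in enumerate(blocks_a):
        assignment["A"].update({lvl: ia for lvl in ba})
    for ib, bb in enumerate(blocks_b):
        assignment["B"].update({lvl: ib for lvl in bb})
    for ba in blocks_a:
        in_a = df["pert_a"].isin(ba)
        for bb in blocks_b:
            sub = df[in_a & df["pert_b"].isin(bb)]
            if len(sub) == 0:
                continue
            sub_table = ScreenTable(sub.copy(), dict(table.meta))
            part = lm_analyze(
                sub_table,
                pseudocount=pseudocount,
                tuning_k=tuning_k,
                combine_method=combine_method,
                tail=tail,
            )
            parts.append(part.data)
    out = pd.concat(parts, ignore_index=True).sort_values(
        ["pertA", "pertB"], kind="stable", ignore_index=True
    )
    meta = {
        "method": "slm",
        "group_size": group_size,
        "shuffle_seed": shuffle_seed,
        "pseudocount": pseudocount,
        "tuning_k": tuning_k,
        "combine_method": combine_method,
        "tail": tail,
        "blocks": assignment,
    }
    return ResultTable(out, meta).validate()
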