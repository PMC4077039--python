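"""Rank-based interaction scoring: median normalization + Mann-Whitney U.

The second hit-calling model makes no distributional assumption.  Scores
are arranged in an A x B x replicate array; each value is divided by its
row median (over everything sharing the same A-perturbation), then by its
column median recomputed on the row-normalized values, and finally
log10-transformed.  Under the rare-interaction assumption the medians
estimate the marginal fitness effects, so normalized null values scatter
around zero.

For each pair the replicate values are then compared by a two-sided
Mann-Whitney U test against the pooled normalized values of all other
pairs sharing the same column (the distribution over A, giving ``p_a``)
and, symmetrically, the same row (``p_b``).  At least 3 replicates per
pair are required; pairs below the floor keep their magnitude columns but
propagate missing p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from pairscreen._common import assemble_results
from pairscreen.lm import default_pseudocount
from pairscreen.screen_io import ResultTable, ScreenTable, ScreenValidationError

__all__ = ["NormalizedMatrix", "median_normalize", "mann_whitney", "ut_analyze"]

#: largest combined sample size for which the exact null distribution of U
#: is enumerated (924 arrangements at 6+6)
EXACT_LIMIT = 12


@dataclass
class NormalizedMatrix:
    """A x B x replicate array of normalized scores with its divisors.

    ``values`` holds the scores after row-median division, column-median
    division and (if ``stage == "log10"``) the log10 transform; missing
    (A, B, replicate) slots are NaN and flagged in ``missing``.
    """

    values: np.ndarray
    row_medians: np.ndarray
    col_medians: np.ndarray
    missing: np.ndarray
    levels_a: list[str]
    levels_b: list[str]
    stage: str = "log10"


def median_normalize(
    table: ScreenTable, pseudocount: float | None = None, log: bool = True
) -> NormalizedMatrix:
    """Sequential row/column median normalization of the screen matrix.

    Rows are A-perturbations, columns B-perturbations; replicate slots are
    filled per pair in measurement order (sub-perturbations and replicate
    indices flattened).  Every value is divided by the median of its row's
    non-missing values, then by its column's median recomputed on the
    row-normalized values (a single pass per axis, not a median polish to
    convergence), then log10-transformed.  After the row step the median
    of each row is exactly 1; the column step leaves a small residual row
    deviation, which is accepted.
    """
    table.validate()
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    df = table.data
    la, lb = table.levels_a, table.levels_b
    ai = pd.Categorical(df["pert_a"], categories=la).codes.astype(np.int64)
    bi = pd.Categorical(df["pert_b"], categories=lb).codes.astype(np.int64)
    slot = df.groupby(["pert_a", "pert_b"], sort=False).cumcount().to_numpy()
    n_rep = int(slot.max()) + 1
    values = np.full((len(la), len(lb), n_rep), np.nan)
    scores = df["score"].to_numpy(dtype=float) + pseudocount
    values[ai, bi, slot] = scores
    missing = np.isnan(values)

    row_med = np.nanmedian(values, axis=(1, 2))
    if np.any(row_med == 0):
        bad = [la[i] for i in np.nonzero(row_med == 0)[0]]
        raise ScreenValidationError(f"zero row median for perturbation(s) {bad}")
    values = values / row_med[:, None, None]
    col_med = np.nanmedian(values, axis=(0, 2))
    if np.any(col_med == 0):
        bad = [lb[j] for j in np.nonzero(col_med == 0)[0]]
        raise ScreenValidationError(f"zero column median for perturbation(s) {bad}")
    values = values / col_med[None, :, None]
    stage = "normalized"
    if log:
        if np.nanmin(values) <= 0:
            raise ScreenValidationError(
                "scores plus pseudocount must be positive for the log10 transform"
            )
        values = np.log10(values)
        stage = "log10"
    return NormalizedMatrix(values, row_med, col_med, missing, la, lb, stage)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x versus y: #(x > y) pairs, ties counted half, via ranks."""
    nx = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def _exact_two_sided(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    nx, n = len(x), len(x) + len(y)
    all_pos = np.arange(1, n + 1, dtype=float)
    offset = nx * (nx + 1) / 2.0
    us = np.fromiter(
        (sum(c) - offset for c in combinations(all_pos, nx)),
        dtype=float,
    )
    total = len(us)
    c_le = int(np.sum(us <= u))
    c_ge = int(np.sum(us >= u))
    return min(1.0, 2.0 * min(c_le, c_ge) / total)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts the (x, y) pairs with x > y (ties
    half).  The p-value is exact by enumeration of all rank assignments
    when the combined sample size is at most 12 and there are no ties,
    otherwise a normal approximation with tie-corrected variance and
    continuity correction is used.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n
    if n <= EXACT_LIMIT and not has_ties:
        return u, _exact_two_sided(x, y, u)
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    z = max(0.0, abs(u - mu) - 0.5) / np.sqrt(var)
    return u, min(1.0, 2.0 * stats.norm.sf(z))


def ut_analyze(
    table: ScreenTable,
    pseudocount: float | None = None,
    combine_method: str = "brown",
    min_replicates: int = 3,
) -> ResultTable:
    """Full rank-test pipeline: normalize, test both directions, combine.

    ``p_a`` of pair (a, b) compares the pair's normalized replicate values
    against all normalized values sharing perturbation b but coming from a
    different A-perturbation; ``p_b`` is the symmetric comparison along
    the row.  Pairs with fewer than ``min_replicates`` values keep their
    magnitudes but report missing p-values and are excluded from the
    combination calibration.
    """
    table.validate()
    nm = median_normalize(table, pseudocount=pseudocount)
    vals = nm.values
    n_a, n_b, _ = vals.shape
    records = []
    for i in range(n_a):
        row_all = vals[i]  # n_b x reps
        for j in range(n_b):
            pair = vals[i, j]
            pair = pair[~np.isnan(pair)]
            if pair.size == 0:
                continue
            if pair.size < min_replicates:
                records.append((nm.levels_a[i], nm.levels_b[j], np.nan, np.nan))
                continue
            col_others = np.delete(vals[:, j, :], i, axis=0).ravel()
            col_others = col_others[~np.isnan(col_others)]
            row_others = np.delete(row_all, j, axis=0).ravel()
            row_others = row_others[~np.isnan(row_others)]
            # a direction with no comparison population (axis level with a
            # single pair) reports a missing p
            p_a = mann_whitney(pair, col_others)[1] if col_others.size else np.nan
            p_b = mann_whitney(pair, row_others)[1] if row_others.size else np.nan
            records.append((nm.levels_a[i], nm.levels_b[j], p_a, p_b))
    pv = pd.DataFrame(records, columns=["pertA", "pertB", "p_a", "p_b"])
    meta = {
        "method": "ut",
        "pseudocount": pseudocount,
        "combine_method": combine_method,
        "min_replicates": min_replicates,
    }
    return assemble_results(
        table,
        pv[["pertA", "pertB", "p_a"]].rename(columns={"p_a": "p"}),
        pv[["pertA", "pertB", "p_b"]].rename(columns={"p_b": "p"}),
        combine_method=combine_method,
        meta=meta,
    )
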