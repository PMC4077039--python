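"""Pre-analysis removal of technically noisy perturbations.

Because genuine interactions are rare, the fitness profile of any one
perturbation across the other axis should correlate well with the profiles
of its peers; a profile dominated by technical noise does not.  For every
perturbation on an axis we build the profile vector of replicate-mean log
scores across the other axis, compute all pairwise Spearman correlations on
shared positions, and summarize each perturbation by the median of its
correlations with all others.  Cutoffs can then be applied independently
per axis to drop low-correlation perturbations before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pairscreen.lm import default_pseudocount
from pairscreen.screen_io import ScreenTable, ScreenValidationError

__all__ = [
    "CorrelationReport",
    "spearman",
    "correlation_report",
    "apply_cutoffs",
    "correlation_histogram",
]

#: minimum shared observations for a pairwise correlation to count
MIN_SHARED = 3


@dataclass
class CorrelationReport:
    """Pairwise Spearman correlations of one axis's perturbation profiles.

    ``pair_matrix[i, j]`` is the Spearman correlation of the profiles of
    perturbations i and j over their shared positions (NaN when fewer than
    three positions are shared); ``n_common`` counts those positions.
    ``per_perturbation`` maps each identifier to its summary correlation,
    the median of its defined correlations with all other perturbations.
    """

    axis: str
    identifiers: list[str]
    pair_matrix: np.ndarray
    n_common: np.ndarray
    per_perturbation: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": self.axis,
                "identifier": self.identifiers,
                "summary_correlation": [
                    self.per_perturbation[i] for i in self.identifiers
                ],
            }
        )


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Missing entries are removed pairwise; fewer than three complete pairs
    yield NaN (undefined, flagged rather than raised).  Equals the Pearson
    correlation of the average-rank vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < MIN_SHARED:
        return float("nan")
    rho = stats.spearmanr(x[ok], y[ok]).statistic
    return float(rho)


def correlation_report(
    table: ScreenTable, axis: str = "A", pseudocount: float | None = None
) -> CorrelationReport:
    """All pairwise profile correlations for one perturbation axis.

    The profile of a perturbation is the vector of replicate-mean
    log-transformed scores indexed by the other axis's levels; pairs of
    profiles sharing fewer than three positions contribute no correlation.
    """
    if axis not in ("A", "B"):
        raise ValueError("axis must be 'A' or 'B'")
    own, other = ("pert_a", "pert_b") if axis == "A" else ("pert_b", "pert_a")
    df = table.data
    if df[own].nunique() < 3:
        raise ScreenValidationError(
            f"axis {axis} needs at least 3 perturbations for a correlation report"
        )
    if pseudocount is None:
        pseudocount = default_pseudocount(table)
    log_score = np.log(df["score"].to_numpy(dtype=float) + pseudocount)
    prof = (
        pd.DataFrame({own: df[own], other: df[other], "v": log_score})
        .groupby([own, other], sort=True)["v"]
        .mean()
        .unstack(other)
    )  # rows: this axis; columns: profile positions
    ids = list(prof.index)
    mat = prof.to_numpy()
    n = len(ids)
    pair = np.full((n, n), np.nan)
    ncom = np.zeros((n, n), dtype=int)
    present = ~np.isnan(mat)
    for i in range(n):
        pair[i, i] = 1.0
        ncom[i, i] = int(present[i].sum())
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            ncom[i, j] = ncom[j, i] = int(shared.sum())
            rho = spearman(mat[i], mat[j])
            pair[i, j] = pair[j, i] = rho
    summary = {}
    for i, ident in enumerate(ids):
        others = np.delete(pair[i], i)
        others = others[~np.isnan(others)]
        summary[ident] = float(np.median(others)) if others.size else float("nan")
    return CorrelationReport(axis, ids, pair, ncom, summary)


def apply_cutoffs(
    table: ScreenTable,
    report_a: CorrelationReport,
    report_b: CorrelationReport,
    cutoff_a: float,
    cutoff_b: float,
) -> ScreenTable:
    """Drop all measurements of perturbations below their axis cutoff.

    A measurement is removed when its A-perturbation's summary correlation
    is below ``cutoff_a`` or its B-perturbation's is below ``cutoff_b``.
    Removed identifiers are recorded in the returned table's ``meta``.
    Applying the same cutoffs twice is a no-op the second time.
    """
    if report_a.axis != "A" or report_b.axis != "B":
        raise ValueError("pass the axis-A report first and the axis-B report second")
    drop_a = {i for i, c in report_a.per_perturbation.items() if c < cutoff_a}
    drop_b = {i for i, c in report_b.per_perturbation.items() if c < cutoff_b}
    df = table.data
    keep = ~(df["pert_a"].isin(drop_a) | df["pert_b"].isin(drop_b))
    kept = df[keep]
    if kept.empty or kept["pert_a"].nunique() < 2 or kept["pert_b"].nunique() < 2:
        raise ScreenValidationError(
            "cutoffs remove too many perturbations "
            f"(A cutoff {cutoff_a}, B cutoff {cutoff_b}); choose lower cutoffs"
        )
    meta = dict(table.meta)
    meta["prefilter"] = {
        "cutoff_a": cutoff_a,
        "cutoff_b": cutoff_b,
        "removed_a": sorted(drop_a & set(df["pert_a"])),
        "removed_b": sorted(drop_b & set(df["pert_b"])),
    }
    return ScreenTable(kept.copy(), meta).validate()


def correlation_histogram(report: CorrelationReport, ax=None, bins: int = 30):
    """Histogram of an axis's summary correlations (cutoff-picking aid)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = [v for v in report.per_perturbation.values() if np.isfinite(v)]
    ax.hist(values, bins=bins, color="steelblue", edgecolor="white")
    ax.set_xlabel(f"summary Spearman correlation (axis {report.axis})")
    ax.set_ylabel("perturbations")
    return ax
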