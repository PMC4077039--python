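"""Shared helpers: effect magnitudes and result-table assembly.

Both analysis models report the same four magnitude columns per (A, B)
pair, computed from the raw (untransformed) scores:

* ``rel_mag_a`` -- mean pair signal divided by the median of the mean pair
  signals over all A-perturbations at the same B (treatment vs the median
  of all treatments); ``rel_mag_b`` is the symmetric ratio over B at
  fixed A.
* ``abs_mag_a`` -- mean raw assay signal of the A-perturbation across the
  whole screen (mean Luminex signal or mean read count), used downstream to
  filter out low-abundance barcodes; ``abs_mag_b`` symmetric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pairscreen import pcombine
from pairscreen.screen_io import RESULT_COLUMNS, ResultTable, ScreenTable

__all__ = ["pair_magnitudes", "assemble_results"]


def pair_magnitudes(table: ScreenTable) -> pd.DataFrame:
    """Per-pair relative and absolute magnitudes from raw scores.

    Returns a frame with columns ``pertA, pertB, rel_mag_a, rel_mag_b,
    abs_mag_a, abs_mag_b``, one row per observed pair, sorted by pair.
    """
    df = table.data
    pair_mean = (
        df.groupby(["pert_a", "pert_b"], sort=True)["score"].mean().rename("pair_mean")
    )
    out = pair_mean.reset_index()
    # median over all A of the pair means at the same B, and vice versa
    med_at_b = out.groupby("pert_b")["pair_mean"].transform("median")
    med_at_a = out.groupby("pert_a")["pair_mean"].transform("median")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rel_mag_a"] = out["pair_mean"] / med_at_b
        out["rel_mag_b"] = out["pair_mean"] / med_at_a
    marg_a = df.groupby("pert_a")["score"].mean()
    marg_b = df.groupby("pert_b")["score"].mean()
    out["abs_mag_a"] = out["pert_a"].map(marg_a)
    out["abs_mag_b"] = out["pert_b"].map(marg_b)
    return out.rename(columns={"pert_a": "pertA", "pert_b": "pertB"})[
        ["pertA", "pertB", "rel_mag_a", "rel_mag_b", "abs_mag_a", "abs_mag_b"]
    ]


#: floor applied to computed p-values so that log-based combination stays finite
P_FLOOR = 1e-300


def assemble_results(
    table: ScreenTable,
    p_a: pd.DataFrame,
    p_b: pd.DataFrame,
    combine_method: str = "brown",
    meta: dict | None = None,
) -> ResultTable:
    """Merge magnitudes with directional p-values and combine them.

    ``p_a`` / ``p_b`` are frames with columns ``pertA, pertB, p``; pairs
    absent from either frame, or with a missing p, get a missing combined
    p-value but keep their magnitude columns.
    """
    out = pair_magnitudes(table)
    out = out.merge(
        p_a.rename(columns={"p": "p_a"}), on=["pertA", "pertB"], how="left"
    )
    out = out.merge(
        p_b.rename(columns={"p": "p_b"}), on=["pertA", "pertB"], how="left"
    )
    for col in ("p_a", "p_b"):
        out[col] = out[col].clip(lower=P_FLOOR)
    out["p_combined"] = pcombine.combine(
        out["p_a"].to_numpy(), out["p_b"].to_numpy(), method=combine_method
    )
    result = ResultTable(out[RESULT_COLUMNS], dict(meta or {}))
    return result.validate()
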