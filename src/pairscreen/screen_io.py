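"""Canonical data model and readers/writers for screen tables and results.

The canonical long-format input is a semicolon-separated table with up to
five columns::

    perturbation A; perturbation B; fitness score; replicate 1; replicate 2

``replicate 1`` groups multiple perturbations aimed at the same outcome
(e.g. several hairpins targeting one gene); ``replicate 2`` indexes repeat
measurements of the same (A, B) combination.  Three-column files carry only
``A; B; score`` and duplicated identifier rows are automatically interpreted
as replicate measurements.

Two technology-specific importers reduce raw exports to this format:
bead-level Luminex xMAP tables (trimmed mean per pair) and sequencing count
tables (``cell line; shRNA; number of reads``).

Analysis output is a nine-column semicolon-separated results file, one row
per (A, B) pair::

    pertA; pertB; rel_mag_a; rel_mag_b; abs_mag_a; abs_mag_b; p_a; p_b; p_combined

Externally produced files in the same layout can be read back for filtering
and plotting.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ScreenFormatError",
    "ScreenValidationError",
    "Measurement",
    "ScreenTable",
    "ResultTable",
    "RESULT_COLUMNS",
    "SCREEN_COLUMNS",
    "read_screen_csv",
    "import_luminex",
    "import_mps",
    "write_screen_csv",
    "write_results",
    "read_results",
    "trimmed_mean",
    "n_measurements",
    "reads_per_barcode",
]

SCREEN_COLUMNS = ["pert_a", "pert_b", "score", "rep1", "rep2"]

#: Canonical result columns, in file order.
RESULT_COLUMNS = [
    "pertA",
    "pertB",
    "rel_mag_a",
    "rel_mag_b",
    "abs_mag_a",
    "abs_mag_b",
    "p_a",
    "p_b",
    "p_combined",
]

_DIALECTS = {"semicolon": ";", "comma": ",", "tab": "\t"}


class ScreenFormatError(ValueError):
    """A file does not conform to the expected column layout."""


class ScreenValidationError(ValueError):
    """Parsed data violates a screen-table invariant."""


@dataclass(frozen=True)
class Measurement:
    """One fitness measurement of a perturbation pair.

    Attributes
    ----------
    pert_a, pert_b : str
        Identifiers of the two perturbations (e.g. cell line and drug).
    score : float
        Non-negative barcode-abundance fitness proxy (Luminex trimmed-mean
        intensity or sequencing read count).
    rep1 : str
        Sub-perturbation identifier grouping multiple perturbations toward
        the same outcome (e.g. hairpin ID within a gene).
    rep2 : int
        Replicate index of the (A, B, rep1) combination, 1-based.
    """

    pert_a: str
    pert_b: str
    score: float
    rep1: str = "1"
    rep2: int = 1


@dataclass
class ScreenTable:
    """Long-format screen measurement table.

    Wraps a :class:`pandas.DataFrame` with columns ``pert_a, pert_b, score,
    rep1, rep2`` plus a free-form provenance ``meta`` mapping.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ScreenValidationError(f"missing screen columns: {missing}")
        self.data = self.data[SCREEN_COLUMNS].reset_index(drop=True)

    # -- convenience accessors -------------------------------------------
    @property
    def levels_a(self) -> list[str]:
        return sorted(self.data["pert_a"].unique())

    @property
    def levels_b(self) -> list[str]:
        return sorted(self.data["pert_b"].unique())

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_measurements(
        cls, measurements: Iterable[Measurement], meta: dict | None = None
    ) -> "ScreenTable":
        df = pd.DataFrame([m.__dict__ for m in measurements])
        return cls(df, meta or {})

    def validate(self) -> "ScreenTable":
        """Check screen-table invariants; return self or raise."""
        df = self.data
        if len(df) == 0:
            raise ScreenValidationError("screen table is empty")
        scores = df["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ScreenValidationError("scores must be finite")
        if np.any(scores < 0):
            raise ScreenValidationError("scores must be non-negative")
        if df["pert_a"].nunique() < 2 or df["pert_b"].nunique() < 2:
            raise ScreenValidationError(
                "need at least 2 distinct perturbations on each axis "
                "(downstream normalization estimates per-level effects)"
            )
        if df.duplicated(subset=["pert_a", "pert_b", "rep1", "rep2"]).any():
            raise ScreenValidationError(
                "(pert_a, pert_b, rep1, rep2) must be jointly unique"
            )
        # rep2 must form 1..n without gaps within each (A, B, rep1) group
        grp = df.groupby(["pert_a", "pert_b", "rep1"], sort=False)["rep2"]
        sizes = grp.size()
        if not ((grp.min() == 1).all() and (grp.max() == sizes).all()):
            raise ScreenValidationError("rep2 indices must form 1..n with no gaps")
        return self


@dataclass
class ResultTable:
    """One row per (A, B) pair: magnitudes and directional/combined p-values."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ScreenValidationError(f"missing result columns: {missing}")
        self.data = self.data[RESULT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> "ResultTable":
        df = self.data
        if df.duplicated(subset=["pertA", "pertB"]).any():
            raise ScreenValidationError("one record per (pertA, pertB) pair required")
        for col in ("p_a", "p_b", "p_combined"):
            p = df[col].to_numpy(dtype=float)
            ok = np.isnan(p) | ((p > 0) & (p <= 1))
            if not ok.all():
                raise ScreenValidationError(f"{col} values must lie in (0, 1]")
        return self


# ---------------------------------------------------------------------------
# helpers


def n_measurements(n_a: int, n_b: int, n_replicates: int = 1) -> int:
    """Number of measurements for a full A x B screen in ``n_replicates``.

    A screen of 100 genes against 100 drugs in quadruplicate requires
    ``n_measurements(100, 100, 4) == 40_000`` measurements.
    """
    if n_a < 1 or n_b < 1 or n_replicates < 1:
        raise ValueError("screen dimensions must be positive")
    return n_a * n_b * n_replicates


def reads_per_barcode(total_reads: float, n_a: int, n_b: int) -> float:
    """Average sequencing depth per barcode for a pooled A x B screen.

    A run yielding 1e8 aligned reads over 100 x 100 barcodes gives an
    average depth of 10,000 reads per barcode.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("screen dimensions must be positive")
    return total_reads / (n_a * n_b)


def trimmed_mean(values: np.ndarray, trim_fraction: float) -> float:
    """Symmetric trimmed mean: drop ``floor(k * trim_fraction)`` per tail."""
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    v = np.sort(np.asarray(values, dtype=float))
    k = len(v)
    drop = int(math.floor(k * trim_fraction))
    kept = v[drop : k - drop]
    if kept.size == 0:
        raise ScreenValidationError("no bead values survive trimming")
    return float(kept.mean())


def _read_rows(path: str | Path, delim: str) -> list[tuple[int, list[str]]]:
    """Read non-blank CSV rows as (1-based physical line number, fields)."""
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, fields in enumerate(csv.reader(fh, delimiter=delim), start=1):
            fields = [f.strip() for f in fields]
            if not fields or all(f == "" for f in fields):
                continue
            rows.append((lineno, fields))
    return rows


def _parse_score(text: str, lineno: int, what: str = "score") -> float:
    try:
        value = float(text)
    except ValueError:
        raise ScreenFormatError(
            f"line {lineno}: {what} field {text!r} is not numeric"
        ) from None
    if not math.isfinite(value):
        raise ScreenFormatError(f"line {lineno}: {what} must be finite")
    if value < 0:
        raise ScreenFormatError(f"line {lineno}: {what} must be non-negative")
    return value


def _is_header(fields: list[str], score_index: int) -> bool:
    if score_index >= len(fields):
        return False
    try:
        float(fields[score_index])
        return False
    except ValueError:
        return True


def _autonumber_rep2(df: pd.DataFrame) -> pd.Series:
    """Assign rep2 = 1..n within (pert_a, pert_b, rep1) by file order."""
    return df.groupby(["pert_a", "pert_b", "rep1"], sort=False).cumcount() + 1


# ---------------------------------------------------------------------------
# readers


def read_screen_csv(path: str | Path, dialect: str = "semicolon") -> ScreenTable:
    """Read a canonical screen table (3, 4 or 5 columns).

    Columns map positionally to ``pert_a, pert_b, score, rep1, rep2``.
    Three-column files get ``rep1 = "1"``; missing ``rep2`` is assigned by
    duplicate order, so repeated (A, B, rep1) identifier rows become
    successive replicate measurements.  An optional header row is detected
    as a first row whose score field does not parse as a number.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {list(_DIALECTS)}")
    rows = _read_rows(path, _DIALECTS[dialect])
    if not rows:
        raise ScreenFormatError(f"{path}: empty input file")
    ncol = len(rows[0][1])
    if not 3 <= ncol <= 5:
        raise ScreenFormatError(
            f"{path}: expected 3 to 5 columns "
            "(perturbation A; perturbation B; score[; replicate 1[; replicate 2]]), "
            f"got {ncol}"
        )
    has_header = _is_header(rows[0][1], score_index=2)
    data_rows = rows[1:] if has_header else rows

    records = []
    for lineno, fields in data_rows:
        if len(fields) != ncol:
            raise ScreenFormatError(
                f"line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        score = _parse_score(fields[2], lineno)
        rep1 = fields[3] if ncol >= 4 else "1"
        rep2: int | None = None
        if ncol == 5:
            try:
                rep2 = int(fields[4])
            except ValueError:
                raise ScreenFormatError(
                    f"line {lineno}: replicate 2 field {fields[4]!r} is not an integer"
                ) from None
        records.append((fields[0], fields[1], score, rep1, rep2))

    if not records:
        raise ScreenFormatError(f"{path}: no data rows")
    df = pd.DataFrame(records, columns=SCREEN_COLUMNS)
    meta = {
        "source_file": str(path),
        "importer": "read_screen_csv",
        "dialect": dialect,
        "header": has_header,
    }
    if ncol < 5:
        df["rep2"] = _autonumber_rep2(df)
    else:
        df["rep2"] = df["rep2"].astype(int)
        dup = df.duplicated(subset=["pert_a", "pert_b", "rep1", "rep2"])
        if dup.any():
            # non-unique identifiers are replicate measurements: renumber
            df = df.sort_values("rep2", kind="stable")
            df["rep2"] = _autonumber_rep2(df)
            df = df.sort_index()
            meta["rep2_renumbered"] = True
    return ScreenTable(df, meta).validate()


def import_luminex(
    path: str | Path,
    trim_fraction: float = 0.25,
    dialect: str = "semicolon",
) -> ScreenTable:
    """Reduce a bead-level Luminex xMAP export to one score per pair.

    Input rows are ``cell line; drug; bead value`` with many bead rows per
    (cell line, drug) pair.  Bead values of each pair are sorted,
    ``floor(k * trim_fraction)`` values are dropped from each tail, and the
    mean of the remainder becomes the measurement score.  An optional fourth
    column names a replicate; bead groups are then trimmed per replicate and
    the replicates become successive ``rep2`` indices.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    rows = _read_rows(path, _DIALECTS[dialect])
    if not rows:
        raise ScreenFormatError(f"{path}: empty input file")
    ncol = len(rows[0][1])
    if ncol not in (3, 4):
        raise ScreenFormatError(
            f"{path}: expected 'cell line; drug; bead value[; replicate]', got {ncol} columns"
        )
    has_header = _is_header(rows[0][1], score_index=2)
    data_rows = rows[1:] if has_header else rows

    # group beads by (cell, drug[, replicate]) preserving first appearance
    groups: dict[tuple, list[float]] = {}
    for lineno, fields in data_rows:
        if len(fields) != ncol:
            raise ScreenFormatError(
                f"line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        bead = _parse_score(fields[2], lineno, what="bead value")
        key = (fields[0], fields[1], fields[3] if ncol == 4 else "")
        groups.setdefault(key, []).append(bead)
    if not groups:
        raise ScreenFormatError(f"{path}: no data rows")

    records = []
    for (cell, drug, _rep), beads in groups.items():
        score = trimmed_mean(np.asarray(beads), trim_fraction)
        records.append((cell, drug, score, "1", None))
    df = pd.DataFrame(records, columns=SCREEN_COLUMNS)
    df["rep2"] = _autonumber_rep2(df)
    meta = {
        "source_file": str(path),
        "importer": "import_luminex",
        "trim_fraction": trim_fraction,
    }
    return ScreenTable(df, meta).validate()


def import_mps(path: str | Path, gene_delimiter: str = "_") -> ScreenTable:
    """Import a sequencing count table ``cell line; shRNA; number of reads``.

    ``pert_a`` is the cell line; ``pert_b`` is the target gene parsed from
    the shRNA name (the substring before the first ``gene_delimiter``, or
    the whole name if absent); ``rep1`` keeps the full shRNA name so that
    several hairpins against one gene are grouped as sub-perturbations.
    Zero counts are retained (a pseudocount is applied later, at log
    transformation).
    """
    rows = _read_rows(path, _DIALECTS["semicolon"])
    if not rows:
        raise ScreenFormatError(f"{path}: empty input file")
    if len(rows[0][1]) != 3:
        raise ScreenFormatError(
            f"{path}: expected 'cell line; shRNA; number of reads', got "
            f"{len(rows[0][1])} columns"
        )
    has_header = _is_header(rows[0][1], score_index=2)
    data_rows = rows[1:] if has_header else rows

    records = []
    for lineno, fields in data_rows:
        if len(fields) != 3:
            raise ScreenFormatError(
                f"line {lineno}: expected 3 fields, got {len(fields)}"
            )
        try:
            count = int(fields[2])
        except ValueError:
            raise ScreenFormatError(
                f"line {lineno}: read count {fields[2]!r} is not an integer"
            ) from None
        if count < 0:
            raise ScreenFormatError(f"line {lineno}: read count must be non-negative")
        shrna = fields[1]
        gene = shrna.split(gene_delimiter, 1)[0] if gene_delimiter in shrna else shrna
        records.append((fields[0], gene, float(count), shrna, None))
    if not records:
        raise ScreenFormatError(f"{path}: no data rows")
    df = pd.DataFrame(records, columns=SCREEN_COLUMNS)
    df["rep2"] = _autonumber_rep2(df)
    meta = {
        "source_file": str(path),
        "importer": "import_mps",
        "gene_delimiter": gene_delimiter,
    }
    return ScreenTable(df, meta).validate()


def write_screen_csv(
    table: ScreenTable, path: str | Path, dialect: str = "semicolon"
) -> None:
    """Write a screen table in the canonical five-column layout."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {list(_DIALECTS)}")
    table.validate()
    table.data.to_csv(path, sep=_DIALECTS[dialect], index=False, header=False)


# ---------------------------------------------------------------------------
# results file


def write_results(results: ResultTable, path: str | Path) -> None:
    """Write the nine-column semicolon-separated results file.

    Floats are written at full precision so a round trip through
    :func:`read_results` reproduces the table beyond 12 significant digits.
    """
    results.validate()
    results.data.to_csv(path, sep=";", index=False, columns=RESULT_COLUMNS)


def read_results(path: str | Path) -> ResultTable:
    """Read a nine-column results file (own output or externally produced)."""
    try:
        df = pd.read_csv(
            path, sep=";", header=0, dtype={0: str, 1: str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise ScreenFormatError(f"{path}: empty results file") from None
    if df.shape[1] != len(RESULT_COLUMNS):
        raise ScreenFormatError(
            f"{path}: expected {len(RESULT_COLUMNS)} semicolon-separated columns "
            f"({'; '.join(RESULT_COLUMNS)}), got {df.shape[1]}"
        )
    df.columns = RESULT_COLUMNS
    for col in RESULT_COLUMNS[2:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("p_a", "p_b", "p_combined"):
        p = df[col].to_numpy(dtype=float)
        bad = ~np.isnan(p) & ((p <= 0) | (p > 1))
        if bad.any():
            warnings.warn(
                f"{path}: {int(bad.sum())} {col} values outside (0, 1]; rows kept",
                stacklevel=2,
            )
    meta = {"source_file": str(path), "importer": "read_results", "source": "external"}
    return ResultTable(df, meta)
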