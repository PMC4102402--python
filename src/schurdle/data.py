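"""Long-format single-cell expression tables and gene metadata.

The central container is :class:`CellTable`, a validated long-format table
with one row per cell x gene carrying the raw log2 count (``lcount``), the
plate-normalized log2 count (``ncount``), the thresholded expression value
(``et``, where 0 encodes "no detectable expression") and per-cell
annotations (cycle phase, cell line, plate, fraction of genes detected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical phase ordering used for reference levels and tie-breaking
PHASE_ORDER = ("G0/G1", "S", "G2/M")

# external (file) column names -> internal names
_S2_COLUMNS = {
    "CellID": "cell_id",
    "cycle": "cycle",
    "cellline": "cell_line",
    "plate": "plate",
    "platerow": "plate_row",
    "ngeneson": "ngeneson",
    "primerid": "gene_id",
    "et": "et",
    "lCount": "lcount",
    "nCount": "ncount",
}
_INTERNAL_TO_S2 = {v: k for k, v in _S2_COLUMNS.items()}

_S1_COLUMNS = {
    "primerid": "gene_id",
    "cbRank": "cb_rank",
    "cbPeaktime": "cb_peaktime",
    "expPeaktime": "exp_peaktime",
    "pvalue": "neg_log10_p",
}

REQUIRED = ("cell_id", "gene_id")
OPTIONAL_EXPR = ("lcount", "ncount", "et")
OPTIONAL_META = ("cycle", "cell_line", "plate", "plate_row", "ngeneson")


class DuplicateRecordError(ValueError):
    """A (cell_id, gene_id) pair occurs more than once."""


@dataclass
class CellTable:
    """Validated long-format cell x gene expression table.

    Parameters
    ----------
    df : pandas.DataFrame
        Long-format table with internal column names. Must contain
        ``cell_id`` and ``gene_id`` plus at least one expression column.
    """

    df: pd.DataFrame
    absent: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for col in REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"required column {col!r} missing")
        if not any(c in self.df.columns for c in OPTIONAL_EXPR):
            raise ValueError("need at least one expression column (lcount/ncount/et)")
        dup = self.df.duplicated(subset=["cell_id", "gene_id"])
        if dup.any():
            first = self.df.loc[dup.idxmax(), ["cell_id", "gene_id"]]
            raise DuplicateRecordError(
                f"duplicate record for cell {first['cell_id']!r}, gene {first['gene_id']!r}"
            )
        self.absent = tuple(
            c for c in OPTIONAL_EXPR + OPTIONAL_META if c not in self.df.columns
        )
        if "et" in self.df.columns:
            et = self.df["et"].to_numpy(float)
            if np.nanmin(et) < -1e-9:
                raise ValueError("et must be nonnegative (0 = no detectable expression)")

    # -- basic properties ------------------------------------------------
    @property
    def cells(self) -> np.ndarray:
        return np.asarray(sorted(self.df["cell_id"].unique()))

    @property
    def genes(self) -> np.ndarray:
        return np.asarray(sorted(self.df["gene_id"].unique()))

    @property
    def n_cells(self) -> int:
        return self.df["cell_id"].nunique()

    @property
    def n_genes(self) -> int:
        return self.df["gene_id"].nunique()

    def has(self, col: str) -> bool:
        return col in self.df.columns

    def require(self, *cols: str) -> None:
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"stage requires missing column(s): {', '.join(missing)}")

    def wide(self, value: str = "et") -> pd.DataFrame:
        """Cells x genes matrix of one value column."""
        self.require(value)
        return self.df.pivot(index="cell_id", columns="gene_id", values=value)

    def cell_meta(self) -> pd.DataFrame:
        """One row per cell with its annotation columns."""
        cols = [c for c in OPTIONAL_META if c in self.df.columns]
        return self.df.groupby("cell_id", sort=True)[cols].first() if cols else (
            pd.DataFrame(index=pd.Index(self.cells, name="cell_id"))
        )

    def with_column(self, name: str, values: pd.Series | np.ndarray) -> "CellTable":
        df = self.df.copy()
        df[name] = np.asarray(values)
        return CellTable(df)

    def subset(self, cells=None, genes=None) -> "CellTable":
        df = self.df
        if cells is not None:
            df = df[df["cell_id"].isin(set(cells))]
        if genes is not None:
            df = df[df["gene_id"].isin(set(genes))]
        return CellTable(df.reset_index(drop=True))


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_cell_table(path, dialect: str | None = None) -> CellTable:
    """Read a long-format expression table (CSV, or TSV auto-detected).

    Accepts either the published S2-style header (CellID, cellline,
    primerid, lCount, nCount, ...) or internal names. If a raw ``count``
    column is given instead of ``lcount``, the shifted log2 transform
    ``lcount = log2(count + 1)`` is applied at ingest. Missing optional
    columns are flagged absent rather than fabricated.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect) or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    df = df.rename(columns={c: _S2_COLUMNS.get(c, c) for c in df.columns})
    if "lcount" not in df.columns and "count" in df.columns:
        df["lcount"] = np.log2(df["count"].to_numpy(float) + 1.0)
        df = df.drop(columns=["count"])
    table = CellTable(df)
    known_phases = set(PHASE_ORDER)
    if table.has("cycle"):
        unknown = set(df["cycle"].dropna().unique()) - known_phases
        if unknown:
            warnings.warn(
                f"unrecognized phase label(s) {sorted(map(str, unknown))}; "
                "treated as additional factor levels"
            )
    return table


def write_cell_table(table: CellTable, path) -> None:
    """Write in the S2 column layout at full precision (round-trip safe)."""
    df = table.df.rename(columns=_INTERNAL_TO_S2)
    order = [c for c in _S2_COLUMNS if c in df.columns]
    order += [c for c in df.columns if c not in order]
    df[order].to_csv(path, index=False, float_format="%.17g")


@dataclass
class GeneMeta:
    """Per-gene external annotation (Cyclebase-style rank and peak time)."""

    gene_id: str
    cb_rank: float | None = None
    cb_peaktime: float | None = None  # 0 = G0, 100 = M
    exp_peaktime: str | None = None
    neg_log10_p: float | None = None
    flagged_missing: bool = False

    @property
    def ranked(self) -> bool:
        return self.cb_rank is not None and self.cb_rank < 1000


def read_gene_meta(path, cell_table: CellTable | None = None) -> dict[str, GeneMeta]:
    """Read gene metadata (S1 layout); NA ranks map to unranked genes."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.empty and "gene_id" not in df.columns and "primerid" not in df.columns:
        return {}
    df = df.rename(columns={c: _S1_COLUMNS.get(c, c) for c in df.columns})
    known = set(cell_table.genes) if cell_table is not None else None
    out: dict[str, GeneMeta] = {}
    for _, row in df.iterrows():
        g = str(row["gene_id"])
        rank = row.get("cb_rank")
        peak = row.get("cb_peaktime")
        out[g] = GeneMeta(
            gene_id=g,
            cb_rank=None if pd.isna(rank) else float(rank),
            cb_peaktime=None if pd.isna(peak) else float(peak),
            exp_peaktime=None if pd.isna(row.get("exp_peaktime")) else str(row.get("exp_peaktime")),
            neg_log10_p=None if pd.isna(row.get("neg_log10_p")) else float(row.get("neg_log10_p")),
            flagged_missing=(known is not None and g not in known),
        )
    return out


def peaktime_phase(cb_peaktime: float, boundaries: tuple[float, float] = (100 / 3, 200 / 3)) -> str:
    """Bin a 0-100 peak time into a phase label (thirds by default)."""
    if cb_peaktime < boundaries[0]:
        return PHASE_ORDER[0]
    if cb_peaktime < boundaries[1]:
        return PHASE_ORDER[1]
    return PHASE_ORDER[2]
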