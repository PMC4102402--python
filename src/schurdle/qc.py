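"""Per-cell nuisance covariates and cell/gene quality-control filters.

The fraction of panel genes detected in a cell (``ngeneson``) proxies
per-cell reverse-transcription / pre-amplification efficiency and is
highly correlated with the cell's log-sum of expression (the analog of
log-total read count in RNA-seq); it is carried downstream as an
adjustment covariate. Cells with no expression, or outlying in expression
proportion and positive-expression mean under robust z-scoring, are
removed, followed by genes with detectable expression below a frequency
floor in any cell line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CellTable

__all__ = [
    "compute_ngeneson",
    "compute_logsum",
    "filter_cells",
    "filter_genes",
    "apply_qc",
]

#: normal-consistency constant for the median absolute deviation
MAD_SCALE = 1.4826


def compute_ngeneson(table: CellTable) -> pd.Series:
    """Fraction of assayed genes with et > 0, per cell."""
    table.require("et")
    df = table.df
    return df.groupby("cell_id", sort=True)["et"].apply(lambda v: float((v > 0).mean()))


def attach_ngeneson(table: CellTable) -> CellTable:
    """Recompute ngeneson from et and attach it to every record."""
    ng = compute_ngeneson(table)
    return table.with_column("ngeneson", table.df["cell_id"].map(ng).to_numpy())


def compute_logsum(table: CellTable) -> pd.Series:
    """log2 of each cell's summed un-thresholded counts (sum of 2^lcount - 1).

    Cells with zero total count get NaN (log of zero is undefined).
    """
    table.require("lcount")
    df = table.df
    total = df.groupby("cell_id", sort=True)["lcount"].apply(
        lambda v: float(np.sum(np.exp2(v.to_numpy(float)) - 1.0))
    )
    with np.errstate(divide="ignore"):
        return pd.Series(np.where(total > 0, np.log2(total.clip(lower=1e-300)), np.nan),
                         index=total.index)


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med)) * MAD_SCALE
    if mad == 0:
        warnings.warn("MAD is zero; falling back to standard deviation")
        sd = np.nanstd(values)
        if sd == 0:
            return np.zeros_like(values, dtype=float)
        return (values - med) / sd
    return (values - med) / mad


@dataclass
class CellFilterResult:
    kept: list
    removed: pd.DataFrame  # cell_id, reason


def filter_cells(
    table: CellTable,
    n_outlier: int = 2,
    sigma_proportion: float = 2.0,
    sigma_continuous: float = 5.0,
) -> CellFilterResult:
    """Remove empty wells and robustly outlying cells.

    A cell is removed unconditionally when it expresses no gene, and
    otherwise when it is flagged on at least ``n_outlier`` of the two
    outlier criteria: |robust z| of its expression proportion exceeding
    ``sigma_proportion``, and |robust z| of its positive-expression mean
    exceeding ``sigma_continuous``. With the default n_outlier = 2 both
    criteria must fire for removal. Robust z uses median/MAD with the
    1.4826 normal-consistency constant.
    """
    table.require("et")
    df = table.df
    per_cell = df.groupby("cell_id", sort=True)["et"].agg(
        prop=lambda v: float((v > 0).mean()),
        pem=lambda v: float(v[v > 0].mean()) if (v > 0).any() else np.nan,
    )
    z_prop = _robust_z(per_cell["prop"].to_numpy())
    z_pem = _robust_z(per_cell["pem"].to_numpy())
    removals = []
    kept = []
    for i, (cell, row) in enumerate(per_cell.iterrows()):
        if row["prop"] == 0:
            removals.append((cell, "no expression"))
            continue
        fired = []
        if abs(z_prop[i]) > sigma_proportion:
            fired.append("proportion outlier")
        if np.isfinite(z_pem[i]) and abs(z_pem[i]) > sigma_continuous:
            fired.append("continuous outlier")
        if len(fired) >= n_outlier:
            removals.append((cell, " + ".join(fired)))
        else:
            kept.append(cell)
    removed = pd.DataFrame(removals, columns=["cell_id", "reason"])
    return CellFilterResult(kept=kept, removed=removed)


def filter_genes(table: CellTable, min_freq: float = 0.01) -> list:
    """Retain genes with expression frequency >= min_freq in every cell line."""
    table.require("et", "cell_line")
    df = table.df
    freq = df.assign(on=df["et"] > 0).groupby(["gene_id", "cell_line"])["on"].mean()
    by_gene = freq.groupby(level="gene_id").min()
    return sorted(by_gene.index[by_gene >= min_freq])


def apply_qc(
    table: CellTable,
    n_outlier: int = 2,
    sigma_proportion: float = 2.0,
    sigma_continuous: float = 5.0,
    min_freq: float = 0.01,
) -> tuple[CellTable, CellFilterResult, list]:
    """Cell filtering, then gene filtering on the retained cells.

    Gene expression frequencies are evaluated after outlying cells are
    removed, matching the order in which the filters are defined. The
    ngeneson covariate is recomputed on the retained panel.
    """
    cell_res = filter_cells(table, n_outlier, sigma_proportion, sigma_continuous)
    kept_cells = table.subset(cells=cell_res.kept)
    genes = filter_genes(kept_cells, min_freq=min_freq)
    out = kept_cells.subset(genes=genes)
    out = attach_ngeneson(out)
    return out, cell_res, genes
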