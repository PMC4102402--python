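"""Plate-location normalization of log counts.

Plates (96-well PCR batches) shift the locations of the signal and noise
clusters. Within each experimental batch (plates run on the same date),
preliminary signal/noise cluster labels are obtained from the
empirical-Bayes thresholding, a linear model

    lcount ~ gene + cluster + plate:cluster

is fitted, and each record is corrected by its plate's deviation of the
cluster intercept from the across-plate mean — a non-pooled, location-only
analog of ComBat. Finally each gene is translated so its minimum
normalized value is exactly zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import CellTable
from .thresholding import (
    build_prior,
    fit_gene_map,
    fit_omnibus_mixture,
    posterior_signal_prob,
)

__all__ = [
    "preliminary_cluster",
    "align_plates",
    "translate_min_zero",
    "normalize_table",
]


def _batch_series(table: CellTable, batches: dict | None) -> pd.Series:
    """Map each record's plate to a batch label (one batch if no map given)."""
    if not table.has("plate"):
        return pd.Series("batch0", index=table.df.index)
    plates = table.df["plate"]
    if batches is None:
        return pd.Series("batch0", index=table.df.index)
    return plates.map(lambda p: batches.get(p, "batch0"))


def preliminary_cluster(
    table: CellTable,
    batches: dict | None = None,
    value: str = "lcount",
    **threshold_kwargs,
) -> pd.Series:
    """Per-record preliminary cluster labels ('noise' or 'signal').

    The empirical-Bayes mixture thresholding is run independently within
    each batch; a record is labeled 'signal' when its posterior signal
    probability under its gene's batch fit is at least .5 (zero counts are
    always noise).
    """
    table.require(value)
    df = table.df
    batch = _batch_series(table, batches)
    labels = pd.Series("noise", index=df.index, dtype=object)
    for _, bidx in df.groupby(batch.to_numpy()).indices.items():
        sub = df.iloc[bidx]
        x_all = sub[value].to_numpy(float)
        pooled = x_all[x_all > 0]
        omnibus = fit_omnibus_mixture(pooled, **threshold_kwargs)
        prior = build_prior(omnibus)
        for _, gidx in sub.groupby("gene_id").indices.items():
            x = x_all[gidx]
            fit = fit_gene_map(x, prior, **threshold_kwargs)
            signal = (posterior_signal_prob(x, fit) >= 0.5) & (x > 0)
            labels.iloc[bidx[gidx]] = np.where(signal, "signal", "noise")
    return labels


def align_plates(
    table: CellTable,
    labels: pd.Series,
    batches: dict | None = None,
    value: str = "lcount",
) -> np.ndarray:
    """Subtract plate-specific cluster-intercept deviations within batches.

    Per batch, ordinary least squares is used to fit gene main effects, a
    cluster main effect, and sum-coded plate-within-cluster intercepts;
    the fitted plate x cluster deviation (from the across-plate mean for
    that cluster) is subtracted from every record on that plate in that
    cluster. Differences between records on the same plate and cluster are
    preserved exactly. Returns the normalized values (ncount).
    """
    table.require(value)
    df = table.df
    batch = _batch_series(table, batches).to_numpy()
    y_all = df[value].to_numpy(float)
    ncount = y_all.copy()
    lab = np.asarray(labels)
    for _, bidx in pd.Series(batch).groupby(batch).indices.items():
        sub = df.iloc[bidx]
        y = y_all[bidx]
        cl = lab[bidx]
        plates = np.sort(sub["plate"].unique()) if table.has("plate") else np.array(["p0"])
        if plates.size < 2:
            continue  # single plate: nothing to align
        pl = sub["plate"].to_numpy()
        genes = np.sort(sub["gene_id"].unique())
        cols = [np.ones(len(sub))]
        for g in genes[1:]:
            cols.append((sub["gene_id"] == g).to_numpy(float))
        cols.append((cl == "signal").astype(float))
        # sum-coded plate intercepts within each cluster
        slots = []  # (cluster, plate) -> column position
        for c in ("noise", "signal"):
            in_c = cl == c
            present = np.sort(np.unique(pl[in_c]))
            if present.size < plates.size:
                warnings.warn(
                    f"cluster {c!r} missing on some plate(s); "
                    "their correction terms are dropped"
                )
            if present.size < 2:
                continue
            ref = present[-1]
            for p in present[:-1]:
                col = np.where(in_c & (pl == p), 1.0, 0.0)
                col -= np.where(in_c & (pl == ref), 1.0, 0.0)
                cols.append(col)
                slots.append((c, p))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        k0 = X.shape[1] - len(slots)
        delta: dict[tuple[str, str], float] = {}
        by_cluster: dict[str, float] = {"noise": 0.0, "signal": 0.0}
        for (c, p), b in zip(slots, beta[k0:]):
            delta[(c, p)] = b
            by_cluster[c] -= b  # reference plate gets minus the sum
        for c in ("noise", "signal"):
            present = np.sort(np.unique(pl[cl == c]))
            if present.size >= 2:
                delta[(c, present[-1])] = by_cluster[c]
        corr = np.array([delta.get((c, p), 0.0) for c, p in zip(cl, pl)])
        ncount[bidx] = y - corr
    return ncount


def translate_min_zero(table: CellTable, value: str = "ncount") -> np.ndarray:
    """Translate each gene so its minimum value is exactly zero (idempotent)."""
    table.require(value)
    df = table.df
    mins = df.groupby("gene_id")[value].transform("min").to_numpy(float)
    return df[value].to_numpy(float) - mins


def normalize_table(
    table: CellTable,
    batches: dict | None = None,
    value: str = "lcount",
    **threshold_kwargs,
) -> tuple[CellTable, pd.Series]:
    """Full normalization: preliminary clustering, plate alignment within
    batches, then per-gene min-zero translation. Returns the table with an
    ``ncount`` column and the preliminary cluster labels."""
    labels = preliminary_cluster(table, batches, value=value, **threshold_kwargs)
    ncount = align_plates(table, labels, batches, value=value)
    out = table.with_column("ncount", ncount)
    out = out.with_column("ncount", translate_min_zero(out, "ncount"))
    return out, labels
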