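"""Synthetic single-cell expression with the hurdle generative structure.

The generator is the inverse of the fitting model: per cell x gene, an
on/off state is drawn from a logistic model (gene baseline logit-frequency
plus sum-to-zero cell-line, cycle, and interaction effects plus a per-cell
efficiency shift), and conditional on "on" a positive log2 value is drawn
from a Gaussian whose mean carries the analogous effects. "Off" records
draw from the gene's near-zero noise cluster (a normal with mean 0.5 and
sd 0.5 truncated at zero, reproducing the background mode of raw log
counts). Per-cell efficiency shifts move both the on/off odds and the
positive mean, inducing the strong correlation between the fraction of
genes detected (ngeneson) and the cell's log-sum of expression that real
plates show; plate-level intercept shifts perturb the signal cluster so
that plate alignment has something to remove. Conditional-dependence edges
between gene pairs can be planted for network benchmarks, and full ground
truth (every coefficient, cluster label, and planted edge) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data import CellTable, PHASE_ORDER

__all__ = [
    "SimulationSpec",
    "simulate_dataset",
    "simulate_null",
    "paper_scale_spec",
    "attach_truth_et",
]


def _sum_zero(rng, levels, sd):
    """Random effect vector with exact sum-to-zero constraint."""
    e = rng.normal(0.0, sd, size=levels)
    return e - e.mean()


def _sum_zero_matrix(rng, n_rows, n_cols, sd):
    """Random matrix with zero row and column sums."""
    m = rng.normal(0.0, sd, size=(n_rows, n_cols))
    m -= m.mean(axis=1, keepdims=True)
    m -= m.mean(axis=0, keepdims=True)
    return m


@dataclass
class SimulationSpec:
    """Study design and effect sizes for one synthetic dataset.

    Defaults mirror the assay the framework was developed for: three cell
    lines x three cycle phases, log2-scale signal means around 6-11,
    per-gene expression frequencies uniform on [0.56, 0.9] (the
    interquartile range observed on real panels), a truncated-normal
    noise cluster hugging zero, and a per-cell efficiency shift strong
    enough to give an ngeneson-logsum correlation above 0.8.
    """

    n_genes: int = 40
    cells_per_group: int = 34  # per (line, phase, plate)
    lines: tuple = ("H9", "MB231", "PC3")
    phases: tuple = PHASE_ORDER
    plates_per_batch: int = 2
    n_batches: int = 1
    freq_range: tuple[float, float] = (0.56, 0.9)
    signal_mean_range: tuple[float, float] = (6.0, 11.0)
    signal_sd: float = 1.0
    noise_mean: float = 0.5
    noise_sd: float = 0.5
    line_effect_sd_logit: float = 0.5
    line_effect_sd_mean: float = 0.5
    cycle_effect_sd_logit: float = 0.0
    cycle_effect_sd_mean: float = 0.0
    interaction_sd_logit: float = 0.0
    interaction_sd_mean: float = 0.0
    efficiency_sd: float = 0.5  # per-cell shift, log2 units on the mean
    efficiency_logit_weight: float = 2.0  # shift scaling on the logit scale
    plate_shift_sd: float = 0.25
    planted_edges: tuple = ()  # (gene_i, gene_j, effect) index triples
    cycle_effect_genes: tuple = ()  # indices given explicit cycle effects
    cycle_effect_size: float = 1.0  # logit and mean shift for those genes
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2 or self.cells_per_group < 1:
            raise ValueError("need at least 2 genes and 1 cell per group")
        if self.signal_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if not (0 < self.freq_range[0] <= self.freq_range[1] < 1):
            raise ValueError("frequency range must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows: coefficients, labels, planted edges."""

    freq_baseline: np.ndarray
    signal_mean: np.ndarray
    line_logit: np.ndarray  # genes x lines
    line_mean: np.ndarray
    cycle_logit: np.ndarray  # genes x phases
    cycle_mean: np.ndarray
    inter_logit: np.ndarray  # genes x lines x phases
    inter_mean: np.ndarray
    efficiency: pd.Series  # per cell
    plate_shift: dict
    cluster_label: np.ndarray  # per record, 'signal' or 'noise'
    planted_edges: tuple
    peak_phase: dict = field(default_factory=dict)  # effect gene -> phase index


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(spec: SimulationSpec) -> tuple[CellTable, GroundTruth]:
    """Draw one dataset plus its ground truth (deterministic in spec.seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    L, C = len(spec.lines), len(spec.phases)

    freq = rng.uniform(*spec.freq_range, size=G)
    base_logit = np.log(freq / (1 - freq))
    mu_sig = rng.uniform(*spec.signal_mean_range, size=G)
    line_logit = np.stack([_sum_zero(rng, L, spec.line_effect_sd_logit) for _ in range(G)])
    line_mean = np.stack([_sum_zero(rng, L, spec.line_effect_sd_mean) for _ in range(G)])
    cycle_logit = np.stack([_sum_zero(rng, C, spec.cycle_effect_sd_logit) for _ in range(G)])
    cycle_mean = np.stack([_sum_zero(rng, C, spec.cycle_effect_sd_mean) for _ in range(G)])
    inter_logit = np.stack(
        [_sum_zero_matrix(rng, L, C, spec.interaction_sd_logit) for _ in range(G)]
    )
    inter_mean = np.stack(
        [_sum_zero_matrix(rng, L, C, spec.interaction_sd_mean) for _ in range(G)]
    )
    # explicit cycle effects on chosen genes: each gene peaks in one phase
    # (assigned round-robin so the panel stays phase-balanced, as real
    # cycle genes peak throughout the cycle); the sum-to-zero contrast
    # raises the peak phase by 2/3 of the effect size and lowers the other
    # phases, so peak-minus-trough equals cycle_effect_size on both the
    # logit-frequency and the positive mean
    peak_phase = {}
    for rank, gi in enumerate(spec.cycle_effect_genes):
        c = rank % C
        peak_phase[gi] = c
        contrast = spec.cycle_effect_size * (np.eye(C)[c] - 1.0 / C)
        cycle_logit[gi] += contrast
        cycle_mean[gi] += contrast

    # cells: lines x phases x plates, plates nested in batches
    cell_rows = []
    cid = 0
    for b in range(spec.n_batches):
        for p in range(spec.plates_per_batch):
            plate = f"b{b}p{p}"
            for li, line in enumerate(spec.lines):
                for ci, phase in enumerate(spec.phases):
                    for _ in range(spec.cells_per_group):
                        cell_rows.append((f"C{cid:05d}", line, li, phase, ci, plate, b))
                        cid += 1
    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "cell_line", "li", "cycle", "ci", "plate", "batch"]
    )
    n_cells = len(cells)
    eff = rng.normal(0.0, spec.efficiency_sd, size=n_cells)
    plate_shift = {
        pl: rng.normal(0.0, spec.plate_shift_sd) for pl in cells["plate"].unique()
    }

    li = cells["li"].to_numpy()
    ci = cells["ci"].to_numpy()
    pshift = cells["plate"].map(plate_shift).to_numpy()

    a, bnd = (0.0 - spec.noise_mean) / spec.noise_sd, np.inf
    on = np.empty((n_cells, G), bool)
    val = np.empty((n_cells, G), float)
    order = _generation_order(G, spec.planted_edges)
    eff_centered = eff - eff.mean()
    for g in order:
        logit = (
            base_logit[g]
            + line_logit[g, li]
            + cycle_logit[g, ci]
            + inter_logit[g, li, ci]
            + spec.efficiency_logit_weight * eff_centered
        )
        mean = (
            mu_sig[g]
            + line_mean[g, li]
            + cycle_mean[g, ci]
            + inter_mean[g, li, ci]
            + eff_centered
            + pshift
        )
        for (i, j, effect) in spec.planted_edges:
            if j == g:
                parent = val[:, i] * on[:, i]
                z = (parent - parent.mean()) / max(parent.std(), 1e-12)
                logit = logit + effect * z
                mean = mean + 0.5 * effect * z
        on[:, g] = rng.random(n_cells) < _logistic(logit)
        sig = mean + rng.normal(0.0, spec.signal_sd, size=n_cells)
        noise = truncnorm.rvs(
            a, bnd, loc=spec.noise_mean, scale=spec.noise_sd,
            size=n_cells, random_state=rng,
        )
        val[:, g] = np.where(on[:, g], np.maximum(sig, 0.0), noise)

    counts = np.round(np.exp2(val) - 1.0).clip(min=0)
    lcount = np.log2(counts + 1.0)
    long = pd.DataFrame(
        {
            "cell_id": np.repeat(cells["cell_id"].to_numpy(), G),
            "cycle": np.repeat(cells["cycle"].to_numpy(), G),
            "cell_line": np.repeat(cells["cell_line"].to_numpy(), G),
            "plate": np.repeat(cells["plate"].to_numpy(), G),
            "plate_row": np.repeat(
                np.array([chr(ord("A") + i % 8) for i in range(n_cells)]), G
            ),
            "gene_id": np.tile(np.array([f"G{g:03d}" for g in range(G)]), n_cells),
            "lcount": lcount.reshape(-1),
        }
    )
    truth = GroundTruth(
        freq_baseline=freq,
        signal_mean=mu_sig,
        line_logit=line_logit,
        line_mean=line_mean,
        cycle_logit=cycle_logit,
        cycle_mean=cycle_mean,
        inter_logit=inter_logit,
        inter_mean=inter_mean,
        efficiency=pd.Series(eff, index=cells["cell_id"].to_numpy()),
        plate_shift=plate_shift,
        cluster_label=np.where(on, "signal", "noise").reshape(-1),
        planted_edges=spec.planted_edges,
        peak_phase=peak_phase,
    )
    return CellTable(long), truth


def attach_truth_et(table: CellTable, truth: GroundTruth) -> CellTable:
    """Attach et and ngeneson using the generator's own cluster labels.

    Bypasses mixture thresholding: records the generator drew from the
    noise cluster get et = 0, signal records keep their lcount. Useful for
    testing the downstream fitters in isolation from the thresholder.
    """
    from .qc import attach_ngeneson

    et = np.where(truth.cluster_label == "signal", table.df["lcount"].to_numpy(float), 0.0)
    return attach_ngeneson(table.with_column("et", et))


def _generation_order(G, planted_edges):
    """Parents before children so planted dependences can condition on them."""
    order = []
    seen = set()

    def visit(g, stack=()):
        if g in seen:
            return
        for (i, j, _) in planted_edges:
            if j == g and i not in seen and i not in stack:
                visit(i, stack + (g,))
        seen.add(g)
        order.append(g)

    for g in range(G):
        visit(g)
    return order


def simulate_null(spec: SimulationSpec, n_reps: int, seed: int | None = None):
    """Stream of datasets with all cycle effects forced to zero.

    Rep ``r`` uses seed ``base_seed + r`` so any rep is reproducible in
    isolation.
    """
    base = spec.seed if seed is None else seed
    null_spec = replace(
        spec,
        cycle_effect_sd_logit=0.0,
        cycle_effect_sd_mean=0.0,
        interaction_sd_logit=0.0,
        interaction_sd_mean=0.0,
        cycle_effect_genes=(),
    )
    for r in range(n_reps):
        yield simulate_dataset(replace(null_spec, seed=(base + r) % (2**31 - 1)))


def paper_scale_spec(seed: int = 0, n_genes: int = 253) -> SimulationSpec:
    """A spec at the scale of the motivating assay: 930 cells held in
    3 lines x 3 phases across plates (rounded to 936 = 3*3*2*2*26), with
    a quarter of the genes carrying cycle effects."""
    rng = np.random.default_rng(seed)
    k = max(1, n_genes // 4)
    cyc = tuple(sorted(rng.choice(n_genes, size=k, replace=False).tolist()))
    return SimulationSpec(
        n_genes=n_genes,
        cells_per_group=26,
        plates_per_batch=2,
        n_batches=2,
        cycle_effect_genes=cyc,
        cycle_effect_size=1.0,
        seed=seed,
    )
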