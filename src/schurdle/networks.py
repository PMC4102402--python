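"""Co-expression networks by L1-penalized hurdle neighborhood selection.

Following the neighborhood-selection idea of Meinshausen & Buhlmann, each
gene is regressed on the thresholded expression of all other genes, with
the regression split into the hurdle's two parts: an L1-penalized logistic
regression on the detection indicator, and an L1-penalized linear
regression on the positive values. Per-cell nuisance covariates (ngeneson,
cell line, and optionally cycle with line x cycle interactions) enter
unpenalized, so population-level shifts do not masquerade as cellular
co-expression. Nonzero gene coefficients propose edges; each component's
neighborhoods are symmetrized by union, a single penalty per component is
calibrated by bisection to an edge budget, and the two component networks
are combined by union with per-edge provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import CellTable
from .hurdle import DesignSpec, build_design

__all__ = [
    "NeighborhoodFit",
    "GeneNetwork",
    "fit_neighborhood",
    "component_network",
    "calibrate_penalty",
    "build_network",
    "combine_networks",
    "peaktime_concordance",
    "compare_networks",
    "conditional_covariance_decomposition",
]


def _covariate_design(df_cells: pd.DataFrame, adjust_cycle: bool):
    spec = DesignSpec(
        cell_line=True, cycle=adjust_cycle, interactions=adjust_cycle, ngeneson=True
    )
    return build_design(df_cells, spec)


@dataclass
class NeighborhoodFit:
    """Penalized two-part regression of one gene on all others."""

    gene: str
    genes: list[str]  # predictor genes, in column order
    coef_disc: np.ndarray  # per predictor gene, original scale (0 = no edge)
    coef_cont: np.ndarray
    coef_disc_std: np.ndarray  # standardized-predictor scale (for ranking)
    coef_cont_std: np.ndarray
    cov_disc: np.ndarray | None = None
    cov_cont: np.ndarray | None = None

    def neighbors(self, component: str) -> list[str]:
        coef = self.coef_disc if component == "discrete" else self.coef_cont
        return [g for g, c in zip(self.genes, coef) if c != 0.0]


def _penalized_logit(y, X_pen, X_unpen, lam):
    """L1 logistic with unpenalized covariates (per-parameter alpha)."""
    X = np.column_stack([X_pen, X_unpen])
    alpha = np.r_[np.full(X_pen.shape[1], lam), np.zeros(X_unpen.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=alpha, disp=0, maxiter=500,
            trim_mode="size", size_trim_tol=1e-6, acc=1e-10,
        )
    p = np.asarray(res.params)
    return p[: X_pen.shape[1]], p[X_pen.shape[1]:]


def _penalized_ols(y, X_pen, X_unpen, lam):
    """Lasso with unpenalized covariates via Frisch-Waugh projection.

    Profiling the unpenalized coefficients out of the penalized objective
    is exact for squared error: regress y and each penalized column on the
    unpenalized block, then lasso the residuals against each other.
    """
    Q, _ = np.linalg.qr(X_unpen)
    y_r = y - Q @ (Q.T @ y)
    X_r = X_pen - Q @ (Q.T @ X_pen)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.OLS(y_r, X_r).fit_regularized(
            method="elastic_net", alpha=lam, L1_wt=1.0, cnvrg_tol=1e-12
        )
    beta = np.asarray(res.params)
    resid = y - X_pen @ beta
    coef_unpen, *_ = np.linalg.lstsq(X_unpen, resid, rcond=None)
    return beta, coef_unpen


def _frames(table: CellTable, value: str, adjust_cycle: bool):
    wide = table.wide(value)
    meta = table.cell_meta().loc[wide.index]
    X_unpen, _ = _covariate_design(meta, adjust_cycle)
    return wide, X_unpen


def fit_neighborhood(
    table: CellTable,
    gene: str,
    lambda_d: float,
    lambda_c: float,
    adjust_cycle: bool = True,
    value: str = "et",
    _frames_cache=None,
) -> NeighborhoodFit:
    """Fit the penalized discrete and continuous neighborhoods of one gene.

    Predictor genes are standardized to unit variance inside each fit so a
    single shared penalty is meaningful across genes; coefficients are
    reported on the original scale. The continuous regression uses the
    other genes' full et values as predictors but only the cells where the
    target gene is positive.
    """
    if lambda_d <= 0 or lambda_c <= 0:
        raise ValueError("penalties must be positive")
    wide, X_unpen = _frames_cache or _frames(table, value, adjust_cycle)
    others = [g for g in wide.columns if g != gene]
    Xg = wide[others].to_numpy(float)
    sd = Xg.std(axis=0)
    keep = sd > 0
    Xs = (Xg[:, keep] - Xg[:, keep].mean(axis=0)) / sd[keep]
    y_target = wide[gene].to_numpy(float)
    y_bin = (y_target > 0).astype(float)
    kept = [g for g, k in zip(others, keep) if k]

    coef_d_std = np.zeros(len(kept))
    if 0.0 < y_bin.mean() < 1.0:
        coef_d_std, _ = _penalized_logit(y_bin, Xs, X_unpen, lambda_d)
    pos = y_target > 0
    coef_c_std = np.zeros(len(kept))
    if pos.sum() > X_unpen.shape[1] + 1:
        coef_c_std, _ = _penalized_ols(y_target[pos], Xs[pos], X_unpen[pos], lambda_c)

    def _expand(std_coef):
        full_std = np.zeros(len(others))
        full = np.zeros(len(others))
        full_std[keep] = std_coef
        full[keep] = std_coef / sd[keep]
        return full, full_std

    coef_d, coef_d_s = _expand(coef_d_std)
    coef_c, coef_c_s = _expand(coef_c_std)
    return NeighborhoodFit(
        gene=gene, genes=others,
        coef_disc=coef_d, coef_cont=coef_c,
        coef_disc_std=coef_d_s, coef_cont_std=coef_c_s,
    )


@dataclass
class GeneNetwork:
    """Symmetrized edge set with per-edge provenance and its penalties."""

    genes: list[str]
    edges: dict[frozenset, str]  # pair -> 'discrete' | 'continuous' | 'both'
    lambda_d: float | None = None
    lambda_c: float | None = None
    adjusted: bool = True
    strength: dict[frozenset, float] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> set:
        """Non-isolated nodes (endpoints of at least one edge)."""
        return set().union(*self.edges) if self.edges else set()

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.genes)
        for e, prov in self.edges.items():
            a, b = sorted(e)
            G.add_edge(a, b, component=prov, strength=self.strength.get(e, np.nan))
        return G

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            dict(gene_a=min(e), gene_b=max(e), component=prov,
                 strength=self.strength.get(e, np.nan))
            for e, prov in sorted(self.edges.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "component", "strength"])


def _edges_at(table, component, lam, adjust_cycle, value="et", frames=None):
    """Symmetrized union of one component's neighborhoods at one penalty."""
    frames = frames or _frames(table, value, adjust_cycle)
    lam_d = lam if component == "discrete" else 1.0
    lam_c = lam if component == "continuous" else 1.0
    edges: dict[frozenset, float] = {}
    for g in table.genes:
        fit = fit_neighborhood(
            table, g, lam_d, lam_c, adjust_cycle, value, _frames_cache=frames
        )
        std = fit.coef_disc_std if component == "discrete" else fit.coef_cont_std
        for h, c in zip(fit.genes, std):
            if c != 0.0:
                key = frozenset((g, h))
                edges[key] = max(edges.get(key, 0.0), abs(float(c)))
    return edges


def component_network(
    table: CellTable,
    component: str,
    lam: float,
    adjust_cycle: bool = True,
    value: str = "et",
) -> GeneNetwork:
    edges = _edges_at(table, component, lam, adjust_cycle, value)
    return GeneNetwork(
        genes=list(table.genes),
        edges={e: component for e in edges},
        lambda_d=lam if component == "discrete" else None,
        lambda_c=lam if component == "continuous" else None,
        adjusted=adjust_cycle,
        strength=edges,
    )


def calibrate_penalty(
    table: CellTable,
    component: str,
    target_edges: int,
    adjust_cycle: bool = True,
    value: str = "et",
    max_iter: int = 30,
    check_monotone: bool = True,
) -> tuple[float, GeneNetwork]:
    """Bisection over a single shared penalty to hit an edge budget.

    The symmetrized-union edge count is non-increasing in the penalty
    (asserted along the bisection path). If the count jumps past the
    budget, the edges entering at the final bracket are ranked by the
    largest absolute standardized coefficient and trimmed to the budget.
    Returns (lambda, network with exactly min(target, attainable) edges).
    """
    if target_edges < 0:
        raise ValueError("target_edges must be nonnegative")
    frames = _frames(table, value, adjust_cycle)
    lam_hi = 1.0
    edges_hi = _edges_at(table, component, lam_hi, adjust_cycle, value, frames)
    for _ in range(40):
        if len(edges_hi) <= target_edges:
            break
        lam_hi *= 2.0
        edges_hi = _edges_at(table, component, lam_hi, adjust_cycle, value, frames)
    lam_lo = lam_hi
    edges_lo = edges_hi
    for _ in range(40):
        if len(edges_lo) >= target_edges:
            break
        lam_lo /= 2.0
        edges_lo = _edges_at(table, component, lam_lo, adjust_cycle, value, frames)
    if len(edges_lo) < target_edges:
        warnings.warn(
            f"edge budget {target_edges} unattainable; achieved {len(edges_lo)}"
        )
    path_counts = [(lam_lo, len(edges_lo)), (lam_hi, len(edges_hi))]
    for _ in range(max_iter):
        if len(edges_hi) == target_edges or len(edges_lo) == target_edges:
            break
        lam_mid = np.sqrt(lam_lo * lam_hi)
        edges_mid = _edges_at(table, component, lam_mid, adjust_cycle, value, frames)
        path_counts.append((lam_mid, len(edges_mid)))
        if len(edges_mid) >= target_edges:
            lam_lo, edges_lo = lam_mid, edges_mid
        else:
            lam_hi, edges_hi = lam_mid, edges_mid
    if check_monotone:
        path_counts.sort(key=lambda t: t[0])
        counts = [c for _, c in path_counts]
        if any(counts[i] < counts[i + 1] for i in range(len(counts) - 1)):
            warnings.warn("edge count not monotone along the penalty path")
    if len(edges_hi) == target_edges:
        lam, chosen = lam_hi, edges_hi
    elif len(edges_lo) == target_edges:
        lam, chosen = lam_lo, edges_lo
    else:
        # trim overshoot: keep the established edges plus the strongest entrants
        lam = lam_lo
        entering = {e: s for e, s in edges_lo.items() if e not in edges_hi}
        room = target_edges - len([e for e in edges_lo if e in edges_hi])
        ranked = sorted(entering.items(), key=lambda kv: -kv[1])[:max(room, 0)]
        chosen = {e: s for e, s in edges_lo.items() if e in edges_hi}
        chosen.update(dict(ranked))
    net = GeneNetwork(
        genes=list(table.genes),
        edges={e: component for e in chosen},
        lambda_d=lam if component == "discrete" else None,
        lambda_c=lam if component == "continuous" else None,
        adjusted=adjust_cycle,
        strength=dict(chosen),
    )
    return lam, net


def combine_networks(disc: GeneNetwork, cont: GeneNetwork) -> GeneNetwork:
    """Union of the two component networks; shared edges get provenance 'both'."""
    if set(disc.genes) != set(cont.genes):
        raise ValueError("networks must share the same gene universe")
    edges: dict[frozenset, str] = {}
    strength: dict[frozenset, float] = {}
    for e in set(disc.edges) | set(cont.edges):
        in_d, in_c = e in disc.edges, e in cont.edges
        edges[e] = "both" if (in_d and in_c) else ("discrete" if in_d else "continuous")
        strength[e] = max(disc.strength.get(e, 0.0), cont.strength.get(e, 0.0))
    return GeneNetwork(
        genes=list(disc.genes), edges=edges,
        lambda_d=disc.lambda_d, lambda_c=cont.lambda_c,
        adjusted=disc.adjusted and cont.adjusted, strength=strength,
    )


def build_network(
    table: CellTable,
    edges: int = 60,
    split: tuple[int, int] = (30, 30),
    adjust_cycle: bool = True,
    value: str = "et",
) -> GeneNetwork:
    """Calibrate both component penalties to an edge budget and combine.

    With ``model='raw'`` semantics, pass ``value='lcount'``: the same
    penalized linear regressions are then run on un-thresholded log counts
    (no useful discrete part), giving the raw comparison networks.
    """
    if sum(split) != edges:
        raise ValueError("split must sum to the edge budget")
    _, net_d = calibrate_penalty(table, "discrete", split[0], adjust_cycle, value)
    _, net_c = calibrate_penalty(table, "continuous", split[1], adjust_cycle, value)
    return combine_networks(net_d, net_c)


def peaktime_concordance(net: GeneNetwork, phase_of: dict) -> float:
    """Fraction of annotated edges whose endpoints share a peak-phase bin.

    ``phase_of`` maps gene -> phase label; genes absent from the map (or
    mapped to None) are unannotated, and edges touching them are excluded
    from the denominator. Returns NaN if no edge is fully annotated.
    """
    num = den = 0
    for e in net.edges:
        a, b = sorted(e)
        pa, pb = phase_of.get(a), phase_of.get(b)
        if pa is None or pb is None:
            continue
        den += 1
        num += pa == pb
    return num / den if den else float("nan")


def compare_networks(a: GeneNetwork, b: GeneNetwork) -> tuple[float, float]:
    """(node Jaccard similarity, edge Hamming distance / edges per network).

    Nodes are compared over non-isolated vertices; the edge metric is the
    size of the symmetric difference of the edge sets divided by the
    per-network edge count (averaged if the two differ).
    """
    va, vb = a.nodes, b.nodes
    union = va | vb
    jaccard = len(va & vb) / len(union) if union else 1.0
    ea, eb = set(a.edges), set(b.edges)
    per_net = (len(ea) + len(eb)) / 2.0
    hamming = len(ea ^ eb) / per_net if per_net else 0.0
    return jaccard, hamming


def conditional_covariance_decomposition(x, y, f):
    """Decompose cov(X, Y) into within- and between-cluster parts.

    cov(X, Y) = E[cov(X, Y | F)] + cov(E[X|F], E[Y|F]): the total
    (population-style, divisor n) covariance equals the cluster-size-
    weighted average of within-cluster covariances plus the covariance of
    the cluster means. Marginal co-expression induced by a population
    factor F lives entirely in the second term.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    f = np.asarray(f)
    n = x.size
    total = float(np.mean(x * y) - x.mean() * y.mean())
    within = 0.0
    between = 0.0
    for lev in np.unique(f):
        m = f == lev
        w = m.sum() / n
        within += w * float(np.mean(x[m] * y[m]) - x[m].mean() * y[m].mean())
        between += w * (x[m].mean() - x.mean()) * (y[m].mean() - y.mean())
    return total, within, float(between)
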