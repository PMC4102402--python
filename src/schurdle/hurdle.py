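"""Two-part (Hurdle) generalized linear models for zero-inflated expression.

Thresholded single-cell expression ``et`` is modeled in two parts: a
logistic regression on the detection indicator 1{et > 0}, and a Gaussian
linear model on the strictly positive values. Both parts share a design of
cell-line effects, cell-cycle effects, optional line x cycle interactions
(all in sum-to-zero parameterization) and the per-cell detection-rate
covariate ngeneson. The joint log-likelihood is additive in the two parts,
so likelihood-ratio statistics for nested hypotheses add across parts and
are referred to a chi-square with doubled degrees of freedom. Component
p-values also support a Bonferroni-allocated union-intersection test.

Variability attributable to the cycle is quantified by a deviance ratio
(cycle deviance over cycle-plus-residual deviance), the hurdle analog of
the coefficient of determination. Deviance here follows the GLM
convention: -2 log-likelihood for the Bernoulli part (saturated fit has
zero log-likelihood) and residual sum of squares for the Gaussian part, so
the ratio reduces exactly to the OLS R^2 when the data have no zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import CellTable, PHASE_ORDER

__all__ = [
    "DesignSpec",
    "HurdleFit",
    "TestResult",
    "DevianceDecomposition",
    "build_design",
    "fit_hurdle",
    "lrt_cycle",
    "union_test",
    "deviance_ratio",
    "bonferroni_adjust",
    "estimate_peaktime",
    "test_all_genes",
    "deviance_all_genes",
]


@dataclass(frozen=True)
class DesignSpec:
    """Which terms enter both parts of the hurdle regression.

    Factors use sum-to-zero coding: each factor's effects sum to zero and
    the interaction matrix has zero row and column sums, so test statistics
    are invariant to the choice of reference level.
    """

    cell_line: bool = True
    cycle: bool = True
    interactions: bool = False
    ngeneson: bool = True
    line_levels: tuple = ()
    cycle_levels: tuple = PHASE_ORDER

    def resolve(self, df: pd.DataFrame) -> "DesignSpec":
        levels = self.line_levels or tuple(sorted(df["cell_line"].unique()))
        cyc = tuple(l for l in self.cycle_levels if l in set(df["cycle"].unique()))
        cyc = cyc or tuple(sorted(df["cycle"].unique()))
        return DesignSpec(
            self.cell_line, self.cycle, self.interactions, self.ngeneson,
            tuple(levels), tuple(cyc),
        )

    def without_cycle(self) -> "DesignSpec":
        return DesignSpec(
            self.cell_line, False, False, self.ngeneson,
            self.line_levels, self.cycle_levels,
        )


def _sum_code(values: np.ndarray, levels: tuple) -> np.ndarray:
    """(n, L-1) sum-to-zero coding; the last level maps to minus the sum."""
    X = np.zeros((len(values), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        X[values == lev, j] = 1.0
    X[values == levels[-1], :] = -1.0
    return X


def build_design(df: pd.DataFrame, spec: DesignSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for one gene's cells."""
    spec = spec.resolve(df)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if spec.cell_line and len(spec.line_levels) > 1:
        X = _sum_code(df["cell_line"].to_numpy(), spec.line_levels)
        cols.append(X)
        names += [f"line[{l}]" for l in spec.line_levels[:-1]]
    if spec.cycle and len(spec.cycle_levels) > 1:
        Xc = _sum_code(df["cycle"].to_numpy(), spec.cycle_levels)
        cols.append(Xc)
        names += [f"cycle[{c}]" for c in spec.cycle_levels[:-1]]
        if spec.interactions and spec.cell_line and len(spec.line_levels) > 1:
            Xl = _sum_code(df["cell_line"].to_numpy(), spec.line_levels)
            inter = np.einsum("ni,nj->nij", Xl, Xc).reshape(len(df), -1)
            cols.append(inter)
            names += [
                f"line[{l}]:cycle[{c}]"
                for l in spec.line_levels[:-1]
                for c in spec.cycle_levels[:-1]
            ]
    if spec.ngeneson:
        cols.append(df["ngeneson"].to_numpy(float)[:, None])
        names.append("ngeneson")
    X = np.column_stack([np.atleast_2d(c.T).T for c in cols])
    return X, names


def _ridge_logit(y, X, penalty=1e-6, max_iter=200, tol=1e-8):
    """IRLS logistic fit with a small fixed ridge; used under separation."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        grad = X.T @ (y - p) - penalty * beta
        H = (X * w[:, None]).T @ X + penalty * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            break
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, ll


def _fit_logistic(y, X):
    """Binomial GLM by IRLS; falls back to a fixed 1e-6 ridge on separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            params = np.asarray(res.params)
            if res.converged and np.all(np.isfinite(params)) and np.max(np.abs(params)) < 30:
                return params, float(res.llf), np.asarray(res.bse), False
        except Exception:
            pass
    beta, ll = _ridge_logit(y, X)
    return beta, ll, np.full(X.shape[1], np.nan), True


@dataclass
class HurdleFit:
    """Paired logistic and Gaussian-on-positives fits with log-likelihoods."""

    gene_id: str
    design: DesignSpec
    names: list[str]
    coef_disc: np.ndarray | None
    coef_cont: np.ndarray | None
    se_disc: np.ndarray | None
    se_cont: np.ndarray | None
    loglik_disc: float
    loglik_cont: float
    rss: float  # Gaussian residual sum of squares (its GLM deviance)
    sigma2: float  # ML (n-denominator) residual variance
    n: int
    n_pos: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def loglik(self) -> float:
        return self.loglik_disc + self.loglik_cont

    @property
    def deviance(self) -> float:
        """-2 x total log-likelihood (used for likelihood-ratio statistics)."""
        return -2.0 * self.loglik

    @property
    def glm_deviance(self) -> float:
        """GLM deviance: Bernoulli -2 loglik plus Gaussian RSS."""
        return -2.0 * self.loglik_disc + self.rss


def fit_hurdle(table: CellTable, gene: str, design: DesignSpec | None = None) -> HurdleFit:
    """Fit the two-part hurdle regression for one gene.

    The discrete part is a logistic regression of 1{et > 0}; the
    continuous part is an ordinary least-squares fit on the strictly
    positive et values (maximum-likelihood variance, n-denominator, so
    deviances are comparable across nested models). Genes expressed in
    all or no cells contribute only the available component, flagged
    accordingly.
    """
    design = (design or DesignSpec()).resolve(table.df)
    table.require("et")
    if design.ngeneson:
        table.require("ngeneson")
    df = table.df[table.df["gene_id"] == gene]
    if df.empty:
        raise ValueError(f"gene {gene!r} not present")
    y = (df["et"].to_numpy(float) > 0).astype(float)
    X, names = build_design(df, design)
    flags = []
    # discrete part
    if y.min() == y.max():
        coef_d, se_d, ll_d = None, None, 0.0
        flags.append("discrete_degenerate")
    else:
        coef_d, ll_d, se_d, ridged = _fit_logistic(y, X)
        if ridged:
            flags.append("separation_ridge")
    # continuous part on positives
    pos = df["et"].to_numpy(float) > 0
    n_pos = int(pos.sum())
    if n_pos >= X.shape[1] + 1:
        Xp = X[pos]
        yp = df["et"].to_numpy(float)[pos]
        ols = sm.OLS(yp, Xp).fit()
        rss = float(ols.ssr)
        sigma2 = max(rss / n_pos, 1e-12)
        ll_c = -0.5 * n_pos * (np.log(2 * np.pi * sigma2) + 1.0)
        coef_c, se_c = np.asarray(ols.params), np.asarray(ols.bse)
    elif n_pos >= 2 and np.ptp(df["et"].to_numpy(float)[pos]) > 0:
        yp = df["et"].to_numpy(float)[pos]
        mu = yp.mean()
        sigma2 = max(yp.var(), 1e-12)
        rss = float(((yp - mu) ** 2).sum())
        ll_c = -0.5 * n_pos * (np.log(2 * np.pi * sigma2) + 1.0)
        coef_c = se_c = None
        flags.append("continuous_intercept_only")
    else:
        coef_c, se_c, ll_c, rss, sigma2 = None, None, 0.0, 0.0, np.nan
        flags.append("continuous_degenerate")
    return HurdleFit(
        gene_id=gene, design=design, names=names,
        coef_disc=coef_d, coef_cont=coef_c, se_disc=se_d, se_cont=se_c,
        loglik_disc=float(ll_d), loglik_cont=float(ll_c),
        rss=rss, sigma2=sigma2, n=len(df), n_pos=n_pos,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class TestResult:
    """Combined and component likelihood-ratio tests for nested hurdle fits."""

    lambda_d: float
    lambda_c: float
    df_d: int
    df_c: int
    p_discrete: float
    p_continuous: float
    flags: tuple[str, ...] = ()

    @property
    def lam(self) -> float:
        return self.lambda_d + self.lambda_c

    @property
    def df(self) -> int:
        return self.df_d + self.df_c

    @property
    def p_combined(self) -> float:
        if self.df == 0:
            return 1.0
        return float(stats.chi2.sf(self.lam, self.df))

    def union_reject(self, alpha: float = 0.05, component_level: float | None = None) -> bool:
        return union_test(self.p_discrete, self.p_continuous, alpha, component_level)


def lrt_cycle(full: HurdleFit, reduced: HurdleFit) -> TestResult:
    """Wilks likelihood-ratio test combining discrete and continuous parts.

    The component statistics -2(loglik_reduced - loglik_full) are added;
    the null reference is a chi-square with the degrees of freedom of the
    two components summed (doubled relative to a single-part test: with
    three phases under a sum-to-zero constraint, two degrees per part,
    four in total). Components that are degenerate in either fit
    contribute zero with zero degrees of freedom.
    """
    extra = set(reduced.names) - set(full.names)
    if extra:
        raise ValueError(f"models are not nested; reduced has extra terms {sorted(extra)}")
    flags = tuple(sorted(set(full.flags) | set(reduced.flags)))
    if "discrete_degenerate" in flags:
        lam_d, df_d = 0.0, 0
    else:
        lam_d = max(0.0, 2.0 * (full.loglik_disc - reduced.loglik_disc))
        df_d = len(full.names) - len(reduced.names)
    if "continuous_degenerate" in flags or "continuous_intercept_only" in flags:
        lam_c, df_c = 0.0, 0
    else:
        lam_c = max(0.0, 2.0 * (full.loglik_cont - reduced.loglik_cont))
        df_c = len(full.names) - len(reduced.names)
    p_d = float(stats.chi2.sf(lam_d, df_d)) if df_d else 1.0
    p_c = float(stats.chi2.sf(lam_c, df_c)) if df_c else 1.0
    return TestResult(lam_d, lam_c, df_d, df_c, p_d, p_c, flags)


def union_test(
    p_discrete: float,
    p_continuous: float,
    alpha: float = 0.05,
    component_level: float | None = None,
) -> bool:
    """Union-intersection test: reject the joint null when either component
    rejects at the allocated level (alpha/2 by default, which controls the
    overall size by the Bonferroni inequality)."""
    if not (0 <= p_discrete <= 1 and 0 <= p_continuous <= 1):
        raise ValueError("p-values must lie in [0, 1]")
    level = alpha / 2.0 if component_level is None else component_level
    return min(p_discrete, p_continuous) <= level


@dataclass(frozen=True)
class DevianceDecomposition:
    """Partition of a gene's deviance into cycle and residual components."""

    gene_id: str
    dev_full: float
    dev_nocycle: float
    max_ratio: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def cycle_deviance(self) -> float:
        return max(0.0, self.dev_nocycle - self.dev_full)

    @property
    def residual_deviance(self) -> float:
        return self.dev_full

    @property
    def ratio(self) -> float:
        denom = self.cycle_deviance + self.residual_deviance
        return self.cycle_deviance / denom if denom > 0 else 0.0

    @property
    def deflated_ratio(self) -> float | None:
        return None if self.max_ratio is None else self.ratio / self.max_ratio


def deviance_ratio(
    table: CellTable,
    gene: str,
    design: DesignSpec | None = None,
    max_ratio: float | None = None,
) -> DevianceDecomposition:
    """Proportion of a gene's deviance explained by the cell cycle.

    The full model carries cycle main effects and line x cycle
    interactions; the reduced model drops every cycle term. The ratio
    (D0 - D1)/D0 of GLM deviances is the hurdle analog of the coefficient
    of determination and reduces to the OLS R^2 when no zeros are present.
    The deflated ratio rescales by the largest ratio observed (an upper
    bound under the assumption that the top gene is fully cycle-driven).
    """
    design = (design or DesignSpec(interactions=True)).resolve(table.df)
    full = fit_hurdle(table, gene, design)
    reduced = fit_hurdle(table, gene, design.without_cycle())
    flags = tuple(sorted(set(full.flags) | set(reduced.flags)))
    d1, d0 = full.glm_deviance, reduced.glm_deviance
    if d0 < d1:
        flags = flags + ("negative_cycle_deviance_clamped",)
    return DevianceDecomposition(
        gene_id=gene, dev_full=d1, dev_nocycle=d0, max_ratio=max_ratio, flags=flags
    )


def bonferroni_adjust(pvals) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, p * m)."""
    p = np.asarray(pvals, float)
    return np.minimum(1.0, p * p.size)


def estimate_peaktime(table: CellTable, gene: str) -> tuple[str, bool]:
    """Phase of peak expression: the phase with maximum mean et (zeros
    included) over all cells of all lines; ties resolve to the earliest
    phase in cycle order and are flagged."""
    table.require("et", "cycle")
    df = table.df[table.df["gene_id"] == gene]
    means = df.groupby("cycle")["et"].mean()
    order = [p for p in PHASE_ORDER if p in means.index] + [
        p for p in means.index if p not in PHASE_ORDER
    ]
    vals = means.reindex(order).to_numpy(float)
    best = int(np.argmax(vals))
    tie = bool(np.sum(np.isclose(vals, vals[best])) > 1)
    return order[best], tie


def test_all_genes(
    table: CellTable,
    design: DesignSpec | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cycle differential-expression test for every gene.

    Per gene: expression frequency, component and combined LRT statistics,
    degrees of freedom, p-value (also as -log10), Bonferroni-adjusted
    p-value, union-test decision, and estimated peak phase.
    """
    design = (design or DesignSpec()).resolve(table.df)
    rows = []
    for gene in table.genes:
        full = fit_hurdle(table, gene, design)
        reduced = fit_hurdle(table, gene, design.without_cycle())
        res = lrt_cycle(full, reduced)
        peak, tie = estimate_peaktime(table, gene)
        rows.append(
            dict(
                gene_id=gene,
                freq=full.n_pos / full.n,
                lambda_d=res.lambda_d,
                lambda_c=res.lambda_c,
                lam=res.lam,
                df=res.df,
                p=res.p_combined,
                neg_log10_p=-np.log10(max(res.p_combined, 1e-300)),
                union_reject=res.union_reject(alpha),
                peaktime=peak,
                peaktime_tie=tie,
                flags=";".join(res.flags),
            )
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def deviance_all_genes(
    table: CellTable,
    design: DesignSpec | None = None,
) -> pd.DataFrame:
    """Cycle deviance ratio for every gene, with the deflated ratio scaled
    by the maximum observed ratio across genes."""
    design = (design or DesignSpec(interactions=True)).resolve(table.df)
    decs = [deviance_ratio(table, g, design) for g in table.genes]
    max_ratio = max((d.ratio for d in decs), default=np.nan)
    return pd.DataFrame(
        dict(
            gene_id=[d.gene_id for d in decs],
            dev_full=[d.dev_full for d in decs],
            dev_nocycle=[d.dev_nocycle for d in decs],
            ratio=[d.ratio for d in decs],
            deflated_ratio=[d.ratio / max_ratio if max_ratio > 0 else np.nan for d in decs],
            flags=[";".join(d.flags) for d in decs],
        )
    )
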