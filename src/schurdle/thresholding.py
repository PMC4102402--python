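"""Empirical-Bayes Gaussian-mixture thresholding of bimodal log counts.

Single-cell log2 expression is typically bimodal: a noise cluster near
zero (no detectable transcript) and a signal cluster at a gene-specific
positive mean. Signal is separated from background in two stages:

1. A two-component Gaussian mixture is fitted by maximum likelihood to the
   *omnibus* of expression pooled over all genes, guaranteeing that both
   clusters are represented.
2. The omnibus estimates seed an empirical-Bayes prior (Normal-Inverse-Gamma
   on each cluster's mean/variance with effective weight kappa*Nt, Beta on
   the mixing proportion); each gene is then fitted by MAP Expectation
   Conditional Maximization against that prior, and observations with
   posterior probability > .5 of belonging to the noise cluster are
   truncated to zero. The truncated value is the expression threshold (et).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "MixtureFit",
    "MixturePrior",
    "fit_omnibus_mixture",
    "build_prior",
    "fit_gene_map",
    "posterior_signal_prob",
    "threshold_gene",
    "threshold_table",
]


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture (noise cluster below signal cluster)."""

    mu_noise: float
    mu_signal: float
    var_noise: float
    var_signal: float
    pi_signal: float
    loglik: float
    n_obs: int
    converged: bool = True

    def __post_init__(self):
        if self.var_noise <= 0 or self.var_signal <= 0:
            raise ValueError("variances must be positive")
        if not (0.0 < self.pi_signal < 1.0):
            raise ValueError("pi_signal must lie in (0, 1)")
        if self.mu_noise > self.mu_signal:
            raise ValueError("clusters must be labeled so mu_noise <= mu_signal")

    @property
    def separation(self) -> float:
        """Cluster-mean gap in units of the pooled standard deviation."""
        pooled = np.sqrt(
            (1 - self.pi_signal) * self.var_noise + self.pi_signal * self.var_signal
        )
        return (self.mu_signal - self.mu_noise) / pooled


@dataclass(frozen=True)
class MixturePrior:
    """Conjugate empirical-Bayes prior derived from the omnibus fit.

    Each cluster mean is Normal(center, var/mean_strength) given its
    variance; each variance is Inverse-Gamma(shape, scale) with mode at the
    omnibus variance; the signal mixing proportion is Beta(mix_a, mix_b).
    """

    mean_locations: tuple[float, float]  # (noise, signal)
    mean_strength: float  # kappa * Nt pseudo-observations per cluster
    var_shape: tuple[float, float]
    var_scale: tuple[float, float]
    mix_a: float
    mix_b: float


_EPS = 1e-300


def _loglik(x, mu, var, pi):
    comp = np.stack(
        [
            np.log1p(-pi[1]) + norm.logpdf(x, mu[0], np.sqrt(var[0])),
            np.log(pi[1]) + norm.logpdf(x, mu[1], np.sqrt(var[1])),
        ]
    )
    m = comp.max(axis=0)
    return float(np.sum(m + np.log(np.exp(comp - m).sum(axis=0))))


def _responsibilities(x, mu, var, pi, force_noise=None):
    lw = np.stack(
        [
            np.log1p(-pi[1]) + norm.logpdf(x, mu[0], np.sqrt(var[0])),
            np.log(pi[1]) + norm.logpdf(x, mu[1], np.sqrt(var[1])),
        ]
    )
    lw -= lw.max(axis=0, keepdims=True)
    w = np.exp(lw)
    w /= w.sum(axis=0, keepdims=True)
    if force_noise is not None and force_noise.any():
        w[0, force_noise] = 1.0
        w[1, force_noise] = 0.0
    return w


def _kmeans2_init(x):
    """Deterministic 2-means split; ties broken by value order."""
    lo, hi = np.quantile(x, [0.15, 0.85])
    if hi <= lo:
        lo, hi = x.min(), x.max() + 1e-6
    for _ in range(50):
        assign = np.abs(x - hi) < np.abs(x - lo)  # True -> upper cluster
        if assign.all() or (~assign).all():
            med = np.median(x)
            assign = x > med
            if assign.all() or (~assign).all():
                assign = x > x.min()
        nlo, nhi = x[~assign].mean(), x[assign].mean()
        if np.isclose(nlo, lo) and np.isclose(nhi, hi):
            break
        lo, hi = nlo, nhi
    return assign


def _em_run(x, assign, force_noise, tol, max_iter):
    """One EM run from a hard initial assignment (True = upper cluster)."""
    if assign.all() or (~assign).all():
        return None
    mu = np.array([x[~assign].mean(), x[assign].mean()])
    var = np.array([max(x[~assign].var(), 1e-4), max(x[assign].var(), 1e-4)])
    pi = np.array([1 - assign.mean(), assign.mean()]).clip(1e-3, 1 - 1e-3)
    ll = -np.inf
    converged = False
    for _ in range(max_iter):
        w = _responsibilities(x, mu, var, pi, force_noise)
        n = w.sum(axis=1)
        pi = (n / x.size).clip(1e-8, 1 - 1e-8)
        mu = (w @ x) / np.maximum(n, 1e-12)
        var = np.maximum(
            (w * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / np.maximum(n, 1e-12),
            1e-8,
        )
        new_ll = _loglik(x, mu, var, pi)
        if abs(new_ll - ll) <= tol * (abs(ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return mu, var, pi, ll, converged


def fit_omnibus_mixture(
    values, tol: float = 1e-8, max_iter: int = 500
) -> MixtureFit:
    """Maximum-likelihood two-component Gaussian mixture via EM.

    Values equal to zero (log2 of a zero count) are pinned to the noise
    cluster: a zero count cannot be signal, and the point mass would
    otherwise distort the Gaussian fit. EM is restarted from a
    deterministic set of initial splits and the highest-likelihood run is
    kept; if that run still falls below the single-Gaussian likelihood
    (a bad local optimum, e.g. on unimodal data) the convergence flag is
    lowered.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need at least 10 observations for the omnibus fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all observations identical")
    force_noise = x == 0.0
    inits = [_kmeans2_init(x)]
    for q in (0.05, 0.5, 0.95):
        inits.append(x > np.quantile(x, q))
    for f in (0.1, 0.25):  # low-range splits keep discretized noise together
        inits.append(x > x.min() + f * np.ptp(x))
    # a component narrower than 1% of the data spread models repeated
    # (discretized) values, not a cluster; such runs chase the unbounded
    # likelihood spike and are rejected unless nothing else converged
    sd_floor = 0.01 * x.std()
    best = None
    best_any = None
    for assign in inits:
        run = _em_run(x, assign, force_noise, tol, max_iter)
        if run is None:
            continue
        if best_any is None or run[3] > best_any[3]:
            best_any = run
        if np.sqrt(run[1].min()) >= sd_floor and (best is None or run[3] > best[3]):
            best = run
    mu, var, pi, ll, converged = best if best is not None else best_any
    single_ll = float(
        np.sum(norm.logpdf(x, x.mean(), max(x.std(), 1e-6)))
    )
    if ll < single_ll - 1e-6 * (abs(single_ll) + 1.0):
        converged = False  # stuck below the one-component likelihood
    if mu[0] > mu[1]:  # relabel so noise is the lower cluster
        mu, var, pi = mu[::-1], var[::-1], pi[::-1]
    return MixtureFit(
        mu_noise=float(mu[0]),
        mu_signal=float(mu[1]),
        var_noise=float(var[0]),
        var_signal=float(var[1]),
        pi_signal=float(pi[1]),
        loglik=ll,
        n_obs=x.size,
        converged=converged,
    )


def build_prior(
    omnibus: MixtureFit,
    kappa: float = 3.0,
    nt: float = 5.0,
    mix_weight: float = 5.0,
) -> MixturePrior:
    """Empirical-Bayes prior from the omnibus fit by method of moments.

    The mean prior is centered at the omnibus cluster means with
    pseudo-observation weight ``kappa * nt``; the Inverse-Gamma variance
    prior has its mode at the omnibus cluster variance with the same
    effective weight (shape = (kappa*nt - 3)/2, scale = (shape+1)*var);
    the Beta prior on the signal proportion defaults to Beta(5, 5), i.e.
    prior mass equivalent to 10 observations.
    """
    if kappa <= 0 or nt <= 0 or mix_weight <= 0:
        raise ValueError("kappa, nt and mix_weight must be positive")
    k0 = kappa * nt
    shape = max((k0 - 3.0) / 2.0, 0.51)
    scales = tuple((shape + 1.0) * v for v in (omnibus.var_noise, omnibus.var_signal))
    return MixturePrior(
        mean_locations=(omnibus.mu_noise, omnibus.mu_signal),
        mean_strength=k0,
        var_shape=(shape, shape),
        var_scale=scales,
        mix_a=mix_weight,
        mix_b=mix_weight,
    )


def fit_gene_map(
    values,
    prior: MixturePrior,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """MAP fit of the per-gene mixture by Expectation Conditional Maximization.

    CM steps update the mixing proportion (Beta-MAP), then cluster means
    (Normal shrinkage toward the prior centers), then variances (joint
    posterior mode of the Normal-Inverse-Gamma). With final responsibilities
    summing to n_signal over the signal cluster, the MAP mixing proportion
    is (n_signal + mix_a - 1) / (n + mix_a + mix_b - 2).
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 observations for a gene fit")
    force_noise = x == 0.0
    k0 = prior.mean_strength
    m = np.asarray(prior.mean_locations, float)
    a = np.asarray(prior.var_shape, float)
    b = np.asarray(prior.var_scale, float)
    mu = m.copy()
    var = b / (a + 1.0)
    pi = np.array([0.5, 0.5])
    obj = -np.inf
    converged = False
    for _ in range(max_iter):
        w = _responsibilities(x, mu, var, pi, force_noise)
        n = w.sum(axis=1)
        pi1 = (n[1] + prior.mix_a - 1.0) / (x.size + prior.mix_a + prior.mix_b - 2.0)
        pi = np.array([1 - pi1, pi1]).clip(1e-8, 1 - 1e-8)
        mu = (k0 * m + w @ x) / (k0 + n)
        var = np.maximum(
            (2 * b + k0 * (mu - m) ** 2 + (w * (x[None, :] - mu[:, None]) ** 2).sum(axis=1))
            / (n + 2 * a + 3.0),
            1e-8,
        )
        new_obj = _map_objective(x, mu, var, pi, prior)
        if abs(new_obj - obj) <= tol * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if mu[0] > mu[1]:
        mu, var, pi = mu[::-1], var[::-1], pi[::-1]
    return MixtureFit(
        mu_noise=float(mu[0]),
        mu_signal=float(mu[1]),
        var_noise=float(var[0]),
        var_signal=float(var[1]),
        pi_signal=float(pi[1]),
        loglik=obj,
        n_obs=x.size,
        converged=converged,
    )


def _map_objective(x, mu, var, pi, prior: MixturePrior) -> float:
    """Log-likelihood plus log-prior (unnormalized), the ECM objective."""
    ll = _loglik(x, mu, var, pi)
    k0 = prior.mean_strength
    m = np.asarray(prior.mean_locations)
    a = np.asarray(prior.var_shape)
    b = np.asarray(prior.var_scale)
    lp = np.sum(
        -0.5 * np.log(var) - 0.5 * k0 * (mu - m) ** 2 / var
        - (a + 1.0) * np.log(var) - b / var
    )
    lp += (prior.mix_a - 1.0) * np.log(pi[1]) + (prior.mix_b - 1.0) * np.log(pi[0])
    return float(ll + lp)


def posterior_signal_prob(x, fit: MixtureFit):
    """Posterior probability that an observation belongs to the signal cluster."""
    x = np.asarray(x, float)
    ls = np.log(fit.pi_signal) + norm.logpdf(x, fit.mu_signal, np.sqrt(fit.var_signal))
    ln = np.log1p(-fit.pi_signal) + norm.logpdf(x, fit.mu_noise, np.sqrt(fit.var_noise))
    m = np.maximum(ls, ln)
    p = np.exp(ls - m) / (np.exp(ls - m) + np.exp(ln - m) + _EPS)
    return p if p.ndim else float(p)


def threshold_gene(values, fit: MixtureFit):
    """Truncate noise-classified observations to zero.

    Observations with posterior probability strictly greater than .5 of
    belonging to the noise cluster become 0; all others (including the
    exact .5 boundary) are kept unchanged.
    """
    x = np.asarray(values, float)
    noise_prob = 1.0 - posterior_signal_prob(x, fit)
    out = np.where(noise_prob > 0.5, 0.0, x)
    return out


def threshold_table(
    table,
    value: str = "lcount",
    kappa: float = 3.0,
    nt: float = 5.0,
    mix_weight: float = 5.0,
    tol: float = 1e-8,
    max_iter: int = 500,
    unimodal_sd_factor: float = 0.5,
):
    """Threshold every gene in a CellTable, returning (table-with-et, fits).

    The omnibus mixture is fitted to the pooled positive values of the
    chosen column, the empirical-Bayes prior is built from it, and each
    gene is fitted by MAP ECM. A gene whose MAP fit is effectively
    unimodal (cluster-mean gap below ``unimodal_sd_factor`` pooled
    standard deviations) falls back to the omnibus-derived threshold to
    avoid arbitrary splits of unimodal genes.
    """
    from .data import CellTable

    table.require(value)
    df = table.df
    pooled = df.loc[df[value] > 0, value].to_numpy(float)
    omnibus = fit_omnibus_mixture(pooled, tol=tol, max_iter=max_iter)
    prior = build_prior(omnibus, kappa=kappa, nt=nt, mix_weight=mix_weight)
    fits: dict[str, MixtureFit] = {}
    et = np.empty(len(df), float)
    for gene, idx in df.groupby("gene_id", sort=True).indices.items():
        x = df[value].to_numpy(float)[idx]
        fit = fit_gene_map(x, prior, tol=tol, max_iter=max_iter)
        pooled_sd = np.sqrt(
            (1 - fit.pi_signal) * fit.var_noise + fit.pi_signal * fit.var_signal
        )
        if fit.mu_signal - fit.mu_noise < unimodal_sd_factor * pooled_sd:
            fit = replace(
                omnibus, n_obs=fit.n_obs, converged=fit.converged
            )  # omnibus fallback for effectively unimodal genes
        fits[gene] = fit
        et[idx] = threshold_gene(x, fit)
    out = df.copy()
    out["et"] = et
    return CellTable(out), fits
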