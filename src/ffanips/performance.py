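"""Two-phase ROC performance model plus standard confusion-matrix metrics.

Phase 1 (training): a Markov chain Monte Carlo fit learns how positive
samples' z-scores scale with fetal fraction and read depth,

    z_i ~ Normal(beta * FF_i * sqrt(N_i / N0), sigma_z),

with priors beta ~ HalfNormal(scale) on (0, inf) and sigma_z = 1 +
HalfNormal(scale) (the positives cannot be less noisy than the null).  The
``beta * FF * sqrt(N/N0)`` form follows from the Poisson z-statistic: signal
is proportional to FF, noise to 1/sqrt(depth).

Phase 2 (simulation): mock positives are drawn by sampling (beta, sigma_z)
from the posterior and FF/depth from population distributions, decoupling
the performance estimate from the biased FF of the few observed positives;
mock negatives are standard normal (the euploid z-scores are standard normal
by construction of the reference).  Sweeping the z threshold over both mock
populations yields the ROC curve, with uncertainty bands from posterior
draws.

The sampler is a self-contained adaptive Metropolis-Hastings (Gaussian
proposals, step size adapted during burn-in toward 20-40% acceptance),
run as 4 lock-stepped chains with split-chain potential-scale-reduction as
the convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np


class PerformanceError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """MCMC did not converge; advise longer chains."""


@dataclass(frozen=True)
class McmcSettings:
    n_chains: int = 4
    burn: int = 2000
    keep: int = 8000
    target_accept_low: float = 0.2
    target_accept_high: float = 0.4
    rhat_limit: float = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 4:
            raise PerformanceError("at least 4 chains required for diagnostics")


@dataclass(frozen=True)
class Priors:
    beta_scale: float = 200.0
    sigma_scale: float = 2.0
    sigma_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_floor < 1.0:
            raise PerformanceError(
                "sigma_z floor below 1 would allow positives less noisy than the null"
            )


@dataclass(frozen=True)
class PosteriorSamples:
    """Kept (beta, sigma_z) draws, pooled across chains, plus diagnostics."""

    beta: np.ndarray          # (n_chains, keep)
    sigma_z: np.ndarray
    acceptance_rate: float
    rhat: dict[str, float]
    seed: int
    weakly_identified: bool = False

    @property
    def flat(self) -> np.ndarray:
        return np.stack([self.beta.ravel(), self.sigma_z.ravel()], axis=1)

    def credible_interval(self, param: str = "beta", level: float = 0.95
                          ) -> tuple[float, float]:
        draws = getattr(self, param if param != "sigma" else "sigma_z").ravel()
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(draws, lo)), float(np.quantile(draws, 1.0 - lo)))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin)."""
    n_chains, n = chains.shape
    half = n // 2
    split = chains[:, : 2 * half].reshape(n_chains * 2, half)
    m, n = split.shape
    chain_means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    if w <= 0:
        return np.inf
    return float(np.sqrt(var_plus / w))


def fit_z_scaling_mcmc(
    positives: list[tuple[float, float, float]],
    priors: Priors | None = None,
    settings: McmcSettings | None = None,
    seed: int = 0,
    reference_depth: float = 500_000.0,
) -> PosteriorSamples:
    """Fit the z-scaling law to observed positives ((z, FF, N) triples).

    Raises on fewer than 5 positives or on non-convergence (split-Rhat >=
    1.05).  A design with no FF/depth variation is accepted but flagged
    ``weakly_identified`` (beta and sigma_z trade off against each other).
    """
    priors = priors or Priors()
    settings = settings or McmcSettings()
    if len(positives) < 5:
        raise PerformanceError(f"need >= 5 positives, got {len(positives)}")
    arr = np.asarray(positives, dtype=float)
    z, ff, depth = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(ff <= 0) or np.any(depth <= 0):
        raise PerformanceError("positives must have FF > 0 and depth > 0")
    x = ff * np.sqrt(depth / reference_depth)
    weakly_identified = float(np.ptp(x)) < 1e-12 * max(1.0, float(np.max(x)))

    rng = np.random.default_rng(seed)
    nc = settings.n_chains

    def log_post(beta: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        lp = np.full(beta.shape, -np.inf)
        ok = (beta > 0) & (sigma >= priors.sigma_floor)
        if not np.any(ok):
            return lp
        b, s = beta[ok], sigma[ok]
        resid = z[None, :] - b[:, None] * x[None, :]
        loglik = -0.5 * np.sum((resid / s[:, None]) ** 2, axis=1) \
            - z.size * np.log(s)
        lprior = -0.5 * (b / priors.beta_scale) ** 2 \
            - 0.5 * ((s - priors.sigma_floor) / priors.sigma_scale) ** 2
        lp[ok] = loglik + lprior
        return lp

    # moment-based start, jittered per chain
    beta0 = max(float(np.sum(z * x) / np.sum(x * x)), 1e-3)
    sigma0 = max(float(np.std(z - beta0 * x, ddof=1)), priors.sigma_floor + 0.01)
    beta = beta0 * np.exp(0.1 * rng.standard_normal(nc))
    sigma = priors.sigma_floor + (sigma0 - priors.sigma_floor) * np.exp(
        0.1 * rng.standard_normal(nc))
    lp = log_post(beta, sigma)

    step = np.full((nc, 2), 1.0)
    step[:, 0] = max(0.1 * beta0, 1e-3)
    step[:, 1] = 0.3
    kept_beta = np.empty((nc, settings.keep))
    kept_sigma = np.empty((nc, settings.keep))
    n_accept = 0
    n_total = 0
    target_mid = 0.5 * (settings.target_accept_low + settings.target_accept_high)
    batch_accept = np.zeros(nc)

    total_iters = settings.burn + settings.keep
    for t in range(total_iters):
        prop_beta = beta + step[:, 0] * rng.standard_normal(nc)
        prop_sigma = sigma + step[:, 1] * rng.standard_normal(nc)
        lp_prop = log_post(prop_beta, prop_sigma)
        accept = np.log(rng.random(nc)) < lp_prop - lp
        beta = np.where(accept, prop_beta, beta)
        sigma = np.where(accept, prop_sigma, sigma)
        lp = np.where(accept, lp_prop, lp)
        batch_accept += accept

        if t < settings.burn:
            if (t + 1) % 50 == 0:
                rate = batch_accept / 50.0
                step *= np.exp((rate - target_mid))[:, None]
                batch_accept[:] = 0.0
        else:
            kept_beta[:, t - settings.burn] = beta
            kept_sigma[:, t - settings.burn] = sigma
            n_accept += int(accept.sum())
            n_total += nc

    rhat = {
        "beta": _split_rhat(kept_beta),
        "sigma_z": _split_rhat(kept_sigma),
    }
    if max(rhat.values()) >= settings.rhat_limit and not weakly_identified:
        raise ConvergenceError(
            f"split-Rhat {rhat} >= {settings.rhat_limit}; run longer chains"
        )
    return PosteriorSamples(
        beta=kept_beta,
        sigma_z=kept_sigma,
        acceptance_rate=n_accept / max(n_total, 1),
        rhat=rhat,
        seed=seed,
        weakly_identified=weakly_identified,
    )


def _draw_values(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    """Accept a scalar, an empirical array (resampled), or a frozen
    distribution with ``.rvs``."""
    if np.isscalar(dist):
        return np.full(n, float(dist))
    if hasattr(dist, "rvs"):
        return np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
    arr = np.asarray(dist, dtype=float)
    if arr.size == n:
        return arr.copy()          # paired use: caller supplies exact values
    return rng.choice(arr, size=n, replace=True)


def simulate_mock_cohort(
    posterior: PosteriorSamples,
    ff_distribution,
    depth_distribution,
    n_mock_pos: int,
    n_mock_neg: int,
    seed: int = 0,
    reference_depth: float = 500_000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate mock positive/negative z arrays.

    Each mock positive draws (beta, sigma_z) from the posterior, FF and N
    from the supplied population distributions, then z ~ Normal(beta * FF *
    sqrt(N/N0), sigma_z).  Mock negatives are standard normal.  FF and depth
    inputs may be scalars, empirical arrays (length n -> used as-is, else
    resampled), or frozen distributions.  The draw order is fixed so that two
    calls with the same seed and n share the (beta, sigma_z, noise) draws —
    enabling paired pre/post-FFA comparisons with common random numbers.
    """
    draws = posterior.flat
    if draws.size == 0:
        raise PerformanceError("empty posterior")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, draws.shape[0], size=n_mock_pos)
    beta, sigma = draws[idx, 0], draws[idx, 1]
    noise = rng.standard_normal(n_mock_pos)
    ff = _draw_values(ff_distribution, n_mock_pos, rng)
    depth = _draw_values(depth_distribution, n_mock_pos, rng)
    z_pos = beta * ff * np.sqrt(depth / reference_depth) + sigma * noise
    z_neg = rng.standard_normal(n_mock_neg)
    return z_pos, z_neg


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    sens_lo: np.ndarray | None = None
    sens_hi: np.ndarray | None = None
    spec_lo: np.ndarray | None = None
    spec_hi: np.ndarray | None = None
    label: str = ""
    n_mock_pos: int = 0
    n_mock_neg: int = 0

    def auc(self) -> float:
        """Area under the ROC curve via the trapezoid rule over (FPR, TPR),
        anchored at (0,0) and (1,1)."""
        fpr = 1.0 - self.specificity
        order = np.argsort(fpr, kind="stable")
        x = np.concatenate([[0.0], fpr[order], [1.0]])
        y = np.concatenate([[0.0], self.sensitivity[order], [1.0]])
        return float(np.trapezoid(y, x))


def roc_from_mocks(
    z_pos: np.ndarray,
    z_neg: np.ndarray,
    thresholds: np.ndarray,
    label: str = "",
) -> RocResult:
    """Threshold sweep: sensitivity = P(z_pos >= t), specificity = P(z_neg < t)."""
    z_pos = np.asarray(z_pos, dtype=float)
    z_neg = np.asarray(z_neg, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if z_pos.size == 0 or z_neg.size == 0:
        raise PerformanceError("mock arrays must be nonempty")
    if thresholds.size == 0 or np.any(np.isnan(thresholds)) \
            or np.any(np.diff(thresholds) < 0):
        raise PerformanceError("thresholds must be sorted, NaN-free, nonempty")
    sens = np.array([np.mean(z_pos >= t) for t in thresholds])
    spec = np.array([np.mean(z_neg < t) for t in thresholds])
    assert np.all(np.diff(sens) <= 0) and np.all(np.diff(spec) >= 0)
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     label=label, n_mock_pos=z_pos.size, n_mock_neg=z_neg.size)


def roc_with_uncertainty(
    posterior: PosteriorSamples,
    ff_distribution,
    depth_distribution,
    thresholds: np.ndarray,
    n_mock_pos: int = 100_000,
    n_mock_neg: int = 100_000,
    n_interval_draws: int = 200,
    n_per_draw: int = 2000,
    seed: int = 0,
    reference_depth: float = 500_000.0,
    label: str = "",
) -> RocResult:
    """Central ROC from the full posterior plus 2.5/97.5-percentile bands
    from per-draw mock cohorts (one (beta, sigma_z) draw each)."""
    z_pos, z_neg = simulate_mock_cohort(
        posterior, ff_distribution, depth_distribution, n_mock_pos, n_mock_neg,
        seed=seed, reference_depth=reference_depth)
    central = roc_from_mocks(z_pos, z_neg, thresholds, label=label)

    rng = np.random.default_rng(seed + 1)
    draws = posterior.flat
    pick = rng.integers(0, draws.shape[0], size=n_interval_draws)
    sens_mat = np.empty((n_interval_draws, thresholds.size))
    spec_mat = np.empty((n_interval_draws, thresholds.size))
    for i, k in enumerate(pick):
        beta, sigma = draws[k]
        ff = _draw_values(ff_distribution, n_per_draw, rng)
        depth = _draw_values(depth_distribution, n_per_draw, rng)
        zp = beta * ff * np.sqrt(depth / reference_depth) \
            + sigma * rng.standard_normal(n_per_draw)
        zn = rng.standard_normal(n_per_draw)
        sens_mat[i] = [np.mean(zp >= t) for t in thresholds]
        spec_mat[i] = [np.mean(zn < t) for t in thresholds]
    return RocResult(
        thresholds=central.thresholds,
        sensitivity=central.sensitivity,
        specificity=central.specificity,
        sens_lo=np.quantile(sens_mat, 0.025, axis=0),
        sens_hi=np.quantile(sens_mat, 0.975, axis=0),
        spec_lo=np.quantile(spec_mat, 0.025, axis=0),
        spec_hi=np.quantile(spec_mat, 0.975, axis=0),
        label=label,
        n_mock_pos=n_mock_pos,
        n_mock_neg=n_mock_neg,
    )


@dataclass(frozen=True)
class PerformanceEstimate:
    label: str
    threshold: float
    sensitivity: float
    specificity: float
    sens_interval: tuple[float, float] | None = None
    spec_interval: tuple[float, float] | None = None


def performance_summary(
    roc: RocResult,
    threshold: float,
) -> PerformanceEstimate:
    """Sensitivity/specificity (with percentile intervals when available) at
    one threshold of the ROC grid."""
    i = int(np.argmin(np.abs(roc.thresholds - threshold)))
    if abs(roc.thresholds[i] - threshold) > 1e-9:
        raise PerformanceError(f"threshold {threshold} not on the ROC grid")
    sens_iv = (float(roc.sens_lo[i]), float(roc.sens_hi[i])) \
        if roc.sens_lo is not None else None
    spec_iv = (float(roc.spec_lo[i]), float(roc.spec_hi[i])) \
        if roc.spec_lo is not None else None
    return PerformanceEstimate(
        label=roc.label, threshold=float(roc.thresholds[i]),
        sensitivity=float(roc.sensitivity[i]),
        specificity=float(roc.specificity[i]),
        sens_interval=sens_iv, spec_interval=spec_iv,
    )


def aggregate_performance(
    estimates: list[PerformanceEstimate],
    weights: list[float] | None = None,
    label: str = "aggregate",
) -> PerformanceEstimate:
    """Aggregate a region class: equal weights by default, incidence weights
    optionally."""
    if not estimates:
        raise PerformanceError("nothing to aggregate")
    w = np.ones(len(estimates)) if weights is None else np.asarray(weights, dtype=float)
    if w.size != len(estimates) or np.any(w < 0) or w.sum() <= 0:
        raise PerformanceError("invalid aggregation weights")
    w = w / w.sum()
    return PerformanceEstimate(
        label=label,
        threshold=estimates[0].threshold,
        sensitivity=float(np.sum(w * [e.sensitivity for e in estimates])),
        specificity=float(np.sum(w * [e.specificity for e in estimates])),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise PerformanceError("confusion counts must be nonnegative")


def confusion_metrics(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """(sensitivity, specificity) by the standard definitions
    TP/(TP+FN) and TN/(TN+FP); an undefined metric is None, not 0."""
    sens = float(Fraction(counts.tp, counts.tp + counts.fn)) \
        if counts.tp + counts.fn > 0 else None
    spec = float(Fraction(counts.tn, counts.tn + counts.fp)) \
        if counts.tn + counts.fp > 0 else None
    return sens, spec
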