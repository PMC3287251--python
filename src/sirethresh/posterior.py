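"""Posterior summaries and recovery metrics for threshold-model chains."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PosteriorSummary",
    "RecoveryMetrics",
    "BiasReport",
    "hpd_interval",
    "summarize_chain",
    "pearson_true_vs_estimated",
    "bias_report",
    "effective_sample_size",
    "geweke_z",
]


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    hpd_lower: float
    hpd_upper: float
    n_draws: int


@dataclass(frozen=True)
class RecoveryMetrics:
    """Estimation-quality scores against simulation truth."""

    pearson_fixed: float
    pearson_sire: float
    relative_bias_sigma_u2: float


@dataclass(frozen=True)
class BiasReport:
    relative_bias: float
    biased: bool  # truth outside the HPD interval


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-posterior-density interval by the shortest-sorted-window method.

    Returns the shortest contiguous window over the sorted draws containing
    ceil(mass * n) draws; for a unimodal posterior this converges to the HPD
    region.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws for an HPD interval")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    m = int(np.ceil(mass * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize_chain(draws: np.ndarray, mass: float = 0.95) -> PosteriorSummary:
    """Mean, SD (n-1 denominator) and HPD bounds of post-burn-in draws."""
    x = np.asarray(draws, dtype=float).ravel()
    lo, hi = hpd_interval(x, mass)
    return PosteriorSummary(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        hpd_lower=lo,
        hpd_upper=hi,
        n_draws=x.size,
    )


def pearson_true_vs_estimated(true_values: np.ndarray, estimates: np.ndarray) -> float:
    """Pearson product-moment correlation between true effects and estimates."""
    t = np.asarray(true_values, dtype=float).ravel()
    e = np.asarray(estimates, dtype=float).ravel()
    if t.size != e.size or t.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if t.std() == 0 or e.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(t, e)[0, 1])


def bias_report(summary: PosteriorSummary, truth: float) -> BiasReport:
    """Relative bias of the posterior mean and an HPD-exclusion flag."""
    if truth <= 0:
        raise ValueError("truth must be > 0")
    rel = (summary.mean - truth) / truth
    outside = truth < summary.hpd_lower or truth > summary.hpd_upper
    return BiasReport(relative_bias=float(rel), biased=bool(outside))


def effective_sample_size(draws: np.ndarray) -> float:
    """Bulk effective sample size of a single chain (via ArviZ)."""
    import arviz as az

    x = np.asarray(draws, dtype=float).ravel()
    return float(az.ess(x[np.newaxis, :]))


def geweke_z(draws: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke-style convergence z-score comparing early and late chain means.

    Means of the first ``first`` and last ``last`` fractions are compared,
    with variances estimated by non-overlapping batch means to absorb
    autocorrelation.  |z| well above ~2 signals a drifting chain.
    """
    x = np.asarray(draws, dtype=float).ravel()
    a = x[: max(10, int(first * x.size))]
    b = x[-max(10, int(last * x.size)) :]

    def batch_var_of_mean(seg: np.ndarray) -> float:
        nb = max(5, int(np.sqrt(seg.size)))
        size = seg.size // nb
        means = seg[: nb * size].reshape(nb, size).mean(axis=1)
        return float(means.var(ddof=1) / nb)

    denom = np.sqrt(batch_var_of_mean(a) + batch_var_of_mean(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)
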