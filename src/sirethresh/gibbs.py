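"""Gibbs sampler for the Bayesian threshold sire model with a g-prior option.

Model (liability scale, residual variance fixed at 1 for identification):

    l = X beta + Z s + e,        e ~ N(0, I)
    y_i = 1(l_i > 0)
    s | A, sigma_u2 ~ N(0, A sigma_u2)
    sigma_u2 ~ scaled-inv-chi2(nu_u, S2_u)
    beta_j (non-ECP) ~ N(0, sigma_prior2)            [vague, default 1e6]
    beta_ECP | beta0 ~ N(beta0, [g X'X]^{-1})        [Zellner-style g-prior]

Classes with an extreme case problem (all responses 0 or all 1) carry no
likelihood information about their effect; the g-prior shrinks them toward a
reference mean beta0 (by default the running average of the non-ECP
solutions).  All full conditionals are in closed form: truncated normal for
the liabilities, normal for beta and s, scaled inverse chi-square for
sigma_u2 (data augmentation in the Albert–Chib style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cholesky, eigh, solve_triangular
from scipy.special import ndtr, ndtri

from .simulator import UNKNOWN, Dataset, Pedigree, as_rng, ecp_classes

__all__ = [
    "GibbsConfig",
    "ChainState",
    "GibbsResult",
    "SireFactor",
    "build_a_inverse",
    "relationship_matrix",
    "sample_liabilities",
    "sample_fixed_nonecp",
    "sample_fixed_ecp",
    "compute_beta0",
    "sample_gauge_shift",
    "sire_factor",
    "sample_sires",
    "sample_sire_variance",
    "run_chain",
]


@dataclass(frozen=True)
class GibbsConfig:
    """Chain controls and prior hyperparameters.

    ``g_weight`` is the relative weight of the g-prior on ECP classes;
    ``g_weight = 0`` reduces their conditional to the flat-prior one, i.e.
    the normal-prior (NP) analysis.  ``S2_u``/``nu_u`` parameterize the
    scaled inverse chi-square prior on the sire variance.  ``beta0_fixed``
    pins the g-prior mean to a constant instead of the per-iteration average
    of the non-ECP solutions.
    """

    g_weight: float = 0.0
    nonecp_prior_variance: float = 1e6
    nu_u: float = 2.0
    S2_u: float = 0.05
    n_iterations: int = 75_000
    burn_in: int = 25_000
    thinning: int = 1
    seed: int = 0
    beta0_fixed: Optional[float] = None
    recenter: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.g_weight <= 1.0:
            raise ValueError("g_weight must lie in [0, 1]")
        if self.nonecp_prior_variance <= 0 or self.nu_u <= 0 or self.S2_u <= 0:
            raise ValueError("prior hyperparameters must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class ChainState:
    """Current values of all augmented/model parameters."""

    liabilities: np.ndarray
    beta: np.ndarray
    s: np.ndarray
    sigma_u2: float
    beta0: float = 0.0


@dataclass(frozen=True)
class GibbsResult:
    """Retained output of one chain.

    ``sigma_u2_draws`` are the post-burn-in (thinned) sire-variance draws;
    ``beta_mean``/``s_mean`` are posterior means of the effects accumulated
    over the same draws.  ``sigma_u2_trace`` is the full unthinned trace for
    convergence diagnostics.
    """

    sigma_u2_draws: np.ndarray
    sigma_u2_trace: np.ndarray
    beta_mean: np.ndarray
    s_mean: np.ndarray
    ecp: np.ndarray
    config: GibbsConfig
    n_retained: int = field(default=0)


def build_a_inverse(pedigree: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix of a sire pedigree.

    Henderson's rules with only one parent (the sire of the sire) known and
    no inbreeding: the Mendelian-sampling variance is d_i = 1 for unknown
    parent and d_i = 3/4 for a known parent; each individual contributes
    1/d_i at (i,i), -1/(2 d_i) at (i,p) and (p,i) and 1/(4 d_i) at (p,p).
    """
    n = pedigree.n_sires
    parents = pedigree.sire_of_sire
    rows, cols, vals = [], [], []
    for i in range(n):
        p = parents[i]
        if p == UNKNOWN:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
        else:
            inv_d = 1.0 / 0.75
            rows += [i, i, p, p]
            cols += [i, p, i, p]
            vals += [inv_d, -0.5 * inv_d, -0.5 * inv_d, 0.25 * inv_d]
    a_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    a_inv.sum_duplicates()
    return a_inv


def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular recursion.

    Kept as an independent cross-check of :func:`build_a_inverse` (the two
    are exact inverses of each other); O(n^2), so suitable for small
    pedigrees only.
    """
    n = pedigree.n_sires
    order = np.argsort(pedigree.generation, kind="stable")
    a = np.zeros((n, n))
    for i in order:
        p = pedigree.sire_of_sire[i]
        if p == UNKNOWN:
            a[i, i] = 1.0
        else:
            a[i, :] = 0.5 * a[p, :]
            a[:, i] = a[i, :]
            a[i, i] = 1.0  # 0.25*a_pp + d_i = 0.25 + 0.75 without inbreeding
    return a


# ---------------------------------------------------------------------------
# full-conditional samplers
# ---------------------------------------------------------------------------


def _truncated_normal(mu: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance normals truncated to (0, inf) where y=1, (-inf, 0] where y=0.

    Inverse-CDF sampling through the tail that stays numerically accurate:
    for y=1 the survival function is inverted on (0, Phi(mu)], for y=0 the
    CDF on (0, Phi(-mu)].
    """
    u = rng.random(mu.size)
    pos = y == 1
    out = np.empty_like(mu)
    # smallest subnormal: keeps ndtri finite when ndtr underflows for means
    # ~40 sd beyond the threshold (transients far from the mode); the sign
    # clamps below then place the draw at the threshold, which is where
    # essentially all conditional mass sits in that regime
    tiny = np.finfo(np.float64).smallest_subnormal
    # P(l > 0) = Phi(mu); draw v ~ U(0, Phi(mu)) and set l = mu - ndtri(v)
    v1 = np.maximum(u[pos] * ndtr(mu[pos]), tiny)
    out[pos] = mu[pos] - ndtri(v1)
    v0 = np.maximum(u[~pos] * ndtr(-mu[~pos]), tiny)
    out[~pos] = mu[~pos] + ndtri(v0)
    # guard against round-off at the threshold
    np.maximum(out, 1e-12, where=pos, out=out)
    np.minimum(out, 0.0, where=~pos, out=out)
    return out


def sample_liabilities(
    state: ChainState, dataset: Dataset, rng: np.random.Generator
) -> np.ndarray:
    """Draw liabilities from their truncated-normal full conditional."""
    mu = state.beta[dataset.fixed_class] + state.s[dataset.sire]
    return _truncated_normal(mu, dataset.y, rng)


def _class_residual_sums(state: ChainState, dataset: Dataset) -> np.ndarray:
    """Per-class sums of sire-adjusted residuals l - Zs."""
    r = state.liabilities - state.s[dataset.sire]
    return np.bincount(dataset.fixed_class, weights=r, minlength=dataset.n_classes)


def sample_fixed_nonecp(
    state: ChainState,
    dataset: Dataset,
    prior_variance: float,
    rng: np.random.Generator,
    *,
    classes: np.ndarray | None = None,
    class_sums: np.ndarray | None = None,
    class_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Draw non-ECP class effects from their normal full conditional.

    With residual variance 1 and prior N(0, prior_variance), class j has
    conditional N(sum_j / (n_j + 1/prior_variance), 1 / (n_j + 1/prior_variance))
    where sum_j adds l_i - s_sire(i) over the class's records.
    """
    if prior_variance <= 0:
        raise ValueError("prior_variance must be > 0")
    if class_sums is None:
        class_sums = _class_residual_sums(state, dataset)
    if class_counts is None:
        class_counts = np.bincount(dataset.fixed_class, minlength=dataset.n_classes)
    if classes is None:
        classes = np.arange(dataset.n_classes)
    prec = class_counts[classes] + 1.0 / prior_variance
    mean = class_sums[classes] / prec
    return mean + rng.standard_normal(classes.size) / np.sqrt(prec)


def sample_fixed_ecp(
    state: ChainState,
    dataset: Dataset,
    g: float,
    beta0: float,
    rng: np.random.Generator,
    *,
    classes: np.ndarray | None = None,
    class_sums: np.ndarray | None = None,
    class_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ECP class effects from the g-prior full conditional.

    Class j with least-squares estimate bhat_j (mean of l - Zs over its
    records) is drawn from N((bhat_j + g beta0)/(1+g), 1/((1+g) n_j)).
    g = 0 recovers the flat-prior conditional N(bhat_j, 1/n_j).
    """
    if not 0.0 <= g <= 1.0:
        raise ValueError("g must lie in [0, 1]")
    if classes is None:
        classes = ecp_classes(dataset)
    if class_sums is None:
        class_sums = _class_residual_sums(state, dataset)
    if class_counts is None:
        class_counts = np.bincount(dataset.fixed_class, minlength=dataset.n_classes)
    n = class_counts[classes]
    if classes.size and n.min() == 0:
        raise ValueError("ECP classes must be non-empty (X'X full rank)")
    bhat = class_sums[classes] / n
    mean = (bhat + g * beta0) / (1.0 + g)
    sd = 1.0 / np.sqrt((1.0 + g) * n)
    return mean + sd * rng.standard_normal(classes.size)


def compute_beta0(state: ChainState, nonecp: np.ndarray) -> float:
    """g-prior reference mean: average of the current non-ECP solutions."""
    if nonecp.size == 0:
        raise ValueError(
            "all fixed-effect classes are ECP; beta0 (and the likelihood) is "
            "unidentifiable"
        )
    return float(state.beta[nonecp].mean())


@dataclass(frozen=True)
class SireFactor:
    """Pre-factorized pieces for the joint sire draw.

    The conditional precision is C(lam) = Z'Z + lam * A^{-1} with
    lam = sigma_e2 / sigma_u2 = 1 / sigma_u2.  Writing A^{-1} = L L' and
    M = L^{-1} Z'Z L^{-T} = Q diag(evals) Q', we get
    C = L Q diag(lam + evals) Q' L', so with U = L^{-T} Q both the mean
    solve and the covariance square root reduce to two dense mat-vecs per
    iteration for any value of lam.
    """

    u: np.ndarray  # L^{-T} Q
    evals: np.ndarray
    chol_a_inv: np.ndarray  # lower Cholesky factor L of A^{-1}


def sire_factor(a_inv: sp.spmatrix | np.ndarray, record_counts: np.ndarray) -> SireFactor:
    """Factorize the sire conditional for repeated draws at varying sigma_u2."""
    a_dense = a_inv.toarray() if sp.issparse(a_inv) else np.asarray(a_inv, dtype=float)
    n = a_dense.shape[0]
    L = cholesky(a_dense, lower=True)
    linv = solve_triangular(L, np.eye(n), lower=True)
    m = (linv * record_counts[np.newaxis, :]) @ linv.T
    evals, q = eigh(m)
    u = solve_triangular(L, q, lower=True, trans="T")
    return SireFactor(u=u, evals=np.maximum(evals, 0.0), chol_a_inv=L)


def sample_sires(
    state: ChainState,
    dataset: Dataset,
    a_inv: sp.spmatrix | np.ndarray,
    rng: np.random.Generator,
    *,
    factor: SireFactor | None = None,
) -> np.ndarray:
    """Joint multivariate-normal draw of sire transmitting abilities.

    The full conditional is N(C^{-1} Z'(l - X beta), C^{-1}) with
    C = Z'Z + A^{-1} / sigma_u2 (residual variance 1).
    """
    if state.sigma_u2 <= 0:
        raise ValueError("sigma_u2 must be > 0")
    if factor is None:
        counts = np.bincount(dataset.sire, minlength=dataset.n_sires).astype(float)
        factor = sire_factor(a_inv, counts)
    rhs = np.bincount(
        dataset.sire,
        weights=state.liabilities - state.beta[dataset.fixed_class],
        minlength=dataset.n_sires,
    )
    lam = 1.0 / state.sigma_u2
    denom = lam + factor.evals
    w = factor.u.T @ rhs
    mean = factor.u @ (w / denom)
    noise = factor.u @ (rng.standard_normal(denom.size) / np.sqrt(denom))
    return mean + noise


def sample_sire_variance(
    state: ChainState,
    a_inv: sp.spmatrix | np.ndarray,
    nu_u: float,
    S2_u: float,
    rng: np.random.Generator,
    *,
    chol_a_inv: np.ndarray | None = None,
) -> float:
    """Draw sigma_u2 from its scaled inverse chi-square full conditional.

    Degrees of freedom q + nu_u (q sires) and scale
    (s' A^{-1} s + nu_u * S2_u) / (q + nu_u); equivalently
    sigma_u2 = (s' A^{-1} s + nu_u S2_u) / chi2_{q + nu_u}.
    """
    if nu_u <= 0 or S2_u <= 0:
        raise ValueError("nu_u and S2_u must be > 0")
    s = state.s
    q = s.size
    if q == 0:
        quad = 0.0
    elif chol_a_inv is not None:
        quad = float(np.sum((chol_a_inv.T @ s) ** 2))
    else:
        quad = float(s @ (a_inv @ s))
    df = q + nu_u
    return (quad + nu_u * S2_u) / rng.chisquare(df)


def sample_gauge_shift(
    state: ChainState,
    a_inv_ones: np.ndarray,
    ones_quad: float,
    nonecp: np.ndarray,
    prior_variance: float,
    rng: np.random.Generator,
    *,
    g: float = 0.0,
    ecp: np.ndarray | None = None,
    ecp_counts: np.ndarray | None = None,
    beta0_fixed: float | None = None,
) -> float:
    """Interweaving move along the likelihood-flat shift direction.

    Adding a constant to every class effect and subtracting it from every
    sire effect leaves all liability means (hence the truncated-normal
    likelihood) unchanged; only the priors identify that direction.  The
    alternating scan updates it by a slow random walk, which at high ECP
    fractions couples with the sire-variance draw into a quasi-absorbing
    drift.  This extra Gibbs step draws the shift from its exact Gaussian
    conditional under the priors, restoring practical ergodicity without
    changing the stationary distribution.

    ``a_inv_ones`` is A^{-1} 1 and ``ones_quad`` is 1' A^{-1} 1.  When the
    g-prior mean beta0 is the running average of the non-ECP solutions it
    shifts along with the effects and its term drops out; a fixed beta0 adds
    a restoring term for the ECP classes.
    """
    prec = ones_quad / state.sigma_u2 + nonecp.size / prior_variance
    num = float(a_inv_ones @ state.s) / state.sigma_u2
    num -= float(state.beta[nonecp].sum()) / prior_variance
    if beta0_fixed is not None and g > 0 and ecp is not None and ecp.size:
        gn = g * ecp_counts[ecp]
        prec += float(gn.sum())
        num -= float(gn @ (state.beta[ecp] - beta0_fixed))
    delta = num / prec + rng.standard_normal() / np.sqrt(prec)
    return float(delta)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------


def run_chain(dataset: Dataset, pedigree: Pedigree, config: GibbsConfig) -> GibbsResult:
    """Run the systematic-scan Gibbs sampler.

    Scan order per iteration: liabilities -> non-ECP beta -> beta0 ->
    ECP beta -> s -> sigma_u2.  Post-burn-in draws are retained (thinned by
    ``config.thinning``); effect vectors are accumulated into posterior means
    rather than stored.  Fully reproducible given ``config.seed``.
    """
    if dataset.n_sires != pedigree.n_sires:
        raise ValueError("dataset and pedigree disagree on the number of sires")
    ecp = ecp_classes(dataset)
    nonecp = np.setdiff1d(np.arange(dataset.n_classes), ecp)
    if nonecp.size == 0:
        raise ValueError(
            "every fixed-effect class is an extreme case problem; the model is "
            "unidentifiable (no non-ECP class to anchor beta0)"
        )
    rng = as_rng(config.seed)
    a_inv = build_a_inverse(pedigree)
    class_counts = np.bincount(dataset.fixed_class, minlength=dataset.n_classes)
    sire_counts = np.bincount(dataset.sire, minlength=dataset.n_sires).astype(float)
    factor = sire_factor(a_inv, sire_counts)
    a_inv_ones = np.asarray(a_inv @ np.ones(dataset.n_sires)).ravel()
    ones_quad = float(a_inv_ones.sum())

    state = ChainState(
        liabilities=np.zeros(dataset.n_records),
        beta=np.zeros(dataset.n_classes),
        s=np.zeros(dataset.n_sires),
        sigma_u2=config.S2_u,
        beta0=0.0,
    )
    state.liabilities = sample_liabilities(state, dataset, rng)

    n_keep = (config.n_iterations - config.burn_in + config.thinning - 1) // config.thinning
    sigma_draws = np.empty(n_keep)
    sigma_trace = np.empty(config.n_iterations)
    beta_sum = np.zeros(dataset.n_classes)
    s_sum = np.zeros(dataset.n_sires)
    kept = 0
    g = config.g_weight

    for it in range(config.n_iterations):
        try:
            state.liabilities = sample_liabilities(state, dataset, rng)
            sums = _class_residual_sums(state, dataset)
            state.beta[nonecp] = sample_fixed_nonecp(
                state,
                dataset,
                config.nonecp_prior_variance,
                rng,
                classes=nonecp,
                class_sums=sums,
                class_counts=class_counts,
            )
            state.beta0 = (
                config.beta0_fixed
                if config.beta0_fixed is not None
                else compute_beta0(state, nonecp)
            )
            if ecp.size:
                state.beta[ecp] = sample_fixed_ecp(
                    state,
                    dataset,
                    g,
                    state.beta0,
                    rng,
                    classes=ecp,
                    class_sums=sums,
                    class_counts=class_counts,
                )
            state.s = sample_sires(state, dataset, a_inv, rng, factor=factor)
            if config.recenter:
                delta = sample_gauge_shift(
                    state,
                    a_inv_ones,
                    ones_quad,
                    nonecp,
                    config.nonecp_prior_variance,
                    rng,
                    g=g,
                    ecp=ecp,
                    ecp_counts=class_counts,
                    beta0_fixed=config.beta0_fixed,
                )
                state.beta += delta
                state.s -= delta
                state.beta0 += delta
            state.sigma_u2 = sample_sire_variance(
                state,
                a_inv,
                config.nu_u,
                config.S2_u,
                rng,
                chol_a_inv=factor.chol_a_inv,
            )
        except Exception as exc:  # noqa: BLE001 - annotate with iteration index
            raise RuntimeError(f"Gibbs sampler failed at iteration {it}") from exc
        sigma_trace[it] = state.sigma_u2
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            sigma_draws[kept] = state.sigma_u2
            beta_sum += state.beta
            s_sum += state.s
            kept += 1

    return GibbsResult(
        sigma_u2_draws=sigma_draws[:kept],
        sigma_u2_trace=sigma_trace,
        beta_mean=beta_sum / kept,
        s_mean=s_sum / kept,
        ecp=ecp,
        config=config,
        n_retained=kept,
    )
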