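import numpy as np
import pytest
from scipy import sparse
from scipy.special import ndtr

from sirethresh.gibbs import (
    ChainState,
    GibbsConfig,
    build_a_inverse,
    compute_beta0,
    relationship_matrix,
    run_chain,
    sample_fixed_ecp,
    sample_fixed_nonecp,
    sample_liabilities,
    sample_sire_variance,
    sample_sires,
    sire_factor,
)
from sirethresh.simulator import Dataset, build_pedigree, simulate_dataset


def _state(n_records, n_classes, n_sires, sigma_u2=0.05):
    return ChainState(
        liabilities=np.zeros(n_records),
        beta=np.zeros(n_classes),
        s=np.zeros(n_sires),
        sigma_u2=sigma_u2,
    )


# ---------------------------------------------------------------------------
# relationship-matrix inverse
# ---------------------------------------------------------------------------


def test_a_inverse_unrelated_is_identity():
    ped = build_pedigree(3, 0, 1, seed=0)
    assert np.allclose(build_a_inverse(ped).toarray(), np.eye(3))


def test_a_inverse_father_son_pair():
    ped = build_pedigree(1, 1, 1, seed=0)
    a = relationship_matrix(ped)
    assert np.allclose(a, [[1.0, 0.5], [0.5, 1.0]])
    a_inv = build_a_inverse(ped).toarray()
    assert np.allclose(a_inv, [[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])


@pytest.mark.parametrize("seed", range(5))
def test_a_inverse_inverts_tabular_matrix(seed):
    rng = np.random.default_rng(seed)
    ped = build_pedigree(
        int(rng.integers(2, 6)), int(rng.integers(1, 8)), int(rng.integers(1, 4)), seed
    )
    prod = build_a_inverse(ped).toarray() @ relationship_matrix(ped)
    assert np.allclose(prod, np.eye(ped.n_sires), atol=1e-10)


# ---------------------------------------------------------------------------
# conditional samplers at a frozen state (moment checks, ~2e4 draws)
# ---------------------------------------------------------------------------


def test_liability_conditional_truncation_and_moments(rng):
    n = 20_000
    ds = Dataset(
        y=np.r_[np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8)],
        fixed_class=np.zeros(2 * n, dtype=np.int64),
        sire=np.zeros(2 * n, dtype=np.int64),
        n_classes=1,
        n_sires=1,
    )
    state = _state(2 * n, 1, 1)
    draws = sample_liabilities(state, ds, rng)
    up, down = draws[:n], draws[n:]
    assert (up > 0).all() and (down <= 0).all()
    # half-normal mean sqrt(2/pi) on each side of the threshold
    half_mean = np.sqrt(2 / np.pi)
    half_sd = np.sqrt(1 - half_mean**2)
    assert abs(up.mean() - half_mean) < 4 * half_sd / np.sqrt(n)
    assert abs(down.mean() + half_mean) < 4 * half_sd / np.sqrt(n)


def test_liability_conditional_negligible_truncation(rng):
    n = 20_000
    ds = Dataset(
        y=np.ones(n, dtype=np.int8),
        fixed_class=np.zeros(n, dtype=np.int64),
        sire=np.zeros(n, dtype=np.int64),
        n_classes=1,
        n_sires=1,
    )
    state = _state(n, 1, 1)
    state.beta[:] = 8.0
    draws = sample_liabilities(state, ds, rng)
    assert abs(draws.mean() - 8.0) < 4 / np.sqrt(n)
    assert abs(draws.std() - 1.0) < 0.02


def test_nonecp_conditional_moments(rng):
    # class 0: one record with adjusted residual 2; class 1: 25 records summing to 10
    liab = np.r_[2.0, np.full(25, 0.4)]
    ds = Dataset(
        y=(liab > 0).astype(np.int8),
        fixed_class=np.r_[0, np.ones(25, dtype=np.int64)],
        sire=np.zeros(26, dtype=np.int64),
        n_classes=2,
        n_sires=1,
    )
    state = _state(26, 2, 1)
    state.liabilities = liab
    n = 20_000
    draws = np.array(
        [sample_fixed_nonecp(state, ds, 1e6, rng) for _ in range(n)]
    )
    assert abs(draws[:, 0].mean() - 2.0) < 4 / np.sqrt(n)
    assert abs(draws[:, 0].var() - 1.0) < 0.03
    v1 = 1 / 25
    assert abs(draws[:, 1].mean() - 0.4) < 4 * np.sqrt(v1 / n)
    assert abs(draws[:, 1].var() - v1) < 4 * v1 * np.sqrt(2 / n)


def test_nonecp_dogmatic_prior_collapses_to_zero(rng):
    ds = Dataset(
        y=np.ones(4, dtype=np.int8),
        fixed_class=np.zeros(4, dtype=np.int64),
        sire=np.zeros(4, dtype=np.int64),
        n_classes=1,
        n_sires=1,
    )
    state = _state(4, 1, 1)
    state.liabilities = np.full(4, 3.0)
    draws = np.array([sample_fixed_nonecp(state, ds, 1e-8, rng)[0] for _ in range(200)])
    assert np.abs(draws).max() < 1e-3


def test_ecp_conditional_matches_shrinkage_formula(rng):
    # one all-ones ECP class, 25 records, adjusted residual mean 2.0
    nrec = 25
    ds = Dataset(
        y=np.ones(nrec, dtype=np.int8),
        fixed_class=np.zeros(nrec, dtype=np.int64),
        sire=np.zeros(nrec, dtype=np.int64),
        n_classes=1,
        n_sires=1,
    )
    state = _state(nrec, 1, 1)
    state.liabilities = np.full(nrec, 2.0)
    n = 20_000
    g = 0.15
    draws = np.array([sample_fixed_ecp(state, ds, g, 0.0, rng)[0] for _ in range(n)])
    mean, var = 2.0 / (1 + g), 1 / ((1 + g) * nrec)
    assert abs(draws.mean() - mean) < 4 * np.sqrt(var / n)
    assert abs(draws.var() - var) < 4 * var * np.sqrt(2 / n)
    # g -> 1 with beta0 = bhat leaves the shrinkage target at bhat
    draws1 = np.array([sample_fixed_ecp(state, ds, 1.0, 2.0, rng)[0] for _ in range(n)])
    assert abs(draws1.mean() - 2.0) < 4 * np.sqrt(1 / (2 * nrec) / n)


def test_compute_beta0_is_nonecp_mean():
    state = _state(1, 5, 1)
    state.beta = np.array([1.0, 3.0, -100.0, 0.0, 0.0])
    assert compute_beta0(state, np.array([0, 1])) == 2.0
    rng = np.random.default_rng(1)
    vals = rng.uniform(-1, 1, 150)
    state = _state(1, 150, 1)
    state.beta = vals
    assert compute_beta0(state, np.arange(150)) == pytest.approx(vals.mean(), abs=1e-14)
    with pytest.raises(ValueError, match="ECP"):
        compute_beta0(state, np.array([], dtype=np.int64))


def test_sire_conditional_scalar_ridge(rng):
    # 1 unrelated sire, 4 records with adjusted residuals summing to 4, sigma_u2=1
    ds = Dataset(
        y=np.ones(4, dtype=np.int8),
        fixed_class=np.zeros(4, dtype=np.int64),
        sire=np.zeros(4, dtype=np.int64),
        n_classes=1,
        n_sires=1,
    )
    state = _state(4, 1, 1, sigma_u2=1.0)
    state.liabilities = np.full(4, 1.0)
    a_inv = sparse.identity(1, format="csr")
    n = 20_000
    draws = np.array([sample_sires(state, ds, a_inv, rng)[0] for _ in range(n)])
    assert abs(draws.mean() - 0.8) < 4 * np.sqrt(0.2 / n)
    assert abs(draws.var() - 0.2) < 4 * 0.2 * np.sqrt(2 / n)
    # infinite shrinkage limit
    state.sigma_u2 = 1e-10
    tiny = np.array([sample_sires(state, ds, a_inv, rng)[0] for _ in range(100)])
    assert np.abs(tiny).max() < 1e-3


def test_joint_sire_draw_matches_dense_conditional_and_single_site(rng):
    """The joint draw and a single-site sweep both target the same MVN."""
    ped = build_pedigree(5, 5, 3, seed=14)
    ds, _ = simulate_dataset(ped, 200, 8, (-1.5, 0.6), 0.05, seed=15)
    q = ped.n_sires
    state = _state(200, 8, q, sigma_u2=0.05)
    state.liabilities = np.asarray(ds.liability_true)
    state.beta = rng.normal(0, 0.3, 8)
    a_inv = build_a_inverse(ped).toarray()
    counts = np.bincount(ds.sire, minlength=q).astype(float)
    resid = state.liabilities - state.beta[ds.fixed_class]
    rhs = np.bincount(ds.sire, weights=resid, minlength=q)
    prec = np.diag(counts) + a_inv / state.sigma_u2
    cov = np.linalg.inv(prec)
    mean = cov @ rhs

    n = 4000
    joint = np.array([sample_sires(state, ds, a_inv, rng) for _ in range(n)])
    se = np.sqrt(np.diag(cov) / n)
    assert np.all(np.abs(joint.mean(axis=0) - mean) < 5 * se)
    assert np.allclose(np.cov(joint.T), cov, atol=6 * np.abs(cov).max() * np.sqrt(2 / n))

    # single-site Gibbs sweeps (oracle implementation)
    s = mean.copy()
    sweeps = []
    for it in range(2500):
        for k in range(q):
            m_k = (rhs[k] - prec[k] @ s + prec[k, k] * s[k]) / prec[k, k]
            s[k] = m_k + rng.standard_normal() / np.sqrt(prec[k, k])
        if it >= 500:
            sweeps.append(s.copy())
    sweeps = np.array(sweeps)
    assert np.all(np.abs(sweeps.mean(axis=0) - mean) < 8 * se * np.sqrt(3))
    assert np.allclose(np.diag(np.cov(sweeps.T)), np.diag(cov), rtol=0.35)


def test_sire_variance_conditional(rng):
    q = 500
    state = _state(1, 1, q, sigma_u2=0.05)
    state.s = np.zeros(q)
    a_inv = sparse.identity(q, format="csr")
    n = 20_000
    draws = np.array(
        [sample_sire_variance(state, a_inv, 2.0, 0.05, rng) for _ in range(n)]
    )
    df, scale = q + 2.0, 0.1 / (q + 2.0)
    mean = df * scale / (df - 2)
    assert abs(draws.mean() - mean) < 5 * mean * np.sqrt(2 / (df - 4)) / np.sqrt(n) * df / (df - 2)
    assert abs(np.median(draws) - mean) < 0.1 * mean
    # q = 0: pure prior draw; scaled-inv-chi2(10, 0.05) has mean 10*0.05/8
    state0 = _state(1, 1, 0)
    state0.s = np.zeros(0)
    prior = np.array(
        [sample_sire_variance(state0, sparse.identity(0, format="csr"), 10.0, 0.05, rng) for _ in range(n)]
    )
    assert abs(prior.mean() - 0.0625) < 0.005


# ---------------------------------------------------------------------------
# whole chain
# ---------------------------------------------------------------------------


def test_run_chain_deterministic(small_pedigree, small_dataset):
    ds, _ = small_dataset
    cfg = GibbsConfig(g_weight=0.1, S2_u=0.05, n_iterations=400, burn_in=100, seed=5)
    r1 = run_chain(ds, small_pedigree, cfg)
    r2 = run_chain(ds, small_pedigree, cfg)
    assert np.array_equal(r1.sigma_u2_draws, r2.sigma_u2_draws)
    assert np.array_equal(r1.beta_mean, r2.beta_mean)
    r3 = run_chain(ds, small_pedigree, GibbsConfig(
        g_weight=0.1, S2_u=0.05, n_iterations=400, burn_in=100, seed=6))
    assert not np.array_equal(r3.sigma_u2_draws, r1.sigma_u2_draws)


def test_run_chain_rejects_all_ecp(small_pedigree):
    ds = Dataset(
        y=np.ones(50, dtype=np.int8),
        fixed_class=np.repeat(np.arange(5), 10),
        sire=np.zeros(50, dtype=np.int64),
        n_classes=5,
        n_sires=small_pedigree.n_sires,
    )
    with pytest.raises(ValueError, match="unidentifiable"):
        run_chain(ds, small_pedigree, GibbsConfig(n_iterations=10, burn_in=1))


def test_liability_signs_track_responses(small_pedigree, small_dataset):
    """After every update the latent liabilities stay on their response's side."""
    ds, _ = small_dataset
    from sirethresh import gibbs as G

    rng = np.random.default_rng(3)
    state = _state(ds.n_records, ds.n_classes, ds.n_sires)
    a_inv = build_a_inverse(small_pedigree)
    for _ in range(50):
        state.liabilities = sample_liabilities(state, ds, rng)
        assert ((state.liabilities > 0) == (ds.y == 1)).all()
        state.beta = sample_fixed_nonecp(state, ds, 1e6, rng)
        state.s = sample_sires(state, ds, a_inv, rng)
        state.sigma_u2 = sample_sire_variance(state, a_inv, 2.0, 0.05, rng)


def test_simulation_based_calibration_of_sigma_posterior():
    """When the generating parameters are drawn from the sampler's own priors,
    the posterior rank of the true sire variance is uniform (SBC check),
    confirming the chain targets the exact posterior."""
    rng = np.random.default_rng(42)
    ranks = []
    while len(ranks) < 24:
        sigma = 2 * 0.05 / rng.chisquare(2)
        if sigma > 1.0:
            continue  # keep liabilities in a numerically sane range
        ped = build_pedigree(10, 30, 3, seed=int(rng.integers(2**30)))
        from sirethresh.simulator import sample_transmitting_abilities

        s = sample_transmitting_abilities(ped, sigma, int(rng.integers(2**30)))
        beta = rng.normal(0, 1.0, 40)
        cls = rng.integers(0, 40, 1000)
        sire = rng.integers(0, 100, 1000)
        liab = beta[cls] + s[sire] + rng.standard_normal(1000)
        y = (liab > 0).astype(np.int8)
        n = np.bincount(cls, minlength=40)
        ones = np.bincount(cls, weights=y, minlength=40)
        if n.min() == 0 or ((ones == 0) | (ones == n)).all():
            continue
        ds = Dataset(y=y, fixed_class=cls, sire=sire, n_classes=40, n_sires=100)
        cfg = GibbsConfig(
            g_weight=0.0,
            nonecp_prior_variance=1.0,  # matches the generating beta ~ N(0, 1)
            nu_u=2.0,
            S2_u=0.05,
            n_iterations=5000,
            burn_in=1500,
            seed=int(rng.integers(2**30)),
        )
        res = run_chain(ds, ped, cfg)
        ranks.append(float((res.sigma_u2_draws[::10] < sigma).mean()))
    from scipy import stats

    assert stats.kstest(np.array(ranks), "uniform").pvalue > 0.005


def test_tiny_posterior_matches_grid_oracle():
    """Posterior means from the sampler match dense numerical integration.

    Two classes x two unrelated sires, sigma_u2 integrated out analytically
    (the scaled-inv-chi2 mixture of the iid normal prior on s is a
    multivariate t), leaving a 4-D grid over (beta_1, beta_2, s_1, s_2).
    """
    rng = np.random.default_rng(99)
    n_per_cell = 10
    cls = np.repeat([0, 0, 1, 1], n_per_cell)
    sire = np.tile(np.repeat([0, 1], n_per_cell), 2)
    beta_true, s_true = np.array([0.45, -0.55]), np.array([0.15, -0.1])
    liab = beta_true[cls] + s_true[sire] + rng.standard_normal(cls.size)
    y = (liab > 0).astype(np.int8)
    # make sure no class is extreme so the flat-ish prior branch is exercised
    assert 0 < y[cls == 0].mean() < 1 and 0 < y[cls == 1].mean() < 1
    ds = Dataset(y=y, fixed_class=cls, sire=sire, n_classes=2, n_sires=2)

    nu_u, s2u = 2.0, 0.05
    b = np.linspace(-2.2, 2.2, 89)
    s = np.linspace(-1.1, 1.1, 45)
    b1, b2, s1, s2 = np.meshgrid(b, b, s, s, indexing="ij", sparse=True)
    logpost = -(b1**2 + b2**2) / (2 * 1e6)
    logpost = logpost - ((nu_u + 2) / 2) * np.log1p((s1**2 + s2**2) / (nu_u * s2u))
    mu = {(0, 0): b1 + s1, (0, 1): b1 + s2, (1, 0): b2 + s1, (1, 1): b2 + s2}
    for (c, k), m in mu.items():
        in_cell = (cls == c) & (sire == k)
        n1 = int(y[in_cell].sum())
        n0 = int(in_cell.sum()) - n1
        logpost = logpost + n1 * np.log(ndtr(m)) + n0 * np.log(ndtr(-m))
    w = np.exp(logpost - logpost.max())
    z = w.sum()
    exp_b1 = (w * b1).sum() / z
    exp_b2 = (w * b2).sum() / z
    exp_s1 = (w * s1).sum() / z
    exp_s2 = (w * s2).sum() / z

    ped = build_pedigree(2, 0, 1, seed=0)
    cfg = GibbsConfig(
        g_weight=0.0, nu_u=nu_u, S2_u=s2u, n_iterations=60_000, burn_in=15_000, seed=17
    )
    res = run_chain(ds, ped, cfg)
    assert res.beta_mean[0] == pytest.approx(exp_b1, abs=0.04)
    assert res.beta_mean[1] == pytest.approx(exp_b2, abs=0.04)
    assert res.s_mean[0] == pytest.approx(exp_s1, abs=0.04)
    assert res.s_mean[1] == pytest.approx(exp_s2, abs=0.04)
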