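"""Q function, M-step updates, and the EM loop."""

import math

import numpy as np
import pytest

from emps import (EMPS, EMConfig, NetworkDynamics, ParticleEnsemble,
                  QFunction, StateSpaceModel, TimeCourseDataset, smooth)
from emps.estimation import maximize_bounded

_LOG2PI = math.log(2 * math.pi)


def _setup(three_gene_truth, data, n_cells=2, n_times=5, P=10, seed=4):
    ds = TimeCourseDataset(times=data.times[:n_times],
                           Y=data.Y[:n_cells, :n_times],
                           columns=data.columns)
    dyn = NetworkDynamics(three_gene_truth.copy(), nsub=2)
    model = StateSpaceModel(dynamics=dyn, sigma=np.array([0.2, 0.25, 0.3]),
                            eta=np.array([0.1, 0.12, 0.14]),
                            mu=ds.Y[:, 0, :], gamma=np.array([0.3, 0.4, 0.5]))
    rng = np.random.default_rng(seed)
    ensembles = [smooth(model, ds.Y[a], ds.times, cell_index=a, P=P, rng=rng,
                        n_smooth=P) for a in range(ds.n_cells)]
    return model, ds, ensembles


def _naive_q(model, ds, ensembles, theta_sys=None, sigma=None, eta=None,
             mu=None, gamma=None):
    """Brute-force triple sum over (a, p, t, i/j); the independent oracle."""
    dyn = model.dynamics
    if theta_sys is not None:
        dyn = NetworkDynamics(dyn.network.with_theta(theta_sys), nsub=dyn.nsub)
    sigma = model.sigma if sigma is None else np.asarray(sigma, dtype=float)
    eta = model.eta if eta is None else np.asarray(eta, dtype=float)
    mu = model.mu if mu is None else np.atleast_2d(mu)
    gamma = model.gamma if gamma is None else np.asarray(gamma, dtype=float)
    total = 0.0
    for a, ens in enumerate(ensembles):
        for p in range(ens.n_particles):
            beta = ens.weights[p]
            traj = ens.trajectories[p]
            lp = 0.0
            for i in range(model.k):
                lp += (-0.5 * math.log(2 * math.pi * gamma[i] ** 2)
                       - (traj[0, i] - mu[a, i]) ** 2 / (2 * gamma[i] ** 2))
            for t in range(1, ds.n_times):
                f = dyn.f_batch(traj[t - 1][None], ds.times[t] - ds.times[t - 1])[0]
                for i in range(model.k):
                    lp += (-0.5 * math.log(2 * math.pi * sigma[i] ** 2)
                           - (traj[t, i] - f[i]) ** 2 / (2 * sigma[i] ** 2))
            for t in range(ds.n_times):
                for j, oi in enumerate(model.obs_indices):
                    lp += (-0.5 * math.log(2 * math.pi * eta[j] ** 2)
                           - (ds.Y[a, t, j] - model.alpha * traj[t, oi]) ** 2
                           / (2 * eta[j] ** 2))
            total += beta * lp
    return total


def test_q_matches_naive_triple_loop(three_gene_truth, small_three_gene_data):
    """Vectorised Q equals the brute-force loop on a 2-cell/5-step/P=10
    instance to 1e-10 relative."""
    train, _ = small_three_gene_data
    model, ds, ensembles = _setup(three_gene_truth, train)
    qf = QFunction(model, ds, ensembles)
    q_vec = qf()
    q_naive = _naive_q(model, ds, ensembles)
    assert q_vec == pytest.approx(q_naive, rel=1e-10)
    # also away from theta_old
    theta2 = three_gene_truth.theta() * 1.3
    sigma2 = model.sigma * 0.8
    assert qf(theta_sys=theta2, sigma=sigma2) == pytest.approx(
        _naive_q(model, ds, ensembles, theta_sys=theta2, sigma=sigma2),
        rel=1e-10)


def test_q_single_particle_is_complete_data_log_joint(
        three_gene_truth, small_three_gene_data):
    """With one particle of weight one, Q is the complete-data log joint."""
    train, _ = small_three_gene_data
    model, ds, ensembles = _setup(three_gene_truth, train, n_cells=1, P=2)
    single = [ParticleEnsemble(
        trajectories=ensembles[0].trajectories[:1],
        weights=np.array([1.0]), times=ds.times,
        log_likelihood=0.0)]
    qf = QFunction(model, ds, single)
    assert qf() == pytest.approx(_naive_q(model, ds, single), rel=1e-12)


def test_q_invariant_to_particle_duplication(three_gene_truth,
                                             small_three_gene_data):
    """Duplicating every trajectory at half weight (i.e. rescaling weights
    before normalisation) leaves Q unchanged."""
    train, _ = small_three_gene_data
    model, ds, ensembles = _setup(three_gene_truth, train, n_cells=1, P=8)
    ens = ensembles[0]
    doubled = [ParticleEnsemble(
        trajectories=np.concatenate([ens.trajectories, ens.trajectories]),
        weights=np.concatenate([ens.weights, ens.weights]) / 2.0,
        times=ds.times, log_likelihood=ens.log_likelihood)]
    assert QFunction(model, ds, doubled)() == pytest.approx(
        QFunction(model, ds, ensembles)(), rel=1e-12)


def test_noise_updates_are_stationary_points(three_gene_truth,
                                             small_three_gene_data):
    """The closed-form sigma/eta/mu/gamma updates maximise Q: Q decreases
    under any small perturbation of the updated values."""
    train, _ = small_three_gene_data
    model, ds, ensembles = _setup(three_gene_truth, train, n_times=8, P=15)
    qf = QFunction(model, ds, ensembles)
    theta = model.dynamics.theta
    sigma2, eta2, mu, gamma2 = qf.noise_updates(theta)
    sigma, eta, gamma = np.sqrt(sigma2), np.sqrt(eta2), np.sqrt(gamma2)
    q_star = qf(theta_sys=theta, sigma=sigma, eta=eta, mu=mu, gamma=gamma)
    for eps in (1e-4, -1e-4):
        assert qf(theta_sys=theta, sigma=sigma * (1 + eps), eta=eta, mu=mu,
                  gamma=gamma) <= q_star + 1e-9
        assert qf(theta_sys=theta, sigma=sigma, eta=eta * (1 + eps), mu=mu,
                  gamma=gamma) <= q_star + 1e-9
        assert qf(theta_sys=theta, sigma=sigma, eta=eta, mu=mu,
                  gamma=gamma * (1 + eps)) <= q_star + 1e-9
        mu2 = mu.copy()
        mu2[0, 0] += eps
        assert qf(theta_sys=theta, sigma=sigma, eta=eta, mu=mu2,
                  gamma=gamma) <= q_star + 1e-9


def test_noise_updates_unweighted_special_case(three_gene_truth,
                                               small_three_gene_data):
    """One particle, one cell: the updates are the ordinary residual
    mean/variance formulas."""
    train, _ = small_three_gene_data
    model, ds, ensembles = _setup(three_gene_truth, train, n_cells=1, P=2)
    single = [ParticleEnsemble(trajectories=ensembles[0].trajectories[:1],
                               weights=np.array([1.0]), times=ds.times,
                               log_likelihood=0.0)]
    qf = QFunction(model, ds, single)
    theta = model.dynamics.theta
    sigma2, eta2, mu, gamma2 = qf.noise_updates(theta)
    traj = single[0].trajectories[0]
    F = model.dynamics.f_batch(traj[:-1], 1.0)
    np.testing.assert_allclose(sigma2, ((traj[1:] - F) ** 2).mean(axis=0),
                               rtol=1e-12)
    np.testing.assert_allclose(mu[0], traj[0], rtol=1e-12)
    np.testing.assert_allclose(gamma2, np.zeros(3), atol=1e-30)
    resid = ds.Y[0] - traj[:, model.obs_indices]
    np.testing.assert_allclose(eta2, (resid ** 2).mean(axis=0), rtol=1e-12)


def test_gamma_floor_activates(three_gene_truth, small_three_gene_data):
    """A gamma update below the configured floor returns exactly the floor."""
    train, _ = small_three_gene_data
    cfg = EMConfig(particles=40, n_smooth=10, iterations=1, maxfun=5,
                   nsub=1, gamma_min_frac=10.0)
    m = EMPS(train, three_gene_truth.copy(), config=cfg)
    res = m.fit(seed=0)
    np.testing.assert_array_equal(res.gamma, 10.0 * m.state_scale)


# ----------------------------------------------------- bounded maximisation
def test_maximize_bounded_quadratic_interior():
    c = np.array([0.7, 2.3, 1.1])

    def obj(x):
        return -np.sum((x - c) ** 2), -2 * (x - c)

    x, _ = maximize_bounded(obj, np.array([2.0, 0.5, 3.0]),
                            [(0, np.inf)] * 3, maxfun=200)
    np.testing.assert_allclose(x, c, atol=1e-6)


def test_maximize_bounded_clamps_to_boundary():
    """Unconstrained maximiser at negative K: the bound returns exactly 0."""
    c = np.array([-1.5, 2.0])

    def obj(x):
        return -np.sum((x - c) ** 2), -2 * (x - c)

    x, _ = maximize_bounded(obj, np.array([1.0, 1.0]), [(0.0, np.inf)] * 2,
                            maxfun=200)
    assert x[0] == 0.0
    assert x[1] == pytest.approx(2.0, abs=1e-6)


@pytest.mark.parametrize("transform", ["linear", "log"])
def test_maximize_bounded_ascent_property(transform):
    """f(theta_new) >= f(theta_old) on randomised quadratic instances."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        dim = rng.integers(2, 6)
        c = rng.uniform(-1, 3, dim)
        H = rng.uniform(0.5, 3.0, dim)

        def obj(x):
            return -np.sum(H * (x - c) ** 2), -2 * H * (x - c)

        x0 = rng.uniform(0.05, 3.0, dim)
        f0, _ = obj(x0)
        x, f = maximize_bounded(obj, x0, [(0, np.inf)] * dim,
                                maxfun=rng.integers(3, 40),
                                transform=transform)
        assert f >= f0 - 1e-12


def test_plateau_detector_stops_early(three_gene_truth, small_three_gene_data):
    """With a generous plateau tolerance the run stops after two windows
    instead of the full iteration budget."""
    train, _ = small_three_gene_data
    cfg = EMConfig(particles=30, n_smooth=8, iterations=12, maxfun=5, nsub=1,
                   plateau_tol=10.0, plateau_window=2)
    res = EMPS(train, three_gene_truth.copy(), config=cfg).fit(seed=0)
    assert res.iteration == 4


# ------------------------------------------------------------------ EM loop
def test_em_histories_and_ascent(three_gene_truth, small_three_gene_data):
    """Short EM run: history bookkeeping, bounds, and coarse ascent."""
    train, _ = small_three_gene_data
    init = three_gene_truth.copy()
    init.set_theta(three_gene_truth.theta() * 0.6)
    cfg = EMConfig(particles=60, n_smooth=15, iterations=6, maxfun=25,
                   nsub=2)
    res = EMPS(train, init, config=cfg).fit(seed=9)
    assert res.iteration == 6
    assert len(res.loglik_history) == 6
    assert res.theta_history.shape == (6, init.n_theta)
    # theta within bounds after every M-step
    for _, row in res.theta_history.iterrows():
        for (lo, hi), v in zip(init.theta_bounds(), row.to_numpy()):
            assert lo - 1e-12 <= v <= hi + 1e-12
    # log-likelihood rises overall (ascent modulo Monte-Carlo noise)
    assert np.median(res.loglik_history[-3:]) > np.median(res.loglik_history[:3])
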