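"""EM-PS: maximum-likelihood estimation via EM with particle smoothing.

Each EM iteration approximates the smoothing distribution of every cell's
latent trajectory with a particle ensemble (E-step) and then maximises the
expected complete-data log-likelihood

    Q(theta, theta_old) = sum_a sum_p beta^(a,p) ln p(X^(a,p), Y^(a) | theta)

over the parameters (M-step).  Q splits into three Gaussian blocks — initial
state, transitions, measurements.  The kinetic parameters theta_sys enter
only through the transition means f(x_{t-1}; theta_sys) and are updated by
bound-constrained quasi-Newton (L-BFGS-B with analytic gradients); the noise
and initial-state parameters sigma, eta, mu, gamma have closed-form updates
(weighted residual moments), clipped to configured bounds: a floor on gamma
guards against sample impoverishment, ceilings on sigma and eta against
noise overestimation.

Because the M-step is budgeted (generalised EM) and the E-step is Monte
Carlo, the log-likelihood trace increases monotonically only up to small
stochastic fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .networks import GeneNetwork
from .smoothing import ParticleEnsemble, smooth
from .statespace import NetworkDynamics, StateSpaceModel, TimeCourseDataset

__all__ = ["EMConfig", "QFunction", "EMPS", "EMPSResults",
           "maximize_bounded", "run_em"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EMConfig:
    """Algorithmic settings for EM-PS / EM-PS-Lasso.

    particles: filter particle count P; n_smooth: backward-simulated
    trajectories per cell (defaults to P).  iterations: fixed EM iteration
    count (stochastic fluctuation defeats naive tolerance rules; an optional
    plateau detector can stop early).  maxfun: objective-evaluation budget
    of each M-step (full inner convergence is unnecessary for generalised
    EM).  transform: "log" optimises theta_sys on log scale (robust to
    order-of-magnitude initialisation errors), "linear" optimises raw values
    and is required for L1 pruning to reach exact zeros.  nsub: RK4 substeps
    per unit time in the flow map.  Noise bounds are expressed as fractions
    of the per-state data standard deviation.
    """

    particles: int = 500
    n_smooth: int | None = None
    iterations: int = 100
    maxfun: int = 100
    transform: str = "log"
    nsub: int = 4
    n_range: tuple = (1.0, 8.0)
    gamma_min_frac: float = 0.01
    sigma_max_frac: float = 1.0
    sigma_floor_frac: float = 1e-3
    eta_max_frac: float = 1.0
    eta_floor_frac: float = 1e-3
    smoother: str = "ffbsi"
    ess_threshold: float | None = None
    hard_zero: float = 1e-6
    effective_threshold: float = 1e-3
    plateau_window: int = 10
    plateau_tol: float | None = None
    verbose: bool = False


class QFunction:
    """Particle-weighted expected complete-data log-likelihood Q.

    Precomputes flattened (cell, particle, time) batches so that repeated
    evaluations during the M-step only recompute the transition means.
    """

    def __init__(self, model: StateSpaceModel, dataset: TimeCourseDataset,
                 ensembles: list):
        self.model = model
        self.dataset = dataset
        self.ensembles = ensembles
        times = dataset.times
        dts = np.diff(times)
        if len(dts) and not np.allclose(dts, dts[0], rtol=1e-8):
            raise NotImplementedError("non-uniform time grids are not supported")
        self.dt = float(dts[0]) if len(dts) else 1.0
        A = dataset.n_cells
        k = model.k

        self.X0 = np.stack([e.trajectories[:, 0, :] for e in ensembles])  # (A, ns, k)
        self.W0 = np.stack([e.weights for e in ensembles])                # (A, ns)

        Xp, Xn, Wt = [], [], []
        Xm, Ym, Wm = [], [], []
        for a, e in enumerate(ensembles):
            traj = e.trajectories           # (ns, T, k)
            ns, T, _ = traj.shape
            Xp.append(traj[:, :-1, :].reshape(-1, k))
            Xn.append(traj[:, 1:, :].reshape(-1, k))
            Wt.append(np.repeat(e.weights, T - 1))
            Xm.append(traj.reshape(-1, k))
            Ym.append(np.tile(dataset.Y[a], (ns, 1, 1)).reshape(-1, dataset.n_obs))
            Wm.append(np.repeat(e.weights, T))
        self.Xprev = np.ascontiguousarray(np.concatenate(Xp))
        self.Xnext = np.ascontiguousarray(np.concatenate(Xn))
        self.Wtrans = np.ascontiguousarray(np.concatenate(Wt))
        self.Xmeas = np.concatenate(Xm)
        self.Ymeas = np.concatenate(Ym)
        self.Wmeas = np.concatenate(Wm)
        self.n_trans_terms = A * (dataset.n_times - 1)   # total transition weight
        self.n_meas_terms = A * dataset.n_times

    # ------------------------------------------------------------- blocks
    def initial_block(self, mu, gamma):
        g2 = gamma ** 2
        dev2 = (self.X0 - mu[:, None, :]) ** 2                    # (A, ns, k)
        per = -0.5 * (_LOG2PI + np.log(g2))[None, None, :] - dev2 / (2 * g2)
        return float(np.einsum("ap,apk->", self.W0, per))

    def transition_block(self, theta_sys, sigma):
        s2 = sigma ** 2
        F = self._f_batch(theta_sys)
        resid2 = (self.Xnext - F) ** 2
        per = -0.5 * (_LOG2PI + np.log(s2))[None, :] - resid2 / (2 * s2)
        return float(self.Wtrans @ per.sum(axis=1))

    def measurement_block(self, eta, alpha=None):
        model = self.model
        alpha = model.alpha if alpha is None else alpha
        e2 = eta ** 2
        resid2 = (self.Ymeas - alpha * self.Xmeas[:, model.obs_indices]) ** 2
        per = -0.5 * (_LOG2PI + np.log(e2))[None, :] - resid2 / (2 * e2)
        return float(self.Wmeas @ per.sum(axis=1))

    def __call__(self, theta_sys=None, sigma=None, eta=None, mu=None,
                 gamma=None) -> float:
        """Full Q at the given parameters (defaults: the E-step model's)."""
        m = self.model
        theta_sys = m.dynamics.theta if theta_sys is None else np.asarray(theta_sys)
        sigma = m.sigma if sigma is None else np.asarray(sigma, dtype=float)
        eta = m.eta if eta is None else np.asarray(eta, dtype=float)
        mu = m.mu if mu is None else np.atleast_2d(np.asarray(mu, dtype=float))
        gamma = m.gamma if gamma is None else np.asarray(gamma, dtype=float)
        return (self.initial_block(mu, gamma)
                + self.transition_block(theta_sys, sigma)
                + self.measurement_block(eta))

    # ------------------------------------------------------------ M-step
    def _f_batch(self, theta_sys):
        dyn = self.model.dynamics
        old = dyn.theta
        try:
            dyn.theta = np.asarray(theta_sys, dtype=float)
            return dyn.f_batch(self.Xprev, self.dt)
        finally:
            dyn.theta = old

    def transition_obj_grad(self, theta_sys, sigma):
        """Theta_sys-dependent part of Q and its gradient (analytic)."""
        dyn = self.model.dynamics
        inv2s2 = 1.0 / (2.0 * sigma ** 2)
        old = dyn.theta
        try:
            dyn.theta = np.asarray(theta_sys, dtype=float)
            return dyn.transition_obj_grad(self.Xprev, self.Xnext,
                                           self.Wtrans, inv2s2, self.dt)
        finally:
            dyn.theta = old

    def noise_updates(self, theta_sys):
        """Closed-form maximisers of Q over mu, gamma, sigma, eta (unclipped).

        These solve the linear stationarity equations dQ/d(par) = 0 exactly:
        weighted first/second moments of the smoothed residuals.
        """
        model = self.model
        mu = np.einsum("ap,apk->ak", self.W0, self.X0)
        dev2 = (self.X0 - mu[:, None, :]) ** 2
        gamma2 = np.einsum("ap,apk->k", self.W0, dev2) / self.dataset.n_cells
        F = self._f_batch(theta_sys)
        sigma2 = self.Wtrans @ ((self.Xnext - F) ** 2) / self.n_trans_terms
        mresid2 = (self.Ymeas - model.alpha * self.Xmeas[:, model.obs_indices]) ** 2
        eta2 = self.Wmeas @ mresid2 / self.n_meas_terms
        return sigma2, eta2, mu, gamma2


def maximize_bounded(obj_grad, x0, bounds, maxfun: int = 100,
                     transform: str = "linear"):
    """Bound-constrained maximisation by L-BFGS-B with ascent guarantee.

    ``obj_grad(x) -> (value, gradient)`` is maximised subject to box bounds.
    With ``transform="log"`` the search runs in log coordinates (strictly
    positive parameters spanning orders of magnitude).  Returns
    ``(x_new, f_new)``; falls back to ``x0`` whenever the optimizer fails to
    improve the objective.
    """
    x0 = np.asarray(x0, dtype=float)
    f0, _ = obj_grad(x0)

    if transform == "log":
        floor = 1e-10
        z0 = np.log(np.maximum(x0, floor))
        zb = [(np.log(max(lb, floor)),
               (np.log(ub) if np.isfinite(ub) else None)) for lb, ub in bounds]

        def negfg(z):
            x = np.exp(z)
            f, g = obj_grad(x)
            return -f, -g * x

        res = minimize(negfg, z0, jac=True, method="L-BFGS-B", bounds=zb,
                       options={"maxfun": maxfun, "maxiter": maxfun})
        x_new = np.exp(res.x)
    elif transform == "linear":
        lb = np.array([b[0] for b in bounds])
        ub = np.array([b[1] for b in bounds])

        def negfg(x):
            f, g = obj_grad(x)
            return -f, -g

        res = minimize(negfg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxfun": maxfun, "maxiter": maxfun})
        x_new = np.clip(res.x, lb, ub)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    if not np.all(np.isfinite(x_new)):
        return x0, f0
    f_new, _ = obj_grad(x_new)
    if not np.isfinite(f_new) or f_new < f0:
        return x0, f0
    return x_new, f_new


@dataclass
class EMPSResults:
    """Fitted EM-PS run: estimates, histories, final smoothed ensembles."""

    network: GeneNetwork
    sigma: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    gamma: np.ndarray
    loglik_history: np.ndarray
    theta_history: pd.DataFrame
    ensembles: list
    final_loglik: float
    config: EMConfig
    dataset: TimeCourseDataset
    obs_indices: np.ndarray
    seed: int | None = None

    @property
    def iteration(self) -> int:
        return len(self.loglik_history)

    @property
    def theta_sys(self) -> pd.Series:
        return pd.Series(self.network.theta(), index=self.network.theta_names())

    @property
    def params(self) -> dict:
        return {"theta_sys": self.network.theta(), "sigma": self.sigma,
                "eta": self.eta, "mu": self.mu, "gamma": self.gamma}

    def state_space_model(self) -> StateSpaceModel:
        return StateSpaceModel(
            dynamics=NetworkDynamics(self.network.copy(), nsub=self.config.nsub),
            sigma=self.sigma, eta=self.eta, mu=self.mu, gamma=self.gamma,
            obs_indices=self.obs_indices)

    def log_likelihood(self, dataset: TimeCourseDataset, seed=0,
                       particles: int | None = None) -> float:
        """Filter log-likelihood of (possibly unseen) data under the fit.

        Initial means of unseen cells are unknown; they are taken as the
        first observation (observed coordinates) and the average fitted
        initial mean (latent coordinates).
        """
        P = particles or self.config.particles
        mu = np.tile(self.mu.mean(axis=0), (dataset.n_cells, 1))
        mu[:, self.obs_indices] = dataset.Y[:, 0, :]
        model = self.state_space_model()
        model.mu = mu
        rng = np.random.default_rng(seed)
        total = 0.0
        for a in range(dataset.n_cells):
            ens = smooth(model, dataset.Y[a], dataset.times, cell_index=a,
                         P=P, rng=rng, n_smooth=2, method="ffbsi")
            total += ens.log_likelihood
        return total

    def smoothed_means(self) -> np.ndarray:
        """(A, T, k) posterior-mean latent trajectories of the final E-step."""
        return np.stack([e.mean() for e in self.ensembles])

    def summary(self) -> str:
        lines = []
        lines.append("EM-PS estimation results")
        lines.append("=" * 58)
        lines.append(f"cells: {self.dataset.n_cells}   time points: "
                     f"{self.dataset.n_times}   genes: {self.network.n_genes}")
        lines.append(f"particles: {self.config.particles}   iterations run: "
                     f"{self.iteration}")
        lines.append(f"final log-likelihood: {self.final_loglik:.3f}")
        lines.append("-" * 58)
        lines.append(f"{'parameter':<14}{'estimate':>12}")
        for name, val in self.theta_sys.items():
            lines.append(f"{name:<14}{val:>12.5g}")
        for i, s in enumerate(self.sigma):
            lines.append(f"{'sigma_' + str(i + 1):<14}{s:>12.5g}")
        for j, e in enumerate(self.eta):
            lines.append(f"{'eta_' + str(j + 1):<14}{e:>12.5g}")
        for i, g in enumerate(self.gamma):
            lines.append(f"{'gamma_' + str(i + 1):<14}{g:>12.5g}")
        lines.append("=" * 58)
        return "\n".join(lines)


class EMPS:
    """EM-PS model: a gene network fitted to single-cell time courses.

    Parameters
    ----------
    dataset : training data (cells x times x observables).
    network : initial :class:`GeneNetwork`; its current parameter values are
        the starting point of the optimisation.
    obs_indices : which genes the data columns measure (default: the first
        ``l`` genes; the fully observed case is ``l == k``).
    lam : L1 penalty strength on the association constants; 0 gives plain
        maximum likelihood.
    config : algorithmic settings (:class:`EMConfig`).
    """

    def __init__(self, dataset: TimeCourseDataset, network: GeneNetwork,
                 obs_indices=None, lam: float = 0.0,
                 config: EMConfig | None = None, alpha: float = 1.0):
        if lam < 0:
            raise ValueError("penalty strength lam must be >= 0")
        self.dataset = dataset
        self.network = network.copy()
        self.lam = float(lam)
        self.config = config or EMConfig()
        self.alpha = float(alpha)
        k = network.n_genes
        if obs_indices is None:
            obs_indices = np.arange(dataset.n_obs)
        self.obs_indices = np.asarray(obs_indices, dtype=int)
        if len(self.obs_indices) != dataset.n_obs:
            raise ValueError("obs_indices must match the data dimension")
        # per-state data scale: observed states from the data, latent states
        # from the average observed scale
        obs_std = dataset.std_per_observable() / self.alpha
        self.state_scale = np.full(k, obs_std.mean())
        self.state_scale[self.obs_indices] = obs_std

    # -------------------------------------------------------------- setup
    def _initial_params(self):
        cfg = self.config
        scale = self.state_scale
        sigma = 0.5 * scale
        eta = 0.5 * self.state_scale[self.obs_indices] * self.alpha
        gamma = scale.copy()
        k = self.network.n_genes
        mu = np.tile(self.dataset.Y.mean(axis=(0, 1)).mean() / self.alpha,
                     (self.dataset.n_cells, k))
        mu[:, self.obs_indices] = self.dataset.Y[:, 0, :] / self.alpha
        return sigma, eta, mu, gamma

    def _bounds_noise(self):
        cfg = self.config
        scale = self.state_scale
        return {
            "gamma_min": cfg.gamma_min_frac * scale,
            "sigma_max": cfg.sigma_max_frac * scale,
            "sigma_floor": cfg.sigma_floor_frac * scale,
            "eta_max": cfg.eta_max_frac * scale[self.obs_indices] * self.alpha,
            "eta_floor": cfg.eta_floor_frac * scale[self.obs_indices] * self.alpha,
        }

    # ---------------------------------------------------------------- fit
    def fit(self, seed: int | None = None, iterations: int | None = None,
            callback=None) -> EMPSResults:
        cfg = self.config
        iterations = cfg.iterations if iterations is None else iterations
        if iterations < 1:
            raise ValueError("need at least one EM iteration")
        rng = np.random.default_rng(seed)
        net = self.network.copy()
        dyn = NetworkDynamics(net, nsub=cfg.nsub)
        sigma, eta, mu, gamma = self._initial_params()
        nb = self._bounds_noise()
        k_idx = net.k_indices()
        bounds = net.theta_bounds(n_range=cfg.n_range)
        n_smooth = cfg.n_smooth or cfg.particles

        loglik_hist = []
        theta_hist = []
        ensembles = None
        A = self.dataset.n_cells

        for it in range(iterations):
            model = StateSpaceModel(dynamics=dyn, sigma=sigma, eta=eta, mu=mu,
                                    gamma=gamma, alpha=self.alpha,
                                    obs_indices=self.obs_indices)
            # E-step: per-cell smoothing with derived, reproducible streams
            cell_seeds = rng.integers(0, 2 ** 31 - 1, size=A)
            ensembles = [
                smooth(model, self.dataset.Y[a], self.dataset.times,
                       cell_index=a, P=cfg.particles,
                       rng=np.random.default_rng(cell_seeds[a]),
                       n_smooth=n_smooth, method=cfg.smoother,
                       ess_threshold=cfg.ess_threshold)
                for a in range(A)
            ]
            ll = sum(e.log_likelihood for e in ensembles)
            loglik_hist.append(ll)
            qf = QFunction(model, self.dataset, ensembles)

            # M-step 1: kinetic parameters by penalised bounded quasi-Newton
            def obj_grad(theta, _qf=qf, _sig=sigma):
                f, g = _qf.transition_obj_grad(theta, _sig)
                if self.lam > 0.0:
                    f = f - self.lam * np.sum(theta[k_idx])
                    g = g.copy()
                    g[k_idx] -= self.lam
                return f, g

            theta_new, _ = maximize_bounded(obj_grad, net.theta(), bounds,
                                            maxfun=cfg.maxfun,
                                            transform=cfg.transform)
            if self.lam > 0.0:
                # clean residual round-off: practically-zero K snaps to the
                # boundary, where the path is exactly absent
                theta_new = theta_new.copy()
                ki = theta_new[k_idx]
                ki[ki < cfg.hard_zero] = 0.0
                theta_new[k_idx] = ki
            net.set_theta(theta_new)

            # M-step 2: closed-form noise/initial-state updates, clipped
            sigma2, eta2, mu_new, gamma2 = qf.noise_updates(theta_new)
            sigma = np.clip(np.sqrt(sigma2), nb["sigma_floor"], nb["sigma_max"])
            eta = np.clip(np.sqrt(eta2), nb["eta_floor"], nb["eta_max"])
            gamma = np.maximum(np.sqrt(gamma2), nb["gamma_min"])
            mu = mu_new

            theta_hist.append(theta_new.copy())
            if cfg.verbose:
                msg = f"[EM iter {it + 1:3d}] loglik = {ll:.3f}"
                if len(theta_hist) > 1:
                    dmax = np.max(np.abs(theta_new - theta_hist[-2]))
                    msg += f"  max|dtheta| = {dmax:.3g}"
                if self.lam > 0.0:
                    n_active = int(np.sum(theta_new[k_idx]
                                          > cfg.effective_threshold))
                    msg += f"  active paths = {n_active}"
                print(msg)
            if callback is not None:
                callback(it, ll, theta_new)
            if cfg.plateau_tol is not None and len(loglik_hist) >= 2 * cfg.plateau_window:
                w = cfg.plateau_window
                prev = np.median(loglik_hist[-2 * w:-w])
                cur = np.median(loglik_hist[-w:])
                if abs(cur - prev) < cfg.plateau_tol * abs(prev):
                    break

        # final log-likelihood at the last parameter values
        model = StateSpaceModel(dynamics=dyn, sigma=sigma, eta=eta, mu=mu,
                                gamma=gamma, alpha=self.alpha,
                                obs_indices=self.obs_indices)
        cell_seeds = rng.integers(0, 2 ** 31 - 1, size=A)
        final_ens = [
            smooth(model, self.dataset.Y[a], self.dataset.times, cell_index=a,
                   P=cfg.particles, rng=np.random.default_rng(cell_seeds[a]),
                   n_smooth=n_smooth, method=cfg.smoother,
                   ess_threshold=cfg.ess_threshold)
            for a in range(A)
        ]
        final_ll = sum(e.log_likelihood for e in final_ens)

        theta_frame = pd.DataFrame(theta_hist, columns=net.theta_names())
        theta_frame.index.name = "iteration"
        return EMPSResults(
            network=net, sigma=sigma, eta=eta, mu=mu, gamma=gamma,
            loglik_history=np.asarray(loglik_hist), theta_history=theta_frame,
            ensembles=final_ens, final_loglik=final_ll, config=self.config,
            dataset=self.dataset, obs_indices=self.obs_indices, seed=seed)


def run_em(network: GeneNetwork, dataset: TimeCourseDataset,
           particles: int | None = None, iterations: int | None = None,
           seed: int | None = None, obs_indices=None,
           config: EMConfig | None = None, **cfg_kwargs) -> EMPSResults:
    """Functional wrapper: plain EM-PS fit of ``network`` to ``dataset``.

    ``particles``/``iterations``/keyword settings override ``config`` only
    when given explicitly.
    """
    cfg = config or EMConfig()
    if particles is not None:
        cfg_kwargs["particles"] = particles
    if iterations is not None:
        cfg_kwargs["iterations"] = iterations
    cfg = dc_replace(cfg, **cfg_kwargs)
    return EMPS(dataset, network, obs_indices=obs_indices, config=cfg).fit(seed=seed)
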