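"""Nonlinear Gaussian state-space model for single-cell time courses.

The latent concentrations evolve deterministically between observation times
through the flow map of an ODE system and pick up additive Gaussian system
noise at each step,

    x_t = f(x_{t-1}) + v_t,       v_{t,i} ~ N(0, sigma_i^2),
    y_t = alpha * x_t[obs] + w_t, w_{t,j} ~ N(0, eta_j^2),
    x_0 ~ N(mu^(a), diag(gamma^2)),

where ``f(x) = x + int g(x, theta_sys) dt`` over the inter-observation
interval.  Only the initial mean ``mu`` is cell specific (index ``a``); it
carries the cell-to-cell variability of the initial state.  Observation may
be partial: ``obs_indices`` selects the measured coordinates (the fully
observed case is the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import batch_propagate, batch_transition_obj_grad

__all__ = [
    "IntegrationError",
    "Dynamics",
    "NetworkDynamics",
    "OdeDynamics",
    "DiscreteMapDynamics",
    "StateSpaceModel",
    "TimeCourseDataset",
    "evolve",
    "measure",
    "transition_logpdf",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class IntegrationError(RuntimeError):
    """Raised when the ODE solver produces a non-finite state."""

    def __init__(self, message, theta=None):
        super().__init__(message)
        self.theta = theta


class Dynamics:
    """Deterministic one-interval propagator abstraction.

    Subclasses provide ``f_batch(X, dt)`` mapping an (N, k) batch of states
    across an interval of length ``dt``; continuous-time dynamics also expose
    the right-hand side ``rhs(x)``.
    """

    k: int

    def f_batch(self, X: np.ndarray, dt: float) -> np.ndarray:
        raise NotImplementedError

    def rhs(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class NetworkDynamics(Dynamics):
    """Hill-network ODE dynamics with numba-accelerated batch propagation.

    ``nsub`` fixed RK4 substeps are used per unit of time (scaled with the
    interval), a resolution chosen so the one-step flow-map error is far
    below the system-noise scale for limit-cycle dynamics of period >~ 10.
    """

    def __init__(self, network, nsub: int = 4):
        self.network = network
        self.nsub = int(nsub)
        self.k = network.n_genes

    def _arrays(self):
        return self.network.path_arrays()

    def _steps(self, dt: float) -> int:
        return max(1, int(round(self.nsub * abs(dt))))

    def f_batch(self, X: np.ndarray, dt: float) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
        return batch_propagate(X, *self._arrays(), float(dt), self._steps(dt))

    def transition_obj_grad(self, Xprev, Xnext, w, inv2s2, dt):
        """Weighted transition objective and flat theta_sys gradient."""
        obj, gnat = batch_transition_obj_grad(
            np.ascontiguousarray(Xprev), np.ascontiguousarray(Xnext),
            np.ascontiguousarray(w), np.ascontiguousarray(inv2s2),
            *self._arrays(), float(dt), self._steps(dt))
        return obj, self._natural_to_flat(gnat)

    def _natural_to_flat(self, gnat: np.ndarray) -> np.ndarray:
        net = self.network
        NP, G = net.n_paths, net.n_genes
        gK, gn, ga = gnat[:NP], gnat[NP:2 * NP], gnat[2 * NP:3 * NP]
        gb, gd = gnat[3 * NP:3 * NP + G], gnat[3 * NP + G:]
        out = np.empty(net.n_theta)
        i = 0
        for p_idx, p in enumerate(net.paths):
            out[i] = gK[p_idx]; i += 1
            out[i] = gn[p_idx]; i += 1
            if p.is_activator:
                out[i] = ga[p_idx]; i += 1
        for g in net.free_basal:
            out[i] = gb[g]; i += 1
        out[i:] = gd
        return out

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.network.rhs(x)

    @property
    def theta(self) -> np.ndarray:
        return self.network.theta()

    @theta.setter
    def theta(self, value: np.ndarray) -> None:
        self.network.set_theta(value)


class OdeDynamics(Dynamics):
    """Generic ODE dynamics from a vectorised right-hand side.

    ``rhs_fn`` must accept states with shape (..., k) and operate on the last
    axis.  Propagation is fixed-step RK4 with ``nsub`` substeps per unit time.
    """

    def __init__(self, rhs_fn, k: int, nsub: int = 10):
        self._rhs = rhs_fn
        self.k = int(k)
        self.nsub = int(nsub)

    def rhs(self, x):
        return np.asarray(self._rhs(np.asarray(x, dtype=float)), dtype=float)

    def f_batch(self, X, dt):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        steps = max(1, int(round(self.nsub * abs(dt))))
        h = dt / steps
        x = X.copy()
        for _ in range(steps):
            k1 = self.rhs(x)
            k2 = self.rhs(x + 0.5 * h * k1)
            k3 = self.rhs(x + 0.5 * h * k2)
            k4 = self.rhs(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return x


class DiscreteMapDynamics(Dynamics):
    """Dynamics given directly as a discrete map ``x_t = F(x_{t-1})``.

    Useful for linear-Gaussian benchmarks where the exact transition is
    known; ``dt`` is ignored.
    """

    def __init__(self, map_fn, k: int):
        self._map = map_fn
        self.k = int(k)

    def f_batch(self, X, dt):
        return np.asarray(self._map(np.atleast_2d(np.asarray(X, dtype=float))))


@dataclass
class StateSpaceModel:
    """State-space model parameters around a :class:`Dynamics` object.

    sigma, gamma: per-state noise scales (length k); eta: per-observable
    (length l); mu: per-cell initial means, shape (A, k).
    """

    dynamics: Dynamics
    sigma: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    gamma: np.ndarray
    alpha: float = 1.0
    obs_indices: np.ndarray = None

    def __post_init__(self):
        k = self.dynamics.k
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(k)
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(k)
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if self.obs_indices is None:
            self.obs_indices = np.arange(k)
        self.obs_indices = np.asarray(self.obs_indices, dtype=int)
        self.eta = np.asarray(self.eta, dtype=float).reshape(self.l)
        if self.mu.shape[1] != k:
            raise ValueError("mu must have one column per state")
        if not (self.k >= self.l >= 1):
            raise ValueError("need k >= l >= 1")
        if np.any(self.sigma <= 0) or np.any(self.eta <= 0) or np.any(self.gamma <= 0):
            raise ValueError("noise scales sigma, eta, gamma must be positive")

    @property
    def k(self) -> int:
        return self.dynamics.k

    @property
    def l(self) -> int:
        return len(self.obs_indices)

    @property
    def n_cells(self) -> int:
        return self.mu.shape[0]


@dataclass
class TimeCourseDataset:
    """Per-cell observation matrices on a common, strictly increasing grid.

    ``Y`` has shape (A, T, l); complete series are assumed (no missing
    values).
    """

    times: np.ndarray
    Y: np.ndarray
    cell_ids: list = None
    columns: list = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 2:
            self.Y = self.Y[None]
        if self.Y.ndim != 3:
            raise ValueError("Y must have shape (cells, times, observables)")
        if self.Y.shape[1] != len(self.times):
            raise ValueError("time grid length does not match observations")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("dataset contains missing/non-finite values")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i+1}" for i in range(self.Y.shape[0])]
        if self.columns is None:
            self.columns = [f"y{j+1}" for j in range(self.Y.shape[2])]

    @property
    def n_cells(self) -> int:
        return self.Y.shape[0]

    @property
    def n_times(self) -> int:
        return self.Y.shape[1]

    @property
    def n_obs(self) -> int:
        return self.Y.shape[2]

    def std_per_observable(self) -> np.ndarray:
        return self.Y.reshape(-1, self.n_obs).std(axis=0)


def evolve(model: StateSpaceModel, x_prev, t0: float, t1: float,
           rtol: float = 1e-6, atol: float = 1e-9) -> np.ndarray:
    """Deterministic state propagation from ``t0`` to ``t1`` (no noise).

    Continuous dynamics are integrated with an adaptive stiff-capable solver
    (LSODA); discrete-map dynamics apply their map directly.
    """
    if t1 <= t0:
        raise ValueError("require t1 > t0")
    x_prev = np.asarray(x_prev, dtype=float)
    if not np.all(np.isfinite(x_prev)):
        raise IntegrationError("non-finite initial state")
    if isinstance(model.dynamics, DiscreteMapDynamics):
        return model.dynamics.f_batch(x_prev, t1 - t0)[0]
    sol = solve_ivp(lambda t, x: model.dynamics.rhs(x), (t0, t1), x_prev,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        theta = getattr(model.dynamics, "theta", None)
        raise IntegrationError(f"ODE integration failed: {sol.message}", theta=theta)
    return sol.y[:, -1]


def measure(model: StateSpaceModel, x) -> np.ndarray:
    """Noise-free measurement mean ``alpha * x[obs_indices]``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.k:
        raise ValueError(f"state dimension {x.shape[-1]} != k={model.k}")
    return model.alpha * x[..., model.obs_indices]


def transition_logpdf(model: StateSpaceModel, x_t, x_prev,
                      t0: float, t1: float) -> float:
    """Gaussian log-density of ``x_t`` given ``x_prev`` one interval earlier."""
    mean = evolve(model, x_prev, t0, t1)
    resid = np.asarray(x_t, dtype=float) - mean
    s2 = model.sigma ** 2
    return float(np.sum(-0.5 * (_LOG2PI + np.log(s2)) - resid ** 2 / (2.0 * s2)))
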