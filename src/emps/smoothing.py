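"""Particle filtering and smoothing for the nonlinear state-space model.

The smoothing distribution p(X | Y, theta) of one cell's full latent
trajectory is approximated by a weighted particle ensemble.  A bootstrap
particle filter (transition prior as proposal, systematic resampling) runs
forward; the smoothed ensemble is then drawn either by

* ``"ffbsi"`` — forward-filter backward-simulation: trajectories are sampled
  backwards against the filter clouds using the transition density, giving
  equally weighted smoothed draws (the default), or
* ``"ancestral"`` — the surviving ancestral paths of the final filter
  particles, weighted by their final normalised weights (each weight is the
  particle's data likelihood relative to the ensemble total).

All weight arithmetic is carried in log space with log-sum-exp
stabilisation.  The marginal log-likelihood estimate of a cell is the usual
product-of-stage-averages filter estimator; summing it over cells gives the
dataset log-likelihood (cells are independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .statespace import StateSpaceModel

__all__ = ["ParticleDegeneracyError", "ParticleEnsemble", "smooth",
           "log_likelihood"]

_LOG2PI = float(np.log(2.0 * np.pi))


class ParticleDegeneracyError(RuntimeError):
    """All particle likelihoods underflowed at some time index."""

    def __init__(self, time_index: int):
        super().__init__(
            f"particle weights collapsed at time index {time_index}")
        self.time_index = time_index


@dataclass
class ParticleEnsemble:
    """Weighted smoothed trajectories for one cell.

    trajectories: (P, T, k); weights sum to one.  ``log_likelihood`` is the
    filter estimate of ln p(Y^(a) | theta) for this cell.
    """

    trajectories: np.ndarray
    weights: np.ndarray
    times: np.ndarray
    log_likelihood: float
    method: str = "ffbsi"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("ensemble weights must be nonnegative")
        s = self.weights.sum()
        if not np.isclose(s, 1.0, rtol=1e-8):
            raise ValueError("ensemble weights must sum to one")

    @property
    def n_particles(self) -> int:
        return self.trajectories.shape[0]

    def mean(self) -> np.ndarray:
        """Posterior-mean trajectory, (T, k)."""
        return np.einsum("p,ptk->tk", self.weights, self.trajectories)


def _systematic_resample(wn: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    P = len(wn)
    positions = (rng.random() + np.arange(P)) / P
    return np.searchsorted(np.cumsum(wn), positions).clip(max=P - 1)


def _meas_logpdf(model: StateSpaceModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise measurement log-density of observation y for states x (P, k)."""
    resid = y[None, :] - model.alpha * x[:, model.obs_indices]
    e2 = model.eta ** 2
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        lp = -0.5 * (_LOG2PI + np.log(e2)) - resid ** 2 / (2.0 * e2)
    return np.sum(np.nan_to_num(lp, nan=-np.inf, neginf=-np.inf), axis=1)


def _forward_filter(model, y, times, cell_index, P, rng, ess_threshold):
    """Bootstrap filter; returns particle history needed for smoothing.

    particles: (T, P, k) pre-resampling clouds; lwn: (T, P) normalised
    log-weights; F: (T-1, P, k) flow-map images of each cloud; loglik.
    """
    T = len(times)
    k = model.k
    particles = np.empty((T, P, k))
    lwn = np.empty((T, P))
    F = np.empty((max(T - 1, 0), P, k))

    x = model.mu[cell_index] + model.gamma * rng.standard_normal((P, k))
    loglik = 0.0
    lw_carry = np.full(P, -np.log(P))  # normalised log-weights carried over
    for t in range(T):
        if t > 0:
            Ft = model.dynamics.f_batch(particles[t - 1], times[t] - times[t - 1])
            F[t - 1] = Ft
            ess = 1.0 / np.sum(np.exp(2.0 * lw_carry))
            if ess_threshold is None or ess < ess_threshold * P:
                idx = _systematic_resample(np.exp(lw_carry), rng)
                lw_carry = np.full(P, -np.log(P))
            else:
                idx = np.arange(P)
            x = Ft[idx] + model.sigma * rng.standard_normal((P, k))
        particles[t] = x
        lw_meas = _meas_logpdf(model, x, y[t])
        tot = logsumexp(lw_carry + lw_meas)
        if not np.isfinite(tot):
            raise ParticleDegeneracyError(t)
        loglik += tot
        lw_carry = lw_carry + lw_meas - tot
        lwn[t] = lw_carry
    return particles, lwn, F, float(loglik)


def _backward_simulate(model, particles, lwn, F, n_smooth, rng):
    """FFBSi: draw ``n_smooth`` trajectories backwards through the filter
    clouds; returns (n_smooth, T, k) equally weighted trajectories."""
    T, P, k = particles.shape
    s2 = 2.0 * model.sigma ** 2
    out = np.empty((n_smooth, T, k))
    # categorical draws via the Gumbel-argmax trick (vectorised over draws)
    g = rng.gumbel(size=(n_smooth, P))
    idx = np.argmax(lwn[T - 1][None, :] + g, axis=1)
    out[:, T - 1] = particles[T - 1][idx]
    for t in range(T - 2, -1, -1):
        # transition log-density of chosen x_{t+1} from every filter particle
        diff = out[:, t + 1][:, None, :] - F[t][None, :, :]   # (ns, P, k)
        logits = lwn[t][None, :] - np.sum(diff * diff / s2, axis=2)
        g = rng.gumbel(size=logits.shape)
        idx = np.argmax(logits + g, axis=1)
        out[:, t] = particles[t][idx]
    return out


def _ancestral_paths(particles, lwn, model, rng):
    """Reconstruct each final particle's ancestral path is not tracked by the
    plain filter; instead re-run selection implicitly by weighting the final
    cloud.  Used only through :func:`smooth`."""
    raise NotImplementedError


def smooth(model: StateSpaceModel, y: np.ndarray, times: np.ndarray,
           cell_index: int = 0, P: int = 500,
           rng: np.random.Generator | int | None = None,
           n_smooth: int | None = None, method: str = "ffbsi",
           ess_threshold: float | None = None) -> ParticleEnsemble:
    """Particle-smoother approximation of p(X^(a) | Y^(a), theta).

    Parameters
    ----------
    y : (T, l) observation matrix of one cell.
    P : number of filter particles (>= 2).
    n_smooth : number of smoothed trajectories drawn (default ``P``).
    method : "ffbsi" (backward simulation; uniform weights) or "ancestral"
        (final-particle ancestral paths weighted by final filter weights).
    ess_threshold : resample only when ESS < threshold * P; ``None`` (the
        default) resamples every step, which is robust for strongly
        oscillatory dynamics.
    """
    if P < 2:
        raise ValueError("need at least two particles")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    times = np.asarray(times, dtype=float)
    if n_smooth is None:
        n_smooth = P

    if method == "ffbsi":
        particles, lwn, F, loglik = _forward_filter(
            model, y, times, cell_index, P, rng, ess_threshold)
        traj = _backward_simulate(model, particles, lwn, F, n_smooth, rng)
        weights = np.full(n_smooth, 1.0 / n_smooth)
    elif method == "ancestral":
        particles, lwn, F, loglik, anc = _forward_filter_tracked(
            model, y, times, cell_index, P, rng, ess_threshold)
        T, _, k = particles.shape
        traj = np.empty((P, T, k))
        idx = np.arange(P)
        for t in range(T - 1, -1, -1):
            traj[:, t] = particles[t][idx]
            if t > 0:
                idx = anc[t - 1][idx]
        weights = np.exp(lwn[T - 1])
        weights = weights / weights.sum()
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return ParticleEnsemble(trajectories=traj, weights=weights, times=times,
                            log_likelihood=loglik, method=method)


def _forward_filter_tracked(model, y, times, cell_index, P, rng, ess_threshold):
    """Filter variant that also records ancestor indices (for "ancestral")."""
    T = len(times)
    k = model.k
    particles = np.empty((T, P, k))
    lwn = np.empty((T, P))
    F = np.empty((max(T - 1, 0), P, k))
    anc = np.empty((max(T - 1, 0), P), dtype=int)

    x = model.mu[cell_index] + model.gamma * rng.standard_normal((P, k))
    loglik = 0.0
    lw_carry = np.full(P, -np.log(P))
    for t in range(T):
        if t > 0:
            Ft = model.dynamics.f_batch(particles[t - 1], times[t] - times[t - 1])
            F[t - 1] = Ft
            ess = 1.0 / np.sum(np.exp(2.0 * lw_carry))
            if ess_threshold is None or ess < ess_threshold * P:
                idx = _systematic_resample(np.exp(lw_carry), rng)
                lw_carry = np.full(P, -np.log(P))
            else:
                idx = np.arange(P)
            anc[t - 1] = idx
            x = Ft[idx] + model.sigma * rng.standard_normal((P, k))
        particles[t] = x
        lw_meas = _meas_logpdf(model, x, y[t])
        tot = logsumexp(lw_carry + lw_meas)
        if not np.isfinite(tot):
            raise ParticleDegeneracyError(t)
        loglik += tot
        lw_carry = lw_carry + lw_meas - tot
        lwn[t] = lw_carry
    return particles, lwn, F, float(loglik), anc


def log_likelihood(ensembles) -> float:
    """Dataset log-likelihood: sum of per-cell filter estimates."""
    if isinstance(ensembles, ParticleEnsemble):
        return ensembles.log_likelihood
    return float(sum(e.log_likelihood for e in ensembles))
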