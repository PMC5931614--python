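"""Numba kernels for batched ODE propagation of Hill networks.

The inference loop needs the one-interval flow map ``f(x) = x + int g dt``
evaluated for very many states at once (every particle at every time point of
every cell), and — inside the M-step — the gradient of a particle-weighted
quadratic objective in ``f`` with respect to every kinetic parameter.  The
flow map is fixed-step classical RK4 over ``nsub`` substeps; the gradient is
obtained by reverse-mode (adjoint) differentiation through the stored RK4
stages, so its cost is independent of the number of parameters.  Hill terms
reuse one log/exp per path per stage for the value and all of its partial
derivatives.

State conventions: concentrations entering Hill terms are clamped at zero
(the Gaussian state-noise model permits small negative excursions; regulation
from a negative concentration is treated as absent), degradation acts on the
raw state so negative excursions decay back toward zero.

Natural-parameter gradient layout (``NP`` paths, ``G`` genes), column index:
``K_p -> p``, ``n_p -> NP + p``, ``a_p -> 2 NP + p`` (zero for repressors),
``basal_g -> 3 NP + g``, ``degradation_g -> 3 NP + G + g``.
"""

import numpy as np
from numba import njit

__all__ = ["batch_propagate", "batch_transition_obj_grad", "langevin_heun",
           "natural_grad_size"]


def natural_grad_size(n_paths: int, n_genes: int) -> int:
    return 3 * n_paths + 2 * n_genes


@njit(cache=True)
def _eval_g(x, src, tgt, act, K, n, amp, basal, degr, g):
    k = x.shape[0]
    NP = src.shape[0]
    A = np.empty(k)
    R = np.empty(k)
    for i in range(k):
        A[i] = basal[i]
        R[i] = 1.0
    for p in range(NP):
        xs = x[src[p]]
        if xs < 0.0:
            xs = 0.0
        kx = K[p] * xs
        if kx > 0.0:
            u = np.exp(n[p] * np.log(kx))
        else:
            u = 0.0
        if act[p]:
            A[tgt[p]] += amp[p] * u / (1.0 + u)
        else:
            R[tgt[p]] *= 1.0 / (1.0 + u)
    for i in range(k):
        g[i] = A[i] * R[i] - degr[i] * x[i]


@njit(cache=True)
def _adjoint_g(x, v, src, tgt, act, K, n, amp, basal, degr,
               grad, bar_x, u_buf, lg_buf):
    """Accumulate ``grad += (dg/dtheta)^T v`` and overwrite
    ``bar_x = (dg/dx)^T v`` for a single state ``x`` and adjoint ``v``."""
    k = x.shape[0]
    NP = src.shape[0]
    G = k
    A = np.empty(k)
    R = np.empty(k)
    for i in range(k):
        A[i] = basal[i]
        R[i] = 1.0
        bar_x[i] = 0.0
    # first pass: Hill terms and aggregate production factors
    for p in range(NP):
        xs = x[src[p]]
        if xs < 0.0:
            xs = 0.0
        kx = K[p] * xs
        if kx > 0.0:
            lg = np.log(kx)
            u = np.exp(n[p] * lg)
        else:
            lg = 0.0
            u = 0.0
        u_buf[p] = u
        lg_buf[p] = lg
        if act[p]:
            A[tgt[p]] += amp[p] * u / (1.0 + u)
        else:
            R[tgt[p]] *= 1.0 / (1.0 + u)
    # second pass: pull the adjoint back through every term
    for p in range(NP):
        s = src[p]
        t = tgt[p]
        vt = v[t]
        if vt == 0.0:
            continue
        xs = x[s]
        if xs < 0.0:
            xs = 0.0
        u = u_buf[p]
        lg = lg_buf[p]
        if u > 0.0:
            du_dx = n[p] * u / xs
            du_dK = n[p] * u / K[p]
            du_dn = u * lg
        else:
            # (Kx)^n at Kx == 0: only n == 1 leaves a finite slope
            du_dx = K[p] if n[p] == 1.0 else 0.0
            du_dK = xs if n[p] == 1.0 else 0.0
            du_dn = 0.0
        if x[s] < 0.0:
            du_dx = 0.0  # clamped concentration: no sensitivity to raw state
        if act[p]:
            w = amp[p] / ((1.0 + u) * (1.0 + u)) * R[t] * vt
            bar_x[s] += w * du_dx
            grad[p] += w * du_dK
            grad[NP + p] += w * du_dn
            grad[2 * NP + p] += (u / (1.0 + u)) * R[t] * vt
        else:
            fac = -(A[t] * R[t]) / (1.0 + u) * vt
            bar_x[s] += fac * du_dx
            grad[p] += fac * du_dK
            grad[NP + p] += fac * du_dn
    for i in range(k):
        vi = v[i]
        bar_x[i] -= degr[i] * vi
        grad[3 * NP + i] += R[i] * vi
        grad[3 * NP + G + i] -= x[i] * vi


@njit(cache=True)
def batch_propagate(X, src, tgt, act, K, n, amp, basal, degr, dt, nsub):
    """Flow map over an interval of length ``dt``: classical RK4, ``nsub``
    substeps, applied row-wise to the (N, k) state batch."""
    N, k = X.shape
    F = np.empty_like(X)
    h = dt / nsub
    x = np.empty(k)
    k1 = np.empty(k)
    k2 = np.empty(k)
    k3 = np.empty(k)
    k4 = np.empty(k)
    xs = np.empty(k)
    for r in range(N):
        for i in range(k):
            x[i] = X[r, i]
        for _ in range(nsub):
            _eval_g(x, src, tgt, act, K, n, amp, basal, degr, k1)
            for i in range(k):
                xs[i] = x[i] + 0.5 * h * k1[i]
            _eval_g(xs, src, tgt, act, K, n, amp, basal, degr, k2)
            for i in range(k):
                xs[i] = x[i] + 0.5 * h * k2[i]
            _eval_g(xs, src, tgt, act, K, n, amp, basal, degr, k3)
            for i in range(k):
                xs[i] = x[i] + h * k3[i]
            _eval_g(xs, src, tgt, act, K, n, amp, basal, degr, k4)
            for i in range(k):
                x[i] = x[i] + (h / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        for i in range(k):
            F[r, i] = x[i]
    return F


@njit(cache=True)
def batch_transition_obj_grad(Xprev, Xnext, w, inv2s2,
                              src, tgt, act, K, n, amp, basal, degr, dt, nsub):
    """Particle-weighted quadratic transition objective and its gradient.

        obj = sum_r w_r sum_i -(Xnext[r,i] - F(Xprev[r])_i)^2 * inv2s2[i]

    Returns ``(obj, grad)`` with ``grad`` in the natural parameter layout.
    The forward RK4 stages of every substep are stored and the scalar
    objective is then differentiated by a reverse (adjoint) sweep, so the
    cost does not grow with the number of parameters.
    """
    N, k = Xprev.shape
    NP = src.shape[0]
    G = k
    M = 3 * NP + 2 * G
    h = dt / nsub
    grad = np.zeros(M)
    obj = 0.0

    x = np.empty(k)
    stage = np.empty((nsub, 4, k))   # base state and stage states x2, x3, x4
    gstage = np.empty((nsub, 4, k))  # g at those states
    g_tmp = np.empty(k)
    bar_y = np.empty(k)
    bar_k1 = np.empty(k)
    bar_k2 = np.empty(k)
    bar_k3 = np.empty(k)
    bar_k4 = np.empty(k)
    bar_x = np.empty(k)
    bxs = np.empty(k)
    u_buf = np.empty(NP)
    lg_buf = np.empty(NP)

    for r in range(N):
        wr = w[r]
        for i in range(k):
            x[i] = Xprev[r, i]
        # forward pass, storing all stage states
        for s in range(nsub):
            for i in range(k):
                stage[s, 0, i] = x[i]
            _eval_g(x, src, tgt, act, K, n, amp, basal, degr, g_tmp)
            for i in range(k):
                gstage[s, 0, i] = g_tmp[i]
                stage[s, 1, i] = x[i] + 0.5 * h * g_tmp[i]
            _eval_g(stage[s, 1], src, tgt, act, K, n, amp, basal, degr, g_tmp)
            for i in range(k):
                gstage[s, 1, i] = g_tmp[i]
                stage[s, 2, i] = x[i] + 0.5 * h * g_tmp[i]
            _eval_g(stage[s, 2], src, tgt, act, K, n, amp, basal, degr, g_tmp)
            for i in range(k):
                gstage[s, 2, i] = g_tmp[i]
                stage[s, 3, i] = x[i] + h * g_tmp[i]
            _eval_g(stage[s, 3], src, tgt, act, K, n, amp, basal, degr, g_tmp)
            for i in range(k):
                gstage[s, 3, i] = g_tmp[i]
                x[i] = x[i] + (h / 6.0) * (gstage[s, 0, i] + 2.0 * gstage[s, 1, i]
                                           + 2.0 * gstage[s, 2, i] + g_tmp[i])
        # objective and seed adjoint
        for i in range(k):
            resid = Xnext[r, i] - x[i]
            obj -= wr * resid * resid * inv2s2[i]
            bar_y[i] = 2.0 * wr * resid * inv2s2[i]  # dObj/dF
        # reverse sweep through the substeps
        for s in range(nsub - 1, -1, -1):
            for i in range(k):
                bar_k1[i] = (h / 6.0) * bar_y[i]
                bar_k2[i] = (h / 3.0) * bar_y[i]
                bar_k3[i] = (h / 3.0) * bar_y[i]
                bar_k4[i] = (h / 6.0) * bar_y[i]
            # k4 = g(x4), x4 = x + h k3
            _adjoint_g(stage[s, 3], bar_k4, src, tgt, act, K, n, amp, basal,
                       degr, grad, bxs, u_buf, lg_buf)
            for i in range(k):
                bar_y[i] += bxs[i]
                bar_k3[i] += h * bxs[i]
            # k3 = g(x3), x3 = x + h/2 k2
            _adjoint_g(stage[s, 2], bar_k3, src, tgt, act, K, n, amp, basal,
                       degr, grad, bxs, u_buf, lg_buf)
            for i in range(k):
                bar_y[i] += bxs[i]
                bar_k2[i] += 0.5 * h * bxs[i]
            # k2 = g(x2), x2 = x + h/2 k1
            _adjoint_g(stage[s, 1], bar_k2, src, tgt, act, K, n, amp, basal,
                       degr, grad, bxs, u_buf, lg_buf)
            for i in range(k):
                bar_y[i] += bxs[i]
                bar_k1[i] += 0.5 * h * bxs[i]
            # k1 = g(x)
            _adjoint_g(stage[s, 0], bar_k1, src, tgt, act, K, n, amp, basal,
                       degr, grad, bxs, u_buf, lg_buf)
            for i in range(k):
                bar_y[i] += bxs[i]
    return obj, grad


@njit(cache=True)
def langevin_heun(x0, noise, src, tgt, act, K, n, amp, basal, degr,
                  h, rec_idx, clip_negative):
    """Chemical-Langevin integration of a Hill network by the stochastic
    Heun (Runge-Kutta) scheme, exact for the additive diffusion term.

    ``noise`` holds the pre-scaled Brownian increments (nsteps, k), i.e.
    sqrt(2 D h) standard normals.  States are recorded after the step counts
    listed in ``rec_idx`` (0 records the initial state).  If
    ``clip_negative`` the state is reflected at zero after every step
    (concentrations feed Hill terms).
    """
    nsteps = noise.shape[0]
    k = x0.shape[0]
    out = np.empty((rec_idx.shape[0], k))
    x = x0.copy()
    g1 = np.empty(k)
    g2 = np.empty(k)
    pred = np.empty(k)
    ri = 0
    if ri < rec_idx.shape[0] and rec_idx[ri] == 0:
        for i in range(k):
            out[ri, i] = x[i]
        ri += 1
    for step in range(nsteps):
        _eval_g(x, src, tgt, act, K, n, amp, basal, degr, g1)
        for i in range(k):
            pred[i] = x[i] + h * g1[i] + noise[step, i]
        _eval_g(pred, src, tgt, act, K, n, amp, basal, degr, g2)
        for i in range(k):
            x[i] = x[i] + 0.5 * h * (g1[i] + g2[i]) + noise[step, i]
            if clip_negative and x[i] < 0.0:
                x[i] = 0.0
            if not np.isfinite(x[i]):
                # signal blow-up through a NaN row; caller raises
                for j in range(k):
                    out[0, j] = np.nan
                return out
        if ri < rec_idx.shape[0] and rec_idx[ri] == step + 1:
            for i in range(k):
                out[ri, i] = x[i]
            ri += 1
    return out
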