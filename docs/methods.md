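# Methods

## Model

A gene circuit with `k` species is modelled as a nonlinear Gaussian
state-space system on the observation grid `t = 0..T-1`:

    x_t = f(x_{t-1}) + v_t,        v_{t,i} ~ N(0, sigma_i^2)
    y_t = alpha * x_t[obs] + w_t,  w_{t,j} ~ N(0, eta_j^2)
    x_0 ~ N(mu^(a), diag(gamma^2))

`f` is the flow map of the deterministic kinetics over one sampling
interval, `f(x) = x + \int g(x, theta_sys) dt`.  Only the initial mean
`mu^(a)` is cell specific: cell-to-cell variability enters through initial
states (in the oscillatory benchmarks, through the phase at which each cell
enters the recording window), not through parameter heterogeneity.
Observation may be partial (`obs` a subset of coordinates, `alpha` a fixed
gain, 1 by default); the benchmark experiments observe either all genes or,
in the node-inference experiment, two of three.

The kinetics are Hill-type: gene `i` is produced at rate

    (b_i + sum_act a_s * (K_s x_src)^{n_s} / (1 + (K_s x_src)^{n_s}))
        * prod_rep 1 / (1 + (K_s x_src)^{n_s})   -   d_i x_i

with first-order degradation `d_i` and an optional constitutive basal rate
`b_i` multiplied by the repressor factors.  The basal term is needed for any
gene whose production is purely repressor-controlled (a repressilator-style
node): with the sum-of-activators form alone such a gene would be inert.  In
redundant candidate models every gene carries a free basal rate; in the
reference circuits only gene X does.

`K = 0` makes a path exactly absent (activator activity 0, repressor factor
1), so the association constants double as structural indicators — the
premise of the sparse estimator.

## EM with particle smoothing (EM-PS)

The log-likelihood of heterogeneous multi-cell data is maximised by EM.  The
E-step needs the smoothing distribution of each cell's latent trajectory; it
is approximated with a particle smoother:

* bootstrap particle filter: proposal = transition prior, systematic
  resampling at every step (robust for strongly oscillatory dynamics; an
  effective-sample-size gate is available in the config),
* backward simulation (FFBSi): `n_smooth` trajectories are drawn backwards
  against the stored filter clouds using the Gaussian transition density,
  giving an equally weighted smoothed ensemble.  An alternative `ancestral`
  mode returns the surviving filter genealogies weighted by their final
  normalised weights (each weight is the particle's data likelihood over the
  ensemble total).

All weight arithmetic is in log space with log-sum-exp stabilisation.  The
per-cell marginal log-likelihood is the standard filter estimator (product
of per-step averaged incremental weights); cells are independent so dataset
values are sums over cells.

The expected complete-data log-likelihood Q(theta, theta_old) splits into
initial-state, transition and measurement Gaussian blocks, each a
particle-weighted sum over (cell, particle, time, coordinate).  The M-step
is split:

1. theta_sys (all kinetic parameters) — only the transition block depends
   on it.  It is maximised by bound-constrained L-BFGS-B with an analytic
   gradient, under nonnegativity bounds and Hill coefficients confined to
   [1, 8] (unbounded n degenerates to step functions).  The optimizer
   budget is capped (default 100 objective evaluations; a partial M-step
   suffices — generalised EM).  For maximum-likelihood fits the search runs
   in log coordinates, which is what makes starting values two orders of
   magnitude off workable; for L1-penalised fits it runs on the raw scale
   so that zeros at the bound are reachable.
2. sigma, eta, mu, gamma — their stationarity equations are linear, so the
   updates are closed-form weighted residual moments, then clipped:
   `gamma >= gamma_min` (1% of the per-state data standard deviation by
   default) to prevent sample impoverishment, `sigma <= sigma_max` and
   `eta <= eta_max` (the data standard deviation by default) to prevent the
   noise from absorbing the signal early in the fit.

Because the E-step is Monte Carlo, the log-likelihood trace fluctuates by a
few units even after convergence; convergence is therefore controlled by a
fixed iteration count (default 100) rather than a tolerance, with an
optional plateau detector on the windowed median.

### Flow-map evaluation and gradients

The inference loop evaluates `f` for every particle at every time point, so
the flow map is computed by fixed-step classical RK4 (numba kernels,
`nsub` substeps per unit time, default 4).  On the reference limit cycles
the one-interval flow error is ~7e-3 at `nsub = 2` and ~4e-4 at `nsub = 4`,
far below the transition noise scale (~0.14).  The reference `evolve`
operation uses an adaptive LSODA integrator instead (rtol 1e-6, atol 1e-9
defaults) and the two are cross-checked in tests.

The M-step gradient of the transition block with respect to all kinetic
parameters is computed by reverse-mode (adjoint) differentiation through the
stored RK4 stages — exact for the discrete objective and with cost
independent of the parameter count, which is what makes the 51-parameter
redundant-model M-steps affordable.

States may go slightly negative under the Gaussian noise model and are not
clipped during inference (the likelihood is exactly the Gaussian model
above); concentrations entering Hill terms are clamped at zero so the
vector field stays defined, and degradation acts on the raw state so
negative excursions decay back.

## EM-PS-Lasso

Topology inference starts from the redundant model over G genes — all
`2 G^2` candidate paths, each ordered pair in both signs, self-loops
included — and penalises the association constants in the M-step:

    Q'(theta, theta_old) = Q(theta, theta_old) - lam * sum_s |K_s|.

Since `K_s >= 0` is enforced, `|K_s| = K_s` and Q' is smooth on the feasible
region; bound-constrained quasi-Newton drives unnecessary K exactly to the
boundary, and a hard threshold (`K < 1e-6 -> 0`) removes round-off residue.
Once a path with `n > 1` reaches `K = 0` its Q-gradient vanishes while the
penalty still pushes down, so pruned paths stay pruned (its Hill
coefficient, unidentifiable at `K = 0`, simply stops moving).  A path is
reported as *effective* when `K` exceeds a practical threshold (default
1e-3); this separates structure from the tiny-but-nonzero K values that
strong penalties can leave with no dynamical effect.

The penalty strength is chosen by a sweep over a logarithmic grid (default
{0.1, 0.3, 1, 3, 10, 15, 30}): each lambda is refitted from the same
redundant start, scored on held-out test cells (test-cell initial means are
taken from their first observation since mu is cell specific), and
*inconsistent* fits — some source gene simultaneously activating and
repressing the same target — are rejected.  The candidates are all
consistent runs within 2% of the best test log-likelihood (a set, not a
forced single winner); the sparsest candidate is the headline model.
Extreme penalties drive every K to zero and the fit collapses; with
`lam = 0` the code path is identical to plain EM-PS (bit-for-bit under a
shared seed).

## Artificial data

Single-cell time courses are generated from the chemical Langevin equation
`dx/dt = g(x) + xi(t)`, `<xi_i(t) xi_j(t')> = 2 D delta_ij delta(t-t')`,
integrated by a stochastic Heun (Runge-Kutta) scheme with step 0.01 — the
additive diffusion is treated exactly; the drift is second order.  States
are reflected at zero during generation (a generator-only convention, since
concentrations feed Hill terms).  Measurement noise is added afterwards:
`y = x + eta * phi`, `phi ~ N(0, 1)`.

Protocol defaults: simulate over `t in [0, 400]` from an initial state drawn
uniformly in `[0, 3]^k` per cell, discard the transient, record
`t = 351..400` at resolution 1 (50 points), 10 independent training and 10
independent test cells from disjoint seed streams.  The long transient makes
cells enter the window at decorrelated phases of the limit cycle, which is
the heterogeneity the estimator must absorb through the cell-specific
initial means.  Noise amplitudes default to `D = 0.01` (per-step transition
noise scale ~0.14) and `eta = 0.1`, i.e. clearly oscillatory but visibly
noisy traces at limit-cycle amplitudes of ~2.

What the generator does *not* emulate: discrete-molecule (Gillespie) noise,
parameter heterogeneity across cells, missing observations, and non-Gaussian
measurement error.  Passing recovery tests therefore demonstrates correct
inference under the stated noise model, not robustness to those real-data
complications.

### Reference circuits

Two ground-truth circuits are frozen in `emps.simulate.reference_circuits`
and guarded by oscillation tests:

* **three_gene** — negative-feedback loop X -> Y -> Z -| X with basal
  production of X (b_X = 2.2, K_ZX = 0.5, n_ZX = 7, d_X = 0.26;
  a_XY = 2.2, K_XY = 0.6, n_XY = 2, d_Y = 0.34; a_YZ = 1.5, K_YZ = 0.55,
  n_YZ = 5, d_Z = 0.36).  Period ~12, amplitudes ~2 for every species.
* **two_gene** — relaxation oscillator: X autoactivation (a = 6, K = 1.3,
  n = 6), Z -| X repression (K = 0.5, n = 5), X -> Z activation (a = 1.5,
  K = 1.3, n = 3), b_X = 0.2, d_X = 0.5, d_Z = 0.2.  Period ~16,
  amplitudes ~3.5.

Both were selected by a two-part a-priori screen: sustained oscillation from
every initial state in the sampling box, and — for the three-gene circuit,
which serves as parameter-recovery ground truth — identifiability at the
default data size: the complete-data Cramér-Rao bound of every kinetic
parameter is below ~7% relative (computed from the generator's Fisher
information, with no fitting involved).  Without that screen it is easy to
pick an oscillator whose basal/repression parameters sit on a likelihood
ridge (production saturated over most of the cycle), making recovery
experiments meaningless no matter how good the estimator is.

## Problem sizes used in the test suite

The validation experiments are scaled so the whole suite runs on one CPU in
minutes; these sizes are the package's chosen benchmark conditions:

* smoother-vs-Kalman oracle: 1-D linear-Gaussian model, T = 15, P = 5000,
  5 Monte-Carlo repeats (agreement within 3 MC standard errors);
* parameter recovery: 10 cells x 50 points, P = 200, n_smooth = 30,
  30 EM iterations, kinetic parameters initialised at 1/100 of truth
  (observed max relative error 4-10% across seeds, vs a ~6% complete-data
  Cramér-Rao floor);
* topology inference: 5 cells, P = 100, n_smooth = 15, 40 iterations,
  lam = 15 (three-gene) and lam = 5 (two-gene node inference);
* penalty-sweep behaviour: 3 cells x 25 points, P = 60, 12 iterations.

`scripts/acceptance.py` re-runs the pipeline at the same sizes from scratch
and reports the measured quantities.

## Known limitations

* Non-uniform observation grids are rejected by the Q function (the spacing
  enters only through the flow map; per-step transition variance is not
  rescaled by interval length).
* No standard errors or posterior uncertainty on the estimates.
* FFBSi costs O(P * n_smooth) per step and cell; very long series or many
  particles will want the ESS-gated resampling and a smaller n_smooth.
* The M-step treats sigma as fixed while optimising theta_sys and then
  updates the noise — one round of a block ascent, not a joint maximiser;
  with the capped optimizer budget this is a generalised EM, and the
  log-likelihood can fluctuate by Monte-Carlo noise on top of that.
* Model selection uses a single train/test split, as in the benchmark
  protocol; no cross-validation or stability selection.
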