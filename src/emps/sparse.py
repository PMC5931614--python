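"""EM-PS-Lasso: sparse network-topology inference by L1-penalised EM.

The redundant network over G genes contains every candidate path; its
association constants K_s are penalised in the M-step,

    Q'(theta, theta_old) = Q(theta, theta_old) - lam * sum_s |K_s|,

so unnecessary paths are driven to K = 0, where they are exactly absent from
the dynamics.  Since all K are constrained nonnegative, |K| = K and Q' stays
smooth on the feasible region: bound-constrained quasi-Newton applies
directly and exact zeros arise at the bound (a hard threshold snaps
round-off-level K to 0).

A lambda sweep refits across a penalty grid, scores each run on held-out
test cells, rejects biologically inconsistent networks (a gene pair both
activated and repressed by the same source), and reports the consistent
near-optimal runs as candidate models — preferring the sparsest among ties.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .networks import GeneNetwork
from .estimation import EMConfig, EMPS, EMPSResults
from .statespace import TimeCourseDataset

__all__ = ["EMPSLasso", "LassoRun", "penalized_q", "count_effective_paths",
           "check_consistency", "lambda_sweep", "run_em_lasso", "SweepResult"]


def penalized_q(q_evaluator, lam: float, k_index_set):
    """Wrap a Q evaluator with the L1 penalty on the association constants.

    ``q_evaluator(theta)`` maps a flat parameter vector to Q; the returned
    callable subtracts ``lam * sum(theta[k_index_set])`` (absolute values
    drop because K >= 0 is enforced).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    k_index_set = np.asarray(list(k_index_set), dtype=int)

    def q_prime(theta, *args, **kwargs):
        theta = np.asarray(theta, dtype=float)
        return q_evaluator(theta, *args, **kwargs) - lam * np.sum(theta[k_index_set])

    return q_prime


def count_effective_paths(obj, threshold: float = 1e-3) -> int:
    """Number of paths whose association constant exceeds ``threshold``.

    The threshold separates structurally present paths from the
    "nonzero but extremely small" K values that large penalties can leave
    behind with practically no effect on the dynamics.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    net = _as_network(obj)
    return len(net.effective_paths(threshold))


def check_consistency(obj, threshold: float = 1e-3):
    """Flag biologically inconsistent sign conflicts.

    A network in which some source gene simultaneously activates *and*
    represses the same target (both paths effective) is rejected from model
    selection.  Returns ``(consistent, violations)`` with violations as
    (source_name, target_name) pairs.
    """
    net = _as_network(obj)
    effective = {}
    for p in net.paths:
        if p.K > threshold:
            effective.setdefault((p.source, p.target), set()).add(p.sign)
    violations = [(net.genes[s], net.genes[t])
                  for (s, t), signs in sorted(effective.items())
                  if len(signs) == 2]
    return len(violations) == 0, violations


def _as_network(obj) -> GeneNetwork:
    if isinstance(obj, GeneNetwork):
        return obj
    if hasattr(obj, "network"):
        return obj.network
    raise TypeError(f"expected GeneNetwork or fitted run, got {type(obj)!r}")


@dataclass
class LassoRun(EMPSResults):
    """EM-PS-Lasso fit results: adds the penalty strength, the per-iteration
    association-constant trace (path-elimination dynamics), the train/test
    log-likelihoods and the consistency flag."""

    lam: float = 0.0
    test_loglik: float | None = None

    @property
    def train_loglik(self) -> float:
        return self.final_loglik

    @property
    def K_history(self) -> pd.DataFrame:
        cols = [c for c in self.theta_history.columns if c.startswith("K_")]
        return self.theta_history[cols]

    def effective_paths(self, threshold: float | None = None) -> list[int]:
        thr = self.config.effective_threshold if threshold is None else threshold
        return self.network.effective_paths(thr)

    @property
    def consistent(self) -> bool:
        ok, _ = check_consistency(self.network, self.config.effective_threshold)
        return ok

    def summary(self) -> str:
        base = super().summary()
        eff = self.effective_paths()
        extra = [f"lambda: {self.lam:g}   effective paths: {len(eff)} {eff}",
                 f"consistent: {self.consistent}"]
        if self.test_loglik is not None:
            extra.append(f"test log-likelihood: {self.test_loglik:.3f}")
        return base + "\n" + "\n".join(extra)


class EMPSLasso(EMPS):
    """EM-PS with L1 regularisation of the association constants.

    Identical to :class:`EMPS` (bit-for-bit at ``lam = 0`` under a shared
    seed) except that the M-step maximises the penalised Q' and prunes
    round-off-level K to exact zeros.  The optimisation runs on the linear
    scale so the K bounds at zero are reachable.
    """

    def __init__(self, dataset, network, lam: float, obs_indices=None,
                 config: EMConfig | None = None, alpha: float = 1.0):
        config = config or EMConfig(transform="linear")
        super().__init__(dataset, network, obs_indices=obs_indices, lam=lam,
                         config=config, alpha=alpha)

    def fit(self, seed=None, iterations=None, callback=None,
            test_dataset: TimeCourseDataset | None = None) -> LassoRun:
        res = super().fit(seed=seed, iterations=iterations, callback=callback)
        test_ll = None
        if test_dataset is not None:
            test_ll = res.log_likelihood(test_dataset, seed=0)
        return LassoRun(
            network=res.network, sigma=res.sigma, eta=res.eta, mu=res.mu,
            gamma=res.gamma, loglik_history=res.loglik_history,
            theta_history=res.theta_history, ensembles=res.ensembles,
            final_loglik=res.final_loglik, config=res.config,
            dataset=res.dataset, obs_indices=res.obs_indices, seed=res.seed,
            lam=self.lam, test_loglik=test_ll)


def run_em_lasso(network: GeneNetwork, dataset: TimeCourseDataset,
                 lam: float, particles: int | None = None,
                 iterations: int | None = None,
                 seed: int | None = None, obs_indices=None,
                 test_dataset: TimeCourseDataset | None = None,
                 config: EMConfig | None = None, **cfg_kwargs) -> LassoRun:
    """Functional wrapper: one EM-PS-Lasso fit at penalty strength ``lam``.

    ``particles``/``iterations``/keyword settings override ``config`` only
    when given explicitly.
    """
    cfg = config or EMConfig(transform="linear")
    if particles is not None:
        cfg_kwargs["particles"] = particles
    if iterations is not None:
        cfg_kwargs["iterations"] = iterations
    cfg = dc_replace(cfg, **cfg_kwargs)
    model = EMPSLasso(dataset, network, lam=lam, obs_indices=obs_indices,
                      config=cfg)
    return model.fit(seed=seed, test_dataset=test_dataset)


@dataclass
class SweepResult:
    """Outcome of a lambda sweep: all runs (lambda-ascending), the summary
    table, and the candidate models selected by the consistency +
    near-maximal-test-likelihood rule."""

    runs: list
    table: pd.DataFrame
    candidates: list
    selection_rel_tol: float

    @property
    def best(self) -> LassoRun | None:
        """Headline model: the sparsest candidate (ties broken by test
        log-likelihood)."""
        if not self.candidates:
            return None
        return min(self.candidates,
                   key=lambda r: (len(r.effective_paths()), -r.test_loglik))


def lambda_sweep(network: GeneNetwork, train: TimeCourseDataset,
                 test: TimeCourseDataset, lam_grid,
                 particles: int | None = None, iterations: int | None = None,
                 seed: int | None = None, obs_indices=None,
                 config: EMConfig | None = None,
                 selection_rel_tol: float = 0.02, **cfg_kwargs) -> SweepResult:
    """EM-PS-Lasso across a penalty grid with train/test scoring.

    Each lambda is fitted from the same initial redundant model with its own
    reproducible seed stream.  Candidates are the consistent runs whose test
    log-likelihood is within ``selection_rel_tol * |best|`` of the best; the
    selection is a candidate *set* (ties are reported, not forced to a single
    winner).  Individual-lambda failures are recorded and the sweep
    continues.
    """
    lam_grid = sorted(float(l) for l in lam_grid)
    if not lam_grid:
        raise ValueError("lam_grid must be nonempty")
    cfg = config or EMConfig(transform="linear")
    if particles is not None:
        cfg_kwargs["particles"] = particles
    if iterations is not None:
        cfg_kwargs["iterations"] = iterations
    cfg = dc_replace(cfg, **cfg_kwargs)
    master = np.random.SeedSequence(seed)
    runs, failures = [], []
    for lam, ss in zip(lam_grid, master.spawn(len(lam_grid))):
        sub_seed = int(ss.generate_state(1)[0] % (2 ** 31 - 1))
        try:
            run = EMPSLasso(train, network.copy(), lam=lam,
                            obs_indices=obs_indices, config=cfg).fit(
                seed=sub_seed, test_dataset=test)
            runs.append(run)
        except Exception as exc:  # per-lambda failure: record, continue
            failures.append((lam, repr(exc)))
    from .reports import sweep_report
    table = sweep_report(runs, selection_rel_tol=selection_rel_tol)
    candidates = [r for r in runs
                  if table.loc[table["lambda"] == r.lam, "candidate"].any()]
    result = SweepResult(runs=runs, table=table, candidates=candidates,
                         selection_rel_tol=selection_rel_tol)
    result.failures = failures
    return result
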