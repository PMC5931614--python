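"""Report tables: parameter-recovery ratios and lambda-sweep summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .networks import GeneNetwork

__all__ = ["recovery_report", "sweep_report"]


def recovery_report(fitted: GeneNetwork, truth: GeneNetwork,
                    threshold: float = 1e-3) -> pd.DataFrame:
    """Estimated/true ratios of the kinetic parameters plus a topology
    confusion summary.

    The two models must share gene sets (hence canonical path ids).  Ratios
    are reported for every nonzero true parameter; the table's ``attrs``
    carry ``max_rel_error`` and the effective-path confusion counts
    (true/false positives/negatives at the given K threshold).
    """
    if list(fitted.genes) != list(truth.genes):
        raise ValueError("models do not share a gene set/parameterization")
    fit_params = dict(zip(fitted.theta_names(), fitted.theta()))
    rows = []
    for name, true_val in zip(truth.theta_names(), truth.theta()):
        if name not in fit_params:
            raise ValueError(f"fitted model lacks parameter {name}")
        est = fit_params[name]
        ratio = est / true_val if true_val != 0 else np.nan
        rows.append({"parameter": name, "true": true_val, "estimated": est,
                     "ratio": ratio})
    table = pd.DataFrame(rows)
    nz = table["true"] != 0
    max_rel = float(np.max(np.abs(table.loc[nz, "ratio"] - 1.0))) if nz.any() else 0.0
    true_eff = set(truth.effective_paths(threshold))
    fit_eff = set(fitted.effective_paths(threshold))
    table.attrs["max_rel_error"] = max_rel
    table.attrs["confusion"] = {
        "true_positive": len(true_eff & fit_eff),
        "false_positive": len(fit_eff - true_eff),
        "false_negative": len(true_eff - fit_eff),
    }
    return table


def sweep_report(runs, selection_rel_tol: float = 0.02) -> pd.DataFrame:
    """Summary table of a lambda sweep, ascending in lambda.

    Candidates are the consistent runs whose test log-likelihood lies within
    ``selection_rel_tol * |best|`` of the best consistent run (train
    log-likelihood is used when no test set was scored).
    """
    if not runs:
        raise ValueError("no runs to report")
    rows = []
    for r in runs:
        score = r.test_loglik if r.test_loglik is not None else r.final_loglik
        rows.append({
            "lambda": r.lam,
            "train_loglik": r.final_loglik,
            "test_loglik": r.test_loglik,
            "n_effective": len(r.effective_paths()),
            "consistent": r.consistent,
            "_score": score,
        })
    table = pd.DataFrame(rows).sort_values("lambda").reset_index(drop=True)
    consistent_scores = table.loc[table["consistent"], "_score"]
    if len(consistent_scores):
        best = consistent_scores.max()
        tol = selection_rel_tol * abs(best)
        table["candidate"] = table["consistent"] & (table["_score"] >= best - tol)
    else:
        table["candidate"] = False
    return table.drop(columns="_score")
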