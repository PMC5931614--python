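"""Reading and writing time-course datasets, models and run outputs.

All artifacts are plain text: one CSV per cell (``time`` column plus one
column per observable), a JSON manifest listing the cell files with their
train/test split, JSON model files and a YAML run configuration.  Round
trips preserve full floating-point precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .networks import GeneNetwork
from .statespace import TimeCourseDataset

__all__ = ["ManifestError", "write_dataset", "read_timecourse_manifest",
           "RunConfig", "save_run"]


class ManifestError(ValueError):
    """Malformed or inconsistent dataset manifest."""


def write_dataset(path, train: TimeCourseDataset,
                  test: TimeCourseDataset | None = None,
                  manifest_name: str = "manifest.json") -> Path:
    """Write per-cell CSVs and a manifest; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds, split in ((train, "train"), (test, "test")):
        if ds is None:
            continue
        for a, cid in enumerate(ds.cell_ids):
            fname = f"{cid}.csv"
            df = pd.DataFrame(ds.Y[a], columns=ds.columns)
            df.insert(0, "time", ds.times)
            df.to_csv(path / fname, index=False)  # default repr round-trips
            entries.append({"id": cid, "file": fname, "split": split})
    manifest = {"columns": list(train.columns), "cells": entries}
    mpath = path / manifest_name
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return mpath


def read_timecourse_manifest(path, split: str | None = None) -> TimeCourseDataset:
    """Load and validate the dataset a manifest describes.

    ``split`` restricts to "train" or "test" cells; ``None`` loads all.
    Every cell must share the manifest's column set and one common,
    strictly increasing time grid.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            manifest = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{path}: malformed manifest: {exc}") from exc
    columns = manifest.get("columns")
    cells = [c for c in manifest.get("cells", [])
             if split is None or c.get("split") == split]
    if not cells:
        raise ManifestError(f"{path}: no cells for split={split!r}")
    times_ref = None
    Ys, ids = [], []
    for entry in cells:
        fpath = path.parent / entry["file"]
        try:
            df = pd.read_csv(fpath, float_precision="round_trip")
        except Exception as exc:
            raise ManifestError(f"{fpath}: cannot read cell file: {exc}") from exc
        if "time" not in df.columns:
            raise ManifestError(f"{fpath}: missing 'time' column")
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ManifestError(f"{fpath}: missing observable columns {missing}")
        times = df["time"].to_numpy(dtype=float)
        if times_ref is None:
            times_ref = times
        elif len(times) != len(times_ref) or not np.allclose(times, times_ref):
            raise ManifestError(
                f"{fpath}: time grid differs from the common grid")
        Ys.append(df[columns].to_numpy(dtype=float))
        ids.append(entry.get("id", Path(entry["file"]).stem))
    return TimeCourseDataset(times=times_ref, Y=np.stack(Ys), cell_ids=ids,
                             columns=list(columns))


@dataclass
class RunConfig:
    """Fully resolved settings of one inference run (persisted alongside its
    outputs so that config + seed + inputs reproduce the run exactly)."""

    seed: int = 0
    particles: int = 500
    n_smooth: int | None = None
    iterations: int = 100
    maxfun: int = 100
    lambda_grid: list = field(default_factory=lambda: [0.1, 0.3, 1.0, 3.0,
                                                       10.0, 15.0, 30.0])
    n_range: tuple = (1.0, 8.0)
    gamma_min_frac: float = 0.01
    sigma_max_frac: float = 1.0
    eta_max_frac: float = 1.0
    nsub: int = 4
    hard_zero: float = 1e-6
    effective_threshold: float = 1e-3
    transform: str = "log"
    model_file: str | None = None
    data_manifest: str | None = None
    test_manifest: str | None = None

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["n_range"] = list(self.n_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "n_range" in d:
            d["n_range"] = tuple(d["n_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def em_config(self, transform: str | None = None):
        from .estimation import EMConfig
        return EMConfig(
            particles=self.particles, n_smooth=self.n_smooth,
            iterations=self.iterations, maxfun=self.maxfun,
            transform=transform or self.transform, nsub=self.nsub,
            n_range=self.n_range, gamma_min_frac=self.gamma_min_frac,
            sigma_max_frac=self.sigma_max_frac,
            eta_max_frac=self.eta_max_frac, hard_zero=self.hard_zero,
            effective_threshold=self.effective_threshold)


def save_run(results, out_dir, config: RunConfig | None = None,
             dump_trajectories: bool = False) -> Path:
    """Persist a fitted run: histories, fitted model, config, trajectories."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"iteration": np.arange(1, len(results.loglik_history) + 1),
                  "loglik": results.loglik_history}).to_csv(
        out / "loglik.csv", index=False)
    results.theta_history.to_csv(out / "theta_history.csv")
    results.network.to_json(out / "fitted_model.json")
    noise = {
        "sigma": results.sigma.tolist(), "eta": results.eta.tolist(),
        "gamma": results.gamma.tolist(), "mu": results.mu.tolist(),
        "final_loglik": results.final_loglik,
        "seed": results.seed,
    }
    if getattr(results, "lam", None) is not None:
        noise["lambda"] = getattr(results, "lam", None)
    with open(out / "fit_info.json", "w") as fh:
        json.dump(noise, fh, indent=2)
    if config is not None:
        config.to_yaml(out / "config.yaml")
    if dump_trajectories:
        rows = []
        for a, ens in enumerate(results.ensembles):
            P, T, k = ens.trajectories.shape
            for p in range(P):
                for t in range(T):
                    rows.append([a, p, ens.times[t], ens.weights[p],
                                 *ens.trajectories[p, t]])
        cols = ["cell", "particle", "time", "weight"] + \
            [f"x_{g}" for g in results.network.genes]
        pd.DataFrame(rows, columns=cols).to_csv(
            out / "smoothed_trajectories.csv", index=False)
    return out
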