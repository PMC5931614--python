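"""Hill-function gene regulatory networks.

A :class:`GeneNetwork` is a collection of genes coupled by regulatory paths,
each path a saturating Hill term: an activator contributes
``a * (K x)^n / (1 + (K x)^n)`` to the production of its target, a repressor
multiplies the target's production by ``1 / (1 + (K x)^n)``.  The association
constant ``K`` doubles as a structural switch: ``K = 0`` silences a path
exactly (activator activity 0, repressor factor 1), which is what makes
L1-penalised estimation of the ``K``'s a topology-inference device.

The fully connected "redundant" network over ``G`` genes contains every
candidate path — ``2 G^2`` of them (each ordered gene pair in both signs,
self-loops included).  Degradation is first order, and each gene may carry a
constitutive basal production rate that is multiplied by its repressor
factors; a gene with no active activator path then behaves like a classic
repressilator node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ACTIVATOR",
    "REPRESSOR",
    "RegulatoryPath",
    "GeneNetwork",
    "activator_activity",
    "repressor_activity",
    "production_rate",
    "build_redundant_model",
    "canonical_path_id",
]

ACTIVATOR = "activator"
REPRESSOR = "repressor"


def activator_activity(K, n, x):
    """Fractional activator occupancy ``(Kx)^n / (1 + (Kx)^n)``.

    Exactly 0 when ``K == 0`` (absent path).  ``x`` is clamped at zero so the
    function stays defined for the small negative state excursions a Gaussian
    state-noise model permits.
    """
    K = np.asarray(K, dtype=float)
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    u = _hill_pow(K, n, x)
    return u / (1.0 + u)


def repressor_activity(K, n, x):
    """Fractional repressor transmission ``1 / (1 + (Kx)^n)``.

    Exactly 1 when ``K == 0`` (absent path).
    """
    K = np.asarray(K, dtype=float)
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    u = _hill_pow(K, n, x)
    return 1.0 / (1.0 + u)


def _hill_pow(K, n, x):
    # (K x)^n with the K*x == 0 branch handled exactly (0^n == 0 for n > 0).
    kx = K * x
    with np.errstate(divide="ignore"):
        u = np.where(kx > 0.0, np.power(np.where(kx > 0.0, kx, 1.0), n), 0.0)
    return u


@dataclass
class RegulatoryPath:
    """One directed regulatory interaction.

    ``a`` (maximal production amplitude) exists for activators only; it is
    ``None`` on repressor paths.  ``path_id`` follows the canonical redundant
    enumeration (targets-major, then sources, activator before repressor,
    1-based) so sparse sub-networks keep the ids of the redundant model they
    embed into.
    """

    source: int
    target: int
    sign: str
    K: float = 0.0
    n: float = 2.0
    a: float | None = None
    path_id: int = 0

    def __post_init__(self):
        if self.sign not in (ACTIVATOR, REPRESSOR):
            raise ValueError(f"sign must be activator/repressor, got {self.sign!r}")
        if self.sign == ACTIVATOR and self.a is None:
            self.a = 1.0
        if self.sign == REPRESSOR:
            self.a = None
        if self.K < 0:
            raise ValueError("association constant K must be >= 0")

    @property
    def is_activator(self) -> bool:
        return self.sign == ACTIVATOR


def canonical_path_id(n_genes: int, target: int, source: int, sign: str) -> int:
    """1-based path index: targets-major, then sources, activator first."""
    return 1 + target * 2 * n_genes + source * 2 + (0 if sign == ACTIVATOR else 1)


def production_rate(paths: Sequence[RegulatoryPath], x, basal: float = 0.0) -> float:
    """Production rate of one gene from the paths targeting it.

    ``(basal + sum_i a_i cA_i) * prod_j cR_j`` — the independent-regulator
    product form; the optional basal term keeps repressor-only genes alive.
    """
    x = np.asarray(x, dtype=float)
    targets = {p.target for p in paths}
    if len(targets) > 1:
        raise ValueError(f"paths target multiple genes: {sorted(targets)}")
    act = basal
    rep = 1.0
    for p in paths:
        if p.is_activator:
            act += p.a * activator_activity(p.K, p.n, x[p.source])
        else:
            rep *= repressor_activity(p.K, p.n, x[p.source])
    return float(act * rep)


@dataclass
class GeneNetwork:
    """Gene network model: nodes, Hill paths, degradation, basal production.

    ``free_basal`` lists the gene indices whose basal rate is an estimated
    kinetic parameter; basal entries of other genes are fixed constants
    (usually 0).
    """

    genes: list[str]
    paths: list[RegulatoryPath]
    degradation: np.ndarray
    basal: np.ndarray = None
    free_basal: tuple = ()

    def __post_init__(self):
        G = len(self.genes)
        self.degradation = np.asarray(self.degradation, dtype=float)
        if self.basal is None:
            self.basal = np.zeros(G)
        self.basal = np.asarray(self.basal, dtype=float)
        self.free_basal = tuple(self.free_basal)
        if self.degradation.shape != (G,) or self.basal.shape != (G,):
            raise ValueError("degradation/basal must have one entry per gene")
        if np.any(self.degradation < 0):
            raise ValueError("degradation rates must be nonnegative")
        for p in self.paths:
            if not (0 <= p.source < G and 0 <= p.target < G):
                raise ValueError(f"path {p} references unknown gene index")
            if p.path_id == 0:
                p.path_id = canonical_path_id(G, p.target, p.source, p.sign)

    # ------------------------------------------------------------------ size
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    # ------------------------------------------------ flat parameter mapping
    # theta_sys layout: per path (listed order): K, n, (a if activator);
    # then basal for genes in free_basal; then degradation for every gene.
    def theta_names(self) -> list[str]:
        names = []
        for p in self.paths:
            names.append(f"K_{p.path_id}")
            names.append(f"n_{p.path_id}")
            if p.is_activator:
                names.append(f"a_{p.path_id}")
        for g in self.free_basal:
            names.append(f"b_{self.genes[g]}")
        for g in range(self.n_genes):
            names.append(f"d_{self.genes[g]}")
        return names

    @property
    def n_theta(self) -> int:
        na = sum(1 for p in self.paths if p.is_activator)
        return 2 * self.n_paths + na + len(self.free_basal) + self.n_genes

    def theta(self) -> np.ndarray:
        out = []
        for p in self.paths:
            out.append(p.K)
            out.append(p.n)
            if p.is_activator:
                out.append(p.a)
        for g in self.free_basal:
            out.append(self.basal[g])
        out.extend(self.degradation)
        return np.array(out, dtype=float)

    def set_theta(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_theta,):
            raise ValueError(f"theta must have length {self.n_theta}")
        i = 0
        for p in self.paths:
            p.K = float(theta[i]); i += 1
            p.n = float(theta[i]); i += 1
            if p.is_activator:
                p.a = float(theta[i]); i += 1
        for g in self.free_basal:
            self.basal[g] = theta[i]; i += 1
        self.degradation = theta[i:].copy()

    def with_theta(self, theta: np.ndarray) -> "GeneNetwork":
        net = self.copy()
        net.set_theta(theta)
        return net

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(
            genes=list(self.genes),
            paths=[replace(p) for p in self.paths],
            degradation=self.degradation.copy(),
            basal=self.basal.copy(),
            free_basal=self.free_basal,
        )

    def k_indices(self) -> np.ndarray:
        """Positions of the association constants in the flat theta vector."""
        idx, i = [], 0
        for p in self.paths:
            idx.append(i)
            i += 3 if p.is_activator else 2
        return np.array(idx, dtype=int)

    def theta_bounds(self, n_range=(1.0, 8.0)) -> list[tuple]:
        """Box bounds for the flat theta vector (all parameters nonnegative;
        Hill coefficients confined to ``n_range`` to avoid step-function
        degeneracy)."""
        bounds = []
        for p in self.paths:
            bounds.append((0.0, np.inf))            # K
            bounds.append((n_range[0], n_range[1]))  # n
            if p.is_activator:
                bounds.append((0.0, np.inf))        # a
        for _ in self.free_basal:
            bounds.append((0.0, np.inf))
        for _ in range(self.n_genes):
            bounds.append((0.0, np.inf))
        return bounds

    # -------------------------------------------------------- kernel arrays
    def path_arrays(self):
        """Natural parameter arrays consumed by the numba propagation kernels."""
        NP = self.n_paths
        src = np.array([p.source for p in self.paths], dtype=np.int64)
        tgt = np.array([p.target for p in self.paths], dtype=np.int64)
        act = np.array([p.is_activator for p in self.paths], dtype=np.bool_)
        K = np.array([p.K for p in self.paths], dtype=float)
        n = np.array([p.n for p in self.paths], dtype=float)
        amp = np.array([p.a if p.is_activator else 0.0 for p in self.paths], dtype=float)
        return src, tgt, act, K, n, amp, self.basal.astype(float), self.degradation.astype(float)

    # ---------------------------------------------------------------- model
    def rhs(self, x: np.ndarray) -> np.ndarray:
        """ODE right-hand side dx/dt = production(x) - degradation * x."""
        x = np.asarray(x, dtype=float)
        G = self.n_genes
        out = np.empty(G)
        by_target: list[list[RegulatoryPath]] = [[] for _ in range(G)]
        for p in self.paths:
            by_target[p.target].append(p)
        for g in range(G):
            out[g] = production_rate(by_target[g], x, basal=self.basal[g]) \
                - self.degradation[g] * x[g]
        return out

    def effective_paths(self, threshold: float = 1e-3) -> list[int]:
        """path_ids of paths whose association constant exceeds ``threshold``."""
        return [p.path_id for p in self.paths if p.K > threshold]

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "paths": [
                {
                    "path_id": p.path_id,
                    "source": self.genes[p.source],
                    "target": self.genes[p.target],
                    "sign": p.sign,
                    "K": p.K,
                    "n": p.n,
                    **({"a": p.a} if p.is_activator else {}),
                }
                for p in self.paths
            ],
            "degradation": self.degradation.tolist(),
            "basal": self.basal.tolist(),
            "free_basal": list(self.free_basal),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneNetwork":
        genes = list(d["genes"])
        gi = {g: i for i, g in enumerate(genes)}
        paths = [
            RegulatoryPath(
                source=gi[p["source"]],
                target=gi[p["target"]],
                sign=p["sign"],
                K=float(p["K"]),
                n=float(p["n"]),
                a=float(p["a"]) if p.get("a") is not None else None,
                path_id=int(p.get("path_id", 0)),
            )
            for p in d["paths"]
        ]
        return cls(
            genes=genes,
            paths=paths,
            degradation=np.asarray(d["degradation"], dtype=float),
            basal=np.asarray(d.get("basal", np.zeros(len(genes))), dtype=float),
            free_basal=tuple(d.get("free_basal", ())),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_redundant_model(
    genes: int | Sequence[str],
    K: float = 0.5,
    n: float = 2.0,
    a: float = 1.0,
    basal: float = 0.5,
    degradation: float = 0.5,
) -> GeneNetwork:
    """Fully connected candidate network over ``G`` genes: ``2 G^2`` paths.

    Every ordered (target, source) gene pair gets one activator and one
    repressor path (self-loops included), enumerated targets-major with the
    activator first — path_id 1..2G^2.  Every gene carries a free basal rate
    so that repressor-only solutions remain reachable after pruning.  The
    scalar arguments are uniform initial parameter values.
    """
    if isinstance(genes, int):
        if genes < 1:
            raise ValueError("need at least one gene")
        gene_names = [f"G{i+1}" for i in range(genes)] if genes > 3 else \
            ["X", "Y", "Z"][:genes]
    else:
        gene_names = list(genes)
    G = len(gene_names)
    paths = []
    for tgt in range(G):
        for src in range(G):
            for sign in (ACTIVATOR, REPRESSOR):
                paths.append(
                    RegulatoryPath(
                        source=src, target=tgt, sign=sign, K=K, n=n,
                        a=a if sign == ACTIVATOR else None,
                        path_id=canonical_path_id(G, tgt, src, sign),
                    )
                )
    return GeneNetwork(
        genes=gene_names,
        paths=paths,
        degradation=np.full(G, float(degradation)),
        basal=np.full(G, float(basal)),
        free_basal=tuple(range(G)),
    )
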