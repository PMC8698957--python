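"""Synthetic expression data from known sparse DAGs.

The generator draws samples from a linear-Gaussian structural equation
model: each gene is a weighted sum of its parents plus independent
Gaussian noise, evaluated in topological order.  Because the Fisher-z
partial-correlation test is exactly calibrated for multivariate Gaussian
data, this is the regime in which skeleton estimation and the expansion
engine can be validated under their own assumptions, with the generating
DAG as ground truth.

Edge weight magnitudes are drawn in [0.5, 1.5] (random sign) by default:
a floor well above zero keeps the model comfortably faithful, avoiding
near-cancellations that would make true edges statistically invisible.

A small registry of named fixtures with hard-coded seeds
(``tiny-collider``, ``chain-5``, ``dag-20``, ``dag-50``) provides the
standard instances used throughout the test-suite and documentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .model import ExpansionList, ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "RecoveryMetrics",
    "NoNeighborsError",
    "random_dag",
    "sample_expression",
    "analytic_covariance",
    "recovery_metrics",
    "get_fixture",
    "FIXTURES",
]


class NoNeighborsError(ValueError):
    """Seed gene has no neighbors in the truth skeleton; AUROC is undefined."""


@dataclass
class SyntheticTruth:
    """Ground-truth DAG with edge weights and per-gene noise scales.

    ``weights[i, j]`` is the coefficient of gene i in the structural
    equation of gene j; nonzero entries define the edge set.  The matrix
    must be permutable to strict upper-triangular form (acyclic).
    """

    gene_ids: list[str]
    weights: np.ndarray  # (n, n); weights[i, j] != 0 iff edge i -> j
    noise_sd: np.ndarray  # (n,)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be n x n")
        if self.noise_sd.shape != (n,):
            raise ValueError("noise_sd must have length n")
        self._topo_order = self._topological_order()

    def _topological_order(self) -> list[int]:
        n = len(self.gene_ids)
        adj = self.weights != 0
        indeg = adj.sum(axis=0)
        order, ready = [], sorted(np.flatnonzero(indeg == 0).tolist())
        indeg = indeg.copy()
        while ready:
            v = ready.pop(0)
            order.append(v)
            for w in np.flatnonzero(adj[v]):
                indeg[w] -= 1
                if indeg[w] == 0:
                    ready.append(int(w))
        if len(order) != n:
            raise ValueError("weight matrix contains a cycle")
        return order

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i, j in zip(*np.nonzero(self.weights)):
            out.append((self.gene_ids[i], self.gene_ids[j], float(self.weights[i, j])))
        return sorted(out)

    def skeleton_neighbors(self, gene: str) -> set[str]:
        """Parents and children of ``gene`` — its true-skeleton neighborhood."""
        i = self.gene_ids.index(gene)
        nbrs = set(np.nonzero(self.weights[i])[0]) | set(np.nonzero(self.weights[:, i])[0])
        return {self.gene_ids[j] for j in nbrs}

    def skeleton_edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.edges()}

    def to_json(self, path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "edges": [[a, b, w] for a, b, w in self.edges()],
            "noise_sd": self.noise_sd.tolist(),
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        genes = payload["gene_ids"]
        idx = {g: i for i, g in enumerate(genes)}
        W = np.zeros((len(genes), len(genes)))
        for a, b, w in payload["edges"]:
            W[idx[a], idx[b]] = w
        return cls(
            gene_ids=genes,
            weights=W,
            noise_sd=np.asarray(payload["noise_sd"], dtype=float),
            rng_seed=payload["rng_seed"],
        )


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def random_dag(
    n: int,
    edge_prob: float,
    rng_seed: int = 0,
    weighted: bool = True,
    weight_range: tuple[float, float] = (0.5, 1.5),
    noise_sd: float = 1.0,
) -> SyntheticTruth:
    """Erdos-Renyi DAG: a random topological order, then each forward pair
    is an edge independently with probability ``edge_prob``.

    With ``weighted`` (default), coefficients are drawn uniformly in
    ``weight_range`` with random sign; otherwise edges get weight 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    W = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < edge_prob:
                i, j = order[a], order[b]
                if weighted:
                    w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
                else:
                    w = 1.0
                W[i, j] = w
    return SyntheticTruth(
        gene_ids=_gene_names(n),
        weights=W,
        noise_sd=np.full(n, float(noise_sd)),
        rng_seed=rng_seed,
    )


def sample_expression(
    truth: SyntheticTruth, n_samples: int, rng_seed: Optional[int] = None
) -> ExpressionMatrix:
    """Draw samples from the linear-Gaussian SEM defined by ``truth``.

    X_j = sum_{i in pa(j)} w_ij X_i + eps_j with eps_j ~ N(0, noise_sd_j^2),
    evaluated in topological order.  Rows are genes, columns samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    seed = truth.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    n = truth.n_genes
    X = np.empty((n, n_samples))
    noise = rng.normal(size=(n, n_samples)) * truth.noise_sd[:, None]
    for j in truth._topo_order:
        parents = np.flatnonzero(truth.weights[:, j])
        X[j] = noise[j]
        if len(parents):
            X[j] += truth.weights[parents, j] @ X[parents]
    samples = [f"S{k:04d}" for k in range(1, n_samples + 1)]
    return ExpressionMatrix(list(truth.gene_ids), samples, X)


def analytic_covariance(truth: SyntheticTruth) -> np.ndarray:
    """Population covariance (I - W)^{-T} D (I - W)^{-1} of the SEM."""
    n = truth.n_genes
    A = np.linalg.inv(np.eye(n) - truth.weights)  # maps noise to X: X = A^T eps
    D = np.diag(truth.noise_sd**2)
    return A.T @ D @ A


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well an expansion list recovers the seed's true neighborhood."""

    auroc: float
    aupr: float
    neighbor_mean_frel: float
    non_neighbor_mean_frel: float
    n_neighbors: int
    n_non_neighbors: int


def recovery_metrics(lst: ExpansionList, truth: SyntheticTruth, seed_gene: str) -> RecoveryMetrics:
    """Score F_rel as a classifier of true skeleton neighbors of the seed.

    Positives are the seed's parents and children in the truth DAG;
    every other gene in the list is a negative.  AUROC and AUPR are
    computed by rank statistics on F_rel.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    positives = truth.skeleton_neighbors(seed_gene)
    if not positives:
        raise NoNeighborsError(f"seed {seed_gene!r} has no neighbors in the truth DAG")
    y, score = [], []
    for r in lst.records:
        y.append(1 if r.gene in positives else 0)
        score.append(r.f_rel)
    y_arr = np.asarray(y)
    if y_arr.all():
        raise ValueError("no negatives in the expansion list; AUROC undefined")
    return RecoveryMetrics(
        auroc=float(roc_auc_score(y_arr, score)),
        aupr=float(average_precision_score(y_arr, score)),
        neighbor_mean_frel=float(np.mean([s for s, t in zip(score, y) if t == 1])),
        non_neighbor_mean_frel=float(np.mean([s for s, t in zip(score, y) if t == 0])),
        n_neighbors=int(y_arr.sum()),
        n_non_neighbors=int(len(y_arr) - y_arr.sum()),
    )


def _tiny_collider() -> SyntheticTruth:
    genes = ["X", "Y", "Z"]
    W = np.zeros((3, 3))
    W[0, 2] = 1.0  # X -> Z
    W[1, 2] = 1.0  # Y -> Z
    return SyntheticTruth(gene_ids=genes, weights=W, noise_sd=np.ones(3), rng_seed=101)


def _chain_5() -> SyntheticTruth:
    genes = [f"X{i}" for i in range(1, 6)]
    W = np.zeros((5, 5))
    for i in range(4):
        W[i, i + 1] = 0.8
    return SyntheticTruth(gene_ids=genes, weights=W, noise_sd=np.ones(5), rng_seed=202)


FIXTURES = {
    "tiny-collider": _tiny_collider,
    "chain-5": _chain_5,
    "dag-20": lambda: random_dag(20, edge_prob=0.15, rng_seed=2020),
    "dag-50": lambda: random_dag(50, edge_prob=0.08, rng_seed=5050),
}


def get_fixture(name: str) -> SyntheticTruth:
    """Named standard instance with a hard-coded seed."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
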