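"""Undirected skeleton estimation via partial-correlation CI tests.

This is the single computation executed once per tile per iteration by the
expansion engine: starting from the complete graph over the tile's genes,
edges are removed whenever the pair is found conditionally independent
given some subset of a neighbourhood, using the Fisher-z test on partial
correlations at a fixed significance level.

The variant implemented is PC-stable: within each conditioning-set size
the neighbourhoods consulted are a snapshot taken before any removal at
that level, which makes the result independent of variable ordering.
Only the skeleton is produced; edges are never oriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import DegenerateInputError

__all__ = [
    "CITestParams",
    "Skeleton",
    "TestUnavailable",
    "partial_correlation",
    "fisher_z_test",
    "estimate_skeleton",
    "estimate_skeleton_from_corr",
    "pc_stable_skeleton",
]


class TestUnavailable(Exception):
    """Fisher-z test not applicable (sample size too small for |S|).

    Callers must treat the edge as retained: absence of evidence for
    independence never removes an edge.
    """

    __test__ = False  # not a test class, despite the name


@dataclass(frozen=True)
class CITestParams:
    """Parameters of the partial-correlation conditional-independence test."""

    alpha: float = 0.05
    n_samples: int = 0
    max_order: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")


@dataclass
class Skeleton:
    """Estimated undirected skeleton with separating sets for removed edges."""

    variables: list[str]
    adjacency: dict[str, set[str]]
    sepsets: dict[frozenset, tuple] = field(default_factory=dict)

    def has_edge(self, a: str, b: str) -> bool:
        return b in self.adjacency.get(a, set())

    def edges(self) -> list[tuple[str, str]]:
        out = set()
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                out.add(tuple(sorted((a, b))))
        return sorted(out)

    def neighbors(self, var: str) -> set[str]:
        return set(self.adjacency[var])

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in self.edges():
                fh.write(f"{a}\t{b}\n")


def _partial_corr_inversion(corr: np.ndarray, i: int, j: int, S: Sequence[int]) -> float:
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular correlation submatrix for ({i},{j}|{tuple(S)})") from exc
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise DegenerateInputError(f"non-positive precision diagonal for ({i},{j}|{tuple(S)})")
    return float(-prec[0, 1] / np.sqrt(denom))


def _partial_corr_recursive(corr: np.ndarray, i: int, j: int, S: tuple) -> float:
    if not S:
        return float(corr[i, j])
    k, rest = S[0], S[1:]
    r_ij = _partial_corr_recursive(corr, i, j, rest)
    r_ik = _partial_corr_recursive(corr, i, k, rest)
    r_jk = _partial_corr_recursive(corr, j, k, rest)
    denom = (1.0 - r_ik**2) * (1.0 - r_jk**2)
    if denom <= 0:
        raise DegenerateInputError(f"degenerate recursion for ({i},{j}|{S})")
    return float((r_ij - r_ik * r_jk) / np.sqrt(denom))


def partial_correlation(
    corr: np.ndarray, i: int, j: int, S: Sequence[int] = (), method: str = "inversion"
) -> float:
    """Partial correlation rho(i, j | S) from a correlation matrix.

    ``method`` selects the submatrix-inversion route (default) or the
    classical first-variable recursion; the two agree to numerical
    precision and serve as mutual checks.
    """
    if i == j:
        raise ValueError("i and j must differ")
    if i in S or j in S:
        raise ValueError("conditioning set must not contain i or j")
    if len(S) == 0:
        return float(corr[i, j])
    if method == "inversion":
        return _partial_corr_inversion(corr, i, j, tuple(S))
    if method == "recursive":
        return _partial_corr_recursive(corr, i, j, tuple(S))
    raise ValueError(f"unknown method {method!r}")


def fisher_z_test(rho: float, params: CITestParams, cond_size: int) -> bool:
    """Fisher-z independence test; returns True when independence is accepted.

    z = sqrt(n - |S| - 3) * atanh(rho); independence is declared when
    |z| <= Phi^{-1}(1 - alpha/2).  rho is clamped away from +-1 before the
    transform.  If n - |S| - 3 <= 0 the test is unavailable and
    :class:`TestUnavailable` is raised (caller retains the edge).
    """
    dof = params.n_samples - cond_size - 3
    if dof <= 0:
        raise TestUnavailable(f"need n - |S| - 3 > 0 (n={params.n_samples}, |S|={cond_size})")
    rho = float(np.clip(rho, -(1 - 1e-12), 1 - 1e-12))
    z = np.sqrt(dof) * np.arctanh(rho)
    threshold = stats.norm.ppf(1 - params.alpha / 2)
    return bool(abs(z) <= threshold)


def pc_stable_skeleton(
    variables: Sequence[str],
    ci_test: Callable[[int, int, tuple], bool],
    max_order: Optional[int] = None,
) -> Skeleton:
    """Order-independent skeleton search over an arbitrary CI test.

    ``ci_test(i, j, S)`` returns True when variables i and j (integer
    positions) are independent given the positions in S.  Starting from
    the complete graph, level ell removes (i, j) as soon as some subset S
    of size ell of adj(i)\\{j} or adj(j)\\{i} — neighbourhoods snapshotted
    at the start of the level — tests independent.  Subsets are enumerated
    in lexicographic order and the first separating set is recorded.
    """
    names = list(variables)
    n = len(names)
    if n < 2:
        raise ValueError("need at least two variables")
    adj: dict[int, set[int]] = {i: set(range(n)) - {i} for i in range(n)}
    sepsets: dict[frozenset, tuple] = {}
    level = 0
    while True:
        if max_order is not None and level > max_order:
            break
        snapshot = {i: frozenset(adj[i]) for i in range(n)}
        if all(len(snapshot[i]) - 1 < level for i in range(n)):
            break
        for i in range(n):
            for j in sorted(adj[i]):
                if j < i or j not in adj[i]:
                    continue
                sep = _find_sepset(i, j, snapshot, ci_test, level)
                if sep is not None:
                    adj[i].discard(j)
                    adj[j].discard(i)
                    sepsets[frozenset((i, j))] = sep
        level += 1
    adjacency = {names[i]: {names[j] for j in nbrs} for i, nbrs in adj.items()}
    named_sepsets = {
        frozenset((names[i], names[j])): tuple(names[k] for k in sep)
        for pair, sep in sepsets.items()
        for i, j in [sorted(pair)]
    }
    return Skeleton(variables=names, adjacency=adjacency, sepsets=named_sepsets)


def _find_sepset(i, j, snapshot, ci_test, level):
    tried: set[tuple] = set()
    for anchor, other in ((i, j), (j, i)):
        candidates = sorted(snapshot[anchor] - {other})
        if len(candidates) < level:
            continue
        for S in combinations(candidates, level):
            if S in tried:
                continue
            tried.add(S)
            try:
                if ci_test(i, j, S):
                    return S
            except TestUnavailable:
                continue
    return None


def estimate_skeleton_from_corr(
    corr: np.ndarray, variables: Sequence[str], params: CITestParams
) -> Skeleton:
    """Skeleton from a precomputed correlation matrix (Fisher-z CI test)."""
    dof0 = params.n_samples - 3
    if dof0 <= 0:
        raise ValueError("n_samples too small for any Fisher-z test")
    threshold = stats.norm.ppf(1 - params.alpha / 2)

    def ci_test(i: int, j: int, S: tuple) -> bool:
        dof = params.n_samples - len(S) - 3
        if dof <= 0:
            raise TestUnavailable("conditioning set too large for sample size")
        rho = partial_correlation(corr, i, j, S)
        rho = float(np.clip(rho, -(1 - 1e-12), 1 - 1e-12))
        return abs(np.sqrt(dof) * np.arctanh(rho)) <= threshold

    return pc_stable_skeleton(variables, ci_test, max_order=params.max_order)


def estimate_skeleton(data, params: CITestParams) -> Skeleton:
    """Skeleton of the causal graph underlying an expression matrix subset.

    ``data`` is an :class:`~genexpand.model.ExpressionMatrix` restricted to
    the variables of interest.  Zero-variance variables are degenerate for
    correlation-based testing and raise an error naming the variable.
    """
    sd = data.values.std(axis=1)
    flat = [g for g, s in zip(data.gene_ids, sd) if s == 0.0]
    if flat:
        raise DegenerateInputError(f"zero-variance variable(s): {flat}")
    if data.n_genes < 2:
        raise ValueError("need at least two variables")
    corr = np.corrcoef(data.values)
    return estimate_skeleton_from_corr(corr, data.gene_ids, params)
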