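"""Pairwise factor co-occurrence over deduplicated clock systems.

Genome databases over-represent some genera (e.g. *Prochlorococcus*,
*Synechococcus*), so strains with identical factor combinations are collapsed
to unique "clock systems" before testing. Each factor pair is then tested for
joint presence with a right-sided (upper-tail) Fisher's exact test under the
null of pairwise-independent presence across systems, followed by
Benjamini-Hochberg correction at FDR 0.01. Significant pairs form a
co-occurrence network; factors are ordered for display by agglomerative
clustering of the adjusted p-value matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import exp, lgamma, log
from collections.abc import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from clockmine.datatypes import ClockSystem
from clockmine.factors import ANALYSIS_FACTORS

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Boolean systems x factors matrix with unique rows."""

    data: pd.DataFrame  # index: system label, columns: factors, dtype bool

    @property
    def factors(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_systems(self) -> int:
        return len(self.data)


@dataclass
class CooccurrenceResult:
    """Fisher-test outcome for one factor pair.

    The 2x2 contingency counts are ``a`` (both present), ``b`` (first only),
    ``c`` (second only) and ``d`` (neither).
    """

    factor_i: str
    factor_j: str
    a: int
    b: int
    c: int
    d: int
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False


def dedup_systems(
    systems: Sequence[ClockSystem],
    factors: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Collapse clock systems to unique factor combinations.

    Rows are the distinct presence patterns over ``factors`` (default: the
    21-factor analysis panel), sorted lexicographically for a canonical,
    permutation-invariant order. Idempotent by construction.
    """
    if factors is None:
        factors = list(ANALYSIS_FACTORS)
    if not systems:
        logger.warning("dedup_systems: empty input")
        return PresenceMatrix(pd.DataFrame(columns=list(factors), dtype=bool))
    patterns = {tuple(f in s.factors for f in factors) for s in systems}
    rows = sorted(patterns, reverse=True)
    data = pd.DataFrame(
        rows, columns=list(factors), index=[f"system_{i+1}" for i in range(len(rows))]
    ).astype(bool)
    return PresenceMatrix(data)


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_right(a: int, b: int, c: int, d: int) -> float:
    """Right-sided Fisher's exact test on a 2x2 table.

    With margins fixed, the count in cell ``a`` follows a hypergeometric
    distribution; the returned p-value is the upper tail ``P(X >= a)``,
    computed with log-factorials for numerical exactness.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0:
        return 1.0
    a_max = min(row1, col1)
    denom = _log_binom(n, col1)
    tail = 0.0
    for x in range(a, a_max + 1):
        log_p = _log_binom(row1, x) + _log_binom(n - row1, col1 - x) - denom
        tail += exp(log_p)
    return min(tail, 1.0)


def bh_adjust(p_values: Sequence[float], fdr: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(p_adj, significant)`` where ``p_adj[i] = min_{j>=rank(i)}
    (m/j) * p_(j)`` with monotonicity enforced, and ``significant`` flags
    ``p_adj <= fdr``. Invariant under permutation of the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adjusted
    return p_adj, p_adj <= fdr


def pairwise_cooccurrence(
    matrix: PresenceMatrix,
    fdr: float = 0.01,
    exclude_constant: bool = True,
) -> list[CooccurrenceResult]:
    """Fisher-test every factor pair for joint presence, with BH correction.

    Factors present in every system (or in none) carry no co-occurrence
    information — their upper-tail test is degenerate with p = 1 — and are
    excluded from testing by default (this always removes the KaiC column,
    whose presence is guaranteed by the strain-retention filter).
    """
    data = matrix.data
    tested = list(data.columns)
    if exclude_constant:
        tested = [f for f in tested if 0 < int(data[f].sum()) < len(data)]
    results: list[CooccurrenceResult] = []
    for fi, fj in combinations(tested, 2):
        x = data[fi].to_numpy()
        y = data[fj].to_numpy()
        a = int(np.sum(x & y))
        b = int(np.sum(x & ~y))
        c = int(np.sum(~x & y))
        d = int(np.sum(~x & ~y))
        results.append(
            CooccurrenceResult(fi, fj, a, b, c, d, p_raw=fisher_right(a, b, c, d))
        )
    if results:
        p_adj, sig = bh_adjust([r.p_raw for r in results], fdr=fdr)
        for r, pa, s in zip(results, p_adj, sig):
            r.p_adj = float(pa)
            r.significant = bool(s)
    return results


def results_table(results: Sequence[CooccurrenceResult]) -> pd.DataFrame:
    """Tidy results table (one row per factor pair)."""
    return pd.DataFrame(
        [
            {
                "factor_i": r.factor_i,
                "factor_j": r.factor_j,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def adjusted_p_matrix(results: Sequence[CooccurrenceResult], factors: Sequence[str]) -> pd.DataFrame:
    """Symmetric factor x factor matrix of adjusted p-values (diagonal 0).

    Untested pairs (involving constant columns) are filled with p = 1.
    """
    mat = pd.DataFrame(1.0, index=list(factors), columns=list(factors))
    for r in results:
        mat.loc[r.factor_i, r.factor_j] = r.p_adj
        mat.loc[r.factor_j, r.factor_i] = r.p_adj
    np.fill_diagonal(mat.values, 0.0)
    return mat


def cluster_factors(p_adj_matrix: pd.DataFrame) -> list[str]:
    """Deterministic leaf order from average-linkage clustering.

    Distance between factors is their adjusted p-value (diagonal 0). Input
    factors are first sorted by label so equal-distance configurations break
    ties stably.
    """
    mat = p_adj_matrix.copy()
    if list(mat.index) != list(mat.columns):
        raise ValueError("p-value matrix must be square with matching labels")
    values = mat.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("p-value matrix must be symmetric")
    labels = sorted(mat.index)
    if len(labels) <= 2:
        return list(mat.index)
    mat = mat.loc[labels, labels]
    values = mat.to_numpy(dtype=float).copy()
    np.fill_diagonal(values, 0.0)
    condensed = squareform(values, checks=False)
    tree = linkage(condensed, method="average")
    order = leaves_list(tree)
    return [labels[i] for i in order]


def build_network(
    results: Sequence[CooccurrenceResult],
    alpha: float = 0.01,
    factors: Sequence[str] | None = None,
) -> nx.Graph:
    """Graph of significantly co-occurring factors.

    An edge joins two factors iff their BH-adjusted p-value is at most
    ``alpha``; the edge weight is that p-value. Every node carries its degree
    as an attribute (node size in the usual rendering is proportional to it).
    """
    graph = nx.Graph()
    if factors is not None:
        graph.add_nodes_from(factors)
    for r in results:
        graph.add_node(r.factor_i)
        graph.add_node(r.factor_j)
        if r.p_adj <= alpha:
            graph.add_edge(r.factor_i, r.factor_j, weight=r.p_adj)
    nx.set_node_attributes(graph, dict(graph.degree()), "degree")
    return graph
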