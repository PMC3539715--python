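"""Edge-weight statistics on the interaction network and their nulls.

The central statistic is the average edge weight

    w = (1 / n_E) * sum over edges (n, m) of e_nm

with two weight definitions: the absolute difference in whole-gene
selective constraint, e_Δω = |ω_n − ω_m| (are interacting proteins
under similar constraint?), and the absolute degree difference
Δk = |k_n − k_m| (do proteins interact with partners of similar
degree?).  Each has its matched null: node-weight permutation for ω
(topology fixed, attributes shuffled) and degree-preserving rewiring
for Δk (degrees fixed, wiring shuffled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import (
    GeneOmegaTable,
    InteractionNetwork,
    Pair,
    PermutationResult,
    canonical_pair,
)
from .null_models import rewire_degree_preserving

log = logging.getLogger(__name__)


def degree_difference(pair: Pair, network: InteractionNetwork) -> int:
    """Absolute degree difference Δk = |k1 − k2| of a pair."""
    a, b = pair
    return abs(network.degree(a) - network.degree(b))


def edge_constraint_weight(pair: Pair, omegas: GeneOmegaTable) -> float:
    """Edge weight e_Δω = |ω_n − ω_m| (absolute difference in
    whole-alignment selective constraint)."""
    a, b = pair
    return abs(omegas.omega(a) - omegas.omega(b))


@dataclass(frozen=True)
class WeightedNetworkStat:
    """Average edge weight w of the network plus its permutation null."""

    definition: str  # {omega-difference, degree-difference}
    observed: float
    n_edges: int
    n_skipped: int
    perm: PermutationResult | None = None


def network_weight(
    network: InteractionNetwork, omegas: GeneOmegaTable
) -> WeightedNetworkStat:
    """Mean |Δω| over scorable edges (both ends have ω); edges with a
    missing ω on either end are skipped with a logged count."""
    weights = []
    skipped = 0
    for a, b in network.pairs():
        if a in omegas and b in omegas:
            weights.append(abs(omegas.omega(a) - omegas.omega(b)))
        else:
            skipped += 1
    if not weights:
        raise ValueError("no edge has omega for both genes")
    if skipped:
        log.info("network_weight: %d edges lack omega and were skipped", skipped)
    return WeightedNetworkStat(
        definition="omega-difference",
        observed=float(np.mean(weights)),
        n_edges=len(weights),
        n_skipped=skipped,
    )


def _scorable(
    network: InteractionNetwork, omegas: GeneOmegaTable
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, int]:
    """Scorable subgraph: nodes with ω incident to scorable edges, edge
    index arrays into the node list, node ω vector, skipped-edge count."""
    edges = [
        (a, b) for a, b in network.pairs() if a in omegas and b in omegas
    ]
    skipped = network.n_edges - len(edges)
    if not edges:
        raise ValueError("no edge has omega for both genes")
    nodes = sorted({g for e in edges for g in e})
    idx = {g: i for i, g in enumerate(nodes)}
    ia = np.array([idx[a] for a, _ in edges])
    ib = np.array([idx[b] for _, b in edges])
    w = np.array([omegas.omega(g) for g in nodes])
    return nodes, ia, ib, w, skipped


def constraint_assortativity_test(
    network: InteractionNetwork,
    omegas: GeneOmegaTable,
    n_perm: int = 10_000,
    seed: int = 0,
) -> WeightedNetworkStat:
    """Is the average |Δω| across edges smaller than under random
    reassignment of the node ω values?

    The scorable subgraph (edges with ω at both ends) is fixed before
    permutation so the observed and null statistics share an edge set;
    each replicate permutes the same multiset of node weights.  The
    test is one-sided for w *smaller* than the null (interacting
    proteins under similar constraint).
    """
    nodes, ia, ib, w, skipped = _scorable(network, omegas)
    if np.unique(w).size < 2:
        raise ValueError("need >=2 distinct omega values among scorable nodes")
    observed = float(np.abs(w[ia] - w[ib]).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        wp = w[rng.permutation(w.size)]
        null[i] = np.abs(wp[ia] - wp[ib]).mean()
    perm = PermutationResult.from_null(observed, null, "less", seed)
    return WeightedNetworkStat(
        definition="omega-difference",
        observed=observed,
        n_edges=ia.size,
        n_skipped=skipped,
        perm=perm,
    )


def degree_assortativity_test(
    network: InteractionNetwork,
    n_rewire: int = 1000,
    n_swaps_per_edge: float = 10,
    seed: int = 0,
) -> WeightedNetworkStat:
    """Is the average |Δk| across edges unusual relative to randomly
    rewired networks with identical node degrees?

    Two-sided empirical p; the direction (observed above or below the
    null mean) is reported through the sign of observed − null mean.
    A w above the null mean means proteins are *less* likely than
    chance to interact with similar-degree partners.
    """
    degrees = network.degrees()
    edges = network.pairs()
    observed = float(
        np.mean([abs(degrees[a] - degrees[b]) for a, b in edges])
    )
    null = np.empty(n_rewire)
    for i in range(n_rewire):
        rw = rewire_degree_preserving(
            network, n_swaps_per_edge=n_swaps_per_edge, seed=seed + i
        )
        null[i] = np.mean([abs(degrees[a] - degrees[b]) for a, b in rw.pairs()])
    perm = PermutationResult.from_null(observed, null, "two-sided", seed)
    return WeightedNetworkStat(
        definition="degree-difference",
        observed=observed,
        n_edges=len(edges),
        n_skipped=0,
        perm=perm,
    )


@dataclass(frozen=True)
class DegreeSetComparison:
    """Degree summaries of two disjoint gene sets + Wilcoxon rank-sum p."""

    k_min: tuple[int, int]
    k_max: tuple[int, int]
    k_mean: tuple[float, float]
    n: tuple[int, int]
    p: float


def compare_degree_sets(
    genes_a: Sequence[str], genes_b: Sequence[str], network: InteractionNetwork
) -> DegreeSetComparison:
    """Wilcoxon rank-sum comparison of the degree distributions of two
    disjoint gene sets."""
    set_a, set_b = set(genes_a), set(genes_b)
    if not set_a or not set_b:
        raise ValueError("both gene sets must be nonempty")
    if set_a & set_b:
        raise ValueError("gene sets must be disjoint")
    ka = np.array([network.degree(g) for g in sorted(set_a)])
    kb = np.array([network.degree(g) for g in sorted(set_b)])
    p = float(stats.mannwhitneyu(ka, kb, alternative="two-sided").pvalue)
    return DegreeSetComparison(
        k_min=(int(ka.min()), int(kb.min())),
        k_max=(int(ka.max()), int(kb.max())),
        k_mean=(float(ka.mean()), float(kb.mean())),
        n=(ka.size, kb.size),
        p=p,
    )


@dataclass(frozen=True)
class DegreeDifferenceComparison:
    """Δk distributions of two PPI sets + Wilcoxon rank-sum p."""

    mean_dk: tuple[float, float]
    max_dk: tuple[int, int]
    n: tuple[int, int]
    p: float
    dk_a: np.ndarray
    dk_b: np.ndarray


def compare_degree_difference_sets(
    ppis_a: Sequence[Pair], ppis_b: Sequence[Pair], network: InteractionNetwork
) -> DegreeDifferenceComparison:
    """Compare the absolute degree differences Δk of two PPI sets
    (e.g. primate-specific vs the remainder)."""
    if not ppis_a or not ppis_b:
        raise ValueError("both PPI sets must be nonempty")
    dk_a = np.array([degree_difference(canonical_pair(*p), network) for p in ppis_a])
    dk_b = np.array([degree_difference(canonical_pair(*p), network) for p in ppis_b])
    p = float(stats.mannwhitneyu(dk_a, dk_b, alternative="two-sided").pvalue)
    return DegreeDifferenceComparison(
        mean_dk=(float(dk_a.mean()), float(dk_b.mean())),
        max_dk=(int(dk_a.max()), int(dk_b.max())),
        n=(dk_a.size, dk_b.size),
        p=p,
        dk_a=dk_a,
        dk_b=dk_b,
    )
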