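"""The three randomisation engines behind every test in the package.

* degree-proportional pseudo-pair (pr-PPI) sampling — gene pairs drawn
  from the interactome's genes with probability proportional to degree,
  excluding self-pairs and true edges;
* node-weight permutation — uniformly random reassignment of a set of
  node attributes over the same gene set;
* degree-preserving rewiring — repeated double-edge swaps with
  rejection of self-loops and multi-edges.

All engines are deterministic under a seed; multi-replicate callers use
one stream per replicate seeded ``seed + replicate index``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .data import InteractionNetwork, Pair, canonical_pair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudoPairSet:
    """A set of unique non-interacting gene pairs (pr-PPIs)."""

    pairs: tuple[Pair, ...]
    seed: int

    @property
    def size(self) -> int:
        return len(self.pairs)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_pseudo_pairs(
    network: InteractionNetwork,
    n_pairs: int,
    seed: int = 0,
    candidates: Sequence[str] | None = None,
    predicate: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    max_batches: int = 10_000,
) -> PseudoPairSet:
    """Draw ``n_pairs`` unique pseudo-pairs, genes weighted by degree.

    The two members of each pair are drawn independently from the gene
    set (probability proportional to the number of interactions the
    gene has); draws producing a self-pair, a true edge of ``network``
    or a pair already in the set are rejected and redrawn.  Uniqueness
    is enforced at the pair level only — a gene may appear in many
    pseudo-pairs within one replicate.

    Parameters
    ----------
    candidates
        Restrict sampling to this gene subset (still degree-weighted);
        defaults to every network gene with degree ≥ 1.
    predicate
        Optional vectorised filter ``f(idx_a, idx_b) -> bool array``
        over candidate indices, used by callers that impose extra
        pair eligibility rules (e.g. a minimum of shared mirrortree
        branches).  With a predicate the feasibility of the request
        cannot be checked up front; exhaustion of ``max_batches``
        raises instead.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if candidates is None:
        genes = [g for g in network.nodes if network.degree(g) > 0]
    else:
        genes = list(candidates)
    m = len(genes)
    if m < 2:
        raise ValueError("need at least two candidate genes with degree > 0")
    weights = np.array([network.degree(g) for g in genes], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("candidate genes all have degree 0")
    prob = weights / weights.sum()

    index_of = {g: i for i, g in enumerate(genes)}
    true_edges = {
        (index_of[a], index_of[b])
        for a, b in network.pairs()
        if a in index_of and b in index_of
    }
    true_edges = {(min(i, j), max(i, j)) for i, j in true_edges}
    if predicate is None:
        available = m * (m - 1) // 2 - len(true_edges)
        if n_pairs > available:
            raise ValueError(
                f"cannot draw {n_pairs} pseudo-pairs: only {available} "
                "non-edges exist among the candidate genes"
            )

    rng = _rng(seed)
    chosen: list[tuple[int, int]] = []
    chosen_set: set[tuple[int, int]] = set()
    rejected = 0
    for _ in range(max_batches):
        need = n_pairs - len(chosen)
        if need <= 0:
            break
        batch = max(4 * need, 64)
        draw = rng.choice(m, size=(batch, 2), p=prob)
        lo = np.minimum(draw[:, 0], draw[:, 1])
        hi = np.maximum(draw[:, 0], draw[:, 1])
        ok = lo != hi
        if predicate is not None:
            ok &= predicate(lo, hi)
        for i, j, keep in zip(lo.tolist(), hi.tolist(), ok.tolist()):
            if len(chosen) >= n_pairs:
                break
            key = (i, j)
            if not keep or key in true_edges or key in chosen_set:
                rejected += 1
                continue
            chosen.append(key)
            chosen_set.add(key)
    else:
        raise RuntimeError(
            f"pseudo-pair sampling did not reach {n_pairs} pairs after "
            f"{max_batches} batches ({len(chosen)} found)"
        )
    log.debug("sample_pseudo_pairs: %d rejected draws", rejected)
    pairs = tuple(canonical_pair(genes[i], genes[j]) for i, j in chosen)
    base_seed = seed if isinstance(seed, int) else -1
    return PseudoPairSet(pairs=pairs, seed=base_seed)


def permute_node_weights(
    weights: Mapping[str, float], seed: int = 0
) -> dict[str, float]:
    """Uniformly random permutation of the value multiset over the same
    gene set; the multiset of values is preserved exactly."""
    genes = sorted(weights)
    if len(genes) < 2:
        raise ValueError("need at least two genes to permute")
    values = np.array([weights[g] for g in genes], dtype=float)
    rng = _rng(seed)
    return dict(zip(genes, values[rng.permutation(len(genes))]))


def rewire_degree_preserving(
    network: InteractionNetwork,
    n_swaps_per_edge: float = 10,
    seed: int = 0,
) -> InteractionNetwork:
    """Degree-preserving randomisation by repeated double-edge swaps.

    Two edges (a,b) and (c,d) are replaced by (a,d) and (c,b); any
    proposal creating a self-loop or a multi-edge is rejected (silently,
    with a logged count).  ``n_swaps_per_edge × edge count`` swaps are
    attempted; every node keeps its exact degree.
    """
    edges = [tuple(e) for e in network.pairs()]
    if len(edges) < 2:
        raise ValueError("network must have at least two edges to rewire")
    edge_set = set(edges)
    n_attempts = int(round(n_swaps_per_edge * len(edges)))
    rng = _rng(seed)
    idx = rng.integers(0, len(edges), size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    rejected = 0
    for (i, j), fl in zip(idx.tolist(), flip.tolist()):
        if i == j:
            rejected += 1
            continue
        a, b = edges[i]
        c, d = edges[j]
        if fl:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            rejected += 1
            continue
        e1 = canonical_pair(a, d)
        e2 = canonical_pair(c, b)
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            rejected += 1
            continue
        edge_set.discard(canonical_pair(a, b))
        edge_set.discard(canonical_pair(c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    log.debug(
        "rewire_degree_preserving: %d/%d proposals rejected", rejected, n_attempts
    )
    return InteractionNetwork(edges=sorted(edge_set), nodes=network.nodes)
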