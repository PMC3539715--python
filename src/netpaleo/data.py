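"""Domain containers: interaction network, presence matrix, ω tables,
mirrortrees and permutation results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .phylogeny import BRANCHES, REFERENCE_SPECIES, SPECIES

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Unordered pairs are stored with the lexicographically smaller
    gene first; the "first gene" of the status coding refers to this
    canonical order."""
    return (a, b) if a <= b else (b, a)


class InteractionNetwork:
    """Simple undirected graph over gene identifiers.

    Self-loops and duplicate edges are invalid (the interactome this
    models excludes self-interactions); the degree k of a gene is its
    number of distinct neighbours.
    """

    def __init__(self, edges: Iterable[Pair] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-interaction {a!r} is not allowed")
            g.add_edge(a, b)
        self._g = g

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def pairs(self) -> list[Pair]:
        """Edges as canonically ordered pairs, sorted."""
        return sorted(canonical_pair(a, b) for a, b in self._g.edges)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    def degree(self, gene: str) -> int:
        if gene not in self._g:
            raise KeyError(f"unknown gene {gene!r}")
        return self._g.degree(gene)

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def neighbors(self, gene: str) -> list[str]:
        if gene not in self._g:
            raise KeyError(f"unknown gene {gene!r}")
        return sorted(self._g.neighbors(gene))

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and set(
            self.pairs()
        ) == set(other.pairs())

    def __repr__(self) -> str:
        return f"InteractionNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


class PresenceMatrix:
    """Gene × species ortholog presence indicators.

    Every gene must be present in the reference species (human): the
    gene universe is defined from the human gene set.  Lookup of an
    unknown gene or species raises, never silently reports absence.
    """

    def __init__(self, frame: pd.DataFrame):
        if list(frame.columns) != list(SPECIES):
            raise ValueError(
                f"presence matrix columns must be {list(SPECIES)}, got {list(frame.columns)}"
            )
        values = frame.to_numpy()
        if not np.isin(values, [0, 1]).all():
            raise ValueError("presence values must be 0 or 1")
        frame = frame.astype(bool)
        if not frame[REFERENCE_SPECIES].all():
            bad = frame.index[~frame[REFERENCE_SPECIES]].tolist()
            raise ValueError(f"genes absent in human are invalid: {bad[:5]}")
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene rows: {dups[:5]}")
        self._frame = frame

    @classmethod
    def from_dict(cls, entries: Mapping[str, Iterable[str]]) -> "PresenceMatrix":
        """Build from a mapping gene -> iterable of species with the ortholog."""
        rows = {
            gene: [1 if sp in set(present) else 0 for sp in SPECIES]
            for gene, present in entries.items()
        }
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(SPECIES))
        return cls(frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def genes(self) -> list[str]:
        return list(self._frame.index)

    def is_present(self, gene: str, species: str) -> bool:
        if species not in self._frame.columns:
            raise KeyError(f"unknown species {species!r}")
        if gene not in self._frame.index:
            raise KeyError(f"unknown gene {gene!r}")
        return bool(self._frame.at[gene, species])

    def species_with(self, gene: str) -> frozenset[str]:
        if gene not in self._frame.index:
            raise KeyError(f"unknown gene {gene!r}")
        row = self._frame.loc[gene]
        return frozenset(row.index[row])

    def __contains__(self, gene: str) -> bool:
        return gene in self._frame.index

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self._frame.sort_index().equals(other._frame.sort_index())


class BranchOmegaTable:
    """Per-gene, per-branch selective constraint ω (Ka/Ks).

    Missing (gene, branch) entries are explicit — they are never
    zero-filled — because per-gene branch coverage is partial when a
    gene's orthologs do not span the whole tree.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, float]]):
        self._entries: dict[str, dict[str, float]] = {}
        for gene, branches in entries.items():
            row: dict[str, float] = {}
            for branch, omega in branches.items():
                if branch not in BRANCHES:
                    raise ValueError(f"unknown branch label {branch!r} for {gene!r}")
                omega = float(omega)
                if not omega >= 0:
                    raise ValueError(f"negative omega {omega} for ({gene!r}, {branch!r})")
                row[branch] = omega
            self._entries[gene] = row

    @property
    def genes(self) -> list[str]:
        return sorted(self._entries)

    def branches(self, gene: str) -> frozenset[str]:
        return frozenset(self._row(gene))

    def coverage(self, gene: str) -> int:
        return len(self._row(gene))

    def omega(self, gene: str, branch: str) -> float:
        row = self._row(gene)
        if branch not in row:
            raise KeyError(f"no omega for ({gene!r}, {branch!r})")
        return row[branch]

    def _row(self, gene: str) -> dict[str, float]:
        if gene not in self._entries:
            raise KeyError(f"unknown gene {gene!r}")
        return self._entries[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def matrix(self, genes: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Dense genes × 13 matrix (NaN = missing) in canonical branch
        order, for vectorised correlation work."""
        genes = list(genes) if genes is not None else self.genes
        m = np.full((len(genes), len(BRANCHES)), np.nan)
        col = {b: j for j, b in enumerate(BRANCHES)}
        for i, g in enumerate(genes):
            for b, w in self._row(g).items():
                m[i, col[b]] = w
        return m, genes

    def items(self) -> Iterator[tuple[str, str, float]]:
        for gene in sorted(self._entries):
            for branch in BRANCHES:
                if branch in self._entries[gene]:
                    yield gene, branch, self._entries[gene][branch]

    def __eq__(self, other) -> bool:
        if not isinstance(other, BranchOmegaTable):
            return NotImplemented
        return self._entries == other._entries


class GeneOmegaTable:
    """One whole-alignment ω per gene (one-ratio model output)."""

    def __init__(self, entries: Mapping[str, float]):
        self._entries: dict[str, float] = {}
        for gene, omega in entries.items():
            omega = float(omega)
            if not omega >= 0:
                raise ValueError(f"negative omega {omega} for gene {gene!r}")
            self._entries[gene] = omega

    @property
    def genes(self) -> list[str]:
        return sorted(self._entries)

    def omega(self, gene: str) -> float:
        if gene not in self._entries:
            raise KeyError(f"unknown gene {gene!r}")
        return self._entries[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._entries

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(sorted(self._entries.items()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneOmegaTable):
            return NotImplemented
        return self._entries == other._entries


@dataclass(frozen=True)
class MirrorTree:
    """Paired branch-wise ω vectors for one interacting pair, aligned on
    the branches present for *both* genes (canonical branch order)."""

    pair: Pair
    branches: tuple[str, ...]
    omega_a: np.ndarray
    omega_b: np.ndarray

    def __post_init__(self):
        if len(self.branches) != len(self.omega_a) or len(self.branches) != len(
            self.omega_b
        ):
            raise ValueError("omega vectors must align with the branch list")

    @property
    def n_branches(self) -> int:
        return len(self.branches)


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, null replicates and the empirical p-value.

    p is the bias-avoiding estimator (r + 1) / (n + 1) with r the number
    of null replicates at least as extreme in the tested direction;
    ``p_label`` renders "<1/(n+1)" when no replicate reaches the
    observed value.
    """

    observed: float
    null_values: np.ndarray
    n_replicates: int
    p_empirical: float
    direction: str  # {greater, less, two-sided}
    seed: int

    @classmethod
    def from_null(
        cls,
        observed: float,
        null_values: Iterable[float],
        direction: str,
        seed: int,
    ) -> "PermutationResult":
        null = np.asarray(list(null_values), dtype=float)
        n = null.size
        if n < 1:
            raise ValueError("at least one null replicate is required")
        ge = int(np.sum(null >= observed))
        le = int(np.sum(null <= observed))
        if direction == "greater":
            r = ge
            p = (r + 1) / (n + 1)
        elif direction == "less":
            r = le
            p = (r + 1) / (n + 1)
        elif direction == "two-sided":
            p = min(1.0, 2.0 * min((ge + 1) / (n + 1), (le + 1) / (n + 1)))
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return cls(
            observed=float(observed),
            null_values=null,
            n_replicates=n,
            p_empirical=float(p),
            direction=direction,
            seed=seed,
        )

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1)) if self.n_replicates > 1 else 0.0

    @property
    def p_label(self) -> str:
        limit = 1.0 / (self.n_replicates + 1)
        if self.direction != "two-sided" and self.p_empirical <= limit:
            return f"<{limit:.3g}"
        return f"{self.p_empirical:.4g}"
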