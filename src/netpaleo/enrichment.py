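"""Gene-set construction and hypergeometric term enrichment.

Three gene sets tie the origin and selection analyses to function:

* ``PrimPresI`` — genes in at least one primate-specific interaction
  (origin in the primate-stem, human-chimp-stem or human-terminal
  class), contrasted with network genes never seen in one;
* ``PrimUniqI`` — genes *all* of whose interactions are
  primate-specific, contrasted with the rest of the network;
* ``AdaptI`` — genes in at least one interaction where some branch has
  both members' ω above a threshold (shared directional/relaxed
  selection), contrasted with the other genes of the mirrortree
  universe.

Each contrast's universe is members ∪ complement (the comparison the
set was framed against), not the whole genome.  Term
over/under-representation uses the hypergeometric distribution (the
smaller tail, with direction reported) and a Bonferroni correction
across the terms tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .data import BranchOmegaTable, InteractionNetwork, Pair

log = logging.getLogger(__name__)

PRIMATE_CLASSES = frozenset({"primates", "human-chimp", "human"})


@dataclass(frozen=True)
class GeneSetDefinition:
    """A study set and its explicit background contrast."""

    id: str
    members: frozenset[str]
    complement: frozenset[str]

    def __post_init__(self):
        if self.members & self.complement:
            raise ValueError("members and complement must be disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return self.members | self.complement


def define_gene_sets(
    origin_assignments: Mapping[Pair, str],
    network: InteractionNetwork,
    branch_table: BranchOmegaTable | None = None,
    adapt_threshold: float = 0.5,
) -> dict[str, GeneSetDefinition]:
    """Build the PrimPresI / PrimUniqI / AdaptI sets and contrasts.

    ``origin_assignments`` maps each network pair to its origin class
    (as produced by the origin census).  AdaptI requires the branch-ω
    table and is defined over the genes of pairs whose mirrortrees are
    constructible (both genes in the table).
    """
    all_genes = frozenset(network.nodes)
    prim_pres: set[str] = set()
    gene_pairs: dict[str, list[str]] = {g: [] for g in all_genes}
    for (a, b), cls in origin_assignments.items():
        gene_pairs[a].append(cls)
        gene_pairs[b].append(cls)
        if cls in PRIMATE_CLASSES:
            prim_pres.update((a, b))
    prim_uniq = {
        g
        for g, classes in gene_pairs.items()
        if classes and all(c in PRIMATE_CLASSES for c in classes)
    }
    sets = {
        "PrimPresI": GeneSetDefinition(
            "PrimPresI",
            frozenset(prim_pres),
            all_genes - prim_pres,
        ),
        "PrimUniqI": GeneSetDefinition(
            "PrimUniqI",
            frozenset(prim_uniq),
            all_genes - prim_uniq,
        ),
    }
    if branch_table is not None:
        universe: set[str] = set()
        adapt: set[str] = set()
        for a, b in network.pairs():
            if a not in branch_table or b not in branch_table:
                continue
            universe.update((a, b))
            shared = branch_table.branches(a) & branch_table.branches(b)
            if any(
                branch_table.omega(a, br) > adapt_threshold
                and branch_table.omega(b, br) > adapt_threshold
                for br in shared
            ):
                adapt.update((a, b))
        sets["AdaptI"] = GeneSetDefinition(
            "AdaptI", frozenset(adapt), frozenset(universe) - adapt
        )
    return sets


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    observed: int
    expected: float
    fold_excess: float
    p_raw: float
    p_adjusted: float
    direction: str  # {over, under}


def hypergeometric_enrichment(
    gene_set: GeneSetDefinition,
    annotations: Mapping[str, Iterable[str]],
    bonferroni: bool = True,
) -> list[EnrichmentRow]:
    """Per-term over/under-representation of the study set within its
    contrast universe.

    For each term annotating ≥1 universe gene, the smaller
    hypergeometric tail is reported with its direction; the adjusted p
    is min(1, raw p × number of terms tested) when ``bonferroni`` is
    on, else the raw p.  Rows are sorted by adjusted p then term.
    """
    study = gene_set.members
    universe = gene_set.universe
    if not study:
        raise ValueError("empty study set")
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    n_skipped = 0
    rows: list[EnrichmentRow] = []
    tested = {t: g for t, g in term_genes.items() if g}
    n_terms = len(tested)
    if n_terms == 0:
        raise ValueError("no term annotates any universe gene")
    m_univ = len(universe)
    n_study = len(study)
    for term, genes in sorted(tested.items()):
        k_term = len(genes)
        k_obs = len(genes & study)
        expected = n_study * k_term / m_univ
        p_over = float(stats.hypergeom.sf(k_obs - 1, m_univ, k_term, n_study))
        p_under = float(stats.hypergeom.cdf(k_obs, m_univ, k_term, n_study))
        if p_over <= p_under:
            p_raw, direction = p_over, "over"
        else:
            p_raw, direction = p_under, "under"
        p_adj = min(1.0, p_raw * n_terms) if bonferroni else p_raw
        rows.append(
            EnrichmentRow(
                term=term,
                observed=k_obs,
                expected=expected,
                fold_excess=(k_obs / expected) if expected > 0 else float("nan"),
                p_raw=p_raw,
                p_adjusted=p_adj,
                direction=direction,
            )
        )
    if n_skipped:
        log.info("hypergeometric_enrichment: %d empty terms skipped", n_skipped)
    rows.sort(key=lambda r: (r.p_adjusted, r.term))
    return rows
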