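"""Constrained-parsimony dating of interactions and Ks-calibrated rates.

Because the interactions are defined in human, orthology calling rests
on sequence plus synteny (so independent re-appearance of the same gene
is vanishingly unlikely), and an absent ortholog may reflect annotation
failure rather than loss, standard parsimony is inappropriate.  Instead
each gene is assigned the *latest* branch on the root-to-human path at
which it could have appeared given the species that carry its ortholog:
the branch immediately ancestral to the MRCA of those species.  A pair
of interacting genes is dated to the more recent of its two gene
origins.

Rates of interaction loss are calibrated on internal branches off the
human lineage (mouse-rat and horse-dog stems) where a loss is
observable without contradicting the human data; gains are read off the
origin census.  Both are expressed per PPI per unit Ks so that, under a
steady-state network, gain and loss rates should agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import (
    InteractionNetwork,
    Pair,
    PermutationResult,
    PresenceMatrix,
    canonical_pair,
)
from .null_models import sample_pseudo_pairs
from .phylogeny import (
    CALIBRATION_PARENT_CLASS,
    CALIBRATION_TIPS,
    ORIGIN_CLASSES,
    REFERENCE_SPECIES,
    SPECIES,
    Phylogeny,
)

log = logging.getLogger(__name__)

# status codes for one PPI in one species
STATUS_BOTH_PRESENT = 4
STATUS_FIRST_ABSENT = 2
STATUS_SECOND_ABSENT = 1
STATUS_BOTH_ABSENT = 0


def code_pair_status(
    pair: Pair, species: str, presence: PresenceMatrix
) -> int:
    """Code a PPI's status in one species: 4 both orthologs present,
    2 only the first (canonically ordered) gene absent, 1 only the
    second absent, 0 both absent."""
    a, b = canonical_pair(*pair)
    pa = presence.is_present(a, species)
    pb = presence.is_present(b, species)
    if pa and pb:
        return STATUS_BOTH_PRESENT
    if not pa and pb:
        return STATUS_FIRST_ABSENT
    if pa and not pb:
        return STATUS_SECOND_ABSENT
    return STATUS_BOTH_ABSENT


def gene_origin_branch(
    gene: str, presence: PresenceMatrix, phylo: Phylogeny
) -> str:
    """Latest origin-eligible branch class consistent with the gene's
    ortholog distribution under the single-appearance model."""
    return phylo.mrca_origin_class(presence.species_with(gene))


def ppi_origin_branch(
    pair: Pair, presence: PresenceMatrix, phylo: Phylogeny
) -> str:
    """Latest possible origin of the pair: the younger of the two gene
    origins (both genes must exist before the interaction can)."""
    a, b = pair
    return phylo.younger_class(
        gene_origin_branch(a, presence, phylo),
        gene_origin_branch(b, presence, phylo),
    )


@dataclass(frozen=True)
class OriginCensus:
    """Per-branch origin counts and cumulative node presence fractions."""

    counts: Mapping[str, int]  # origin class -> pairs first appearing there
    n_pairs: int
    assignments: Mapping[Pair, str] = field(default_factory=dict)

    def __post_init__(self):
        if sum(self.counts.values()) != self.n_pairs:
            raise ValueError("per-branch counts must sum to the number of pairs")

    def node_fraction(self, origin_class: str) -> float:
        """Fraction of all pairs inferred present at the child node of
        the class branch (cumulative from the root; 1.0 at the human tip)."""
        idx = ORIGIN_CLASSES.index(origin_class)
        if self.n_pairs == 0:
            raise ValueError("census over zero pairs has no fractions")
        present = sum(self.counts.get(c, 0) for c in ORIGIN_CLASSES[: idx + 1])
        return present / self.n_pairs

    def node_fractions(self) -> dict[str, float]:
        return {c: self.node_fraction(c) for c in ORIGIN_CLASSES}


def _gene_classes(
    genes: Sequence[str], presence: PresenceMatrix, phylo: Phylogeny
) -> dict[str, int]:
    return {
        g: phylo.class_index(gene_origin_branch(g, presence, phylo)) for g in genes
    }


def origin_census(
    network: InteractionNetwork,
    presence: PresenceMatrix,
    phylo: Phylogeny,
) -> OriginCensus:
    """Census of pair origins over the five human-lineage branch classes."""
    pairs = network.pairs()
    gene_idx = _gene_classes(network.nodes, presence, phylo)
    counts = {c: 0 for c in ORIGIN_CLASSES}
    assignments: dict[Pair, str] = {}
    for a, b in pairs:
        cls = ORIGIN_CLASSES[max(gene_idx[a], gene_idx[b])]
        counts[cls] += 1
        assignments[(a, b)] = cls
    log.info(
        "origin_census: %d pairs; counts %s", len(pairs), counts
    )
    return OriginCensus(counts=counts, n_pairs=len(pairs), assignments=assignments)


# ---------------------------------------------------------------------------
# concerted presence/absence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcertedPresenceResult:
    """Counts of the four status codes per species for the real pairs,
    and a permutation test of the pooled concordant count (statuses 4
    and 0) against pseudo-pair ensembles."""

    per_species: Mapping[str, Mapping[int, int]]
    pooled: PermutationResult


def _status_counts(
    pairs: Sequence[Pair], presence: PresenceMatrix
) -> tuple[dict[str, dict[int, int]], int]:
    frame = presence.frame
    row_of = {g: i for i, g in enumerate(frame.index)}
    mat = frame.to_numpy()
    ia = np.array([row_of[a] for a, _ in pairs], dtype=int)
    ib = np.array([row_of[b] for _, b in pairs], dtype=int)
    per_species: dict[str, dict[int, int]] = {}
    concordant = 0
    for j, sp in enumerate(SPECIES):
        if sp == REFERENCE_SPECIES:
            continue
        pa = mat[ia, j]
        pb = mat[ib, j]
        counts = {
            STATUS_BOTH_PRESENT: int(np.sum(pa & pb)),
            STATUS_FIRST_ABSENT: int(np.sum(~pa & pb)),
            STATUS_SECOND_ABSENT: int(np.sum(pa & ~pb)),
            STATUS_BOTH_ABSENT: int(np.sum(~pa & ~pb)),
        }
        per_species[sp] = counts
        concordant += counts[STATUS_BOTH_PRESENT] + counts[STATUS_BOTH_ABSENT]
    return per_species, concordant


def concerted_presence_test(
    network: InteractionNetwork,
    presence: PresenceMatrix,
    n_null: int = 100,
    seed: int = 0,
) -> ConcertedPresenceResult:
    """Do interacting genes show concerted presence/absence?

    Counts, per species, how often both members of a pair are present
    (status 4) or both absent (status 0) and compares the pooled
    concordant count to pseudo-pair ensembles of the same size; the
    empirical p is one-sided for an excess of concordant states.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    pairs = network.pairs()
    if not pairs:
        raise ValueError("network has no edges")
    per_species, observed = _status_counts(pairs, presence)
    null = np.empty(n_null)
    for i in range(n_null):
        pps = sample_pseudo_pairs(network, len(pairs), seed=seed + i)
        _, null[i] = _status_counts(pps.pairs, presence)
    pooled = PermutationResult.from_null(observed, null, "greater", seed)
    return ConcertedPresenceResult(per_species=per_species, pooled=pooled)


# ---------------------------------------------------------------------------
# degree vs age
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeAgeResult:
    """Mean degree of proteins in pairs originating at each class,
    branch ages, the Pearson correlation of the two and its pseudo-pair
    randomisation test."""

    mean_degree: Mapping[str, float]
    branch_age: Mapping[str, float]
    perm: PermutationResult


def _class_mean_degrees(
    pairs: Sequence[Pair],
    gene_idx: Mapping[str, int],
    degrees: Mapping[str, int],
) -> dict[str, float]:
    members: dict[str, set[str]] = {c: set() for c in ORIGIN_CLASSES}
    for a, b in pairs:
        cls = ORIGIN_CLASSES[max(gene_idx[a], gene_idx[b])]
        members[cls].update((a, b))
    return {
        c: float(np.mean([degrees[g] for g in sorted(genes)]))
        for c, genes in members.items()
        if genes
    }


def degree_age_correlation(
    network: InteractionNetwork,
    presence: PresenceMatrix,
    phylo: Phylogeny,
    n_null: int = 100,
    seed: int = 0,
) -> DegreeAgeResult:
    """Correlation of per-class mean protein degree with branch age.

    For each origin class, the mean degree of the distinct proteins
    participating in pairs originating there (this is *not* the degree
    of genes appearing at that node: an old hub interacting with a
    young gene counts toward the young class).  Branch age is the
    cumulative Ks from the human tip to the branch midpoint.  The
    Pearson correlation is compared to pseudo-pair networks; p is the
    fraction of null correlations at least as extreme in the observed
    direction.
    """
    pairs = network.pairs()
    gene_idx = _gene_classes(network.nodes, presence, phylo)
    degrees = network.degrees()
    mean_degree = _class_mean_degrees(pairs, gene_idx, degrees)
    if len(mean_degree) < 3:
        raise ValueError(
            f"need >=3 origin classes with pairs, got {len(mean_degree)}"
        )
    ages = {c: phylo.class_age(c) for c in mean_degree}
    order = [c for c in ORIGIN_CLASSES if c in mean_degree]
    x = np.array([ages[c] for c in order])
    y = np.array([mean_degree[c] for c in order])
    observed = float(stats.pearsonr(x, y).statistic)
    direction = "greater" if observed >= 0 else "less"
    null = np.empty(n_null)
    for i in range(n_null):
        pps = sample_pseudo_pairs(network, len(pairs), seed=seed + i)
        md = _class_mean_degrees(pps.pairs, gene_idx, degrees)
        common = [c for c in ORIGIN_CLASSES if c in md]
        if len(common) < 3:
            null[i] = np.nan
            continue
        xv = np.array([ages.get(c, phylo.class_age(c)) for c in common])
        yv = np.array([md[c] for c in common])
        null[i] = stats.pearsonr(xv, yv).statistic
    null = null[np.isfinite(null)]
    perm = PermutationResult.from_null(observed, null, direction, seed)
    return DegreeAgeResult(mean_degree=mean_degree, branch_age=ages, perm=perm)


# ---------------------------------------------------------------------------
# gain / loss rates and the steady-state correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateEstimate:
    """Events per exposed PPI per unit Ks on one branch."""

    branch: str
    events: int
    exposure: int
    ks: float

    def __post_init__(self):
        if self.exposure <= 0:
            raise ValueError(f"zero exposure on branch {self.branch!r}")
        if self.ks <= 0:
            raise ValueError(f"branch {self.branch!r} has Ks <= 0")

    @property
    def rate(self) -> float:
        return self.events / self.exposure / self.ks


def loss_rate(
    branch: str,
    network: InteractionNetwork,
    presence: PresenceMatrix,
    phylo: Phylogeny,
) -> RateEstimate:
    """PPI loss rate on a loss-calibration branch (mouse-rat or
    horse-dog stem).

    Exposure: pairs inferred present at the branch's parent node, i.e.
    pairs whose origin class is at or above that node (under the
    single-appearance model a gene whose MRCA spans the parent is
    necessarily present there).  Events: exposed pairs with at least
    one member gene absent from *both* descendants of the branch — the
    minimal-loss reading places a single loss on the stem.
    """
    if branch not in CALIBRATION_PARENT_CLASS:
        raise ValueError(f"{branch!r} is not a loss-calibration branch")
    ks = float(phylo.branch_ks[branch])
    parent_idx = phylo.class_index(CALIBRATION_PARENT_CLASS[branch])
    tip1, tip2 = CALIBRATION_TIPS[branch]
    gene_idx = _gene_classes(network.nodes, presence, phylo)
    absent_both = {
        g: not (presence.is_present(g, tip1) or presence.is_present(g, tip2))
        for g in network.nodes
    }
    exposure = events = 0
    for a, b in network.pairs():
        if max(gene_idx[a], gene_idx[b]) > parent_idx:
            continue
        exposure += 1
        if absent_both[a] or absent_both[b]:
            events += 1
    return RateEstimate(branch=branch, events=events, exposure=exposure, ks=ks)


def gain_rate(
    origin_class: str, census: OriginCensus, phylo: Phylogeny
) -> RateEstimate:
    """PPI gain rate on an origin-eligible branch class: pairs
    originating there over pairs present at the branch's child node,
    per unit Ks."""
    idx = phylo.class_index(origin_class)
    ks = phylo.class_ks(origin_class)
    events = census.counts.get(origin_class, 0)
    exposure = sum(census.counts.get(c, 0) for c in ORIGIN_CLASSES[: idx + 1])
    return RateEstimate(branch=origin_class, events=events, exposure=exposure, ks=ks)


@dataclass(frozen=True)
class SteadyStateCorrection:
    """Raw and gain-corrected root-presence fractions.

    The correction subtracts the expected number of pairs gained along
    each human-lineage branch (gain rate × pairs at risk × branch Ks)
    from the pairs attributed to ancient origins.  The linear form is a
    first-order stand-in for an exponential gain model (per-branch
    g·Ks ≪ 1), flagged here because the exact correction is a
    modelling choice.
    """

    raw_root_fraction: float
    corrected_root_fraction: float
    gain_rate: float
    loss_rate: float | None
    expected_gains: Mapping[str, float]
    note: str = "linear expected-gains correction"


def steady_state_correction(
    gain: float,
    census: OriginCensus,
    phylo: Phylogeny,
    loss: float | None = None,
) -> SteadyStateCorrection:
    """Correct the root-presence fraction for gains between existing
    orthologs, assuming the network is at steady state (so a loss rate
    estimated off-lineage can stand in for the gain rate)."""
    if gain < 0 or (loss is not None and loss < 0):
        raise ValueError("rates must be nonnegative")
    n_total = census.n_pairs
    raw = census.node_fraction("root")
    expected = {}
    total_gained = 0.0
    for cls in ORIGIN_CLASSES:
        idx = phylo.class_index(cls)
        n_at_child = sum(census.counts.get(c, 0) for c in ORIGIN_CLASSES[: idx + 1])
        e = gain * n_at_child * phylo.class_ks(cls)
        expected[cls] = e
        total_gained += e
    corrected = raw * max(0.0, 1.0 - total_gained / n_total)
    return SteadyStateCorrection(
        raw_root_fraction=raw,
        corrected_root_fraction=corrected,
        gain_rate=gain,
        loss_rate=loss,
        expected_gains=expected,
    )
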