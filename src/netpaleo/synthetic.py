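"""Synthetic study generator: internally consistent interactome,
ortholog presence, ω tables and annotations with recorded ground truth.

The generator emulates the statistical structure the analyses assume:

* a fixed 8-mammal tree with literature-scale Ks branch lengths;
* genes born on one of the five human-lineage branch classes (heavily
  weighted toward the root — most mammalian genes are ancient) and
  subsequently lost along off-lineage branches with per-Ks probability
  1 − exp(−λ·Ks); losses are inherited, and the human lineage is
  loss-protected because the gene universe is conditioned on human;
* a heavy-tailed interactome degree distribution, optionally coupling
  hub status to gene age;
* branch-wise ω built from a latent Gaussian field: a per-branch effect
  shared by all genes (which gives non-interacting pairs the nonzero
  baseline rank correlation real data show) plus, for a planted subset
  of interacting pairs, a pair-shared branch factor with latent
  correlation ρ*; the latent score is pushed through a fixed monotone
  quantile map onto a right-skewed ω marginal (bulk below 1, plus
  configurable spike mass in (1,5) and (5,9)), so rank correlations are
  exactly those of the latent field;
* whole-gene ω with tunable edge assortativity via neighbourhood
  smoothing of a latent constraint;
* a flat gene → term annotation table.

Every planted parameter is recorded in :class:`GroundTruth` so the
analysis modules can be closed-loop tested against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml
from scipy.stats import norm

from .data import (
    BranchOmegaTable,
    GeneOmegaTable,
    InteractionNetwork,
    Pair,
    PresenceMatrix,
    canonical_pair,
)
from .null_models import rewire_degree_preserving
from .phylogeny import (
    BRANCH_CLADES,
    BRANCHES,
    CLASS_CLADES,
    ORIGIN_CLASSES,
    SPECIES,
    Phylogeny,
    write_phylogeny,
    write_roles,
)

#: Default mean synonymous divergences per branch (substitutions per
#: synonymous site), at the scale reported for placental mammals.
DEFAULT_KS: dict[str, float] = {
    "human": 0.011,
    "chimpanzee": 0.012,
    "human-chimp": 0.056,
    "macaque": 0.082,
    "primates": 0.061,
    "mouse": 0.083,
    "rat": 0.092,
    "mouse-rat": 0.196,
    "horse": 0.107,
    "dog": 0.132,
    "horse-dog": 0.063,
    "cow": 0.178,
    "root": 0.301,
}

#: Rooted branches off the human lineage where an ortholog can be lost,
#: with the tips removed when the loss occurs.  The laurasiatheria stem
#: is the laur-side half of the central branch.
LOSS_BRANCHES: tuple[tuple[str, frozenset[str]], ...] = (
    ("chimpanzee", frozenset({"chimpanzee"})),
    ("macaque", frozenset({"macaque"})),
    ("mouse-rat", frozenset({"mouse", "rat"})),
    ("mouse", frozenset({"mouse"})),
    ("rat", frozenset({"rat"})),
    ("laurasiatheria", frozenset({"horse", "dog", "cow"})),
    ("horse-dog", frozenset({"horse", "dog"})),
    ("horse", frozenset({"horse"})),
    ("dog", frozenset({"dog"})),
    ("cow", frozenset({"cow"})),
)


def loss_branch_ks(label: str, phylo: Phylogeny) -> float:
    if label == "laurasiatheria":
        return phylo.central_ks / 2.0
    return float(phylo.branch_ks[label])


DEFAULT_ORIGIN_PROBS: dict[str, float] = {
    "root": 0.95,
    "euarchontoglires": 0.015,
    "primates": 0.015,
    "human-chimp": 0.01,
    "human": 0.01,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    The defaults are the package's standing study conditions: an
    ancient-dominated gene set (~90% of pairs dating to the root), a
    per-gene per-Ks ortholog loss rate of 0.1, a right-skewed ω
    marginal with small directional-selection spike masses, a planted
    latent co-evolution correlation ρ* = 0.3 carried by half the
    pairable edges, and moderate constraint assortativity.
    """

    n_genes: int = 300
    degree_exponent: float = 2.2
    degree_sequence: tuple[int, ...] | None = None
    age_coupled_degrees: bool = False
    origin_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORIGIN_PROBS)
    )
    loss_rate: float = 0.1  # λ, per gene per unit Ks
    coevolution_rho: float = 0.3  # ρ*, latent correlation for flagged pairs
    coevolution_fraction: float = 0.5  # of edges, capped by a matching
    coevolution_branches: tuple[str, ...] | None = None  # None = all 13
    branch_effect_sd: float = 0.35
    omega_log_mean: float = float(np.log(0.2))
    omega_log_sd: float = 0.8
    omega_p_mid: float = 0.04  # spike mass in (1, 5)
    omega_p_high: float = 0.01  # spike mass in (5, 9)
    assortativity_strength: float = 0.4  # s in [0, 1]
    n_terms: int = 20
    terms_per_gene_mean: float = 2.0
    ks: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_KS))

    def __post_init__(self):
        probs = dict(self.origin_probs)
        if set(probs) != set(ORIGIN_CLASSES):
            raise ValueError(f"origin_probs must cover {ORIGIN_CLASSES}")
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"origin probabilities must sum to 1, got {total}")
        if self.loss_rate < 0:
            raise ValueError("loss rate must be >= 0")
        if not abs(self.coevolution_rho) < 1:
            raise ValueError("|rho*| must be < 1")
        if not 0 <= self.assortativity_strength <= 1:
            raise ValueError("assortativity strength must be in [0, 1]")
        if self.omega_p_mid < 0 or self.omega_p_high < 0 or (
            self.omega_p_mid + self.omega_p_high >= 1
        ):
            raise ValueError("spike masses must be >= 0 and sum below 1")
        if self.coevolution_branches is not None:
            unknown = set(self.coevolution_branches) - set(BRANCHES)
            if unknown:
                raise ValueError(f"unknown coevolution branches {sorted(unknown)}")
        for label, ks in dict(self.ks).items():
            if label not in BRANCHES:
                raise ValueError(f"unknown branch {label!r} in ks")
            if not ks > 0:
                raise ValueError(f"Ks must be positive, got {ks} on {label!r}")


@dataclass
class GroundTruth:
    """Planted state emitted alongside every synthetic dataset."""

    origins: dict[str, str]  # gene -> origin class
    losses: set[tuple[str, str]]  # (gene, loss branch)
    coevolving_pairs: tuple[Pair, ...]
    latent_constraint: dict[str, float]
    branch_effects: dict[str, float]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    seed: int
    phylo: Phylogeny
    network: InteractionNetwork
    presence: PresenceMatrix
    branch_omega: BranchOmegaTable
    gene_omega: GeneOmegaTable
    annotations: dict[str, frozenset[str]]
    truth: GroundTruth


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_phylogeny(config: SimulationConfig | None = None) -> Phylogeny:
    """The fixed 8-mammal topology with the configured Ks lengths."""
    ks = dict(DEFAULT_KS)
    if config is not None:
        ks.update(config.ks)
    return Phylogeny(branch_ks=ks)


def simulate_gene_origins(
    config: SimulationConfig, rng: np.random.Generator, genes: Sequence[str]
) -> dict[str, str]:
    probs = np.array([config.origin_probs[c] for c in ORIGIN_CLASSES])
    draws = rng.choice(len(ORIGIN_CLASSES), size=len(genes), p=probs / probs.sum())
    return {g: ORIGIN_CLASSES[i] for g, i in zip(genes, draws)}


def simulate_presence(
    phylo: Phylogeny,
    origins: Mapping[str, str],
    loss_rate: float,
    rng: np.random.Generator,
) -> tuple[PresenceMatrix, set[tuple[str, str]]]:
    """Presence matrix from origins plus per-branch stochastic loss.

    Each gene appears once on its origin branch and is then lost along
    any off-lineage branch below the origin with probability
    1 − exp(−λ·Ks); losses remove the branch's whole tip set (inherited
    by descendants).  The human lineage is loss-protected.
    """
    if loss_rate < 0:
        raise ValueError("loss rate must be >= 0")
    genes = sorted(origins)
    p_loss = {
        label: 1.0 - np.exp(-loss_rate * loss_branch_ks(label, phylo))
        for label, _tips in LOSS_BRANCHES
    }
    entries: dict[str, frozenset[str]] = {}
    losses: set[tuple[str, str]] = set()
    for g in genes:
        clade = set(CLASS_CLADES[origins[g]])
        present = set(clade)
        for label, tips in LOSS_BRANCHES:
            if not tips <= clade:
                continue
            if rng.random() < p_loss[label]:
                present -= tips
                losses.add((g, label))
        entries[g] = frozenset(present)
    return PresenceMatrix.from_dict(entries), losses


def _graphical_degrees(
    config: SimulationConfig, rng: np.random.Generator
) -> list[int]:
    n = config.n_genes
    if config.degree_sequence is not None:
        deg = list(config.degree_sequence)
        if len(deg) != n:
            raise ValueError("degree sequence length must equal n_genes")
        if not nx.is_graphical(deg):
            raise ValueError("requested degree sequence is not graphical")
        return deg
    cap = max(2, n // 8)
    deg = np.minimum(rng.zipf(config.degree_exponent, size=n), cap).astype(int)
    deg = deg.tolist()
    if sum(deg) % 2:
        deg[int(np.argmin(deg))] += 1
    while not nx.is_graphical(deg):
        deg[int(np.argmax(deg))] -= 1
    return deg


def simulate_network(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: Sequence[str],
    origins: Mapping[str, str] | None = None,
) -> InteractionNetwork:
    """Simple interactome with a heavy-tailed degree sequence.

    The Havel–Hakimi construction realises the degree sequence exactly;
    degree-preserving swaps then randomise the wiring.  In age-coupled
    mode the highest-degree nodes are preferentially assigned to the
    oldest genes (for degree-vs-age power tests).
    """
    deg = _graphical_degrees(config, rng)
    if config.age_coupled_degrees:
        if origins is None:
            raise ValueError("age-coupled degrees require gene origins")
        return _age_assortative_network(genes, deg, origins, rng)
    g = nx.havel_hakimi_graph(deg)
    node_order = sorted(g.nodes, key=lambda v: (-g.degree(v), v))
    gene_order = [genes[i] for i in rng.permutation(len(genes))]
    mapping = dict(zip(node_order, gene_order))
    edges = sorted(
        canonical_pair(mapping[u], mapping[v]) for u, v in g.edges
    )
    net = InteractionNetwork(edges=edges, nodes=sorted(genes))
    if net.n_edges >= 2:
        net = rewire_degree_preserving(
            net, n_swaps_per_edge=10, seed=int(rng.integers(2**31 - 1))
        )
    return net


def _age_assortative_network(
    genes: Sequence[str],
    deg: Sequence[int],
    origins: Mapping[str, str],
    rng: np.random.Generator,
) -> InteractionNetwork:
    """Old genes get the high degrees and wiring is age-assortative:
    interaction stubs are sorted by (noisy) gene age and matched to
    their neighbours in that order, so ancient hubs connect mostly to
    other ancient genes and young genes to each other.  A handful of
    stubs whose pairing would create a self-loop or multi-edge are
    dropped, so realised degrees can fall slightly short of the
    requested sequence in this mode."""
    n = len(genes)
    age_rank = np.array([ORIGIN_CLASSES.index(origins[g]) for g in genes], dtype=float)
    # largest degrees to the oldest genes (noisy sort)
    gene_order = np.argsort(age_rank + rng.gumbel(0.0, 0.3, n), kind="stable")
    deg_sorted = sorted(deg, reverse=True)
    deg_of = np.empty(n, dtype=int)
    deg_of[gene_order] = deg_sorted
    stubs = np.repeat(np.arange(n), deg_of)
    keys = age_rank[stubs] + rng.normal(0.0, 0.6, stubs.size)
    stubs = stubs[np.argsort(keys, kind="stable")]
    edges: set[tuple[str, str]] = set()
    leftover: list[int] = []
    for k in range(0, stubs.size - 1, 2):
        i, j = int(stubs[k]), int(stubs[k + 1])
        e = canonical_pair(genes[i], genes[j])
        if i == j or e in edges:
            leftover.extend((i, j))
        else:
            edges.add(e)
    if stubs.size % 2:
        leftover.append(int(stubs[-1]))
    pool = np.array(leftover)
    rng.shuffle(pool)
    for k in range(0, pool.size - 1, 2):
        i, j = int(pool[k]), int(pool[k + 1])
        e = canonical_pair(genes[i], genes[j])
        if i != j and e not in edges:
            edges.add(e)
    return InteractionNetwork(edges=sorted(edges), nodes=sorted(genes))


# ---------------------------------------------------------------------------
# omega simulation
# ---------------------------------------------------------------------------


def omega_quantile(u: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Monotone quantile map from (0,1) onto the ω marginal: a
    lognormal bulk truncated below 1, then uniform spikes on (1,5) and
    (5,9) with masses ``omega_p_mid`` and ``omega_p_high``."""
    u = np.clip(np.asarray(u, dtype=float), 1e-12, 1 - 1e-12)
    c0 = 1.0 - config.omega_p_mid - config.omega_p_high
    mu, sd = config.omega_log_mean, config.omega_log_sd
    out = np.empty_like(u)
    bulk = u < c0
    # quantile of LogNormal(mu, sd) conditioned on being < 1
    mass_below_1 = norm.cdf(-mu / sd)
    v = (u[bulk] / c0) * mass_below_1
    out[bulk] = np.exp(mu + sd * norm.ppf(v))
    mid = (~bulk) & (u < c0 + config.omega_p_mid)
    if config.omega_p_mid > 0:
        out[mid] = 1.0 + 4.0 * (u[mid] - c0) / config.omega_p_mid
    high = u >= c0 + config.omega_p_mid
    if config.omega_p_high > 0:
        out[high] = 5.0 + 4.0 * (u[high] - c0 - config.omega_p_mid) / config.omega_p_high
    return out


def covered_branches(present: frozenset[str]) -> tuple[str, ...]:
    """Branches of the full tree spanned by a gene's present species:
    a branch is covered iff it separates two present tips (so a
    human-only gene covers nothing — there is no alignment)."""
    return tuple(
        b
        for b in BRANCHES
        if (present & BRANCH_CLADES[b]) and (present - BRANCH_CLADES[b])
    )


def flag_coevolving_pairs(
    network: InteractionNetwork,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[Pair, ...]:
    """A vertex-disjoint random matching of edges to carry the planted
    co-evolution factor (disjointness keeps each shared latent factor
    attributable to exactly one pair); the requested count is
    round(fraction × edges), capped by the matching found."""
    edges = network.pairs()
    order = rng.permutation(len(edges))
    used: set[str] = set()
    matching: list[Pair] = []
    for i in order:
        a, b = edges[i]
        if a in used or b in used:
            continue
        matching.append((a, b))
        used.update((a, b))
    target = int(round(fraction * len(edges)))
    return tuple(matching[: min(target, len(matching))])


def simulate_branch_omega(
    network: InteractionNetwork,
    phylo: Phylogeny,
    config: SimulationConfig,
    rng: np.random.Generator,
    presence: PresenceMatrix | None = None,
) -> tuple[BranchOmegaTable, tuple[Pair, ...], dict[str, float]]:
    """Branch-wise ω via the latent-factor model.

    Latent score of gene g on branch b: t_gb = μ_b + e_gb with μ_b the
    dataset-wide branch effect and e_gb standard normal; for a flagged
    pair, e on the signal branches mixes a pair-shared factor so the
    latent correlation is exactly ρ*.  ω = Q(Φ(t)) with Q the monotone
    marginal quantile map, so rank structure is preserved.  Coverage
    follows the gene's ortholog span when a presence matrix is given.
    """
    genes = network.nodes
    n = len(genes)
    mu = {b: float(x) for b, x in zip(BRANCHES, rng.normal(0.0, config.branch_effect_sd, len(BRANCHES)))}
    flagged = flag_coevolving_pairs(network, config.coevolution_fraction, rng)
    signal = (
        set(config.coevolution_branches)
        if config.coevolution_branches is not None
        else set(BRANCHES)
    )
    rho = config.coevolution_rho
    a_coef = np.sqrt(abs(rho))
    e_coef = np.sqrt(1.0 - abs(rho))
    eps = rng.normal(size=(n, len(BRANCHES)))
    e = eps.copy()
    idx = {g: i for i, g in enumerate(genes)}
    for a, b in flagged:
        shared = rng.normal(size=len(BRANCHES))
        for j, br in enumerate(BRANCHES):
            if br not in signal:
                continue
            e[idx[a], j] = a_coef * shared[j] + e_coef * eps[idx[a], j]
            e[idx[b], j] = np.sign(rho) * a_coef * shared[j] + e_coef * eps[idx[b], j]
    t = e + np.array([mu[b] for b in BRANCHES])[None, :]
    omega = omega_quantile(norm.cdf(t), config)
    entries: dict[str, dict[str, float]] = {}
    for g in genes:
        if presence is not None:
            cov = covered_branches(presence.species_with(g))
        else:
            cov = BRANCHES
        row = {br: float(omega[idx[g], BRANCHES.index(br)]) for br in cov}
        if row:
            entries[g] = row
    return BranchOmegaTable(entries), flagged, mu


def simulate_global_omega(
    network: InteractionNetwork,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GeneOmegaTable, dict[str, float]]:
    """Whole-gene ω with planted edge assortativity: each gene's value
    mixes its own latent constraint with the mean over its closed
    neighbourhood (strength s), then is rescaled to the latent marginal
    scale.  s = 0 is topology-independent; s = 1 on a clique makes all
    members share one value."""
    genes = network.nodes
    s = config.assortativity_strength
    x = np.exp(rng.normal(config.omega_log_mean, config.omega_log_sd, len(genes)))
    idx = {g: i for i, g in enumerate(genes)}
    smoothed = np.empty_like(x)
    for g in genes:
        nb = [idx[g]] + [idx[h] for h in network.neighbors(g)]
        smoothed[idx[g]] = x[nb].mean()
    z = (1.0 - s) * x + s * smoothed
    if z.std() > 0:
        z = (z - z.mean()) / z.std() * x.std() + x.mean()
    omega = np.maximum(z, 1e-6)
    latent = {g: float(x[idx[g]]) for g in genes}
    return GeneOmegaTable({g: float(omega[idx[g]]) for g in genes}), latent


def simulate_annotations(
    genes: Sequence[str], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, frozenset[str]]:
    vocab = [f"T{i:03d}" for i in range(1, config.n_terms + 1)]
    anns: dict[str, frozenset[str]] = {}
    for g in sorted(genes):
        k = min(int(rng.poisson(config.terms_per_gene_mean)), len(vocab))
        if k:
            anns[g] = frozenset(rng.choice(vocab, size=k, replace=False).tolist())
        else:
            anns[g] = frozenset()
    return anns


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate one complete, internally consistent synthetic study."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    phylo = simulate_phylogeny(config)
    genes = _gene_ids(config.n_genes)
    origins = simulate_gene_origins(config, rng, genes)
    network = simulate_network(config, rng, genes, origins)
    presence, losses = simulate_presence(phylo, origins, config.loss_rate, rng)
    branch_omega, flagged, mu = simulate_branch_omega(
        network, phylo, config, rng, presence
    )
    gene_omega, latent = simulate_global_omega(network, config, rng)
    annotations = simulate_annotations(genes, config, rng)
    truth = GroundTruth(
        origins=dict(origins),
        losses=losses,
        coevolving_pairs=flagged,
        latent_constraint=latent,
        branch_effects=mu,
    )
    return SyntheticDataset(
        config=config,
        seed=seed,
        phylo=phylo,
        network=network,
        presence=presence,
        branch_omega=branch_omega,
        gene_omega=gene_omega,
        annotations=annotations,
        truth=truth,
    )


def make_study_fixture(
    outdir, config: SimulationConfig | None = None, seed: int = 0
) -> SyntheticDataset:
    """Write a full input bundle (network, presence, tree, roles, ω
    tables, annotations) plus machine-readable ground-truth sidecars.
    Byte-deterministic under a fixed seed."""
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config, seed)
    io.write_network(ds.network, outdir / "network.tsv")
    io.write_presence_matrix(ds.presence, outdir / "presence.tsv")
    write_phylogeny(ds.phylo, outdir / "tree.nwk")
    write_roles(outdir / "roles.yaml")
    io.write_branch_omega(ds.branch_omega, outdir / "branch_omega.tsv")
    io.write_gene_omega(ds.gene_omega, outdir / "gene_omega.tsv")
    io.write_annotations(ds.annotations, outdir / "annotations.tsv")
    with open(outdir / "truth_origins.tsv", "w") as fh:
        fh.write("gene\torigin_class\n")
        for g in sorted(ds.truth.origins):
            fh.write(f"{g}\t{ds.truth.origins[g]}\n")
    with open(outdir / "truth_losses.tsv", "w") as fh:
        fh.write("gene\tbranch\n")
        for g, br in sorted(ds.truth.losses):
            fh.write(f"{g}\t{br}\n")
    with open(outdir / "truth_coevolving_pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(ds.truth.coevolving_pairs):
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "truth_constraint.tsv", "w") as fh:
        fh.write("gene\tlatent\n")
        for g in sorted(ds.truth.latent_constraint):
            fh.write(f"{g}\t{ds.truth.latent_constraint[g]:.10g}\n")
    cfg = dataclasses.asdict(ds.config)
    cfg["origin_probs"] = dict(cfg["origin_probs"])
    cfg["ks"] = dict(cfg["ks"])
    cfg["seed"] = seed
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return ds
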