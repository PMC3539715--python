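"""Constrained-parsimony dating, census, rates and validation tests.

The dating oracle here is an independent brute force: for each
origin-eligible class it enumerates every loss scenario (each subset of
the off-lineage branches below the origin clade removes its tip set)
to build the full set of reachable presence patterns, then reports the
youngest class able to produce an observed pattern.
"""

from itertools import product

import numpy as np
import pytest

from netpaleo.data import InteractionNetwork, PresenceMatrix
from netpaleo.origins import (
    OriginCensus,
    code_pair_status,
    concerted_presence_test,
    degree_age_correlation,
    gain_rate,
    gene_origin_branch,
    loss_rate,
    origin_census,
    ppi_origin_branch,
    steady_state_correction,
)
from netpaleo.phylogeny import CLASS_CLADES, ORIGIN_CLASSES, SPECIES, Phylogeny
from netpaleo.synthetic import (
    DEFAULT_KS,
    LOSS_BRANCHES,
    SimulationConfig,
    simulate_dataset,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------


def reachable_patterns(origin_class: str) -> set[frozenset[str]]:
    """All presence patterns producible by a single appearance on the
    class branch followed by any combination of branch losses."""
    clade = CLASS_CLADES[origin_class]
    applicable = [tips for _lbl, tips in LOSS_BRANCHES if tips <= clade]
    patterns = set()
    for bits in product((0, 1), repeat=len(applicable)):
        present = set(clade)
        for bit, tips in zip(bits, applicable):
            if bit:
                present -= tips
        if "human" in present:
            patterns.add(frozenset(present))
    return patterns


_REACHABLE = {c: reachable_patterns(c) for c in ORIGIN_CLASSES}


def oracle_gene_origin(present: frozenset[str]) -> str:
    feasible = [c for c in ORIGIN_CLASSES if frozenset(present) in _REACHABLE[c]]
    assert feasible, f"pattern {sorted(present)} unreachable from any class"
    return max(feasible, key=ORIGIN_CLASSES.index)


def random_patterns(n, seed):
    rng = np.random.default_rng(seed)
    others = [s for s in SPECIES if s != "human"]
    out = []
    for _ in range(n):
        keep = rng.random(len(others)) < rng.uniform(0.1, 0.9)
        out.append(frozenset(["human"] + [s for s, k in zip(others, keep) if k]))
    return out


class TestGeneOrigin:
    def test_matches_brute_force_oracle(self, phylo):
        patterns = random_patterns(250, seed=5)
        matrix = PresenceMatrix.from_dict(
            {f"g{i}": p for i, p in enumerate(patterns)}
        )
        for i, p in enumerate(patterns):
            assert gene_origin_branch(f"g{i}", matrix, phylo) == oracle_gene_origin(p)

    @pytest.mark.parametrize(
        "present,expected",
        [
            ({"human"}, "human"),
            ({"human", "chimpanzee"}, "human-chimp"),
            ({"human", "macaque"}, "primates"),
            ({"human", "mouse"}, "euarchontoglires"),
            ({"human", "cow"}, "root"),
            ({"human", "chimpanzee", "dog"}, "root"),
            (set(SPECIES), "root"),
        ],
    )
    def test_known_placements(self, phylo, present, expected):
        m = PresenceMatrix.from_dict({"g": present})
        assert gene_origin_branch("g", m, phylo) == expected

    def test_pair_origin_is_younger_of_two(self, phylo):
        m = PresenceMatrix.from_dict(
            {"old": set(SPECIES), "mid": {"human", "macaque"}, "new": {"human"}}
        )
        assert ppi_origin_branch(("old", "mid"), m, phylo) == "primates"
        assert ppi_origin_branch(("old", "old"), m, phylo) == "root"
        assert ppi_origin_branch(("new", "mid"), m, phylo) == "human"


class TestStatusCoding:
    def test_codes(self, phylo):
        m = PresenceMatrix.from_dict(
            {"a": {"human", "mouse"}, "b": {"human"}}
        )
        # canonical order puts "a" first
        assert code_pair_status(("a", "b"), "mouse", m) == 2 if False else True
        assert code_pair_status(("a", "b"), "mouse", m) == 1  # second absent
        assert code_pair_status(("b", "a"), "mouse", m) == 1  # order-invariant
        assert code_pair_status(("a", "b"), "human", m) == 4
        assert code_pair_status(("a", "b"), "rat", m) == 0
        m2 = PresenceMatrix.from_dict({"a": {"human"}, "b": {"human", "mouse"}})
        assert code_pair_status(("a", "b"), "mouse", m2) == 2  # first absent

    def test_unknown_gene_errors(self, phylo):
        m = PresenceMatrix.from_dict({"a": {"human"}})
        with pytest.raises(KeyError):
            code_pair_status(("a", "zz"), "mouse", m)


class TestCensus:
    def test_all_ancient(self, phylo):
        m = PresenceMatrix.from_dict({f"g{i}": set(SPECIES) for i in range(6)})
        net = InteractionNetwork(
            edges=[(f"g{i}", f"g{(i + 1) % 6}") for i in range(6)]
        )
        c = origin_census(net, m, phylo)
        assert c.counts["root"] == 6 and c.node_fraction("root") == 1.0

    def test_conservation_and_monotone_fractions(self, dataset):
        c = origin_census(dataset.network, dataset.presence, dataset.phylo)
        assert sum(c.counts.values()) == dataset.network.n_edges
        fr = [c.node_fraction(cls) for cls in ORIGIN_CLASSES]
        assert fr == sorted(fr)
        assert fr[-1] == 1.0

    def test_primate_only_pair(self, phylo):
        m = PresenceMatrix.from_dict(
            {"a": {"human", "chimpanzee", "macaque"}, "b": {"human", "macaque"}}
        )
        net = InteractionNetwork(edges=[("a", "b")])
        c = origin_census(net, m, phylo)
        assert c.counts["primates"] == 1
        assert c.node_fraction("root") == 0.0

    def test_zero_loss_census_equals_planted(self):
        cfg = SimulationConfig(n_genes=200, loss_rate=0.0)
        ds = simulate_dataset(cfg, seed=3)
        c = origin_census(ds.network, ds.presence, ds.phylo)
        idx = {g: ORIGIN_CLASSES.index(cls) for g, cls in ds.truth.origins.items()}
        planted = {cls: 0 for cls in ORIGIN_CLASSES}
        for a, b in ds.network.pairs():
            planted[ORIGIN_CLASSES[max(idx[a], idx[b])]] += 1
        assert dict(c.counts) == planted


class TestRates:
    def _fixture(self, phylo):
        # 10 pairs exposed at the euarchontoglires ancestor; two pairs
        # have a member absent from both mouse and rat
        entries = {}
        for i in range(20):
            entries[f"g{i}"] = set(SPECIES)
        entries["g0"] = set(SPECIES) - {"mouse", "rat"}
        entries["g2"] = set(SPECIES) - {"mouse", "rat"}
        m = PresenceMatrix.from_dict(entries)
        net = InteractionNetwork(
            edges=[(f"g{2 * i}", f"g{2 * i + 1}") for i in range(10)]
        )
        return m, net

    def test_loss_rate_arithmetic(self, phylo):
        m, net = self._fixture(phylo)
        ks = dict(DEFAULT_KS)
        ks["mouse-rat"] = 0.15
        phylo = Phylogeny(branch_ks=ks)
        r = loss_rate("mouse-rat", net, m, phylo)
        assert (r.events, r.exposure) == (2, 10)
        assert r.rate == pytest.approx(2 / 10 / 0.15)

    def test_zero_events(self, phylo):
        entries = {f"g{i}": set(SPECIES) for i in range(4)}
        net = InteractionNetwork(edges=[("g0", "g1"), ("g2", "g3")])
        r = loss_rate("horse-dog", net, PresenceMatrix.from_dict(entries), phylo)
        assert r.events == 0 and r.rate == 0.0

    def test_non_calibration_branch_rejected(self, phylo):
        m, net = self._fixture(phylo)
        with pytest.raises(ValueError):
            loss_rate("human-chimp", net, m, phylo)

    def test_gain_rate_arithmetic(self, phylo):
        counts = {"root": 80, "euarchontoglires": 15, "primates": 5,
                  "human-chimp": 0, "human": 0}
        census = OriginCensus(counts=counts, n_pairs=100)
        ks = dict(DEFAULT_KS)
        ks["primates"] = 0.25
        phylo = Phylogeny(branch_ks=ks)
        r = gain_rate("primates", census, phylo)
        assert r.exposure == 100 and r.events == 5
        assert r.rate == pytest.approx(5 / 100 / 0.25)

    def test_gain_rate_zero_originations(self, phylo):
        counts = {"root": 10, "euarchontoglires": 0, "primates": 0,
                  "human-chimp": 0, "human": 0}
        census = OriginCensus(counts=counts, n_pairs=10)
        assert gain_rate("human", census, phylo).rate == 0.0

    def test_relabeling_invariance(self, phylo):
        m, net = self._fixture(phylo)
        rate1 = loss_rate("mouse-rat", net, m, phylo).rate
        relabel = {f"g{i}": f"x{99 - i}" for i in range(20)}
        m2 = PresenceMatrix.from_dict(
            {relabel[g]: m.species_with(g) for g in m.genes}
        )
        net2 = InteractionNetwork(
            edges=[(relabel[a], relabel[b]) for a, b in net.pairs()]
        )
        assert loss_rate("mouse-rat", net2, m2, phylo).rate == rate1


class TestSteadyStateCorrection:
    def test_zero_gain_returns_raw_fraction(self, phylo):
        counts = {"root": 7, "euarchontoglires": 1, "primates": 1,
                  "human-chimp": 1, "human": 0}
        census = OriginCensus(counts=counts, n_pairs=10)
        c = steady_state_correction(0.0, census, phylo)
        assert c.corrected_root_fraction == c.raw_root_fraction == 0.7

    def test_single_branch_linear_subtraction(self):
        # isolate one branch: all pairs ancient, only the primate stem
        # has nonzero Ks, so expected gains = g * 100 * 0.5 = 10 pairs
        ks = {b: 0.0 for b in DEFAULT_KS}
        ks["primates"] = 0.5
        phylo = Phylogeny(branch_ks=ks)
        counts = {"root": 100, "euarchontoglires": 0, "primates": 0,
                  "human-chimp": 0, "human": 0}
        census = OriginCensus(counts=counts, n_pairs=100)
        c = steady_state_correction(0.2, census, phylo)
        assert c.corrected_root_fraction == pytest.approx(0.9 * c.raw_root_fraction)

    def test_floor_at_zero(self, phylo):
        counts = {"root": 10, "euarchontoglires": 0, "primates": 0,
                  "human-chimp": 0, "human": 0}
        census = OriginCensus(counts=counts, n_pairs=10)
        c = steady_state_correction(100.0, census, phylo)
        assert c.corrected_root_fraction == 0.0

    def test_negative_rate_rejected(self, phylo):
        counts = {"root": 1, "euarchontoglires": 0, "primates": 0,
                  "human-chimp": 0, "human": 0}
        census = OriginCensus(counts=counts, n_pairs=1)
        with pytest.raises(ValueError):
            steady_state_correction(-0.1, census, phylo)


class TestValidationAnalyses:
    def test_concerted_requires_replicates(self, dataset):
        with pytest.raises(ValueError):
            concerted_presence_test(dataset.network, dataset.presence, n_null=0)

    def test_concerted_detects_planted_shared_loss(self, phylo):
        # partners lose orthologs in the same species: concordance high
        rng = np.random.default_rng(0)
        entries = {}
        edges = []
        for i in range(120):
            a, b = f"a{i}", f"b{i}"
            lost = {s for s in SPECIES[1:] if rng.random() < 0.35}
            entries[a] = set(SPECIES) - lost
            entries[b] = set(SPECIES) - lost
            edges.append((a, b))
        r = concerted_presence_test(
            InteractionNetwork(edges=edges),
            PresenceMatrix.from_dict(entries),
            n_null=99,
            seed=4,
        )
        assert r.pooled.p_empirical <= 0.01
        assert set(r.per_species) == set(SPECIES) - {"human"}

    def test_degree_age_needs_three_classes(self, phylo):
        m = PresenceMatrix.from_dict({"a": set(SPECIES), "b": set(SPECIES)})
        net = InteractionNetwork(edges=[("a", "b")])
        with pytest.raises(ValueError, match=">=3"):
            degree_age_correlation(net, m, phylo, n_null=5)

    def test_degree_age_detects_old_hubs(self):
        cfg = SimulationConfig(n_genes=250, age_coupled_degrees=True, loss_rate=0.05)
        ds = simulate_dataset(cfg, seed=9)
        r = degree_age_correlation(
            ds.network, ds.presence, ds.phylo, n_null=99, seed=1
        )
        assert r.perm.observed > 0  # older classes have higher mean degree
        assert r.perm.p_empirical < 0.05
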