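"""Mirrortree construction, correlations and the permutation tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from netpaleo.coevolution import (
    DEFAULT_CLADES,
    build_mirrortree,
    clade_removal_scan,
    filter_omega,
    mean_rho_test,
    pair_correlation,
    shared_selection_test,
)
from netpaleo.data import BranchOmegaTable, InteractionNetwork, MirrorTree
from netpaleo.phylogeny import BRANCHES
from netpaleo.synthetic import SimulationConfig, simulate_dataset


def _mirror(wa, wb, branches=None):
    branches = tuple(branches or BRANCHES[: len(wa)])
    return MirrorTree(
        pair=("a", "b"),
        branches=branches,
        omega_a=np.asarray(wa, dtype=float),
        omega_b=np.asarray(wb, dtype=float),
    )


class TestMirrorTree:
    def test_intersection_of_branch_sets(self):
        table = BranchOmegaTable(
            {
                "a": {b: 0.1 for b in BRANCHES},
                "b": {b: 0.2 for b in BRANCHES[:10]},
            }
        )
        m = build_mirrortree(("a", "b"), table)
        assert m.n_branches == 10
        assert m.branches == BRANCHES[:10]

    def test_disjoint_sets_give_empty_mirror(self):
        table = BranchOmegaTable(
            {"a": {"human": 0.1}, "b": {"mouse": 0.2}}
        )
        assert build_mirrortree(("a", "b"), table).n_branches == 0

    def test_unknown_gene_errors(self):
        table = BranchOmegaTable({"a": {"human": 0.1}})
        with pytest.raises(KeyError):
            build_mirrortree(("a", "zz"), table)

    def test_vectors_match_table_values(self, dataset):
        a, b = dataset.network.pairs()[0]
        m = build_mirrortree((a, b), dataset.branch_omega)
        for br, wa, wb in zip(m.branches, m.omega_a, m.omega_b):
            assert wa == dataset.branch_omega.omega(m.pair[0], br)
            assert wb == dataset.branch_omega.omega(m.pair[1], br)


class TestFilterOmega:
    def test_infinite_cutoff_is_identity(self):
        m = _mirror([0.1, 0.2, 7.0], [0.3, 6.0, 0.1])
        out = filter_omega(m, np.inf)
        assert out.branches == m.branches

    def test_branch_dropped_when_either_member_exceeds(self):
        m = _mirror([0.2, 0.1], [5.0, 0.1])
        out = filter_omega(m, 5.0)
        assert out.n_branches == 1 and out.omega_b[0] == 0.1

    def test_all_branches_filtered(self):
        m = _mirror([6.0, 7.0], [6.0, 7.0])
        assert filter_omega(m, 5.0).n_branches == 0


class TestPairCorrelation:
    def test_identical_vectors_give_rho_one(self):
        v = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        assert pair_correlation(_mirror(v, v)) == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        v = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        assert pair_correlation(_mirror(v, v[::-1])) == pytest.approx(-1.0)

    def test_near_perfect_rank_agreement(self):
        # rank-formula oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)) with
        # d = (0,0,0,0,1,-1) -> 1 - 12/210
        rho = pair_correlation(_mirror([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 6, 5]))
        assert rho == pytest.approx(1 - 6 * 2 / (6 * 35))

    def test_short_or_constant_vectors_excluded(self):
        assert pair_correlation(_mirror([1, 2, 3], [1, 2, 3])) is None
        assert pair_correlation(_mirror([1] * 6, [1, 2, 3, 4, 5, 6])) is None

    def test_agrees_with_scipy_spearman(self, rng):
        for _ in range(20):
            a = rng.random(9)
            b = rng.random(9)
            ours = pair_correlation(_mirror(a, b))
            ref = stats.spearmanr(a, b).statistic
            assert ours == pytest.approx(ref)

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=4.0, allow_nan=False),
            min_size=6,
            max_size=13,
            unique=True,
        ),
        st.integers(min_value=0, max_value=1000),
    )
    def test_invariant_under_monotone_transforms(self, values, seed):
        r = np.random.default_rng(seed)
        a = np.array(values)
        b = r.permutation(a)
        base = pair_correlation(_mirror(a, b))
        warped = pair_correlation(_mirror(np.exp(a), np.sqrt(b)))
        assert warped == pytest.approx(base)


class TestMeanRhoTest:
    def test_bit_reproducible_under_seed(self, dataset):
        r1 = mean_rho_test(dataset.network, dataset.branch_omega, n_null=30, seed=5)
        r2 = mean_rho_test(dataset.network, dataset.branch_omega, n_null=30, seed=5)
        assert r1.mean_rho == r2.mean_rho
        assert np.array_equal(r1.perm.null_values, r2.perm.null_values)

    def test_excluding_all_branches_errors(self, dataset):
        with pytest.raises(ValueError):
            mean_rho_test(
                dataset.network,
                dataset.branch_omega,
                n_null=5,
                excluded_branches=frozenset(BRANCHES),
            )

    def test_planted_signal_detected(self):
        cfg = SimulationConfig(
            n_genes=200, coevolution_rho=0.6, coevolution_fraction=1.0, loss_rate=0.0
        )
        ds = simulate_dataset(cfg, seed=21)
        res = mean_rho_test(ds.network, ds.branch_omega, n_null=99, seed=2)
        assert res.difference > 0
        assert res.perm.p_empirical <= 0.05

    def test_matches_per_pair_oracle(self, dataset):
        # observed mean equals the mean over per-pair correlations
        # computed one at a time through the scalar path
        res = mean_rho_test(dataset.network, dataset.branch_omega, n_null=1, seed=0)
        rhos = []
        for a, b in dataset.network.pairs():
            if a not in dataset.branch_omega or b not in dataset.branch_omega:
                continue
            m = filter_omega(build_mirrortree((a, b), dataset.branch_omega), 5.0)
            r = pair_correlation(m, min_branches=6)
            if r is not None:
                rhos.append(r)
        assert res.n_pairs == len(rhos)
        assert res.mean_rho == pytest.approx(np.mean(rhos))

    def test_pearson_inflated_by_outlier_branch(self):
        # one extreme-outlier shared branch inflates Pearson r while
        # Spearman stays stable
        rng = np.random.default_rng(4)
        table = {}
        edges = []
        for i in range(60):
            a, b = f"a{i}", f"b{i}"
            wa = rng.uniform(0.05, 0.4, 13)
            wb = rng.uniform(0.05, 0.4, 13)
            wa[-1] = wb[-1] = 4.5  # shared outlier branch
            table[a] = dict(zip(BRANCHES, wa))
            table[b] = dict(zip(BRANCHES, wb))
            edges.append((a, b))
        net = InteractionNetwork(edges=edges)
        tab = BranchOmegaTable(table)
        pear = mean_rho_test(net, tab, n_null=1, seed=0, method="pearson")
        spear = mean_rho_test(net, tab, n_null=1, seed=0, method="spearman")
        assert pear.mean_rho > spear.mean_rho + 0.2


class TestCladeRemoval:
    def test_no_removal_reproduces_full_row(self, dataset):
        rows = clade_removal_scan(
            dataset.network,
            dataset.branch_omega,
            clades={"Mouse": frozenset({"mouse"})},
            n_null=20,
            seed=9,
        )
        full = mean_rho_test(dataset.network, dataset.branch_omega, n_null=20, seed=9)
        assert rows[0].clade == "None"
        assert rows[0].mean_rho == full.mean_rho
        assert rows[0].mean_of_means == full.mean_of_means

    def test_unknown_clade_branch_errors(self, dataset):
        with pytest.raises(ValueError, match="unknown"):
            clade_removal_scan(
                dataset.network,
                dataset.branch_omega,
                clades={"Atlantis": frozenset({"kraken"})},
                n_null=2,
            )

    def test_default_clade_map_well_formed(self):
        for name, branches in DEFAULT_CLADES.items():
            assert branches <= set(BRANCHES), name


class TestSharedSelection:
    def test_threshold_above_every_omega(self, dataset):
        r = shared_selection_test(
            dataset.network, dataset.branch_omega, "mouse", threshold=1e6
        )
        assert r.observed == 0 and r.expected == 0.0 and not r.valid

    def test_hand_computed_chi_square(self):
        # 300 pairs; exceedance frequency 0.25 on each side; 30
        # concordant observed vs 18.75 expected:
        # chi2 = (30-18.75)^2/18.75 + (270-281.25)^2/281.25 = 7.2
        edges = []
        table = {}
        k = 0
        for first_hi in (True, False):
            for second_hi in (True, False):
                if first_hi and second_hi:
                    n_cell = 30
                elif first_hi:
                    n_cell = 45
                elif second_hi:
                    n_cell = 45
                else:
                    n_cell = 180
                for _ in range(n_cell):
                    a, b = f"a{k:03d}", f"b{k:03d}"
                    table[a] = {"human": 2.0 if first_hi else 0.1}
                    table[b] = {"human": 2.0 if second_hi else 0.1}
                    edges.append((a, b))
                    k += 1
        r = shared_selection_test(
            InteractionNetwork(edges=edges),
            BranchOmegaTable(table),
            "human",
            threshold=1.0,
        )
        assert r.n_pairs == 300
        assert (r.observed, r.expected) == (30, pytest.approx(18.75))
        assert r.chi2 == pytest.approx(7.2)
        assert r.p == pytest.approx(stats.chi2.sf(7.2, 1) / 2)

    def test_below_minimum_pairs_flagged(self):
        table = {f"g{i}": {"human": 0.7} for i in range(8)}
        net = InteractionNetwork(edges=[(f"g{2*i}", f"g{2*i+1}") for i in range(4)])
        r = shared_selection_test(net, BranchOmegaTable(table), "human", 0.5)
        assert not r.valid and r.p is None
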