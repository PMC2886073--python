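"""Permutation tests, Abouheif's C_mean and the Hochberg correction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phylodiv as pv
from phylodiv.inference import InferenceError, abouheif_proximity
from phylodiv.synthetic import simulate_bm_trait, simulate_yule_topology


def exact_left_p(stat_fn, values, observed):
    """Exhaustive permutation probability Pr(stat <= observed)."""
    stats = [stat_fn(perm) for perm in itertools.permutations(values)]
    return float(np.mean(np.asarray(stats) <= observed + 1e-10))


class TestConservationTest:
    @pytest.fixture
    def setup(self, cherry_enlarged):
        z, _ = pv.standardize([0.0, 2.0, 4.0, 6.0])
        labels = ["A::1", "A::2", "C", "D"]
        return cherry_enlarged, labels, dict(zip(labels, z))

    def test_exhaustive_null_probability_half(self, setup):
        enl, labels, tv = setup
        res = pv.conservation_test(enl, tv, n_perm=2000, seed=7)
        assert res.observed == pytest.approx(0.1)

        def sc_of(perm):
            dec = pv.decompose_diversity(enl, dict(zip(labels, perm)))
            return pv.sc_statistic(dec, enl.artificial_nodes).value

        exact = exact_left_p(sc_of, list(tv.values()), res.observed)
        assert exact == pytest.approx(0.5)
        # Monte-Carlo p within 3 standard errors of the exact probability
        se = np.sqrt(exact * (1 - exact) / res.n_perm)
        assert abs(res.p_value - exact) <= 3 * se

    def test_left_tail_boundary_smallest_p(self, setup):
        # observed at the null minimum: only ties count, p is the tie mass
        enl, labels, _ = setup
        z, _ = pv.standardize([0.0, 0.0, 5.0, -5.0])
        tv = dict(zip(labels, z))  # replicate pair identical -> S_c minimal
        res = pv.conservation_test(enl, tv, n_perm=500, seed=3)

        def sc_of(perm):
            dec = pv.decompose_diversity(enl, dict(zip(labels, perm)))
            return pv.sc_statistic(dec, enl.artificial_nodes).value

        exact = exact_left_p(sc_of, list(tv.values()), res.observed)
        se = np.sqrt(exact * (1 - exact) / res.n_perm)
        assert res.p_value >= 1 / (res.n_perm + 1)
        assert abs(res.p_value - exact) <= 3 * se + 1 / res.n_perm

    def test_determinism_same_seed(self, setup):
        enl, _, tv = setup
        a = pv.conservation_test(enl, tv, n_perm=99, seed=11)
        b = pv.conservation_test(enl, tv, n_perm=99, seed=11)
        np.testing.assert_array_equal(a.null_sample, b.null_sample)
        assert a.p_value == b.p_value

    def test_requires_artificial_nodes(self, balanced4):
        enl = pv.enlarge_with_replicates(balanced4, {})
        with pytest.raises(InferenceError):
            pv.conservation_test(enl, {t: float(i) for i, t in enumerate("ABCD")},
                                 n_perm=99, seed=0)

    def test_type_one_error_exchangeable(self):
        # 5 species x 3 populations, iid values: rejection rate at 0.05
        # must fall in the binomial 95% interval (reduced-size version;
        # the full-size check lives in the acceptance suite)
        tree = simulate_yule_topology(5, seed=42)
        species = [tree.tip_label[t] for t in tree.tips]
        enl = pv.enlarge_with_replicates(
            tree, {sp: ["p1", "p2", "p3"] for sp in species}
        )
        labels = [enl.tree.tip_label[t] for t in enl.tree.tips]
        rng = np.random.default_rng(99)
        n_data = 150
        rej = 0
        for _ in range(n_data):
            vals = rng.standard_normal(len(labels))
            res = pv.conservation_test(
                enl, dict(zip(labels, vals)), n_perm=199,
                seed=int(rng.integers(2**31)),
            )
            rej += res.p_value <= 0.05
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_data)
        assert abs(rej / n_data - 0.05) <= ci


class TestSkewnessToRootTest:
    def test_root_concentrated_diversity_small_p(self):
        # two constant half-clades: all diversity at the root, S_3 = 0; a
        # permutation reproduces S_3 <= 0 only if both halves stay constant
        # (probability 2 * 6!6!/12!), so the lower tail is extreme
        tree = pv.parse_newick(
            "(((A,(B,C)),(D,(E,F))),((G,(H,I)),(J,(K,L))));"
        )
        enl = pv.enlarge_with_replicates(tree, {})
        ranks = pv.depth_ranks(tree, enl)
        tv = {t: (1.0 if t in "ABCDEF" else -1.0) for t in "ABCDEFGHIJKL"}
        res = pv.skewness_to_root_test(enl, tv, ranks, n_perm=999, seed=2)
        assert res.observed == pytest.approx(0.0)
        assert res.alternative == "two-sided"
        assert res.p_value < 0.05

    def test_doubling_rule_arithmetic(self, balanced4):
        # with p_low = r/(N+1) small, p = 2 * p_low, capped at 1
        enl = pv.enlarge_with_replicates(balanced4, {})
        ranks = pv.depth_ranks(balanced4, enl)
        tv = {"A": 1.0, "B": 1.0, "C": -1.0, "D": -1.0}
        res = pv.skewness_to_root_test(enl, tv, ranks, n_perm=999, seed=2)
        r_low = int(np.sum(res.null_sample <= res.observed + 1e-10))
        r_high = int(np.sum(res.null_sample >= res.observed - 1e-10))
        expected = min(
            1.0,
            2.0 * min((r_low + 1) / 1000, (r_high + 1) / 1000),
        )
        assert res.p_value == pytest.approx(expected)

    def test_type_one_error_exchangeable(self):
        tree = simulate_yule_topology(8, seed=17)
        enl = pv.enlarge_with_replicates(
            tree, {tree.tip_label[t]: ["p1", "p2"] for t in tree.tips[:3]}
        )
        ranks = pv.depth_ranks(tree, enl)
        labels = [enl.tree.tip_label[t] for t in enl.tree.tips]
        rng = np.random.default_rng(123)
        n_data = 150
        rej = 0
        for _ in range(n_data):
            vals = rng.standard_normal(len(labels))
            res = pv.skewness_to_root_test(
                enl, dict(zip(labels, vals)), ranks, n_perm=199,
                seed=int(rng.integers(2**31)),
            )
            rej += res.p_value <= 0.05
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_data)
        # two-sided doubling is slightly conservative; allow the low side
        assert rej / n_data <= 0.05 + ci

    def test_determinism(self, balanced4):
        enl = pv.enlarge_with_replicates(balanced4, {})
        ranks = pv.depth_ranks(balanced4, enl)
        tv = {"A": 0.3, "B": -1.2, "C": 0.8, "D": 0.1}
        a = pv.skewness_to_root_test(enl, tv, ranks, n_perm=99, seed=4)
        b = pv.skewness_to_root_test(enl, tv, ranks, n_perm=99, seed=4)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_sample, b.null_sample)


class TestAbouheifCmean:
    def test_balanced_tree_hand_computation(self, balanced4, balanced4_values):
        # within-cherry proximity 1/2, cross-cherry 1/8 -> C_mean = 2/15
        A, labels = abouheif_proximity(balanced4)
        i = {lab: k for k, lab in enumerate(labels)}
        assert A[i["A"], i["B"]] == pytest.approx(0.5)
        assert A[i["A"], i["C"]] == pytest.approx(1 / 8)
        assert np.all(np.diag(A) == 0)
        assert pv.abouheif_cmean(balanced4, balanced4_values) == \
            pytest.approx(2 / 15)

    def test_discordant_cherries_lower_statistic(self, balanced4):
        concordant = {"A": 0.0, "B": 2.0, "C": 4.0, "D": 6.0}
        discordant = {"A": 0.0, "B": 6.0, "C": 2.0, "D": 4.0}
        assert pv.abouheif_cmean(balanced4, discordant) < \
            pv.abouheif_cmean(balanced4, concordant)

    @pytest.mark.parametrize("n", [4, 7])
    def test_star_tree_closed_form(self, n):
        newick = "(" + ",".join(f"t{i}" for i in range(n)) + ");"
        star = pv.parse_newick(newick)
        rng = np.random.default_rng(n)
        values = {f"t{i}": float(v) for i, v in enumerate(rng.standard_normal(n))}
        assert pv.abouheif_cmean(star, values) == pytest.approx(-1 / (n - 1))

    def test_constant_values_rejected(self, balanced4):
        with pytest.raises(InferenceError):
            pv.abouheif_cmean(balanced4, {t: 1.0 for t in "ABCD"})


class TestAbouheifTest:
    def test_exhaustive_agreement_small_tree(self):
        tree = pv.parse_newick("((A,B),(C,(D,E)));")
        values = {"A": 0.1, "B": 0.4, "C": -1.2, "D": 2.0, "E": 1.7}
        res = pv.abouheif_test(tree, values, n_perm=2000, seed=13)
        labels = sorted(values)
        base = [values[l] for l in labels]
        stats = [
            pv.abouheif_cmean(tree, dict(zip(labels, perm)))
            for perm in itertools.permutations(base)
        ]
        exact = float(np.mean(np.asarray(stats) >= res.observed - 1e-10))
        se = np.sqrt(exact * (1 - exact) / res.n_perm)
        assert abs(res.p_value - exact) <= 3 * se

    def test_power_on_clustered_trait(self):
        hits = 0
        n_data = 40
        for i in range(n_data):
            tree = simulate_yule_topology(32, seed=1000 + i)
            values = simulate_bm_trait(tree, 1.0, seed=2000 + i)
            res = pv.abouheif_test(tree, values, n_perm=199, seed=3000 + i)
            hits += res.p_value <= 0.05
        assert hits / n_data >= 0.85

    def test_type_one_error_iid(self):
        tree = simulate_yule_topology(15, seed=5)
        labels = [tree.tip_label[t] for t in tree.tips]
        rng = np.random.default_rng(77)
        n_data = 150
        rej = 0
        for _ in range(n_data):
            vals = dict(zip(labels, rng.standard_normal(len(labels))))
            res = pv.abouheif_test(tree, vals, n_perm=199,
                                   seed=int(rng.integers(2**31)))
            rej += res.p_value <= 0.05
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_data)
        assert abs(rej / n_data - 0.05) <= ci

    def test_determinism(self, balanced4, balanced4_values):
        a = pv.abouheif_test(balanced4, balanced4_values, n_perm=99, seed=21)
        b = pv.abouheif_test(balanced4, balanced4_values, n_perm=99, seed=21)
        assert a.p_value == b.p_value


class TestHochberg:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            pv.hochberg_adjust([0.01, 0.02, 0.30]), [0.03, 0.04, 0.30]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(pv.hochberg_adjust([0.4]), [0.4])

    def test_all_ones_capped(self):
        np.testing.assert_allclose(pv.hochberg_adjust([1.0, 1.0, 1.0]),
                                   [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(InferenceError):
            pv.hochberg_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_never_decreases_and_preserves_order(self, pvals):
        adj = pv.hochberg_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_step_up_definition(self):
        # independent re-derivation: adjusted_(i) = min_{j>=i} (m-j+1) p_(j)
        rng = np.random.default_rng(8)
        p = rng.uniform(size=9)
        order = np.argsort(p)
        m = p.size
        sorted_adj = np.minimum.accumulate(
            ((m - np.arange(m)) * p[order])[::-1]
        )[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(sorted_adj, 1.0)
        np.testing.assert_allclose(pv.hochberg_adjust(p), expected, atol=1e-12)
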