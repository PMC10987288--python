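import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from microcoalesce import anosim, bh_fdr, bray_curtis, bray_curtis_matrix, nmds, shannon, shared_fraction
from microcoalesce.divstats import (
    DistanceMatrix,
    StatsError,
    anosim_exact,
    anosim_r,
    axis_group_test,
)


def random_distance_matrix(n, seed, dims=4):
    pts = np.random.default_rng(seed).normal(size=(n, dims))
    return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)))


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([5, 0, 0], 0.0),
            ([1, 1, 2], 1.0397),  # -(0.25 ln 0.25 * 2 + 0.5 ln 0.5)
        ],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon(np.array(counts)) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_errors(self):
        with pytest.raises(StatsError):
            shannon(np.zeros(3))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=20))
    def test_bounds(self, counts):
        counts = np.array(counts)
        if counts.sum() == 0:
            return
        h = shannon(counts)
        assert 0 <= h <= np.log(np.count_nonzero(counts)) + 1e-12


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis(np.array([3, 1, 4]), np.array([3, 1, 4])) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis(np.array([5, 0]), np.array([0, 7])) == 1.0

    def test_hand_value(self):
        assert bray_curtis(np.array([1, 1, 0]), np.array([0, 1, 1])) == pytest.approx(0.5)

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(10, 6)) + 1
        dm = bray_curtis_matrix(counts, [f"s{i}" for i in range(6)])
        assert np.all((dm.data >= 0) & (dm.data <= 1))
        # matches the pairwise scalar formula
        for i, j in itertools.combinations(range(6), 2):
            assert dm.data[i, j] == pytest.approx(bray_curtis(counts[:, i], counts[:, j]))

    def test_zero_total_errors(self):
        with pytest.raises(StatsError):
            bray_curtis(np.zeros(3), np.array([1.0, 0, 0]))


class TestNmds:
    def test_planar_configuration_recovered(self):
        dm = random_distance_matrix(12, seed=0, dims=2)
        res = nmds(dm, seed=3)
        assert res.stress < 0.01

    def test_seeded_determinism(self):
        dm = random_distance_matrix(10, seed=1)
        a = nmds(dm, seed=9)
        b = nmds(dm, seed=9)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_degenerate_distances_rejected(self):
        d = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(StatsError):
            nmds(DistanceMatrix([f"s{i}" for i in range(5)], d))


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # two tight pairs far apart: every between-distance > every within
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        dm = DistanceMatrix(["a", "b", "c", "d"], squareform(pdist(pts)))
        res = anosim(dm, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_null_r_centred_on_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for i in range(1000):
            dm = random_distance_matrix(12, seed=2000 + i)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            rs.append(anosim_r(dm, labels))
        assert abs(np.mean(rs)) < 0.05

    def test_min_p_is_one_over_nperm_plus_one(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1], [20.0], [20.1]])
        dm = DistanceMatrix([f"s{i}" for i in range(6)], squareform(pdist(pts)))
        res = anosim(dm, ["a", "a", "a", "b", "b", "b"], n_permutations=999, seed=0)
        assert res.p >= 1 / 1000

    def test_matches_brute_force_enumeration(self):
        """Exact null distribution agrees with an independent double-loop oracle."""
        dm = random_distance_matrix(7, seed=5)
        labels = np.array(["a", "a", "a", "b", "b", "b", "b"])

        def oracle_r(d, lab):
            n = len(lab)
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            ranks = rankdata([d[i, j] for i, j in pairs])
            rw = np.mean([r for r, (i, j) in zip(ranks, pairs) if lab[i] == lab[j]])
            rb = np.mean([r for r, (i, j) in zip(ranks, pairs) if lab[i] != lab[j]])
            return (rb - rw) / (n * (n - 1) / 4)

        obs = oracle_r(dm.data, labels)
        hits = total = 0
        for perm in itertools.permutations(range(7)):
            total += 1
            if oracle_r(dm.data, labels[list(perm)]) >= obs - 1e-12:
                hits += 1
        exact = anosim_exact(dm, labels)
        assert exact.r == pytest.approx(obs)
        assert exact.p == pytest.approx(hits / total)
        # Monte-Carlo p converges to the exact p
        mc = anosim(dm, labels, n_permutations=999, seed=0)
        assert mc.p == pytest.approx(exact.p, abs=0.05)

    def test_matches_scikit_bio_r(self):
        """Cross-check the R statistic against the independent skbio implementation."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        dm = random_distance_matrix(12, seed=8)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = anosim(dm, labels, n_permutations=99, seed=0)
        theirs = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(dm.data, dm.sample_ids),
            grouping=list(labels),
            permutations=99,
        )
        assert ours.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_group_requirements(self):
        dm = random_distance_matrix(5, seed=0)
        with pytest.raises(StatsError):
            anosim(dm, ["a"] * 5)
        with pytest.raises(StatsError):
            anosim(dm, ["a", "a", "a", "a", "b"])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_worked_stepup(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_fdr([0.0, 0.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=15))
    def test_q_at_least_p(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1 + 1e-12)


class TestSharedFraction:
    @pytest.mark.parametrize(
        "src,gut,expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a", "b"}, {"c"}, 0.0),
            ({"a", "b", "c", "d"}, {"a", "b", "c", "x"}, 0.75),
        ],
    )
    def test_values(self, src, gut, expected):
        assert shared_fraction(src, gut) == expected

    def test_empty_source_errors(self):
        with pytest.raises(StatsError):
            shared_fraction(set(), {"a"})


class TestAxisGroupTest:
    def test_complete_separation_tiny_p(self):
        coords = np.concatenate([np.arange(14), 100 + np.arange(14)])
        labels = ["a"] * 14 + ["b"] * 14
        assert axis_group_test(coords, labels) < 1e-6

    def test_identical_multisets_p_one(self):
        coords = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        labels = ["a", "a", "a", "b", "b", "b"]
        assert axis_group_test(coords, labels) == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        swapped = np.where(labels == "a", "b", "a")
        assert axis_group_test(coords, labels) == pytest.approx(
            axis_group_test(coords, swapped)
        )
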