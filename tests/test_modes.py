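"""LCS metric, distance matrices, clustering, and mode summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluxmodes as fm
from fluxmodes.dominance import DynamicFingerprint, SubnetworkRegistry, DominantSubnetwork
from fluxmodes.modes import NOISE_MODE


def brute_force_lcs(x, y):
    """Longest common subsequence by exhaustive subset enumeration."""
    def subsequences(s):
        out = set()
        for r in range(len(s) + 1):
            out.update(itertools.combinations(s, r))
        return out
    common = subsequences(tuple(x)) & subsequences(tuple(y))
    return max(len(c) for c in common)


class TestLcsLength:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [1, 3], 2),
        ([1, 1], [2, 2], 0),
        ([], [1, 2], 0),
        ([1, 2, 1, 2], [2, 1, 2, 1], 3),
    ])
    def test_known_values(self, x, y, expected):
        assert fm.lcs_length(x, y) == expected

    def test_self_lcs_is_length(self):
        x = [3, 1, 4, 1, 5, 9, 2, 6]
        assert fm.lcs_length(x, x) == len(x)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        x = rng.integers(0, 4, size=rng.integers(0, 9))
        y = rng.integers(0, 4, size=rng.integers(0, 9))
        assert fm.lcs_length(x, y) == brute_force_lcs(x, y)


class TestLcsDistance:
    def test_identity(self):
        assert fm.lcs_distance([1, 2, 3], [1, 2, 3]) == 0

    def test_known_value(self):
        assert fm.lcs_distance([1, 2, 3], [1, 3]) == 1

    def test_disjoint_alphabets(self):
        assert fm.lcs_distance([1, 1], [2, 2]) == 4

    seq = st.lists(st.integers(0, 5), max_size=12)

    @settings(max_examples=200, derandomize=True)
    @given(seq, seq, seq)
    def test_metric_axioms(self, x, y, z):
        dxy = fm.lcs_distance(x, y)
        assert dxy >= 0
        assert dxy == fm.lcs_distance(y, x)
        assert (dxy == 0) == (x == y)
        assert dxy <= fm.lcs_distance(x, z) + fm.lcs_distance(z, y)

    def test_metric_axioms_bulk_random_triples(self):
        """Identity/symmetry/triangle inequality over 1,000 random triples."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            x, y, z = (rng.integers(0, 5, size=rng.integers(1, 15))
                       for _ in range(3))
            dxy = fm.lcs_distance(x, y)
            assert dxy == fm.lcs_distance(y, x) >= 0
            assert fm.lcs_distance(x, x) == 0
            assert dxy <= fm.lcs_distance(x, z) + fm.lcs_distance(z, y)


class TestDistanceMatrix:
    def test_identical_fingerprints_give_zero_matrix(self):
        fps = [DynamicFingerprint([1, 2, 3], i) for i in range(4)]
        dm = fm.distance_matrix(fps)
        assert np.all(dm.values == 0)

    def test_duplicate_detection_pattern(self):
        fps = [DynamicFingerprint(s, i) for i, s in enumerate(
            [[1, 1, 1], [2, 2, 2], [1, 1, 1]])]
        dm = fm.distance_matrix(fps)
        assert dm.values[0, 2] == 0
        assert dm.values[0, 1] == 6
        np.testing.assert_array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_shape_is_n_by_n(self):
        fps = [DynamicFingerprint([i, i], i) for i in range(7)]
        assert fm.distance_matrix(fps).values.shape == (7, 7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fm.distance_matrix([DynamicFingerprint([1, 2], 0),
                                DynamicFingerprint([1], 1)])


def _two_group_dm(n1=5, n2=5):
    fps = [DynamicFingerprint([1] * 10, i) for i in range(n1)] + \
          [DynamicFingerprint([2] * 10, n1 + i) for i in range(n2)]
    return fm.distance_matrix(fps), fps


class TestCluster:
    def test_agglomerative_splits_duplicate_groups(self):
        dm, _ = _two_group_dm()
        labels = fm.cluster(dm, "agglomerative", n_clusters=2)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_spectral_splits_duplicate_groups(self):
        dm, _ = _two_group_dm()
        labels = fm.cluster(dm, "spectral", n_clusters=2, seed=0)
        assert labels[0] != labels[5]
        assert len(set(labels[:5])) == len(set(labels[5:])) == 1

    def test_hdbscan_identical_fingerprints_single_mode(self):
        fps = [DynamicFingerprint([1, 2, 3], i) for i in range(12)]
        labels = fm.cluster(fm.distance_matrix(fps), "hdbscan")
        non_noise = [l for l in labels if l != NOISE_MODE]
        assert len(set(non_noise)) <= 1

    def test_invalid_method_rejected(self):
        dm, _ = _two_group_dm()
        with pytest.raises(ValueError, match="unknown clustering method"):
            fm.cluster(dm, "kmeans", n_clusters=2)

    def test_too_many_clusters_rejected(self):
        dm, _ = _two_group_dm(2, 2)
        with pytest.raises(ValueError, match="exceeds"):
            fm.cluster(dm, "agglomerative", n_clusters=10)

    def test_assignments_invariant_to_permutation(self):
        dm, _ = _two_group_dm(4, 6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(dm.n)
        labels = fm.cluster(dm, "agglomerative", n_clusters=2)
        permuted = fm.cluster(fm.DistanceMatrix(dm.values[np.ix_(perm, perm)]),
                              "agglomerative", n_clusters=2)
        # same partition up to relabeling
        for i in range(dm.n):
            for j in range(dm.n):
                assert (labels[perm[i]] == labels[perm[j]]) == \
                    (permuted[i] == permuted[j])


class TestSelectNClusters:
    def test_two_well_separated_groups(self):
        dm, _ = _two_group_dm()
        assert fm.select_n_clusters(dm, k_range=range(2, 6)) == 2

    def test_all_identical_returns_one_with_warning(self):
        fps = [DynamicFingerprint([1, 1], i) for i in range(6)]
        with pytest.warns(UserWarning, match="identical"):
            assert fm.select_n_clusters(fm.distance_matrix(fps)) == 1

    def test_three_planted_regimes_select_three(self, planted_three_regimes,
                                                toy, toy_grid):
        ensemble, _ = planted_three_regimes
        fps, _, _ = fm.fingerprint_ensemble(toy, ensemble, toy_grid, "P",
                                            fm.DominanceConfig())
        dm = fm.distance_matrix(fps)
        assert fm.select_n_clusters(dm, k_range=range(2, 7)) == 3


class TestModeProbabilities:
    def test_uniform_weights_member_counts(self):
        ens = fm.ParameterEnsemble([fm.ParameterVector({"k": 1.0})
                                    for _ in range(4)])
        probs = fm.mode_probabilities(np.array([0, 0, 1, 2]), ens)
        assert probs == {0: 0.5, 1: 0.25, 2: 0.25}

    def test_explicit_weights_sum_per_mode(self):
        vecs = [fm.ParameterVector({"k": 1.0}, weight=w)
                for w in [0.4, 0.3, 0.2, 0.1]]
        ens = fm.ParameterEnsemble(vecs)
        probs = fm.mode_probabilities(np.array([0, 0, 1, 1]), ens)
        assert probs[0] == pytest.approx(0.7)
        assert probs[1] == pytest.approx(0.3)

    def test_sums_to_one_under_any_partition(self):
        rng = np.random.default_rng(5)
        vecs = [fm.ParameterVector({"k": 1.0}, weight=float(w))
                for w in rng.uniform(0, 1, 20)]
        ens = fm.ParameterEnsemble(vecs)
        for _ in range(5):
            assign = rng.integers(0, 4, 20)
            assert sum(fm.mode_probabilities(assign, ens).values()) == \
                pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_mode_relabeling(self):
        ens = fm.ParameterEnsemble([fm.ParameterVector({"k": 1.0})
                                    for _ in range(6)])
        a = fm.mode_probabilities(np.array([0, 0, 0, 1, 1, 2]), ens)
        b = fm.mode_probabilities(np.array([5, 5, 5, 9, 9, 7]), ens)
        assert sorted(a.values()) == sorted(b.values())

    def test_size_mismatch_rejected(self):
        ens = fm.ParameterEnsemble([fm.ParameterVector({"k": 1.0})])
        with pytest.raises(ValueError):
            fm.mode_probabilities(np.array([0, 1]), ens)


class TestRepresentativeSubnetwork:
    def _registry(self):
        reg = SubnetworkRegistry()
        for edges in [{("A", "P")}, {("B", "P")}, {("C", "P")},
                      {("D", "P")}, {("E", "P")}]:
            reg.label_for(DominantSubnetwork("P", frozenset(edges)))
        return reg

    def test_constant_label_mode(self):
        reg = self._registry()
        fps = [DynamicFingerprint([3, 3, 3], i) for i in range(3)]
        assert fm.representative_subnetwork(fps, reg).label == 3

    def test_majority_label_wins(self):
        reg = self._registry()
        fps = [DynamicFingerprint([3] * 10 + [5] * 2, 0)]
        assert fm.representative_subnetwork(fps, reg).label == 3

    def test_tie_breaks_to_smaller_label(self):
        reg = self._registry()
        fps = [DynamicFingerprint([3] * 6 + [5] * 6, 0)]
        assert fm.representative_subnetwork(fps, reg).label == 3
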