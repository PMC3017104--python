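"""Normalized-MI identities, Z-score standardisation, tree-shuffle null."""

import math

import numpy as np
import pytest

from stabcons.coevolution import (
    CoevolPair,
    ShuffleNullSpec,
    annotate_spatial_class,
    joint_entropy,
    normalized_mi,
    significant_pairs,
    tree_shuffle_null,
    zscores_all_pairs,
)
from stabcons.msa import WeightedMSA, henikoff_weights
from stabcons.phylo import DistanceMatrix, kimura_distance_matrix
from stabcons.structure import AtomRecord
from stabcons.synthetic import SyntheticSpec, gen_iid_alignment, gen_msa


def weighted(rows, ids=None):
    msa = WeightedMSA(ids=ids or [f"s{k}" for k in range(len(rows))], rows=rows)
    henikoff_weights(msa)
    return msa


class TestJointEntropy:
    def test_identical_two_symbol_columns(self):
        msa = weighted(["AA", "AA", "VV", "VV"])
        assert joint_entropy(msa, 0, 1) == pytest.approx(math.log(2), rel=1e-12)

    def test_independent_uniform_columns(self):
        msa = weighted(["AA", "AV", "VA", "VV"])
        assert joint_entropy(msa, 0, 1) == pytest.approx(math.log(4), rel=1e-12)

    def test_brute_force_enumeration_oracle(self):
        msa = weighted(["AC", "AD", "VC"])
        w = msa.weights
        # direct weighted joint frequency count
        from collections import Counter

        freq = Counter()
        for wi, row in zip(w, msa.rows):
            freq[(row[0], row[1])] += wi
        total = sum(freq.values())
        oracle = -sum((v / total) * math.log(v / total) for v in freq.values())
        assert joint_entropy(msa, 0, 1) == pytest.approx(oracle, rel=1e-12)


class TestNormalizedMI:
    def test_duplicated_column_is_one(self):
        msa = weighted(["AA", "VV", "AA", "LL"])
        mi, mi_norm = normalized_mi(msa, 0, 1)
        assert mi_norm == pytest.approx(1.0, rel=1e-12)

    def test_independent_exact_product_is_zero(self):
        msa = weighted(["AA", "AV", "VA", "VV"])
        mi, mi_norm = normalized_mi(msa, 0, 1)
        assert mi == pytest.approx(0.0, abs=1e-12)
        assert mi_norm == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_zero_rule(self):
        msa = weighted(["GA", "GV", "GA", "GL"])
        mi, mi_norm = normalized_mi(msa, 0, 1)
        assert mi == 0.0 and mi_norm == 0.0

    def test_symmetry_exact(self):
        msa, _, _ = gen_msa(SyntheticSpec(seed=6, n_positions=10, n_sequences=32))
        henikoff_weights(msa)
        for i, j in [(0, 3), (2, 9), (4, 5)]:
            assert normalized_mi(msa, i, j) == normalized_mi(msa, j, i)

    def test_mi_identities_random_columns(self):
        """mi >= 0, mi <= min(H_i, H_j) + eps, mi_norm in [0, 1] on fuzz columns."""
        rng = np.random.default_rng(12)
        aa = "ACDEFGHIKLMNQRSTVWY"
        for _ in range(300):
            n = rng.integers(5, 40)
            rows = [
                "".join(rng.choice(list(aa), size=2)) for _ in range(n)
            ]
            msa = weighted(rows, ids=[f"s{k}" for k in range(n)])
            mi, mi_norm = normalized_mi(msa, 0, 1)
            hi = joint_entropy(msa, 0, 0) / 2  # H(i,i) = H(i) for the diag trick
            assert mi >= -1e-12
            assert 0.0 <= mi_norm <= 1.0

    def test_mi_bounded_by_marginals(self):
        from stabcons.coevolution import _encode_column, _entropy_from_weights, _K

        msa, _, _ = gen_msa(SyntheticSpec(seed=8, n_positions=12, n_sequences=64))
        henikoff_weights(msa)
        w = np.asarray(msa.weights)
        for i, j in [(0, 1), (3, 7), (5, 11)]:
            ci, cj = _encode_column(msa, i), _encode_column(msa, j)
            h_i = _entropy_from_weights(ci, w, _K)
            h_j = _entropy_from_weights(cj, w, _K)
            mi, _ = normalized_mi(msa, i, j)
            assert mi <= min(h_i, h_j) + 1e-9


class TestZScores:
    def test_standardisation_by_construction(self):
        msa = gen_iid_alignment(60, 12, seed=3)
        henikoff_weights(msa)
        pairs = zscores_all_pairs(msa)
        z = np.array([p.z for p in pairs])
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1) < 1e-9

    def test_planted_pair_has_maximal_z(self):
        spec = SyntheticSpec(seed=13, n_positions=20, n_sequences=128,
                             planted_pairs=[((4, 15), 0.9)])
        msa, _, _ = gen_msa(spec)
        henikoff_weights(msa)
        pairs = zscores_all_pairs(msa)
        assert (pairs[0].i, pairs[0].j) == (4, 15)

    def test_degenerate_alignment_rejected(self):
        msa = weighted(["AAA", "AAA", "AAA"])
        with pytest.raises(ValueError, match="degenerate"):
            zscores_all_pairs(msa)


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(seed=21, n_positions=12, n_sequences=96,
                         planted_pairs=[((2, 9), 0.9)])
    msa, _, _ = gen_msa(spec)
    henikoff_weights(msa)
    dist = kimura_distance_matrix(msa, on_saturation="cap")
    return msa, dist


class TestTreeShuffleNull:

    def test_column_multiset_preserved(self, planted):
        msa, dist = planted
        spec = ShuffleNullSpec(n_iterations=20, n_shuffles_per_iteration=200, seed=4)
        from stabcons.coevolution import _encode_column

        _, _, cols = tree_shuffle_null(msa, dist, 2, 9, spec, collect_columns=True)
        original = np.sort(_encode_column(msa, 9))
        for col in cols:
            assert np.array_equal(np.sort(col), original)

    def test_planted_pair_significant(self, planted):
        msa, dist = planted
        p, _ = tree_shuffle_null(msa, dist, 2, 9, ShuffleNullSpec(seed=1))
        assert p <= 0.05

    def test_uncoupled_pair_large_p(self, planted):
        """Observed mi_norm at/below the null median gives p > 0.5."""
        msa, dist = planted
        p, null = tree_shuffle_null(msa, dist, 0, 1, ShuffleNullSpec(seed=2))
        assert p > 0.5 or normalized_mi(msa, 0, 1)[1] > np.median(null)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ShuffleNullSpec(decay_lambda=-1.0)

    def test_deterministic_given_seed(self, planted):
        msa, dist = planted
        spec = ShuffleNullSpec(n_iterations=25, n_shuffles_per_iteration=100, seed=9)
        p1, n1 = tree_shuffle_null(msa, dist, 2, 9, spec)
        p2, n2 = tree_shuffle_null(msa, dist, 2, 9, spec)
        assert p1 == p2 and np.array_equal(n1, n2)


class TestSignificantPairs:
    def test_threshold_rules(self):
        mk = lambda z, p: CoevolPair(1, 2, 0.5, 1.0, 0.5, z=z, p_shuffle=p)
        retained = mk(4.2, 0.029)   # printed-style pass
        low_z = mk(3.9, 0.001)
        high_p = mk(5.0, 0.2)
        got = significant_pairs([retained, low_z, high_p])
        assert got == [retained]

    def test_spatial_annotation(self):
        atoms = [
            AtomRecord("A", 1, "ALA", "CB", (0.0, 0.0, 0.0), 1.7),
            AtomRecord("A", 2, "ALA", "CB", (5.0, 0.0, 0.0), 1.7),
            AtomRecord("A", 3, "GLY", "CA", (20.0, 0.0, 0.0), 1.7),
        ]
        pairs = [CoevolPair(1, 2, 0, 1, 0), CoevolPair(1, 3, 0, 1, 0),
                 CoevolPair(2, 9, 0, 1, 0)]
        annotate_spatial_class(pairs, atoms, chain="A")
        assert pairs[0].spatial_class == "proximal"
        assert pairs[1].spatial_class == "distant"  # glycine uses CA
        assert pairs[2].spatial_class == "unknown"
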