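"""Feature tests: brute-force oracles, plug-in examples, algebraic identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinclass as kc
from kinclass.features import FEATURE_NAMES, FeatureInputError


def loop_feature_oracle(gi, gj, p):
    """Per-locus Python-loop reference for all 17 measures."""
    table = np.zeros((3, 3))
    d = 0.0
    sum_pq = 0.0
    for a, b, pm in zip(gi, gj, p):
        if a == kc.MISSING or b == kc.MISSING:
            continue
        table[a, b] += 1
        d += (a - b) ** 2
        sum_pq += pm * (1 - pm)
    n = table.sum()
    if n == 0:
        return None
    j = table.reshape(9) / n
    ibs0 = j[2] + j[6]
    ibs2 = j[0] + j[4] + j[8]
    ibs1 = 1 - ibs0 - ibs2
    het_i = table[1, :].sum()
    het_j = table[:, 1].sum()
    k1 = (table[1, 1] - 2 * (table[0, 2] + table[2, 0])) / (het_i + het_j) if het_i + het_j else np.nan
    k0 = 0.5 * (1 - d / (4 * sum_pq)) if sum_pq > 0 else np.nan
    return np.array([k0, k1, ibs0, ibs1, ibs2, ibs0 + ibs1, ibs1 + ibs2, ibs0 + ibs2, *j])


genotype_vectors = st.integers(min_value=20, max_value=200).flatmap(
    lambda n: st.tuples(
        st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=n, max_size=n),
        st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=n, max_size=n),
    )
)


class TestPairCounts:
    def test_direct_count_example(self):
        counts = kc.compute_pair_counts([0, 1, 2, 1], [0, 1, 0, 2])
        assert counts.table[0, 0] == 1
        assert counts.table[1, 1] == 1
        assert counts.table[2, 0] == 1
        assert counts.table[1, 2] == 1
        assert counts.n_valid == 4

    def test_missing_loci_excluded(self):
        counts = kc.compute_pair_counts([1, kc.MISSING], [1, 1])
        assert counts.table[1, 1] == 1
        assert counts.n_valid == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(FeatureInputError):
            kc.compute_pair_counts([0, 1], [0, 1, 2])

    def test_counts_match_loop_oracle(self, rng):
        gi = rng.choice([-1, 0, 1, 2], size=1000, p=[0.05, 0.3, 0.35, 0.3])
        gj = rng.choice([-1, 0, 1, 2], size=1000, p=[0.05, 0.3, 0.35, 0.3])
        counts = kc.compute_pair_counts(gi, gj)
        expected = np.zeros((3, 3), dtype=int)
        for a, b in zip(gi, gj):
            if a != kc.MISSING and b != kc.MISSING:
                expected[a, b] += 1
        assert np.array_equal(counts.table, expected)


class TestKingEstimators:
    def test_self_pair_kinship_is_half(self):
        g = np.array([1, 1, 0, 2])
        counts = kc.compute_pair_counts(g, g)
        assert kc.king_robust(counts) == 0.5
        assert kc.king_homo(g, g, np.full(4, 0.4)) == 0.5

    def test_king_robust_plugin_example(self):
        counts = kc.compute_pair_counts([1, 1, 0, 2], [1, 1, 0, 2])
        assert kc.king_robust(counts) == (2 - 0) / (2 + 2)

    def test_king_homo_plugin_example(self):
        # D = 8, sum pq = 0.5 -> K0 = (1 - 8/2)/2 = -1.5
        assert kc.king_homo([0, 0], [2, 2], np.array([0.5, 0.5])) == -1.5

    def test_no_heterozygotes_is_undefined(self):
        counts = kc.compute_pair_counts([0, 2], [0, 2])
        assert np.isnan(kc.king_robust(counts))

    def test_min_denominator_variant(self):
        # i has 3 het loci, j has 1: symmetric divides by 4, min by 2
        counts = kc.compute_pair_counts([1, 1, 1, 0], [1, 0, 2, 0])
        assert kc.king_robust(counts) == pytest.approx(1 / 4)
        assert kc.king_robust(counts, denominator="min") == pytest.approx(1 / 2)
        with pytest.raises(kc.features.FeatureInputError):
            kc.king_robust(counts, denominator="harmonic")


class TestFractionFeatures:
    def test_ibs_direct_count_example(self):
        counts = kc.compute_pair_counts([0, 1, 2, 1], [0, 1, 0, 2])
        ibs = kc.ibs_fractions(counts)
        assert ibs == (0.25, 0.25, 0.5, 0.5, 0.75, 0.75)

    def test_joint_direct_count_example(self):
        counts = kc.compute_pair_counts([0, 1, 2, 1], [0, 1, 0, 2])
        j = kc.joint_fractions(counts)
        assert j[0] == j[4] == j[5] == j[6] == 0.25
        assert sum(j) == 1.0
        assert all(v == 0 for k, v in enumerate(j) if k not in (0, 4, 5, 6))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(genotype_vectors)
    def test_identities_hold(self, pair):
        """Sum(j)=1, IBS sums, and the IBS/j cross-identities to 1e-12."""
        gi, gj = (np.array(v, dtype=np.int8) for v in pair)
        counts = kc.compute_pair_counts(gi, gj)
        if counts.n_valid == 0:
            return
        j = np.array(kc.joint_fractions(counts))
        ibs0, ibs1, ibs2, ibs01, ibs12, ibs02 = kc.ibs_fractions(counts)
        assert abs(j.sum() - 1) < 1e-12
        assert abs(ibs0 + ibs1 + ibs2 - 1) < 1e-12
        assert abs(ibs01 - (ibs0 + ibs1)) < 1e-12
        assert abs(ibs0 - (j[2] + j[6])) < 1e-12
        assert abs(ibs2 - (j[0] + j[4] + j[8])) < 1e-12
        assert np.all(j >= 0) and np.all(j <= 1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(genotype_vectors)
    def test_swap_symmetry(self, pair):
        """Swapping the pair transposes the j-table and fixes K0, K1, IBS*."""
        gi, gj = (np.array(v, dtype=np.int8) for v in pair)
        c = kc.compute_pair_counts(gi, gj)
        if c.n_valid == 0:
            return
        p = np.full(len(gi), 0.3)
        fwd = kc.feature_vector(gi, gj, p)
        rev = kc.feature_vector(gj, gi, p)
        sym = [0, 1, 2, 3, 4, 5, 6, 7]  # K0, K1 and all IBS features
        np.testing.assert_allclose(fwd[sym], rev[sym], equal_nan=True, atol=1e-12)
        jf, jr = fwd[8:], rev[8:]
        np.testing.assert_allclose(jf, jr.reshape(3, 3).T.reshape(9), equal_nan=True, atol=1e-12)


class TestBatchExtraction:
    def test_vector_length_is_17(self):
        v = kc.feature_vector([0, 1, 2], [0, 1, 2], np.full(3, 0.5))
        assert v.shape == (17,)
        assert len(FEATURE_NAMES) == 17

    def test_batch_equals_per_pair_loop(self, rng):
        n_pairs, n_loci = 100, 300
        gi = rng.choice([-1, 0, 1, 2], size=(n_pairs, n_loci), p=[0.02, 0.3, 0.38, 0.3])
        gj = rng.choice([-1, 0, 1, 2], size=(n_pairs, n_loci), p=[0.02, 0.3, 0.38, 0.3])
        p = rng.uniform(0.05, 0.95, n_loci)
        batch = kc.pair_feature_matrix(gi, gj, p)
        for k in range(0, n_pairs, 17):
            expected = loop_feature_oracle(gi[k], gj[k], p)
            np.testing.assert_allclose(batch[k], expected, atol=1e-10)

    def test_extract_features_table_shape(self, small_features, small_dataset):
        assert len(small_features) == small_dataset.n_pairs
        assert list(small_features.columns[:6]) == ["pair_id", "id1", "id2", "type", "degree", "ger"]
        assert list(small_features.columns[6:]) == list(FEATURE_NAMES)

    def test_extract_matches_single_pair_path(self, small_dataset):
        freq = kc.estimate_allele_freq(small_dataset.genotypes.values())
        table = kc.extract_features(small_dataset, pair_types=["half-sibling"])
        gi, gj = small_dataset.pair_arrays("half-sibling")
        direct = kc.feature_vector(gi[7], gj[7], freq)
        np.testing.assert_allclose(
            table.iloc[7][list(FEATURE_NAMES)].to_numpy(dtype=float), direct, atol=1e-12
        )

    def test_degenerate_pairs_dropped(self, caplog):
        ds = kc.build_pair_dataset(2, 0.0, 50, seed=3)
        for m in ds.genotypes:
            ds.genotypes[m] = np.full_like(ds.genotypes[m], kc.MISSING)
        with caplog.at_level("WARNING", logger="kinclass"):
            table = kc.extract_features(ds)
        assert len(table) == 0

    def test_allele_freq_pooled_estimate(self):
        g1 = np.array([[0, 2, kc.MISSING]], dtype=np.int8)
        g2 = np.array([[2, 2, 1]], dtype=np.int8)
        freq = kc.estimate_allele_freq([g1, g2])
        # locus 3: one observed individual with genotype 1 -> 1/2
        np.testing.assert_allclose(freq, [0.5, 1.0, 0.5])
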