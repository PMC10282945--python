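import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sparsepool.info_measures import (
    IBResult,
    JointDistribution,
    PatternQuantizer,
    default_quantizer,
    estimate_joint,
    evaluate_chain,
    ib_lagrangian,
    markov_chain_joints,
    modified_ib,
    mutual_information,
    quantize,
)


class TestQuantizer:
    def test_identical_patterns_share_symbols_across_calls(self):
        q = PatternQuantizer("dictionary")
        a = quantize(np.array([[1, 0], [0, 1], [1, 0]], dtype=np.uint8), q)
        b = quantize(np.array([[0, 1]], dtype=np.uint8), q)
        assert a.tolist() == [0, 1, 0]
        assert b.tolist() == [1]

    def test_dictionary_assigns_first_seen_order(self):
        q = PatternQuantizer("dictionary")
        syms = quantize(np.eye(3, dtype=np.uint8), q)
        assert syms.tolist() == [0, 1, 2]
        assert q.alphabet_size == 3

    def test_projection_alphabet_bound_and_determinism(self):
        rng = np.random.default_rng(0)
        pats = rng.integers(0, 2, (300, 64)).astype(np.uint8)
        q1 = PatternQuantizer("projection", b=8, seed=5)
        q2 = PatternQuantizer("projection", b=8, seed=5)
        s1, s2 = quantize(pats, q1), quantize(pats, q2)
        assert np.array_equal(s1, s2)
        assert s1.max() < 256

    def test_cluster_falls_back_to_dictionary_when_overparameterized(self, caplog):
        pats = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        q = PatternQuantizer("cluster", m=10, seed=0)
        with caplog.at_level("WARNING"):
            syms = quantize(pats, q)
        assert "falling back" in caplog.text
        assert sorted(syms.tolist()) == [0, 1]

    def test_cluster_groups_near_duplicates(self):
        rng = np.random.default_rng(3)
        protos = rng.integers(0, 2, (2, 40)).astype(np.uint8)
        noisy = np.vstack([p ^ (rng.random(40) < 0.05) for p in protos for _ in range(10)])
        q = PatternQuantizer("cluster", m=2, seed=3)
        syms = quantize(noisy.astype(np.uint8), q)
        first, second = syms[:10], syms[10:]
        assert len(set(first.tolist())) == 1
        assert len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_default_quantizer_picks_dictionary_for_small_alphabets(self):
        pats = np.eye(4, dtype=np.uint8)
        assert default_quantizer(pats).method == "dictionary"


class TestEstimateJoint:
    def test_perfectly_correlated_symbols_make_diagonal_joint(self):
        j = estimate_joint(np.array([0, 1, 2, 0]), np.array([5, 6, 7, 5]))
        assert np.allclose(np.diag(np.diag(j.table)), j.table)

    def test_independent_uniform_pairs_approach_quarter_cells(self):
        rng = np.random.default_rng(42)
        n = 100_000
        j = estimate_joint(rng.integers(0, 2, n), rng.integers(0, 2, n))
        assert np.allclose(j.table, 0.25, atol=0.01)

    def test_single_sample_is_point_mass(self):
        j = estimate_joint(np.array([3]), np.array([9]))
        assert j.table.tolist() == [[1.0]]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_joint(np.array([1, 2]), np.array([1]))


class TestMutualInformation:
    def test_product_joint_has_zero_information(self):
        j = JointDistribution.from_table(np.outer([0.3, 0.7], [0.4, 0.6]))
        assert mutual_information(j) == pytest.approx(0.0, abs=1e-15)

    def test_identity_over_four_symbols_is_two_bits(self):
        j = JointDistribution.from_table(np.eye(4) / 4)
        assert mutual_information(j) == pytest.approx(2.0, abs=1e-12)

    def test_matches_hand_summed_cells(self):
        table = np.array([[0.4, 0.1], [0.1, 0.4]])
        expect = sum(
            p * math.log2(p / (pa * pb))
            for p, pa, pb in [
                (0.4, 0.5, 0.5),
                (0.1, 0.5, 0.5),
                (0.1, 0.5, 0.5),
                (0.4, 0.5, 0.5),
            ]
        )
        j = JointDistribution.from_table(table)
        assert mutual_information(j) == pytest.approx(expect, abs=1e-12)

    @given(seed=st.integers(0, 500))
    def test_nonnegative_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.random((3, 4))
        j = JointDistribution.from_table(t / t.sum())
        mi = mutual_information(j)
        assert mi >= -1e-14
        assert mi == pytest.approx(mutual_information(j.transpose()), abs=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            JointDistribution.from_table(np.array([[0.5, 0.6]]))
        with pytest.raises(ValueError):
            JointDistribution.from_table(np.array([[1.2, -0.2]]))


class TestObjectives:
    def test_lagrangian_arithmetic(self):
        assert ib_lagrangian(0.5, 0.3, 1.0) == pytest.approx(0.2)
        assert ib_lagrangian(0.7, 0.3, 0.0) == pytest.approx(0.7)
        assert ib_lagrangian(0.4, 0.4, 1.0) == pytest.approx(0.0)
        assert modified_ib(0.5, 0.2, 2.0) == pytest.approx(0.1)

    @pytest.mark.parametrize("fn", [ib_lagrangian, modified_ib])
    def test_negative_beta_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.5, 0.3, -0.1)


class TestEvaluateChain:
    def test_copy_channel_collapses_the_two_objectives(self):
        # Y a deterministic encoding of X and Z a copy of Y: the pipeline's
        # own situation, where I(X;Z) = I(Y;Z) = H(Y) exactly.
        rng = np.random.default_rng(1)
        x = rng.integers(0, 8, 500)
        y = x // 2
        res = evaluate_chain(x, y, y, beta=1.7)
        assert res.I_xz == pytest.approx(res.I_yz, abs=1e-12)
        assert res.L_MIB == pytest.approx(res.L_IB, abs=1e-12)

    def test_independent_output_recovers_compression_term(self):
        rng = np.random.default_rng(2)
        n = 60_000
        x = rng.integers(0, 3, n)
        z = rng.integers(0, 3, n)
        res = evaluate_chain(x, x, z, beta=1.0)
        assert res.I_xz == pytest.approx(0.0, abs=0.001)
        assert res.L_MIB == pytest.approx(res.I_xy, abs=0.001)

    def test_beta_zero_makes_both_objectives_equal_compression(self):
        x = np.array([0, 1, 0, 1])
        res = evaluate_chain(x, x, 1 - x, beta=0.0)
        assert res.L_IB == res.L_MIB == pytest.approx(res.I_xy)


def _mi_by_hand(table):
    pa = table.sum(axis=1)
    pb = table.sum(axis=0)
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            if table[i, j] > 0:
                total += table[i, j] * math.log2(table[i, j] / (pa[i] * pb[j]))
    return total


class TestMarkovChains:
    def test_exact_three_symbol_chain_matches_enumeration(self):
        """All five IB quantities agree with a 27-cell hand enumeration."""
        p_x = np.array([0.5, 0.3, 0.2])
        p_yx = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.1, 0.8]])
        p_zy = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.25, 0.25, 0.5]])
        j_xy, j_yz, j_xz = markov_chain_joints(p_x, p_yx, p_zy)
        # independent enumeration of the full (x,y,z) cube
        cube = p_x[:, None, None] * p_yx[:, :, None] * p_zy[None, :, :]
        assert np.allclose(j_xy.table, cube.sum(axis=2), atol=1e-15)
        assert np.allclose(j_yz.table, cube.sum(axis=0), atol=1e-15)
        assert np.allclose(j_xz.table, cube.sum(axis=1), atol=1e-15)
        for j in (j_xy, j_yz, j_xz):
            assert mutual_information(j) == pytest.approx(
                _mi_by_hand(j.table), abs=1e-12
            )

    @given(seed=st.integers(0, 300))
    def test_data_processing_inequality_on_exact_chains(self, seed):
        """I(X;Z) <= I(Y;Z) for every exact finite Markov chain."""
        rng = np.random.default_rng(seed)
        p_x = rng.random(3) + 0.05
        p_x /= p_x.sum()
        p_yx = rng.random((3, 4)) + 0.05
        p_yx /= p_yx.sum(axis=1, keepdims=True)
        p_zy = rng.random((4, 3)) + 0.05
        p_zy /= p_zy.sum(axis=1, keepdims=True)
        _, j_yz, j_xz = markov_chain_joints(p_x, p_yx, p_zy)
        assert mutual_information(j_xz) <= mutual_information(j_yz) + 1e-12

    def test_dpi_within_estimator_tolerance_on_sampled_chains(self):
        """Sampled-chain DPI violations stay below 3/sqrt(n) bits."""
        rng = np.random.default_rng(7)
        n = 5000
        x = rng.integers(0, 3, n)
        y = np.where(rng.random(n) < 0.8, x, rng.integers(0, 3, n))
        z = np.where(rng.random(n) < 0.7, y, rng.integers(0, 3, n))
        res = evaluate_chain(x, y, z, beta=1.0)
        tol = 3 / math.sqrt(n)
        assert res.I_xz <= res.I_yz + tol
        assert res.I_xz <= res.I_xy + tol
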