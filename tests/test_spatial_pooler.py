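import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

import sparsepool as sp
from sparsepool.synthetic_data import ConfigurationError, PatternSet
from sparsepool.spatial_pooler import SDR, inhibit, sdr_change


class TestInit:
    def test_full_potential_fraction_connects_everything(self):
        cfg = sp.SPConfig(n_inputs=30, n_columns=8, potential_fraction=1.0,
                          column_activation_pct=25.0, seed=0)
        state = sp.init_pooler(cfg)
        assert state.potential_mask.all()

    def test_exact_pool_size_and_determinism(self):
        cfg = sp.SPConfig(n_inputs=100, n_columns=16, potential_fraction=0.5,
                          column_activation_pct=25.0, seed=4)
        a, b = sp.init_pooler(cfg), sp.init_pooler(cfg)
        assert (a.potential_mask.sum(axis=1) == 50).all()
        assert np.array_equal(a.permanences, b.permanences)
        assert np.array_equal(a.potential_idx, b.potential_idx)

    def test_permanences_zero_outside_mask_and_bounded(self, small_state):
        assert (small_state.permanences[~small_state.potential_mask] == 0).all()
        assert small_state.permanences.min() >= 0
        assert small_state.permanences.max() <= 1

    def test_zero_active_columns_rejected(self):
        with pytest.raises(ConfigurationError):
            sp.SPConfig(n_inputs=10, n_columns=10, column_activation_pct=1.0)


class TestOverlap:
    def test_all_zero_input_gives_zero_overlap(self, small_state):
        raw, boosted = sp.compute_overlap(small_state, np.zeros(120, dtype=np.uint8))
        assert not raw.any() and not boosted.any()

    def test_matches_per_synapse_brute_force(self, small_state):
        """Overlap equals an exhaustive count over connected synapses."""
        rng = np.random.default_rng(8)
        pattern = rng.integers(0, 2, 120).astype(np.uint8)
        raw, boosted = sp.compute_overlap(small_state, pattern)
        cfg = small_state.config
        for c in range(cfg.n_columns):
            expect = sum(
                1
                for i in range(cfg.n_inputs)
                if pattern[i]
                and small_state.potential_mask[c, i]
                and small_state.permanences[c, i] >= cfg.perm_connected
            )
            assert raw[c] == expect
        assert np.allclose(boosted, raw * small_state.boost_factors)

    def test_width_mismatch_rejected(self, small_state):
        with pytest.raises(ValueError):
            sp.compute_overlap(small_state, np.zeros(7, dtype=np.uint8))


class TestInhibit:
    @pytest.mark.parametrize(
        "overlaps,k,expected",
        [
            ([5, 1, 3, 3], 2, [0, 2]),
            ([2, 2, 2, 2], 3, [0, 1, 2]),
            ([1, 2, 3, 4], 4, [0, 1, 2, 3]),
        ],
    )
    def test_topk_with_index_tie_break(self, overlaps, k, expected):
        sdr = inhibit(np.asarray(overlaps, dtype=float), k)
        assert sdr.active_columns.tolist() == expected

    @given(seed=st.integers(0, 10_000), k=st.integers(1, 20))
    def test_matches_stable_argsort_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        boosted = rng.integers(0, 6, 20).astype(float)
        expect = sorted(np.argsort(-boosted, kind="stable")[:k].tolist())
        assert inhibit(boosted, k).active_columns.tolist() == expect


class TestLearnStep:
    def test_zero_increments_change_only_duty_cycles(self, tiny_family):
        cfg = sp.SPConfig(n_inputs=120, n_columns=32, column_activation_pct=10.0,
                          perm_inc=0.0, perm_dec=0.0, seed=1)
        state = sp.init_pooler(cfg)
        before = state.permanences.copy()
        sp.compute_sdr(state, tiny_family[0], learn=True)
        assert np.array_equal(state.permanences, before)
        assert state.active_duty_cycles.any()

    def test_all_ones_input_raises_masked_permanences_by_inc(self):
        cfg = sp.SPConfig(n_inputs=20, n_columns=4, column_activation_pct=25.0,
                          perm_connected=0.5, perm_inc=0.03, seed=2)
        state = sp.init_pooler(cfg)
        before = state.permanences.copy()
        pattern = np.ones(20, dtype=np.uint8)
        sdr = sp.compute_sdr(state, pattern, learn=True)
        (c,) = sdr.active_columns.tolist()[:1]
        mask = state.potential_mask[c]
        expect = np.clip(before[c, mask] + 0.03, 0, 1)
        assert np.allclose(state.permanences[c, mask], expect)

    def test_zero_boost_strength_keeps_unit_boost(self, trained_small):
        assert np.array_equal(trained_small.boost_factors, np.ones(64))

    def test_permanences_stay_bounded_after_training(self, trained_small):
        assert trained_small.permanences.min() >= 0
        assert trained_small.permanences.max() <= 1


class TestFixedSparsity:
    # compute_sdr with learn=False never mutates the state, so sharing the
    # fixture across generated examples is safe
    @settings(suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(seed=st.integers(0, 1000))
    def test_sdr_size_is_always_k(self, small_state, seed):
        """Output sparsity is fixed for any input, including all-zero."""
        rng = np.random.default_rng(seed)
        pattern = (rng.random(120) < rng.random()).astype(np.uint8)
        sdr = sp.compute_sdr(small_state, pattern)
        assert len(sdr) == small_state.config.k == 6

    def test_all_zero_input_still_fixed_size(self, small_state):
        assert len(sp.compute_sdr(small_state, np.zeros(120, dtype=np.uint8))) == 6


class TestFit:
    def test_deterministic_given_seed(self, small_config, tiny_family):
        a = sp.fit(sp.init_pooler(small_config), tiny_family, 3)
        b = sp.fit(sp.init_pooler(small_config), tiny_family, 3)
        assert np.array_equal(a.permanences, b.permanences)

    def test_empty_dataset_rejected(self, small_state):
        with pytest.raises(ConfigurationError):
            sp.fit(small_state, PatternSet(np.zeros((0, 120), dtype=np.uint8)))

    @pytest.mark.parametrize("boost_strength", [0.0, 1.5])
    def test_fast_path_matches_stepwise_reference(self, tiny_family, boost_strength):
        """The batched numba kernels and the numpy step ops agree bit-for-bit."""
        cfg = sp.SPConfig(n_inputs=120, n_columns=64, column_activation_pct=10.0,
                          boost_strength=boost_strength, duty_cycle_period=10, seed=3)
        fast = sp.fit(sp.init_pooler(cfg), tiny_family, 4)
        ref = sp.init_pooler(cfg)
        for _ in range(4):
            for pattern in tiny_family:
                sp.compute_sdr(ref, pattern, learn=True)
        assert np.array_equal(fast.permanences, ref.permanences)
        assert np.array_equal(fast.connected_t, ref.connected_t)
        assert np.array_equal(fast.active_duty_cycles, ref.active_duty_cycles)
        assert np.allclose(fast.boost_factors, ref.boost_factors, rtol=0, atol=1e-14)
        batch = sp.compute_sdrs(fast, tiny_family)
        loop = [sp.compute_sdr(ref, p) for p in tiny_family]
        for a, b in zip(batch, loop):
            assert np.array_equal(a.active_columns, b.active_columns)

    def test_same_class_sdrs_overlap_more_than_cross_class(self, tiny_family):
        """After training, SDRs cluster by pattern family."""
        cfg = sp.SPConfig(n_inputs=120, n_columns=128, column_activation_pct=5.0, seed=6)
        state = sp.fit(sp.init_pooler(cfg), tiny_family, 10)
        sdrs = sp.compute_sdrs(state, tiny_family)
        labels = tiny_family.labels
        same, cross = [], []
        for i in range(len(sdrs)):
            for j in range(i + 1, len(sdrs)):
                inter = np.intersect1d(
                    sdrs[i].active_columns, sdrs[j].active_columns
                ).size
                (same if labels[i] == labels[j] else cross).append(inter)
        assert np.mean(same) > np.mean(cross)


class TestNoiseRobustness:
    def test_trained_sdr_changes_less_than_untrained_under_noise(self):
        """Learning stabilizes SDRs against moderate input corruption."""
        data = sp.generate_prototypes(40, 800, 0.1, seed=9)
        cfg = sp.SPConfig(n_inputs=800, n_columns=256, column_activation_pct=2.0, seed=9)
        trained = sp.fit(sp.init_pooler(cfg), data, 21)
        untrained = sp.init_pooler(cfg)
        changes = {"trained": [], "untrained": []}
        for name, state in (("trained", trained), ("untrained", untrained)):
            ref = sp.compute_sdrs(state, data)
            noisy = np.vstack(
                [sp.swap_noise(p, 10.0, seed=100 + i) for i, p in enumerate(data)]
            )
            now = sp.compute_sdrs(state, noisy)
            changes[name] = np.mean([sdr_change(r, s) for r, s in zip(ref, now)])
        assert changes["trained"] < changes["untrained"]


class TestSdrChange:
    def test_identical_and_disjoint_extremes(self):
        a = SDR(np.array([1, 5, 9]), 16)
        b = SDR(np.array([0, 2, 4]), 16)
        assert sdr_change(a, a) == 0.0
        assert sdr_change(a, b) == 1.0

    def test_partial_overlap_fraction(self):
        ref = SDR(np.arange(20), 64)
        other = SDR(np.arange(5, 25), 64)
        assert sdr_change(ref, other) == pytest.approx(0.25)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            sdr_change(SDR(np.array([], dtype=int), 8), SDR(np.array([1]), 8))
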