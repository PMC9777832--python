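"""Sigmoid binarization, swarm dynamics, fitness and planted-channel recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from entrochan import (ChannelMask, KNNConfig, PSOConfig, SynthConfig, binarize,
                       cross_validate, epoch_segments, extract_features, fitness,
                       generate_subject, pso_select, update_swarm)
from entrochan.classify import fold_partition
from entrochan.pso import SwarmState

CHANNELS = ("Fp1", "F3", "F7", "FT9")


class TestBinarize:
    def test_zero_position_not_selected(self):
        mask = binarize(np.zeros(4), CHANNELS)
        assert mask.n_selected == 0  # weight exactly 0.5, strict >

    def test_saturation(self):
        mask = binarize(np.array([10.0, -10.0, 10.0, -10.0]), CHANNELS)
        assert mask.selected == ("Fp1", "F7")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(float, 4, elements=st.floats(-10, 10, allow_nan=False)
                      .map(lambda v: 0.0 if abs(v) < 1e-12 else v)))
    def test_threshold_half_equals_sign_test(self, x):
        """Sigmoid monotonicity: threshold 0.5 selects exactly x_j > 0.

        Magnitudes below ~1e-16 are snapped to zero first: there the sigmoid
        itself rounds to exactly 0.5 and the strict-> rule applies.
        """
        mask = binarize(x, CHANNELS, threshold=0.5)
        np.testing.assert_array_equal(mask.bits, (x > 0).astype(np.uint8))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.0, np.nan, 0.0, 0.0]), CHANNELS)


class TestUpdateSwarm:
    def _state(self, x, v, pbest=None, gbest=None, seed=0):
        x = np.atleast_2d(np.asarray(x, float))
        v = np.atleast_2d(np.asarray(v, float))
        pb = x.copy() if pbest is None else np.atleast_2d(np.asarray(pbest, float))
        gb = x[0].copy() if gbest is None else np.asarray(gbest, float)
        return SwarmState(x=x, v=v, pbest_x=pb, pbest_f=np.zeros(len(x)),
                          gbest_x=gb, gbest_f=0.0,
                          gbest_bits=np.zeros(x.shape[1], np.uint8),
                          rng=np.random.default_rng(seed))

    def test_pure_inertia_advances_until_clamped(self):
        cfg = PSOConfig(n_particles=1, c1=0.0, c2=0.0, inertia=1.0)
        st_ = self._state([[0.0, 0.0]], [[3.0, -3.0]])
        for expected in ([3.0, -3.0], [6.0, -6.0], [9.0, -9.0],
                         [10.0, -10.0], [10.0, -10.0]):
            update_swarm(st_, cfg)
            np.testing.assert_allclose(st_.x[0], expected)

    def test_stationary_at_global_best_with_zero_velocity(self):
        cfg = PSOConfig(n_particles=2)
        x = [[1.0, 2.0], [1.0, 2.0]]
        st_ = self._state(x, [[0.0, 0.0]] * 2, pbest=x, gbest=[1.0, 2.0])
        update_swarm(st_, cfg)
        np.testing.assert_allclose(st_.x, x)
        np.testing.assert_allclose(st_.v, 0.0)

    def test_bounds_always_respected(self):
        """After any update, X stays in its box and V in its box."""
        cfg = PSOConfig(n_particles=25)
        rng = np.random.default_rng(1)
        st_ = self._state(rng.uniform(-10, 10, (25, 6)),
                          rng.uniform(-4, 4, (25, 6)),
                          pbest=rng.uniform(-10, 10, (25, 6)),
                          gbest=rng.uniform(-10, 10, 6), seed=2)
        for _ in range(40):
            update_swarm(st_, cfg)
            assert (np.abs(st_.x) <= 10.0).all()
            assert (np.abs(st_.v) <= 4.0).all()


class TestFitness:
    def test_full_mask_equals_whole_table_cv(self, small_synth):
        table = small_synth["table"]
        mask = ChannelMask(table.channels, np.ones(len(table.channels), int))
        part = fold_partition(table.n_epochs, 10, seed=3)
        f = fitness(mask, table, KNNConfig(seed=3), partition=part)
        cv = cross_validate(table, KNNConfig(seed=3), partition=part)
        assert f == cv.mean_accuracy

    def test_empty_mask_is_zero(self, small_synth):
        table = small_synth["table"]
        mask = ChannelMask(table.channels, np.zeros(len(table.channels), int))
        assert fitness(mask, table) == 0.0

    def test_informative_pair_beats_null_pair(self, small_synth):
        table = small_synth["table"]
        gt = small_synth["gt"]
        inf = gt.informative_channels[:2]
        null = [c for c in table.channels if c not in gt.informative_channels][:2]
        wins = 0
        for seed in range(10):
            part = fold_partition(table.n_epochs, 10, seed=seed)
            def f(chs):
                bits = [1 if c in chs else 0 for c in table.channels]
                return fitness(ChannelMask(table.channels, bits), table,
                               KNNConfig(seed=seed), partition=part)
            if f(inf) > f(null):
                wins += 1
        assert wins >= 9

    def test_mismatched_channels_rejected(self, small_synth):
        mask = ChannelMask(("X", "Y"), np.array([1, 0]))
        with pytest.raises(ValueError):
            fitness(mask, small_synth["table"])


class TestPsoSelect:
    def test_tmax_zero_returns_best_of_initial_population(self, small_synth):
        table = small_synth["table"]
        cfg = PSOConfig(n_particles=8, t_max=0, seed=4)
        mask, trace = pso_select(table, cfg)
        assert len(trace.best_fitness) == 1
        assert trace.n_evaluations <= 8
        assert mask.fitness == trace.best_fitness[0]

    def test_trace_monotone_and_seed_reproducible(self, small_synth):
        table = small_synth["table"]
        cfg = PSOConfig(n_particles=10, t_max=10, seed=5)
        mask1, trace1 = pso_select(table, cfg)
        mask2, trace2 = pso_select(table, cfg)
        bf = trace1.best_fitness
        assert all(b >= a for a, b in zip(bf, bf[1:]))
        assert trace1.best_fitness == trace2.best_fitness
        np.testing.assert_array_equal(mask1.bits, mask2.bits)
        assert mask1.fitness == mask2.fitness

    def test_memoization_bounds_evaluations(self, small_synth):
        table = small_synth["table"]
        cfg = PSOConfig(n_particles=10, t_max=10, seed=6)
        _, trace = pso_select(table, cfg)
        assert trace.n_evaluations <= 10 * 11
        # with 10-bit masks and converging particles, repeats are certain
        assert trace.n_evaluations < 10 * 11

    def test_recovers_planted_channels(self):
        """Selected mask finds >=3 of 4 planted channels in >=8 of 10 seeds."""
        hits = 0
        for seed in range(10):
            cfg = SynthConfig(n_subjects=1, seed=100 + seed)
            rec, ann, gt = generate_subject(cfg, 0)
            table = extract_features(epoch_segments(rec, ann))
            mask, _ = pso_select(table, PSOConfig(n_particles=20, t_max=30,
                                                  seed=seed))
            found = len(set(mask.selected) & set(gt.informative_channels))
            if found >= 3:
                hits += 1
        assert hits >= 8

    def test_not_worse_than_full_mask(self, small_synth):
        """PSO should not lose to a candidate it can represent (full mask)."""
        table = small_synth["table"]
        for seed in range(3):
            cfg = PSOConfig(n_particles=20, t_max=30, seed=30 + seed)
            mask, trace = pso_select(table, cfg)
            rng = np.random.default_rng(30 + seed)
            fold_seed = int(rng.integers(0, 2**31 - 1))
            part = fold_partition(table.n_epochs, 10, fold_seed)
            full = ChannelMask(table.channels, np.ones(len(table.channels), int))
            f_full = fitness(full, table, KNNConfig(), partition=part)
            assert mask.fitness >= f_full - 0.02

    def test_mask_json_roundtrip(self, small_synth, tmp_path):
        table = small_synth["table"]
        mask, _ = pso_select(table, PSOConfig(n_particles=5, t_max=2, seed=7))
        mask.to_json(tmp_path / "m.json")
        back = ChannelMask.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.bits, mask.bits)
        assert back.channels == mask.channels
        assert back.fitness == mask.fitness
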