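import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgnmech.core_io import SinusoidStimulus, TWO_PI
from sgnmech.phaselock import (POLAR_ANGLES, count_peaks, cycle_histogram,
                               histogram_vector_strength, polar_summary,
                               rayleigh_p, spike_phases, vector_strength)
from sgnmech.synthetic import PhaseLockGenSpec, gen_phase_locked_train

from conftest import make_train


def circ_close(a, b, tol=1e-9):
    d = abs(a - b) % TWO_PI
    return min(d, TWO_PI - d) < tol


class TestSpikePhases:
    def test_period_multiples_map_to_zero(self, sinusoid_50hz):
        train = make_train([0.0, 10.0, 20.0], 100.0)
        # spikes at 0 and full periods (20 ms at 50 Hz) -> phase 0
        ph = spike_phases(train, stim=sinusoid_50hz)
        assert circ_close(ph[0], 0.0) and circ_close(ph[2], 0.0)
        assert ph[1] == pytest.approx(math.pi)

    def test_quarter_and_half_period(self, sinusoid_50hz):
        # 50 Hz -> 20 ms period: 5 ms is a quarter cycle, 10 ms half
        train = make_train([5.0, 10.0], 100.0)
        ph = spike_phases(train, stim=sinusoid_50hz)
        assert ph[0] == pytest.approx(math.pi / 2)
        assert ph[1] == pytest.approx(math.pi)

    def test_missing_stimulus_rejected(self):
        with pytest.raises(ValueError):
            spike_phases(make_train([1.0], 10.0))

    @given(st.lists(st.floats(min_value=0, max_value=999.9,
                              allow_nan=False), min_size=1, max_size=40,
                    unique=True))
    @settings(max_examples=40, deadline=None)
    def test_matches_direct_recomputation(self, times):
        stim = SinusoidStimulus("displacement", 50.0, 0.2, onset=0.0,
                                duration=1000.0)
        times = np.sort(np.array(times))
        if np.any(np.diff(times) <= 0):
            return
        train = make_train(times, 1000.0)
        got = spike_phases(train, stim=stim)
        expect = (TWO_PI * 50.0 * times / 1000.0) % TWO_PI
        assert got == pytest.approx(expect)


class TestVectorStrength:
    def test_identical_phases_give_unity(self):
        s = vector_strength(np.full(50, 1.3))
        assert s.vs == pytest.approx(1.0)
        assert s.mean_phase == pytest.approx(1.3)

    def test_symmetric_quadrants_give_zero(self):
        s = vector_strength([0.0, math.pi / 2, math.pi, 3 * math.pi / 2])
        assert s.vs == pytest.approx(0.0, abs=1e-12)

    def test_two_against_one(self):
        # |1 + 1 + e^{i pi}| / 3 = 1/3
        assert vector_strength([0.0, 0.0, math.pi]).vs == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vector_strength([])

    @given(st.lists(st.floats(min_value=0, max_value=TWO_PI - 1e-9,
                              allow_nan=False), min_size=2, max_size=100),
           st.floats(min_value=-3, max_value=3))
    @settings(max_examples=40, deadline=None)
    def test_rotation_invariance(self, phases, rot):
        base = vector_strength(phases)
        rotated = vector_strength((np.array(phases) + rot) % TWO_PI)
        assert rotated.vs == pytest.approx(base.vs, abs=1e-9)
        if base.vs > 1e-6:
            diff = (rotated.mean_phase - base.mean_phase - rot) % TWO_PI
            assert min(diff, TWO_PI - diff) == pytest.approx(0.0, abs=1e-6)


class TestRayleigh:
    def test_zero_vs_gives_p_one(self):
        assert rayleigh_p(0.0, 50) == 1.0

    def test_corrected_series_value(self):
        # independently evaluated: Z=1, n=100 ->
        # exp(-1)*(1 + 1/400 + 41/2880000)
        assert rayleigh_p(0.1, 100) == pytest.approx(0.36880437694697094,
                                                     rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_p(0.5, 1)

    def test_strictly_decreasing_in_vs(self):
        for n in (5, 20, 200):
            ps = [rayleigh_p(v, n) for v in np.linspace(0.01, 0.99, 40)]
            assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_type_one_error_calibrated(self):
        """p < 0.05 under uniform phases rejects ~5% of the time."""
        rng = np.random.default_rng(42)
        n, reps = 50, 4000
        phases = rng.uniform(0, TWO_PI, size=(reps, n))
        resultant = np.abs(np.exp(1j * phases).sum(axis=1)) / n
        rej = np.mean([rayleigh_p(v, n) < 0.05 for v in resultant])
        assert 0.035 <= rej <= 0.065


class TestCycleHistogram:
    def test_all_mass_in_first_bin(self):
        h = cycle_histogram(np.zeros(17), n_bins=36)
        assert h.counts[0] == 17 and h.counts[1:].sum() == 0

    def test_uniform_grid_fills_every_bin(self):
        centers = (np.arange(36) + 0.5) * TWO_PI / 36
        h = cycle_histogram(centers, n_bins=36)
        assert np.all(h.counts == 1)

    def test_counts_sum_preserved(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(0, TWO_PI, 357)
        assert cycle_histogram(ph).counts.sum() == 357

    def test_fine_binned_fundamental_matches_spikewise_vs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ph = rng.vonmises(1.0, rng.uniform(0, 5), size=300) % TWO_PI
            direct = vector_strength(ph).vs
            binned = histogram_vector_strength(cycle_histogram(ph, 360))
            assert binned == pytest.approx(direct, abs=1e-3)


class TestCountPeaks:
    def test_single_von_mises_component_is_unimodal(self):
        spec = PhaseLockGenSpec(rate=25.0, frequency=50.0, duration=20000.0,
                                components=((2.0, 4.0, 1.0),), seed=5)
        ph = spike_phases(gen_phase_locked_train(spec))
        res = count_peaks(cycle_histogram(ph))
        assert res.n_peaks == 1 and res.reliable

    def test_antipodal_mixture_is_bimodal(self):
        spec = PhaseLockGenSpec(
            rate=25.0, frequency=50.0, duration=20000.0,
            components=((1.0, 4.0, 0.5), (1.0 + math.pi, 4.0, 0.5)), seed=6)
        ph = spike_phases(gen_phase_locked_train(spec))
        res = count_peaks(cycle_histogram(ph))
        assert res.n_peaks == 2

    def test_uniform_phases_flagged_unreliable(self):
        rng = np.random.default_rng(7)
        ph = rng.uniform(0, TWO_PI, 500)
        res = count_peaks(cycle_histogram(ph))
        assert not res.reliable

    def test_empty_histogram_rejected(self):
        h = cycle_histogram(np.empty(0))
        with pytest.raises(ValueError):
            count_peaks(h)


def _trains_with_counts(counts, frequency=50.0, duration=1000.0):
    """One train per angle with ``counts[k]`` perfectly locked spikes."""
    conditions = []
    stim = SinusoidStimulus("current", frequency, 1.0, onset=0.0,
                            duration=duration)
    period = 1000.0 / frequency
    for ang, c in zip(POLAR_ANGLES, counts):
        times = period * np.arange(c) + 1.0
        conditions.append((float(ang),
                           [make_train(times, duration, stim)]))
    return conditions


class TestPolarSummary:
    def test_equal_magnitudes_cancel(self):
        summary = polar_summary(_trains_with_counts([20] * 8), n_perm=50)
        assert summary.resultant_rate[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(summary.rate_norm == 1.0)

    def test_single_nonzero_angle(self):
        counts = [0] * 8
        counts[2] = 30   # 90 degrees
        summary = polar_summary(_trains_with_counts(counts), n_perm=50)
        mag, ang = summary.resultant_rate
        assert mag == pytest.approx(1.0)
        assert ang == pytest.approx(math.pi / 2)

    def test_two_adjacent_angles(self):
        counts = [40, 40] + [0] * 6
        summary = polar_summary(_trains_with_counts(counts), n_perm=50)
        mag, ang = summary.resultant_rate
        assert mag == pytest.approx(math.cos(math.radians(22.5)), abs=1e-9)
        assert ang == pytest.approx(math.radians(22.5), abs=1e-9)

    def test_missing_angle_rejected(self):
        cond = _trains_with_counts([10] * 8)[:7]
        with pytest.raises(ValueError):
            polar_summary(cond)

    def test_rate_normalized_to_max(self):
        counts = [10, 20, 40, 10, 10, 10, 10, 10]
        summary = polar_summary(_trains_with_counts(counts), n_perm=50)
        assert summary.rate_norm.max() == 1.0
        assert summary.rate_norm[2] == 1.0
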