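"""Empirical-wavelet tests: padding, boundary detection, perfect
reconstruction, mode selection, and period-two isolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from kokwave import (
    EWTDecomposition,
    FlashYieldSequence,
    SeparabilityError,
    SpectrumPartition,
    ValidationError,
    decompose,
    detect_boundaries,
    filter_signal,
    reflect_pad,
    select_period_two_mode,
    simulate_yields,
)
from kokwave.synth import (
    DARK_ADAPTED_INIT,
    EFFICIENT_SYSTEM_PARAMS,
    combine_signals,
    default_interference,
    generate_interference,
)


def damped_two_tone(n, f1, f2, a1, a2, d1, d2, phi1=0.0, phi2=0.0):
    t = np.arange(n)
    return (a1 * d1 ** t * np.cos(2 * np.pi * f1 * t + phi1)
            + a2 * d2 ** t * np.cos(2 * np.pi * f2 * t + phi2))


class TestReflectPad:
    def test_mirror_drops_duplicate_endpoints(self):
        padded, crop = reflect_pad(np.array([1.0, 2.0, 3.0]))
        assert np.array_equal(padded, [1.0, 2.0, 3.0, 2.0])
        assert np.array_equal(padded[crop], [1.0, 2.0, 3.0])

    def test_constant_stays_constant(self):
        padded, _ = reflect_pad(np.full(4, 2.5))
        assert padded.shape == (6,)
        assert np.all(padded == 2.5)

    def test_alternating_signal_stays_alternating_circularly(self):
        # the property motivating this mirror: period-two parity is
        # preserved all the way around the circle
        y = (-1.0) ** np.arange(6) * 0.8 ** np.arange(6)
        padded, _ = reflect_pad(y)
        signs = np.sign(padded)
        rolled = np.sign(np.roll(padded, 1))
        assert np.all(signs * rolled == -1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(arrays(np.float64, st.integers(2, 30),
                  elements=st.floats(-5, 5, allow_nan=False)))
    def test_crop_recovers_original_and_padding_is_symmetric(self, y):
        padded, crop = reflect_pad(y)
        assert np.array_equal(padded[crop], y)
        assert padded.size == 2 * y.size - 2
        # symmetric about sample 0: padded[k] == padded[-k]
        assert np.allclose(padded, np.roll(padded[::-1], 1))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            reflect_pad(np.array([1.0]))


class TestDetectBoundaries:
    def test_monochromatic_spectrum_gives_single_band(self):
        y = np.cos(2 * np.pi * 0.25 * np.arange(16))
        padded, _ = reflect_pad(y)
        mag = np.abs(np.fft.rfft(padded))
        part = detect_boundaries(mag)
        assert part.n_bands == 1
        assert part.boundaries == ()

    def test_two_tone_boundary_lies_between_peaks(self):
        y = damped_two_tone(20, 0.25, 0.5, 1.0, 0.6, 0.92, 0.85)
        padded, _ = reflect_pad(y)
        mag = np.abs(np.fft.rfft(padded))
        part = detect_boundaries(mag)
        assert len(part.boundaries) == 1
        assert 0.25 < part.boundaries[0] < 0.5

    def test_flash_oxygen_signal_keeps_period_four_in_lowest_band(self):
        kok = simulate_yields(EFFICIENT_SYSTEM_PARAMS, DARK_ADAPTED_INIT, 20)
        comb = combine_signals(
            kok, generate_interference(default_interference(kok), 20))
        padded, _ = reflect_pad(comb.yields)
        mag = np.abs(np.fft.rfft(padded))
        part = detect_boundaries(mag)
        assert part.n_bands >= 2
        # the donor-side (period-four) peak near 0.25 must fall in a
        # low band, strictly below the acceptor (period-two) band
        freqs = np.arange(mag.size) / (2.0 * (mag.size - 1))
        peak = freqs[1 + int(np.argmax(mag[1:]))]
        assert abs(peak - 0.25) <= 0.05
        p4_band = next(i for i, (lo, hi) in enumerate(part.bands)
                       if lo < peak <= hi)
        assert p4_band < part.n_bands - 1
        assert part.bands[p4_band][1] < 0.5

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            detect_boundaries(np.array([]))


class TestDecompose:
    def test_trend_plus_cosine_recovered_by_two_modes(self):
        t = np.arange(24)
        trend = np.full(24, 0.8)
        tone = 0.3 * np.cos(2 * np.pi * 0.25 * t)
        dec = decompose(trend + tone)
        assert dec.n_modes == 2
        # order by peak frequency: low mode tracks trend, high the tone
        low, high = dec.modes[0], dec.modes[-1]
        assert np.corrcoef(high, tone)[0, 1] >= 0.99
        assert np.std(low - trend) < np.std(tone)

    def test_perfect_reconstruction_on_random_damped_two_tones(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(12, 40))
            y = damped_two_tone(
                n, rng.uniform(0.1, 0.3), rng.uniform(0.35, 0.5),
                rng.uniform(0.5, 2.0), rng.uniform(0.2, 1.0),
                rng.uniform(0.8, 0.99), rng.uniform(0.8, 0.99),
                rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi),
            )
            dec = decompose(y)
            resid = dec.reconstruct() - y
            assert np.sqrt(np.mean(resid ** 2)) <= 1e-8 * np.sqrt(np.mean(y ** 2))

    def test_each_mode_peaks_inside_its_own_band(self):
        kok = simulate_yields(EFFICIENT_SYSTEM_PARAMS, DARK_ADAPTED_INIT, 20)
        comb = combine_signals(
            kok, generate_interference(default_interference(kok), 20))
        dec = decompose(comb)
        for (lo, hi), f in zip(dec.partition.bands, dec.peak_frequencies):
            assert lo < f <= hi

    def test_combined_signal_modes_near_quarter_and_half(self, recovery_result):
        dec = decompose(recovery_result.combined)
        peaks = np.asarray(dec.peak_frequencies)
        assert np.min(np.abs(peaks - 0.25)) <= 0.05
        assert np.min(np.abs(peaks - 0.5)) <= 0.05

    def test_linearity_in_amplitude(self):
        y = damped_two_tone(20, 0.22, 0.48, 1.0, 0.5, 0.9, 0.88)
        d1 = decompose(y)
        d2 = decompose(3.5 * y)
        for m1, m2 in zip(d1.modes, d2.modes):
            assert np.allclose(3.5 * m1, m2, rtol=1e-10, atol=1e-12)

    def test_single_damped_cosine_energy_in_one_mode(self):
        t = np.arange(20)
        y = 0.9 ** t * np.cos(2 * np.pi * 0.25 * t)
        dec = decompose(y)
        energies = [float(m @ m) for m in dec.modes]
        assert max(energies) >= 0.99 * sum(energies)

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            decompose(np.arange(5, dtype=float))


class TestPeriodTwoSelection:
    def _fake(self, peaks):
        n = len(peaks)
        return EWTDecomposition(
            modes=tuple(np.zeros(8) for _ in range(n)),
            peak_frequencies=tuple(peaks),
            partition=SpectrumPartition(boundaries=tuple(
                (peaks[i] + peaks[i + 1]) / 2 for i in range(n - 1))),
            input_yields=np.zeros(8),
        )

    def test_nearest_to_half_wins(self):
        assert select_period_two_mode(self._fake([0.05, 0.26, 0.49])) == 2

    def test_distance_comparison(self):
        assert select_period_two_mode(self._fake([0.26, 0.375, 0.48])) == 2

    def test_two_tone_signal_selects_the_half_cycle_tone(self):
        y = damped_two_tone(20, 0.25, 0.5, 1.0, 0.6, 0.92, 0.85)
        dec = decompose(y)
        idx = select_period_two_mode(dec)
        assert abs(dec.peak_frequencies[idx] - 0.5) <= 0.05

    def test_single_mode_not_separable(self):
        with pytest.raises(SeparabilityError):
            select_period_two_mode(self._fake([0.25]))


class TestFilterSignal:
    def test_outputs_sum_back_to_input(self, recovery_result):
        total = recovery_result.period_four.yields + recovery_result.period_two.yields
        resid = total - recovery_result.combined.yields
        assert np.sqrt(np.mean(resid ** 2)) <= 1e-8 * np.sqrt(
            np.mean(recovery_result.combined.yields ** 2))

    def test_pure_kok_sequence_has_small_period_two_remnant(self):
        kok = simulate_yields(EFFICIENT_SYSTEM_PARAMS, DARK_ADAPTED_INIT, 20)
        p4, p2 = filter_signal(kok)
        assert np.sqrt(np.mean(p2.yields ** 2)) < 0.25 * np.sqrt(
            np.mean(p4.yields ** 2))

    def test_isolated_period_two_tracks_generating_interference(self, recovery_result):
        r = np.corrcoef(recovery_result.period_two.yields,
                        recovery_result.interference.yields)[0, 1]
        assert r >= 0.9

    def test_outputs_flagged_filtered(self, recovery_result):
        assert recovery_result.period_four.filtered
        assert recovery_result.period_two.filtered
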