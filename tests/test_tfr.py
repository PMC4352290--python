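import numpy as np
import pandas as pd
import pytest

from sfgamma.containers import EpochSet, TFRGrid
from sfgamma.tfr import (
    MultitaperSpec,
    baseline_normalize,
    dpss_tapers,
    evoked_power,
    extract_egba,
    extract_tgba,
    multitaper_power,
    select_peak_frequency,
    tgba_band,
    total_power,
)

SRATE = 512.0
N_TIMES = 768
TIMES = -0.6 + np.arange(N_TIMES) / SRATE
SPEC = MultitaperSpec()


def _epochs(data, chan_names=None):
    data = np.asarray(data, dtype=float)
    trials = pd.DataFrame({"participant": 1, "trial": np.arange(data.shape[0])})
    names = chan_names or [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data, SRATE, names, TIMES, trials)


class TestDPSS:
    def test_tapers_orthonormal(self):
        tapers, _ = dpss_tapers(128, 3, 5)
        gram = tapers @ tapers.T
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_concentration_ratios_strictly_decreasing(self):
        _, ratios = dpss_tapers(128, 3, 5)
        assert np.all(np.diff(ratios) < 0)
        assert ratios[0] > 0.99

    def test_first_taper_has_no_sign_change(self):
        tapers, _ = dpss_tapers(128, 3, 5)
        first = tapers[0][np.abs(tapers[0]) > 1e-12]
        assert np.all(first > 0) or np.all(first < 0)

    def test_too_many_tapers_rejected(self):
        with pytest.raises(ValueError, match="2\\*NW-1"):
            dpss_tapers(128, 3, 6)

    def test_default_spec_smoothing_is_12hz(self):
        assert SPEC.nw == 3.0
        assert SPEC.half_bandwidth_hz == pytest.approx(12.0)


class TestMultitaperPower:
    def test_zero_segment_zero_power(self):
        power = multitaper_power(np.zeros(128), SPEC, SRATE)
        assert np.allclose(power, 0.0)

    def test_sinusoid_mainlobe_structure(self):
        # 62 Hz unit sinusoid: argmax at 62; the +-NW/T = +-12 Hz
        # concentration band is nearly flat in its interior and the
        # spectral window is strongly rejected beyond +-16 Hz
        t = np.arange(128) / SRATE
        seg = np.sin(2 * np.pi * 62.0 * t)
        power = multitaper_power(seg, SPEC, SRATE)
        freqs = np.array(SPEC.freqs_hz)
        assert freqs[np.argmax(power)] == 62.0
        peak = power.max()
        inner = np.abs(freqs - 62.0) <= 8.0
        outlobe = np.abs(freqs - 62.0) > 16.0
        assert power[inner].min() >= 0.8 * peak
        assert power[outlobe].max() < 0.05 * peak

    def test_single_taper_equals_direct_dft_oracle(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(size=128)
        spec1 = MultitaperSpec(n_tapers=1, time_bandwidth=3.0)
        power = multitaper_power(seg, spec1, SRATE)
        taper, _ = dpss_tapers(128, 3.0, 1)
        t = np.arange(128) / SRATE
        oracle = np.array(
            [
                np.abs(np.sum(seg * taper[0] * np.exp(-2j * np.pi * f * t))) ** 2
                for f in spec1.freqs_hz
            ]
        )
        assert np.allclose(power, oracle, rtol=1e-10, atol=1e-12)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(1)
        seg = rng.normal(size=128)
        a = multitaper_power(seg, SPEC, SRATE)
        b = multitaper_power(seg[::-1], SPEC, SRATE)
        assert np.allclose(a, b, rtol=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="window length"):
            multitaper_power(np.zeros(100), SPEC, SRATE)


def _burst_epochs(n_trials, freq_hz, phase_locked, amp=1.0, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    env = np.exp(-0.5 * ((TIMES - 0.35) / 0.075) ** 2)
    if phase_locked:
        phases = np.zeros((n_trials, 1))
    else:
        phases = rng.uniform(0, 2 * np.pi, (n_trials, 1))
    data = amp * env[None, :] * np.cos(2 * np.pi * freq_hz * TIMES[None, :] + phases)
    if noise:
        data = data + rng.normal(0, noise, data.shape)
    return _epochs(data[:, None, :])


class TestEvokedVsTotal:
    def test_single_trial_equivalence(self):
        ep = _burst_epochs(1, 70.0, phase_locked=False, noise=0.3)
        ev = evoked_power(ep, SPEC, times=[0.3, 0.35])
        tot = total_power(ep, SPEC, times=[0.3, 0.35])
        assert np.allclose(ev.power, tot.power, rtol=1e-12)

    def test_phase_locked_burst_evoked_matches_total(self):
        ep = _burst_epochs(50, 38.0, phase_locked=True)
        times = [0.3, 0.35, 0.4]
        ev = evoked_power(ep, SPEC, times=times)
        tot = total_power(ep, SPEC, times=times)
        assert np.allclose(ev.power, tot.power, rtol=1e-9)

    def test_random_phase_burst_cancels_in_evoked_only(self):
        ep = _burst_epochs(200, 70.0, phase_locked=False, seed=3)
        times = [0.3, 0.35, 0.4]
        ev = evoked_power(ep, SPEC, times=times)
        tot = total_power(ep, SPEC, times=times)
        f70 = np.array(SPEC.freqs_hz) == 70.0
        assert ev.power[0, f70].max() < 0.02 * tot.power[0, f70].max()

    def test_total_power_additivity_of_independent_components(self):
        rng = np.random.default_rng(4)
        sig = _burst_epochs(100, 70.0, phase_locked=False, seed=5).data
        noise = rng.normal(0, 0.5, sig.shape)
        t = [0.35]
        p_sig = total_power(_epochs(sig), SPEC, times=t).power
        p_noise = total_power(_epochs(noise), SPEC, times=t).power
        p_both = total_power(_epochs(sig + noise), SPEC, times=t).power
        f = np.array(SPEC.freqs_hz) == 70.0
        assert p_both[0, f, 0] == pytest.approx(
            (p_sig + p_noise)[0, f, 0], rel=0.15
        )

    def test_evoked_below_total_pointwise(self):
        ep = _burst_epochs(100, 70.0, phase_locked=False, seed=6, noise=0.5)
        times = np.arange(-0.4, 0.55, 0.05)
        ev = evoked_power(ep, SPEC, times=times)
        tot = total_power(ep, SPEC, times=times)
        assert np.all(ev.power <= tot.power + 1e-9)

    def test_edge_windows_are_nan_flagged(self):
        ep = _burst_epochs(2, 70.0, phase_locked=True)
        with pytest.warns(UserWarning, match="beyond the epoch"):
            ev = evoked_power(ep, SPEC, times=[-0.55, 0.0])
        assert np.isnan(ev.power[..., 0]).all()
        assert np.isfinite(ev.power[..., 1]).all()


class TestBaselineNormalize:
    def _grid(self, power):
        times = np.arange(-0.45, 0.56, 0.05)
        freqs = np.array(SPEC.freqs_hz)
        return TFRGrid(power, freqs, times, ["ch0"], "total")

    def test_percent_change_arithmetic(self):
        times = np.arange(-0.45, 0.56, 0.05)
        power = np.ones((1, 21, len(times)))
        power[..., times >= 0] = 2.0
        out = baseline_normalize(self._grid(power))
        assert np.allclose(out.power[..., times < -0.4], 0.0)
        assert np.allclose(out.power[..., times >= 0], 100.0)

    def test_hand_built_three_bin_baseline(self):
        times = np.arange(-0.45, 0.56, 0.05)
        rng = np.random.default_rng(7)
        power = rng.uniform(1, 2, (1, 21, len(times)))
        out = baseline_normalize(self._grid(power), (-0.4, -0.3))
        mask = (times >= -0.4) & (times <= -0.3)
        assert mask.sum() == 3
        base = power[..., mask].mean(axis=-1, keepdims=True)
        assert np.allclose(out.power, 100 * (power - base) / base, atol=1e-12)
        assert np.all(out.power >= -100.0)

    def test_zero_baseline_names_channel_and_freq(self):
        times = np.arange(-0.45, 0.56, 0.05)
        power = np.ones((1, 21, len(times)))
        power[0, 3, :] = 0.0
        with pytest.raises(ValueError, match="ch0.*42"):
            baseline_normalize(self._grid(power))

    def test_double_normalization_rejected(self):
        times = np.arange(-0.45, 0.56, 0.05)
        out = baseline_normalize(self._grid(np.ones((1, 21, len(times)))))
        with pytest.raises(ValueError, match="already"):
            baseline_normalize(out)


class TestBandExtraction:
    def _uniform_grid(self, value, chans=("O1", "Oz", "O2", "POz")):
        times = np.arange(-0.45, 0.56, 0.05)
        freqs = np.array(SPEC.freqs_hz)
        power = np.full((len(chans), len(freqs), len(times)), value)
        return TFRGrid(power, freqs, times, list(chans), "evoked", normalized=True)

    def test_uniform_grid_returns_value(self):
        assert extract_egba(self._uniform_grid(7.5)) == pytest.approx(7.5)
        grid = self._uniform_grid(3.3, chans=("P7", "PO7", "O1"))
        assert extract_tgba(grid, 62.0, channels=["P7", "PO7", "O1"]) == pytest.approx(3.3)

    def test_evoked_band_power_monotone_in_injected_gain(self):
        p = []
        for gain in (0.5, 1.0, 2.0):
            ep = _burst_epochs(30, 38.0, phase_locked=True, amp=gain, noise=0.2, seed=8)
            ep = _epochs(ep.data, chan_names=["O1"])
            ev = evoked_power(ep, SPEC, times=[0.3, 0.35, 0.4])
            f38 = np.array(SPEC.freqs_hz) == 38.0
            p.append(float(np.nanmax(ev.power[0][f38])))
        assert p[0] < p[1] < p[2]

    def test_alternative_narrow_egba_band_configurable(self):
        grid = self._uniform_grid(5.0)
        assert extract_egba(grid, band_hz=(30.0, 40.0)) == pytest.approx(5.0)

    def test_empty_selection_rejected(self):
        grid = self._uniform_grid(1.0)
        with pytest.raises(ValueError):
            extract_egba(grid, band_hz=(200.0, 300.0))


class TestPeakFrequency:
    def _grid_with_peak(self, peak_hz, chans=("P7", "PO7", "O1")):
        times = np.arange(-0.45, 0.56, 0.05)
        freqs = np.array(SPEC.freqs_hz)
        power = np.zeros((len(chans), len(freqs), len(times)))
        power[:, freqs == peak_hz, times >= 0.2] = 10.0
        return TFRGrid(power, freqs, times, list(chans), "total", normalized=True)

    def test_recovers_synthetic_peak(self):
        grid = self._grid_with_peak(62.0)
        assert select_peak_frequency(grid) == 62.0

    def test_flat_spectrum_ties_to_lowest_bin(self):
        times = np.arange(-0.45, 0.56, 0.05)
        freqs = np.array(SPEC.freqs_hz)
        grid = TFRGrid(
            np.ones((1, len(freqs), len(times))), freqs, times, ["O1"], "total",
            normalized=True,
        )
        with pytest.warns(UserWarning, match="edge"):
            assert select_peak_frequency(grid, search_hz=(40.0, 90.0)) == 42.0

    def test_peak_at_range_edge_warns(self):
        grid = self._grid_with_peak(90.0)
        with pytest.warns(UserWarning, match="edge"):
            assert select_peak_frequency(grid, search_hz=(40.0, 90.0)) == 90.0

    def test_end_to_end_recovery_from_simulated_bursts(self):
        # induced gamma at 62 Hz: grand-mean total power peaks there
        ep = _burst_epochs(80, 62.0, phase_locked=False, amp=2.0, noise=1.0, seed=9)
        ep = _epochs(ep.data, chan_names=["O1"])
        tot = total_power(ep, SPEC, times=np.arange(-0.4, 0.51, 0.05))
        norm = baseline_normalize(tot)
        assert select_peak_frequency(norm, channels=["O1"]) == 62.0


class TestTgbaBand:
    def test_worked_example_58_to_66(self):
        freqs = np.array(SPEC.freqs_hz)
        assert list(tgba_band(62.0, freqs)) == [58.0, 62.0, 66.0]

    def test_edge_peak_uses_available_bins(self):
        freqs = np.array(SPEC.freqs_hz)
        with pytest.warns(UserWarning, match="edge"):
            assert list(tgba_band(30.0, freqs)) == [30.0, 34.0]

    def test_off_grid_peak_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            tgba_band(63.0, np.array(SPEC.freqs_hz))
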