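"""Offline analyses: snippet conditioning, sorting, band power, rates, gating."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from neurotelem.analysis import (
    DEFAULT_BANDS,
    band_power,
    emg_differential,
    firing_rate,
    refilter_and_center,
    sort_spikes,
    threshold_events_gated,
)
from neurotelem.containers import StimSchedule
from neurotelem.synthgen import StimPattern, ap_template, build_stim_schedule

FS = 20_000.0


def two_unit_snippets(n_per=100, amp=200.0, noise=5.0, seed=0):
    rng = np.random.default_rng(seed)
    a = ap_template(0) * amp
    b = ap_template(2) * amp
    snips = np.vstack(
        [a + noise * rng.standard_normal(48) for _ in range(n_per)]
        + [b + noise * rng.standard_normal(48) for _ in range(n_per)]
    )
    labels = np.array([0] * n_per + [1] * n_per)
    return snips, labels


class TestRefilterAndCenter:
    def test_centered_peak_stays_put(self):
        snip = ap_template(0) * 100.0  # trough already at sample 16
        out = refilter_and_center(snip[None, :])[0]
        assert int(np.argmax(np.abs(out))) == 16
        # Band-passing an already in-band waveform barely changes it.
        corr = np.corrcoef(out, snip)[0, 1]
        assert corr > 0.98

    def test_off_center_peak_is_moved_to_center(self):
        snip = np.roll(ap_template(0) * 100.0, -6)  # peak at index 10
        out = refilter_and_center(snip[None, :])[0]
        assert int(np.argmax(np.abs(out))) == 16

    def test_mains_contamination_removed(self):
        t = np.arange(48) / FS
        clean = ap_template(0) * 200.0
        dirty = clean + 60.0 * np.sin(2 * np.pi * 60.0 * t + 0.3)
        out = refilter_and_center(dirty[None, :])[0]
        corr_after = np.corrcoef(out, clean)[0, 1]
        corr_before = np.corrcoef(dirty, clean)[0, 1]
        assert corr_after >= corr_before


class TestSorting:
    def test_well_separated_units_recovered(self):
        snips, truth = two_unit_snippets()
        units = sort_spikes(snips, k=2, seed=0)
        assert adjusted_rand_score(truth, units.labels) >= 0.95
        assert units.mean_waveforms.shape == (2, 48)

    def test_silhouette_selection_finds_two_units(self):
        snips, truth = two_unit_snippets()
        units = sort_spikes(snips, k=None, seed=0)
        assert units.k == 2
        assert adjusted_rand_score(truth, units.labels) >= 0.95

    def test_identical_snippets_collapse_to_one_cluster(self):
        snips = np.tile(ap_template(0) * 100.0, (30, 1))
        units = sort_spikes(snips, k=2, seed=0)
        d = np.linalg.norm(units.mean_waveforms[0] - units.mean_waveforms[1])
        assert d < 1e-6
        units_auto = sort_spikes(snips, k=None, seed=0)
        assert units_auto.k == 1

    def test_fixed_seed_is_deterministic(self):
        snips, _ = two_unit_snippets()
        a = sort_spikes(snips, k=2, seed=42)
        b = sort_spikes(snips, k=2, seed=42)
        assert np.array_equal(a.labels, b.labels)

    def test_invariant_to_snippet_order(self):
        snips, _ = two_unit_snippets()
        perm = np.random.default_rng(5).permutation(snips.shape[0])
        a = sort_spikes(snips, k=2, seed=0)
        b = sort_spikes(snips[perm], k=2, seed=0)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_bad_cluster_counts_rejected(self):
        snips, _ = two_unit_snippets(n_per=3)
        with pytest.raises(ValueError):
            sort_spikes(snips, k=0)
        with pytest.raises(ValueError):
            sort_spikes(snips, k=50)


class TestBandPower:
    def test_pure_theta_tone_lands_in_theta(self):
        fs = 2_000.0
        t = np.arange(int(10 * fs)) / fs
        x = 100.0 * np.sin(2 * np.pi * 6.0 * t)
        table = band_power(x, fs)
        assert table["theta"] >= 99.0

    def test_percentages_sum_to_100(self, rng):
        fs = 2_000.0
        x = rng.standard_normal(int(5 * fs))
        table = band_power(x, fs)
        assert sum(table.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_white_noise_power_tracks_band_widths(self, rng):
        fs = 2_000.0
        x = rng.standard_normal(int(120 * fs))
        table = band_power(x, fs)
        widths = {n: hi - lo for n, (lo, hi) in DEFAULT_BANDS.items()}
        total_width = sum(widths.values())
        for name, pct in table.percentages.items():
            expected = 100.0 * widths[name] / total_width
            assert pct == pytest.approx(expected, rel=0.25)

    def test_bandlimited_signal_concentrates_in_its_band(self, rng):
        from scipy import signal as sps

        fs = 2_000.0
        sos = sps.butter(6, [12, 30], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(int(30 * fs)))
        table = band_power(x, fs)
        assert table["beta"] >= 90.0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(8_000), 2_000.0, bands={"bad": (10.0, 1_500.0)})

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(100), 2_000.0)


class TestFiringRate:
    def test_no_events_all_zero(self):
        _, rates = firing_rate(np.array([]), 0.25, duration_s=2.0)
        assert np.all(rates == 0)

    def test_counts_are_conserved(self, rng):
        times = np.sort(rng.uniform(0, 10.0, size=137))
        _, rates = firing_rate(times, 0.25, duration_s=10.0)
        assert rates.sum() * 0.25 == pytest.approx(137)

    def test_homogeneous_train_mean_rate(self):
        from neurotelem.synthgen import generate_spike_train

        rates_all = []
        for seed in range(40):
            train = generate_spike_train(50.0, 10.0, seed=seed)
            _, r = firing_rate(train.times / FS, 0.25, duration_s=10.0)
            rates_all.append(r.mean())
        rates_all = np.array(rates_all)
        # dead-time-corrected expectation
        expected = 1.0 / (1.0 / 50.0 + 2.4e-3)
        se = rates_all.std(ddof=1) / np.sqrt(rates_all.size)
        assert abs(rates_all.mean() - expected) <= 3 * se


class TestGatedThreshold:
    @pytest.fixture
    def schedule(self):
        return build_stim_schedule(StimPattern(
            pulse_width_s=0.5, train_period_s=5.0, span_s=10.0))

    def test_midlevel_peaks_detected_only_outside_stimulation(self, schedule):
        n = int(10 * FS)
        x = np.zeros(n)
        inside, outside = 1_000, 30_000  # samples in/out of the first pulse
        x[inside] = 50.0
        x[outside] = 50.0
        events = threshold_events_gated(x, thr_in=60.0, thr_out=45.0,
                                        stim_schedule=schedule)
        assert outside in events
        assert inside not in events

    def test_empty_schedule_uses_outer_threshold_everywhere(self):
        x = np.zeros(int(FS))
        x[100] = 50.0
        events = threshold_events_gated(x, thr_in=60.0, thr_out=45.0,
                                        stim_schedule=None)
        assert 100 in events

    def test_dead_time_applies(self):
        x = np.zeros(int(FS))
        x[100] = 50.0
        x[120] = 50.0
        events = threshold_events_gated(x, 60.0, 45.0)
        assert events.tolist() == [100]


class TestEmgDifferential:
    def test_self_subtraction_is_zero(self, rng):
        x = rng.standard_normal(1_000)
        assert np.all(emg_differential(x, x) == 0)

    def test_common_mode_cancels(self, rng):
        common = rng.standard_normal(1_000)
        a, b = common + 1.0, common - 1.0
        assert np.allclose(emg_differential(a, b), 2.0)
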