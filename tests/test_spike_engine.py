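"""Adaptive-threshold detection and the fixed-budget wavelet codec."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from neurotelem.pipeline import match_events
from neurotelem.spike_engine import (
    COMPRESSION_RATIO,
    PAYLOAD_BITS,
    CompressedAp,
    DetectorState,
    compress_ap,
    decompress_ap,
    detect_aps,
    dwt_roundtrip,
    estimate_noise_sigma,
)
from neurotelem.synthgen import ap_template, generate_spike_train, render_spike_component


def float_codec_oracle(snippet, keep=17, q_max=31):
    """Offline float-precision DWT → top-K quantize → reconstruct oracle.

    Independent of the bit-packing path: works on float coefficient arrays
    throughout, with the same retention and quantization rules.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(snippet, "sym4", mode="symmetric", level=4)
    flat = np.concatenate(coeffs)
    order = np.argsort(-np.abs(flat), kind="stable")
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:keep]] = True
    exp = 0
    max_mag = np.max(np.abs(flat[mask])) if keep else 0.0
    while max_mag / 2**exp > q_max:
        exp += 1
    q = np.where(mask, np.clip(np.rint(flat / 2**exp), -q_max, q_max) * 2**exp, 0.0)
    parts, pos = [], 0
    for c in coeffs:
        parts.append(q[pos : pos + len(c)])
        pos += len(c)
    with np.errstate(all="ignore"):
        rec = pywt.waverec(parts, "sym4", mode="symmetric")
    return rec[:48]


def nrmse(a, b):
    rng_ = b.max() - b.min()
    return np.sqrt(np.mean((a - b) ** 2)) / rng_ if rng_ > 0 else 0.0


def make_snippet(seed, amp=3000.0, noise=300.0, template_id=0):
    rng = np.random.default_rng(seed)
    return np.rint(ap_template(template_id) * amp + noise * rng.standard_normal(48))


class TestNoiseSigma:
    def test_zero_window_gives_zero(self):
        assert estimate_noise_sigma(np.zeros(2000)) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.array([]))

    def test_gaussian_sigma_within_5pct(self, rng):
        x = 20.0 * rng.standard_normal(20_000)
        assert estimate_noise_sigma(x) == pytest.approx(20.0, rel=0.05)

    def test_robust_to_sparse_spikes(self, rng):
        x = 20.0 * rng.standard_normal(20_000)
        idx = rng.choice(20_000, size=50, replace=False)
        x[idx] += 500.0
        assert estimate_noise_sigma(x) == pytest.approx(20.0, rel=0.10)


class TestDetection:
    def test_all_zero_signal_yields_no_events(self):
        assert detect_aps(np.zeros(50_000)) == []

    def test_dead_time_suppresses_double_trigger(self, rng):
        x = 1.0 * rng.standard_normal(20_000)
        # two crossings 1 ms (20 samples) apart, well above 4 sigma
        x[1000] += 50.0
        x[1020] += 50.0
        events = detect_aps(x, DetectorState())
        ts = [e.timestamp for e in events if 900 < e.timestamp < 1100]
        assert len(ts) == 1

    def test_recall_and_precision_at_snr8(self):
        """50 AP/s at peak/sigma = 8 over 30 s: both scores >= 0.95."""
        rng = np.random.default_rng(7)
        train = generate_spike_train(50.0, 30.0, seed=17)
        n = 600_000
        sig = render_spike_component([train], 1, n, {0: 160.0})[0]
        sig += 20.0 * rng.standard_normal(n)
        events = detect_aps(sig, DetectorState())
        det = np.array([e.timestamp for e in events])
        matched = match_events(train.times, det, tolerance=20)  # ±1 ms
        assert matched / len(train) >= 0.95          # recall
        assert matched / len(det) >= 0.95            # precision

    def test_detection_count_scales_linearly_with_rate(self):
        """Counts track the true (dead-time-corrected) rate to Poisson error."""
        for rate in (10.0, 50.0, 100.0):
            rng = np.random.default_rng(int(rate))
            train = generate_spike_train(rate, 20.0, seed=int(rate) + 1)
            n = 400_000
            sig = render_spike_component([train], 1, n, {0: 200.0})[0]
            sig += 20.0 * rng.standard_normal(n)
            events = detect_aps(sig, DetectorState())
            expected = len(train)
            assert abs(len(events) - expected) <= 4 * np.sqrt(expected) + 5

    def test_snippet_geometry_and_timestamp_wrap(self, rng):
        x = 1.0 * rng.standard_normal(20_000)
        x[5000] -= 60.0
        (event,) = [e for e in detect_aps(x) if abs(e.timestamp - 5000) < 5]
        assert event.snippet.size == 48
        assert 0 <= event.timestamp < 2**24


class TestCodec:
    def test_zero_snippet_roundtrips_to_zero(self):
        out = decompress_ap(compress_ap(np.zeros(48)))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_payload_is_184_bits_for_any_input(self, rng):
        for seed in range(5):
            c = compress_ap(make_snippet(seed))
            assert len(c.payload) * 8 == PAYLOAD_BITS
        assert 48 * 16 / PAYLOAD_BITS == pytest.approx(4.17, abs=0.005)
        assert COMPRESSION_RATIO == pytest.approx(4.17, abs=0.005)

    def test_wrong_snippet_length_rejected(self):
        with pytest.raises(ValueError):
            compress_ap(np.zeros(47))

    def test_roundtrip_nrmse_bounded_by_float_oracle(self):
        """Bit-packed codec error <= float-precision oracle error + 1%."""
        for seed in range(20):
            snip = make_snippet(seed, amp=3000.0, noise=300.0)  # SNR 10
            packed = decompress_ap(compress_ap(snip))
            oracle = float_codec_oracle(snip)
            assert nrmse(packed, snip) <= nrmse(oracle, snip) + 0.01

    def test_roundtrip_preserves_peak_position(self):
        for seed in range(20):
            snip = make_snippet(seed, amp=3200.0, noise=400.0)  # SNR 8
            out = decompress_ap(compress_ap(snip))
            assert abs(int(np.argmax(np.abs(out))) - int(np.argmax(np.abs(snip)))) <= 1

    def test_codec_determinism(self):
        snip = make_snippet(3)
        assert compress_ap(snip).payload == compress_ap(snip).payload

    def test_error_decreases_with_bit_budget(self):
        """Round-trip error ordering over the 92/184/368-bit budgets."""
        errs = {}
        for bits in (92, 184, 368):
            e = []
            for seed in range(10):
                snip = make_snippet(seed)
                out = decompress_ap(compress_ap(snip, payload_bits=bits))
                e.append(nrmse(out, snip))
            errs[bits] = np.mean(e)
        assert errs[368] < errs[184] < errs[92]

    def test_unquantized_dwt_roundtrip_is_exact(self, rng):
        x = rng.standard_normal(48) * 1000
        out = dwt_roundtrip(x)
        assert np.max(np.abs(out - x)) / np.max(np.abs(x)) < 1e-9

    def test_corrupt_payload_rejected(self):
        c = compress_ap(make_snippet(0))
        with pytest.raises(ValueError):
            CompressedAp(channel=0, timestamp=0, payload=c.payload[:-1])
        # A bitmap claiming more coefficients than the budget allows:
        bad = bytes([0x00, 0xFF, 0xFF, 0xFF, 0xFF, 0xFF, 0xFF, 0xFF, 0xFF,
                     0xFF, 0xFF]) + c.payload[11:]
        with pytest.raises(ValueError):
            decompress_ap(CompressedAp(channel=0, timestamp=0, payload=bad))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_fixed_payload_and_bounded_error_for_random_snippets(self, seed):
        snip = make_snippet(seed)
        c = compress_ap(snip)
        assert len(c.payload) * 8 == PAYLOAD_BITS
        assert nrmse(decompress_ap(c), snip) <= 0.2
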