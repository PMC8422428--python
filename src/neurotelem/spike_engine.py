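"""AP detection and wavelet compression on the high-pass path.

Detection uses an adaptive absolute-value threshold: a robust noise estimate
(median absolute deviation scaled to Gaussian sigma) is refreshed over a
sliding window, the threshold is ``k`` times that estimate (k = 4 by
default), and each crossing clips a 48-sample snippet (16 samples before the
crossing, 32 after — 2.4 ms at 20 ksps) with a dead time of one snippet
suppressing re-triggers.

Compression applies a 4-level discrete wavelet transform (Symmlet-4 by
default, symmetric boundary extension) to each snippet and packs the result
into a fixed 184-bit payload: a 6-bit shared scale exponent, a bitmap over
the 74 wavelet coefficients marking which are retained, and the 17
largest-magnitude coefficients quantized to 6 bits each.  At 16 bits per raw
sample this yields a compression ratio of 48×16 / 184 ≈ 4.17.  Decompression
inverts the quantization and the wavelet transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

SNIPPET_SAMPLES = 48
PRE_SAMPLES = 16
POST_SAMPLES = 32
TIMESTAMP_BITS = 24
TIMESTAMP_MOD = 1 << TIMESTAMP_BITS

PAYLOAD_BITS = 184
RAW_SNIPPET_BITS = SNIPPET_SAMPLES * 16  # 768
COMPRESSION_RATIO = RAW_SNIPPET_BITS / PAYLOAD_BITS  # ≈ 4.17

DWT_LEVELS = 4
DEFAULT_WAVELET = "sym4"
DWT_MODE = "symmetric"
COEFF_BITS = 6
EXPONENT_BITS = 6

# MAD-to-sigma consistency constant for Gaussian noise.
MAD_SCALE = 0.6745


# ---------------------------------------------------------------------------
# Noise estimation and detection
# ---------------------------------------------------------------------------

@dataclass
class DetectorState:
    """Adaptive-threshold detector parameters.

    ``sigma`` is the per-channel noise estimate in signal units; it is
    refreshed every ``window_samples`` from the median absolute deviation of
    that stretch, which is robust to the spikes themselves.  ``k`` scales
    sigma into the detection threshold and ``dead_time`` (≥ one snippet)
    suppresses multiple triggers on one waveform.
    """

    k: float = 4.0
    dead_time: int = SNIPPET_SAMPLES
    window_samples: int = 20_000  # 1 s at 20 ksps
    sigma: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("threshold multiplier must be positive")
        if self.dead_time < SNIPPET_SAMPLES:
            raise ValueError("dead time must cover one snippet")
        if self.window_samples < 1_000:
            raise ValueError("estimation window must span at least 1,000 samples")


@dataclass
class ApEvent:
    """One detected action potential.

    ``timestamp`` is the threshold-crossing sample index modulo 2^24 (the
    wire format's counter width); ``snippet`` holds the 48 samples around
    the crossing in the units of the filtered signal.
    """

    channel: int
    timestamp: int
    snippet: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        self.snippet = np.asarray(self.snippet)
        if self.snippet.size != SNIPPET_SAMPLES:
            raise ValueError(f"snippet must have {SNIPPET_SAMPLES} samples")
        if not (0 <= self.timestamp < TIMESTAMP_MOD):
            raise ValueError("timestamp outside the 24-bit range")


def estimate_noise_sigma(window: np.ndarray) -> float:
    """Robust noise sigma: ``median(|x|) / 0.6745``.

    For zero-mean Gaussian noise this is a consistent sigma estimator, and
    sparse large spikes barely move the median, unlike the sample standard
    deviation.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("cannot estimate noise from an empty window")
    return float(np.median(np.abs(window)) / MAD_SCALE)


def detect_aps(
    hp_signal: np.ndarray,
    state: DetectorState | None = None,
    channel: int = 0,
    saturation_code: float | None = None,
) -> list[ApEvent]:
    """Detect APs on one channel of the high-pass path.

    The signal is scanned in consecutive estimation windows; within each
    window the threshold is ``k × sigma`` of that window's MAD estimate.
    A sample whose absolute value crosses the threshold (from below) starts
    an event: 16 samples before and 32 after the crossing form the snippet,
    and further crossings within the dead time are ignored.  Crossings too
    close to the array edges for a full snippet are dropped.

    Returns events ordered by time; ``state.sigma[channel]`` is left at the
    last window's estimate.
    """
    if state is None:
        state = DetectorState()
    x = np.asarray(hp_signal, dtype=float)
    n = x.size
    events: list[ApEvent] = []
    if n == 0:
        return events

    absx = np.abs(x)
    last_fire = -np.inf
    for w0 in range(0, n, state.window_samples):
        w1 = min(w0 + state.window_samples, n)
        sigma = estimate_noise_sigma(x[w0:w1])
        state.sigma[channel] = sigma
        thr = state.k * sigma
        if thr == 0:
            continue
        over = absx[w0:w1] >= thr
        # Rising edges: first sample of each supra-threshold run.
        idx = np.flatnonzero(over & ~np.concatenate(([False], over[:-1])))
        # The first sample of the window continues the previous run only if
        # the previous window's last sample was also over its own threshold;
        # dead time handles the remaining boundary double counts.
        for i in idx + w0:
            if i - last_fire < state.dead_time:
                continue
            a, b = i - PRE_SAMPLES, i + POST_SAMPLES
            if a < 0 or b > n:
                continue
            snip = x[a:b]
            sat = bool(
                saturation_code is not None
                and np.any(np.abs(snip) >= saturation_code)
            )
            events.append(
                ApEvent(channel=channel, timestamp=int(i % TIMESTAMP_MOD),
                        snippet=snip.copy(), saturated=sat)
            )
            last_fire = i
    return events


# ---------------------------------------------------------------------------
# Wavelet codec
# ---------------------------------------------------------------------------

def _dwt_coeffs(snippet: np.ndarray, wavelet: str) -> tuple[np.ndarray, list[int]]:
    """Forward 4-level DWT, flattened, plus the per-level lengths."""
    with warnings.catch_warnings():
        # 4 levels on 48 samples is at the depth limit by design.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(snippet, wavelet, mode=DWT_MODE, level=DWT_LEVELS)
    lengths = [len(c) for c in coeffs]
    return np.concatenate(coeffs), lengths


def _idwt_coeffs(flat: np.ndarray, lengths: list[int], wavelet: str) -> np.ndarray:
    parts = []
    pos = 0
    for ln in lengths:
        parts.append(flat[pos : pos + ln])
        pos += ln
    rec = pywt.waverec(parts, wavelet, mode=DWT_MODE)
    return rec[:SNIPPET_SAMPLES]


def _coeff_count(wavelet: str) -> int:
    return sum(_dwt_coeffs(np.zeros(SNIPPET_SAMPLES), wavelet)[1])


def _payload_geometry(payload_bits: int, n_coeffs: int) -> int:
    """Number of coefficients retainable within the bit budget."""
    keep = (payload_bits - EXPONENT_BITS - n_coeffs) // COEFF_BITS
    if keep < 1:
        raise ValueError(f"bit budget {payload_bits} too small for the bitmap")
    return int(keep)


@dataclass
class CompressedAp:
    """Fixed-budget wavelet code of one AP snippet.

    ``payload`` is exactly ``payload_bits / 8`` bytes: 6-bit scale exponent,
    one bitmap bit per wavelet coefficient, then the retained coefficients
    as 6-bit two's-complement mantissas, zero-padded to the budget.
    """

    channel: int
    timestamp: int
    payload: bytes
    payload_bits: int = PAYLOAD_BITS
    wavelet: str = DEFAULT_WAVELET

    def __post_init__(self) -> None:
        expected = (self.payload_bits + 7) // 8
        if len(self.payload) != expected:
            raise ValueError(
                f"payload is {len(self.payload)} bytes, expected {expected}"
            )

    @property
    def scale_exponent(self) -> int:
        return (self.payload[0] >> 2) & 0x3F


class _BitWriter:
    def __init__(self) -> None:
        self.bits: list[int] = []

    def write(self, value: int, n: int) -> None:
        for i in range(n - 1, -1, -1):
            self.bits.append((value >> i) & 1)

    def to_bytes(self, total_bits: int) -> bytes:
        padded = ((total_bits + 7) // 8) * 8
        bits = self.bits + [0] * (padded - len(self.bits))
        out = bytearray()
        for i in range(0, padded, 8):
            byte = 0
            for b in bits[i : i + 8]:
                byte = (byte << 1) | b
            out.append(byte)
        return bytes(out)


class _BitReader:
    def __init__(self, payload: bytes) -> None:
        self.payload = payload
        self.pos = 0

    def read(self, n: int) -> int:
        value = 0
        for _ in range(n):
            byte = self.payload[self.pos // 8]
            bit = (byte >> (7 - self.pos % 8)) & 1
            value = (value << 1) | bit
            self.pos += 1
        return value


def compress_ap(
    snippet: np.ndarray,
    channel: int = 0,
    timestamp: int = 0,
    payload_bits: int = PAYLOAD_BITS,
    wavelet: str = DEFAULT_WAVELET,
) -> CompressedAp:
    """Compress one 48-sample snippet to a fixed-size wavelet payload.

    The snippet is transformed (4-level DWT), the largest-magnitude
    coefficients that fit the bit budget are retained, and all retained
    coefficients share one power-of-two scale chosen so the largest fits a
    6-bit signed mantissa.  The codec is deterministic: magnitude ties are
    broken by coefficient index.
    """
    snippet = np.asarray(snippet, dtype=float)
    if snippet.size != SNIPPET_SAMPLES:
        raise ValueError(f"snippet must have {SNIPPET_SAMPLES} samples")
    flat, _lengths = _dwt_coeffs(snippet, wavelet)
    n_coeffs = flat.size
    keep = _payload_geometry(payload_bits, n_coeffs)
    keep = min(keep, n_coeffs)

    # Stable selection of the largest-magnitude coefficients.
    order = np.lexsort((np.arange(n_coeffs), -np.abs(flat)))
    selected = np.sort(order[:keep])

    max_mag = float(np.max(np.abs(flat[selected]))) if keep else 0.0
    q_max = 2 ** (COEFF_BITS - 1) - 1  # 31
    exp = 0
    while max_mag / 2**exp > q_max and exp < 2**EXPONENT_BITS - 1:
        exp += 1
    q = np.clip(np.rint(flat[selected] / 2**exp), -q_max, q_max).astype(int)

    writer = _BitWriter()
    writer.write(exp, EXPONENT_BITS)
    mask = np.zeros(n_coeffs, dtype=bool)
    mask[selected] = True
    for bit in mask:
        writer.write(int(bit), 1)
    for val in q:
        writer.write(int(val) & ((1 << COEFF_BITS) - 1), COEFF_BITS)
    payload = writer.to_bytes(payload_bits)
    return CompressedAp(channel=channel, timestamp=timestamp, payload=payload,
                        payload_bits=payload_bits, wavelet=wavelet)


def decompress_ap(compressed: CompressedAp) -> np.ndarray:
    """Reconstruct a 48-sample snippet from its wavelet payload."""
    n_coeffs = _coeff_count(compressed.wavelet)
    _, lengths = _dwt_coeffs(np.zeros(SNIPPET_SAMPLES), compressed.wavelet)
    expected_bytes = (compressed.payload_bits + 7) // 8
    if len(compressed.payload) != expected_bytes:
        raise ValueError("payload length does not match the declared bit budget")
    reader = _BitReader(compressed.payload)
    exp = reader.read(EXPONENT_BITS)
    mask = np.array([reader.read(1) for _ in range(n_coeffs)], dtype=bool)
    keep = int(mask.sum())
    max_keep = _payload_geometry(compressed.payload_bits, n_coeffs)
    if keep > max_keep:
        raise ValueError("corrupt payload: bitmap retains more coefficients "
                         "than the bit budget allows")
    half = 1 << (COEFF_BITS - 1)
    flat = np.zeros(n_coeffs)
    vals = []
    for _ in range(keep):
        raw = reader.read(COEFF_BITS)
        vals.append(raw - (1 << COEFF_BITS) if raw >= half else raw)
    flat[mask] = np.asarray(vals, dtype=float) * 2**exp
    return _idwt_coeffs(flat, lengths, compressed.wavelet)


def dwt_roundtrip(snippet: np.ndarray, wavelet: str = DEFAULT_WAVELET) -> np.ndarray:
    """Forward + inverse DWT with no quantization (perfect-reconstruction
    check of the filter bank)."""
    flat, lengths = _dwt_coeffs(np.asarray(snippet, dtype=float), wavelet)
    return _idwt_coeffs(flat, lengths, wavelet)
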