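"""Dual-path digital separation engine.

Splits the 20 ksps digitized stream into two bands with linear-phase FIR
filters designed by the windowed-sinc method with a Kaiser window:

* AP path — 41-tap symmetric high-pass at 300 Hz (Kaiser β = 0.1), kept at
  the full sampling rate for spike detection and compression.
* LFP/EMG path — 39-tap symmetric low-pass at 500 Hz (Kaiser β = 3), then
  decimated by 10 to 2 ksps.

Both filters run through one shared time-multiplexed data path visited
round-robin across up to 32 channels, modeled here as a single filter engine
holding one delay-line state per channel.  Symmetric taps let the hardware
halve the multiplication count by reusing products, and the clock budget
(cycles available per sample) bounds the feasible tap count; both quantities
are computed explicitly so designs can be checked against the budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import MultichannelRecording

MAX_CHANNELS = 32

# Default designs for the two paths.
AP_HIGHPASS = dict(kind="high-pass", cutoff=300.0, n_taps=41, beta=0.1)
LFP_LOWPASS = dict(kind="low-pass", cutoff=500.0, n_taps=39, beta=3.0)
LFP_DECIMATION = 10


@dataclass
class CycleBudget:
    """Clock cycles available to process one sample of one channel.

    With a shared data path, all ``n_channels`` samples of one sampling
    period must be processed within that period, so
    ``n_cycles_max = f_clk / (fs * n_channels)``.
    """

    f_clk: float
    fs: float
    n_channels: int
    n_cycles_max: float = field(init=False)

    def __post_init__(self) -> None:
        if self.f_clk <= 0 or self.fs <= 0 or self.n_channels <= 0:
            raise ValueError("clock, sampling rate and channel count must be positive")
        self.n_cycles_max = self.f_clk / (self.fs * self.n_channels)


def cycle_budget(f_clk: float, fs: float, n_channels: int) -> CycleBudget:
    """Cycles-per-sample budget of a shared processing path."""
    return CycleBudget(f_clk=f_clk, fs=fs, n_channels=n_channels)


@dataclass
class FilterSpec:
    """A designed symmetric FIR filter plus its design parameters.

    Symmetry (``taps[i] == taps[n-1-i]``) is required by the
    product-reuse scheme and implies linear phase with group delay
    ``(n_taps - 1) / 2`` samples.
    """

    taps: np.ndarray
    kind: str
    cutoff: float
    beta: float
    fs: float
    quantized_bits: int | None = None

    def __post_init__(self) -> None:
        self.taps = np.asarray(self.taps, dtype=float)
        if not np.allclose(self.taps, self.taps[::-1], rtol=0, atol=1e-12):
            raise ValueError("FIR taps must be symmetric")
        if self.kind not in ("high-pass", "low-pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")

    @property
    def n_taps(self) -> int:
        return int(self.taps.size)

    @property
    def group_delay(self) -> float:
        """Linear-phase group delay in samples."""
        return (self.n_taps - 1) / 2.0

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex frequency response at ``freqs`` in Hz."""
        _, h = sps.freqz(self.taps, worN=np.asarray(freqs, dtype=float), fs=self.fs)
        return h


def design_kaiser_fir(
    kind: str,
    cutoff: float,
    n_taps: int,
    beta: float,
    fs: float,
    budget: CycleBudget | None = None,
    quantize_bits: int | None = None,
) -> FilterSpec:
    """Design a symmetric windowed-sinc FIR with a Kaiser window.

    The low-pass is a Kaiser-windowed sinc normalized to unit DC gain; the
    high-pass is its spectral inversion (delta minus the complementary
    low-pass), which gives unit gain at Nyquist.  The −6 dB point of the
    design sits at ``cutoff``.

    If a :class:`CycleBudget` is supplied, the design is rejected when even
    the symmetric-reuse multiplication count ``ceil(n_taps / 2)`` exceeds
    the whole cycles available per sample.

    ``quantize_bits`` optionally rounds the taps to signed fixed-point of
    that word length (hardware-style coefficient quantization).
    """
    if not (0 < cutoff < fs / 2):
        raise ValueError("cutoff must lie within (0, fs/2)")
    if n_taps < 3:
        raise ValueError("need at least 3 taps")
    if budget is not None:
        mults = math.ceil(n_taps / 2)
        if mults > budget.n_cycles_max:
            raise ValueError(
                f"{n_taps} taps need {mults} multiplications/sample with "
                f"symmetric reuse, exceeding the budget of "
                f"{budget.n_cycles_max:g} cycles/sample "
                f"(f_clk={budget.f_clk:g}, fs={budget.fs:g}, "
                f"n_channels={budget.n_channels})"
            )

    lowpass = sps.firwin(n_taps, cutoff, window=("kaiser", beta), fs=fs,
                         pass_zero=True, scale=True)
    if kind == "low-pass":
        taps = lowpass
    elif kind == "high-pass":
        if n_taps % 2 == 0:
            raise ValueError("spectral-inversion high-pass needs an odd tap count")
        taps = -lowpass
        taps[(n_taps - 1) // 2] += 1.0
    else:
        raise ValueError(f"unknown filter kind {kind!r}")

    if quantize_bits is not None:
        # Fixed-point coefficients: scale to the signed range, round, rescale.
        scale = 2 ** (quantize_bits - 1) - 1
        m = np.max(np.abs(taps))
        q = np.rint(taps / m * scale)
        taps = q * m / scale

    return FilterSpec(taps=taps, kind=kind, cutoff=cutoff, beta=beta, fs=fs,
                      quantized_bits=quantize_bits)


def multiplication_count(spec: FilterSpec, symmetric_reuse: bool = True) -> int:
    """Multiplications per output sample for one channel.

    Direct convolution needs one product per tap; reusing the products of
    symmetric tap pairs halves that to ``ceil(n_taps / 2)``.
    """
    return math.ceil(spec.n_taps / 2) if symmetric_reuse else spec.n_taps


class MultiplexedFIR:
    """One shared FIR engine with a per-channel delay-line bank.

    Mirrors the hardware scheme: a single set of coefficients and one
    multiply-accumulate path, with a bank of per-channel filter states
    visited round-robin, so adding channels adds only state, not logic.
    Because channels never share state, the output equals direct per-channel
    causal convolution sample-for-sample.
    """

    def __init__(self, spec: FilterSpec, n_channels: int):
        if not (1 <= n_channels <= MAX_CHANNELS):
            raise ValueError(f"channel count must be in 1..{MAX_CHANNELS}")
        self.spec = spec
        self.n_channels = n_channels
        # Delay-line bank: one lfilter state vector per channel.
        self._state = np.zeros((n_channels, spec.n_taps - 1))

    def process(self, block: np.ndarray) -> np.ndarray:
        """Filter a (n_channels, n_samples) block, advancing channel states."""
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] != self.n_channels:
            raise ValueError(
                f"block has {block.shape[0]} channels, engine configured for "
                f"{self.n_channels}"
            )
        out = np.empty_like(block)
        for ch in range(self.n_channels):  # round-robin channel visit
            out[ch], self._state[ch] = sps.lfilter(
                self.spec.taps, [1.0], block[ch], zi=self._state[ch]
            )
        return out


def filter_multiplexed(
    rec: MultichannelRecording, spec: FilterSpec, block_size: int = 65536
) -> MultichannelRecording:
    """Run a recording through the shared multiplexed FIR engine.

    The engine processes the stream in blocks, visiting every channel
    round-robin within each block while carrying per-channel delay-line
    state across block boundaries, so the result is independent of
    ``block_size`` and identical to direct per-channel convolution.  The
    first ``n_taps − 1`` output samples are the causal settling transient.
    """
    if rec.n_channels > MAX_CHANNELS:
        raise ValueError(f"recording has {rec.n_channels} channels, "
                         f"the data path supports at most {MAX_CHANNELS}")
    engine = MultiplexedFIR(spec, rec.n_channels)
    x = np.asarray(rec.data, dtype=float)
    out = np.empty_like(x)
    for start in range(0, x.shape[1], block_size):
        stop = min(start + block_size, x.shape[1])
        out[:, start:stop] = engine.process(x[:, start:stop])
    return MultichannelRecording(data=out, fs=rec.fs, units=rec.units,
                                 scale=rec.scale)


def decimate_lfp(
    signal: np.ndarray | MultichannelRecording, factor: int = LFP_DECIMATION
) -> np.ndarray | MultichannelRecording:
    """Keep every ``factor``-th sample, starting at index 0.

    The input must already be low-pass filtered below the post-decimation
    Nyquist (the 500 Hz low-pass leaves margin below the 1 kHz Nyquist of
    the 2 ksps output).  No additional filtering is applied here.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("decimation factor must be a positive integer")
    if isinstance(signal, MultichannelRecording):
        return MultichannelRecording(
            data=signal.data[:, ::factor],
            fs=signal.fs / factor,
            units=signal.units,
            scale=signal.scale,
        )
    return np.asarray(signal)[..., ::factor]


def separate_bands(
    rec: MultichannelRecording,
    ap_spec: FilterSpec | None = None,
    lfp_spec: FilterSpec | None = None,
    decimation: int = LFP_DECIMATION,
) -> tuple[MultichannelRecording, MultichannelRecording]:
    """Run both data paths: (AP at input rate, LFP/EMG decimated).

    Defaults reproduce the platform design: 41-tap 300 Hz high-pass for the
    AP path and 39-tap 500 Hz low-pass decimated by 10 for the LFP/EMG path.
    """
    if ap_spec is None:
        ap_spec = design_kaiser_fir(fs=rec.fs, **AP_HIGHPASS)
    if lfp_spec is None:
        lfp_spec = design_kaiser_fir(fs=rec.fs, **LFP_LOWPASS)
    ap_path = filter_multiplexed(rec, ap_spec)
    lfp_path = decimate_lfp(filter_multiplexed(rec, lfp_spec), decimation)
    return ap_path, lfp_path
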