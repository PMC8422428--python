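"""Analog front-end emulation: band-pass conditioning and 16-bit ADC.

Models a 32-channel neural recording interface whose input stage is a
first-order analog high-pass (configurable 0.1–500 Hz) cascaded with a
third-order Butterworth low-pass (configurable 100 Hz – 20 kHz), followed by
a ±5 mV full-scale 16-bit ADC sampling every channel at the same rate.  One
configuration applies to all channels, matching the shared-filter hardware.

The analog filters are emulated as their discrete-time bilinear-transform
equivalents at the system sampling rate, which preserves the pass-band
behavior at the frequencies of interest.  The quantizer is mid-tread,
two's-complement and saturating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import MultichannelRecording

# Chip limits for the configurable analog corner frequencies (Hz).
HP_RANGE = (0.1, 500.0)
LP_RANGE = (100.0, 20_000.0)
FULL_SCALE_UV = 5_000.0  # ±5 mV input range
ADC_BITS = 16


@dataclass
class FrontendConfig:
    """Analog conditioning and ADC parameters, shared by all channels."""

    hp_cutoff: float = 0.25
    lp_cutoff: float = 7_500.0
    fs: float = 20_000.0
    full_scale_uv: float = FULL_SCALE_UV
    bits: int = ADC_BITS

    def __post_init__(self) -> None:
        if not (HP_RANGE[0] <= self.hp_cutoff <= HP_RANGE[1]):
            raise ValueError(
                f"high-pass cutoff {self.hp_cutoff} Hz outside the "
                f"configurable range {HP_RANGE[0]}-{HP_RANGE[1]} Hz"
            )
        if not (LP_RANGE[0] <= self.lp_cutoff <= LP_RANGE[1]):
            raise ValueError(
                f"low-pass cutoff {self.lp_cutoff} Hz outside the "
                f"configurable range {LP_RANGE[0]}-{LP_RANGE[1]} Hz"
            )
        if self.hp_cutoff >= self.lp_cutoff:
            raise ValueError("high-pass cutoff must be below low-pass cutoff")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def lsb_uv(self) -> float:
        """Quantization step: full input span over the code count."""
        return 2.0 * self.full_scale_uv / 2**self.bits

    @property
    def code_max(self) -> int:
        return 2 ** (self.bits - 1) - 1

    @property
    def code_min(self) -> int:
        return -(2 ** (self.bits - 1))


def _bandpass_sos(config: FrontendConfig) -> np.ndarray:
    """Discrete equivalents of the analog cascade (bilinear transform)."""
    nyq = config.fs / 2.0
    hp = sps.butter(1, config.hp_cutoff / nyq, btype="highpass", output="sos")
    lp_cut = min(config.lp_cutoff, 0.99 * nyq)  # clamp at Nyquist for emulation
    lp = sps.butter(3, lp_cut / nyq, btype="lowpass", output="sos")
    return np.vstack([hp, lp])


def analog_bandpass(signal: np.ndarray, config: FrontendConfig) -> np.ndarray:
    """Apply the emulated analog band-pass causally, per channel.

    Accepts a 1-D trace or a (n_channels, n_samples) matrix in microvolts and
    returns the conditioned signal in microvolts, same shape.
    """
    x = np.asarray(signal, dtype=float)
    sos = _bandpass_sos(config)
    return sps.sosfilt(sos, x, axis=-1)


def bandpass_response(config: FrontendConfig, freqs: np.ndarray) -> np.ndarray:
    """Complex frequency response of the emulated cascade at ``freqs`` (Hz)."""
    sos = _bandpass_sos(config)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=config.fs)
    return h

def adc_quantize(signal: np.ndarray, config: FrontendConfig) -> np.ndarray:
    """Mid-tread quantization of microvolts to signed 16-bit codes.

    ``code = round(x / LSB)`` with the LSB spanning the ±full-scale range;
    out-of-range inputs saturate at the code limits (defined behavior, not an
    error).  Quantization error is at most half an LSB for in-range inputs,
    and the mapping is monotone non-decreasing.
    """
    x = np.asarray(signal, dtype=float)
    codes = np.rint(x / config.lsb_uv)
    return np.clip(codes, config.code_min, config.code_max).astype(np.int32)


def digitize_recording(
    rec: MultichannelRecording, config: FrontendConfig
) -> MultichannelRecording:
    """Condition an analog recording and convert it to ADC codes."""
    if rec.units != "uV":
        raise ValueError("expected an analog (microvolt) recording")
    conditioned = analog_bandpass(rec.data, config)
    codes = adc_quantize(conditioned, config)
    return MultichannelRecording(
        data=codes, fs=rec.fs, units="adc", scale=config.lsb_uv
    )
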