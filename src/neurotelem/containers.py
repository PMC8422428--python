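"""Shared in-memory and on-disk containers.

A recording is a time-aligned sample matrix, one row per electrode channel,
plus the metadata needed to interpret it: the sampling rate and, when the
samples are ADC codes, the scale in microvolts per least-significant bit.

The on-disk container is deliberately simple: a one-line JSON header
(terminated by a newline) followed by channel-interleaved little-endian
16-bit sample frames.  Analog (float microvolt) recordings are stored the
same way after quantization through the front-end, so files always hold
integer codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CONTAINER_MAGIC = "neurotelem-recording"
CONTAINER_VERSION = 1


@dataclass
class MultichannelRecording:
    """Time-aligned multichannel sample matrix.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``.  Either float microvolts
        (``units == "uV"``) or integer ADC codes (``units == "adc"``).
    fs:
        Sampling rate in samples per second, identical for all channels.
    units:
        ``"uV"`` for analog signals, ``"adc"`` for quantized codes.
    scale:
        Microvolts per LSB when ``units == "adc"``; ignored otherwise.
    """

    data: np.ndarray
    fs: float
    units: str = "uV"
    scale: float | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_channels, n_samples) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.units not in ("uV", "adc"):
            raise ValueError(f"unknown units {self.units!r}")
        if self.units == "adc" and self.scale is None:
            raise ValueError("ADC-code recordings require a scale (uV/LSB)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def to_microvolts(self) -> np.ndarray:
        """Return the samples in microvolts regardless of storage units."""
        if self.units == "uV":
            return np.asarray(self.data, dtype=float)
        return np.asarray(self.data, dtype=float) * float(self.scale)


def write_recording(path: str | Path, rec: MultichannelRecording) -> None:
    """Write a recording as JSON header + interleaved int16 LE frames.

    Analog recordings must be quantized first (see
    :func:`neurotelem.frontend.adc_quantize`); only integer codes that fit
    in 16 bits are accepted.
    """
    if rec.units != "adc":
        raise ValueError("container stores ADC codes; quantize first")
    codes = np.asarray(rec.data)
    if codes.min() < -32768 or codes.max() > 32767:
        raise ValueError("codes exceed the signed 16-bit range")
    header = {
        "magic": CONTAINER_MAGIC,
        "version": CONTAINER_VERSION,
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "scale_uv_per_lsb": rec.scale,
    }
    frames = np.ascontiguousarray(codes.T.astype("<i2"))  # channel-interleaved
    with open(path, "wb") as fh:
        fh.write(json.dumps(header).encode("utf-8") + b"\n")
        fh.write(frames.tobytes())


def read_recording(path: str | Path) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording`."""
    with open(path, "rb") as fh:
        header_line = fh.readline()
        raw = fh.read()
    header = json.loads(header_line.decode("utf-8"))
    if header.get("magic") != CONTAINER_MAGIC:
        raise ValueError(f"{path}: not a neurotelem recording container")
    n_ch = int(header["n_channels"])
    n_samp = int(header["n_samples"])
    frames = np.frombuffer(raw, dtype="<i2", count=n_ch * n_samp)
    data = frames.reshape(n_samp, n_ch).T.astype(np.int32)
    return MultichannelRecording(
        data=data,
        fs=float(header["fs"]),
        units="adc",
        scale=float(header["scale_uv_per_lsb"]),
    )


@dataclass
class StimSchedule:
    """Sorted, non-overlapping (on, off) stimulation intervals in samples."""

    intervals: list[tuple[int, int]] = field(default_factory=list)
    fs: float = 20_000.0

    def __post_init__(self) -> None:
        ivs = [(int(a), int(b)) for a, b in self.intervals]
        ivs.sort()
        for (a, b) in ivs:
            if b <= a:
                raise ValueError(f"empty or inverted interval ({a}, {b})")
        for (_, b0), (a1, _) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("overlapping stimulation pulses")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def mask(self, n_samples: int) -> np.ndarray:
        """Boolean array: True where a stimulation pulse is on."""
        m = np.zeros(n_samples, dtype=bool)
        for a, b in self.intervals:
            m[max(a, 0) : min(b, n_samples)] = True
        return m
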