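"""Base-station side: packet decoding and session reconstruction.

The incoming stream interleaves AP packets (compressed snippets with 24-bit
timestamps) and LFP/EMG packets (13 decimated samples each, channel
round-robin).  Decoding partitions the two flavors, restores absolute spike
times by tracking rollovers of the 24-bit counter (an epoch counter is
incremented whenever a timestamp decreases — the counter wraps every
2^24 samples, about 839 s at 20 ksps), decompresses each AP and places it at
its timestamp on an otherwise-zero trace, alongside the de-interleaved
decimated LFP/EMG traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import telemetry
from .spike_engine import (
    PRE_SAMPLES,
    SNIPPET_SAMPLES,
    TIMESTAMP_MOD,
    CompressedAp,
    decompress_ap,
)


@dataclass
class DecodedStream:
    """Typed view of a packet stream after decoding."""

    ap_events: list[CompressedAp] = field(default_factory=list)
    ap_timestamps: list[int] = field(default_factory=list)  # absolute, rollover-corrected
    lfp_samples: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    lfp_start_channels: list[int] = field(default_factory=list)


def depacketize(stream: bytes | list[bytes]) -> DecodedStream:
    """Split a packet stream into AP events and the LFP/EMG sample stream.

    ``stream`` is either raw file bytes (beginning with the magic) or a list
    of 28-byte records.  Record order is preserved within each flavor.
    Unknown type codes and truncated records raise a decode error naming the
    byte offset.
    """
    if isinstance(stream, (bytes, bytearray)):
        blob = bytes(stream)
        if blob[: len(telemetry.STREAM_MAGIC)] != telemetry.STREAM_MAGIC:
            raise ValueError("stream does not begin with the packet-stream magic")
        body = blob[len(telemetry.STREAM_MAGIC):]
        offset0 = len(telemetry.STREAM_MAGIC)
        records = []
        for i in range(0, len(body), telemetry.PACKET_BYTES):
            rec = body[i : i + telemetry.PACKET_BYTES]
            if len(rec) != telemetry.PACKET_BYTES:
                raise ValueError(
                    f"truncated record at byte offset {offset0 + i}"
                )
            records.append(rec)
    else:
        records = list(stream)
        offset0 = 0

    out = DecodedStream()
    lfp_chunks: list[list[int]] = []
    epoch = 0
    prev_ts = -1
    for i, rec in enumerate(records):
        if len(rec) != telemetry.PACKET_BYTES:
            raise ValueError(
                f"truncated record at byte offset "
                f"{offset0 + i * telemetry.PACKET_BYTES}"
            )
        code = rec[0]
        if code == telemetry.AP_TYPE:
            ev = telemetry.unpack_ap(rec)
            if ev.timestamp < prev_ts:
                epoch += 1  # 24-bit counter wrapped
            prev_ts = ev.timestamp
            out.ap_events.append(ev)
            out.ap_timestamps.append(epoch * TIMESTAMP_MOD + ev.timestamp)
        elif code == telemetry.LFP_TYPE:
            samples, start_ch = telemetry.unpack_lfp(rec)
            lfp_chunks.append(samples)
            out.lfp_start_channels.append(start_ch)
        else:
            raise ValueError(
                f"unknown packet type 0x{code:02x} at byte offset "
                f"{offset0 + i * telemetry.PACKET_BYTES}"
            )
    if lfp_chunks:
        out.lfp_samples = np.concatenate(
            [np.asarray(c, dtype=np.int32) for c in lfp_chunks]
        )
    return out


@dataclass
class ReconstructedSession:
    """Dual-modality reconstruction of one telemetry session.

    ``ap`` holds the decompressed snippets placed at their timestamps on a
    zero baseline at the full rate; ``lfp`` holds the de-interleaved
    decimated traces.  Modalities stay in separate traces (they are viewed
    on distinct time and amplitude scales; they are never re-mixed).
    """

    ap: np.ndarray
    lfp: np.ndarray
    fs: float
    lfp_fs: float
    events: list[tuple[int, int, np.ndarray]]  # (channel, abs timestamp, snippet)
    dropped: int = 0


def reconstruct(
    decoded: DecodedStream,
    duration: float,
    n_channels: int,
    fs: float = 20_000.0,
    lfp_factor: int = 10,
) -> ReconstructedSession:
    """Rebuild per-channel traces from a decoded stream.

    Each decompressed snippet is written at ``[t − 16, t + 32)`` around its
    absolute timestamp ``t`` (the detector clips 16 pre-crossing samples);
    overlapping snippets on one channel resolve last-writer-wins.  Events
    whose window exceeds the session duration are dropped with a warning and
    counted.  LFP samples are de-interleaved round-robin: flat sample ``i``
    belongs to channel ``i mod n_channels`` at decimated time
    ``i div n_channels``.
    """
    n_samples = int(round(duration * fs))
    ap = np.zeros((n_channels, n_samples))
    events: list[tuple[int, int, np.ndarray]] = []
    dropped = 0
    for ev, ts in zip(decoded.ap_events, decoded.ap_timestamps):
        snippet = decompress_ap(ev)
        a = ts - PRE_SAMPLES
        b = a + SNIPPET_SAMPLES
        if ev.channel >= n_channels or a < 0 or b > n_samples:
            dropped += 1
            continue
        ap[ev.channel, a:b] = snippet  # last writer wins on overlap
        events.append((ev.channel, ts, snippet))
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) outside the session window",
                      stacklevel=2)

    flat = np.asarray(decoded.lfp_samples)
    n_lfp = int(np.ceil(n_samples / lfp_factor))
    lfp = np.zeros((n_channels, n_lfp))
    n_frames = min(flat.size // n_channels, n_lfp)
    if n_frames:
        frames = flat[: n_frames * n_channels].reshape(n_frames, n_channels)
        lfp[:, :n_frames] = frames.T
    return ReconstructedSession(
        ap=ap, lfp=lfp, fs=fs, lfp_fs=fs / lfp_factor,
        events=events, dropped=dropped,
    )


def interleave_lfp(lfp: np.ndarray) -> np.ndarray:
    """Flatten decimated (n_channels, n_frames) traces channel-round-robin —
    the transmit-side ordering that :func:`reconstruct` inverts."""
    return np.asarray(lfp).T.reshape(-1)


def packetize_session(
    compressed: list[CompressedAp],
    lfp: np.ndarray,
) -> list[bytes]:
    """Serialize one session's events and decimated traces to wire records.

    AP events must be time-ordered (their 24-bit timestamps drive rollover
    recovery on the receive side).  The flattened LFP stream is chunked into
    13-sample packets; a final partial chunk is zero-padded.
    """
    packets = [telemetry.pack_ap(ev) for ev in compressed]
    flat = interleave_lfp(lfp).astype(int)
    n_channels = lfp.shape[0]
    per = telemetry.LFP_SAMPLES_PER_PACKET
    for i in range(0, flat.size, per):
        chunk = list(flat[i : i + per])
        start_ch = i % n_channels
        if len(chunk) < per:
            chunk += [0] * (per - len(chunk))
        packets.append(telemetry.pack_lfp(chunk, start_ch))
    return packets
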