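"""Wire format and data-rate accounting.

Everything the radio sends travels in 28-byte packets of two flavors:

==========  ====================================================
byte(s)     AP packet (type 0x01)
==========  ====================================================
0           packet type code
1–3         detection timestamp, 24-bit little-endian counter
4           channel number in the low 5 bits (high 3 reserved 0)
5–27        184-bit compressed waveform payload (23 bytes)
==========  ====================================================

==========  ====================================================
byte(s)     LFP/EMG packet (type 0x02)
==========  ====================================================
0           packet type code
1           channel number of the first sample
2–27        13 consecutive samples, signed 16-bit little-endian,
            advancing round-robin across channels
==========  ====================================================

The module also evaluates the Combined Data Reduction Ratio (CDRR) — the
raw-stream to reduced-stream volume ratio obtained by sending only detected,
compressed spikes on the high band plus the decimated low band:

    CDRR = f_SH / (NFR × Samples_AP / CR + f_SL)          (per channel)

and its whole-recording form using the actually detected spike count:

    CDRR = (f_SH × T × N) / (n_APs × Samples_AP / CR + f_SL × T × N)

with f_SH the raw sampling rate, f_SL the decimated rate, NFR the neuron
firing rate, Samples_AP the snippet length, CR the codec compression ratio,
T the duration and N the channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spike_engine import (
    COMPRESSION_RATIO,
    PAYLOAD_BITS,
    SNIPPET_SAMPLES,
    TIMESTAMP_MOD,
    CompressedAp,
)

PACKET_BYTES = 28
AP_TYPE = 0x01
LFP_TYPE = 0x02
LFP_SAMPLES_PER_PACKET = 13  # 28 bytes − 2 header bytes, 2 bytes/sample
CHANNEL_BITS = 5
STREAM_MAGIC = b"NTPS"  # packet-stream file magic
LINK_BUDGET_BPS = 1.4e6  # effective transceiver ceiling


def pack_ap(event: CompressedAp) -> bytes:
    """Serialize a compressed AP into one 28-byte record."""
    if not (0 <= event.channel < 2**CHANNEL_BITS):
        raise ValueError(
            f"channel {event.channel} does not fit the {CHANNEL_BITS}-bit field"
        )
    if not (0 <= event.timestamp < TIMESTAMP_MOD):
        raise ValueError("timestamp does not fit the 24-bit field")
    if len(event.payload) != PAYLOAD_BITS // 8:
        raise ValueError("AP packets carry exactly a 184-bit payload")
    rec = bytearray(PACKET_BYTES)
    rec[0] = AP_TYPE
    rec[1:4] = int(event.timestamp).to_bytes(3, "little")
    rec[4] = event.channel & 0x1F
    rec[5:28] = event.payload
    return bytes(rec)


def unpack_ap(record: bytes) -> CompressedAp:
    """Inverse of :func:`pack_ap`."""
    if len(record) != PACKET_BYTES:
        raise ValueError(f"AP record must be {PACKET_BYTES} bytes")
    if record[0] != AP_TYPE:
        raise ValueError(f"not an AP packet (type 0x{record[0]:02x})")
    return CompressedAp(
        channel=record[4] & 0x1F,
        timestamp=int.from_bytes(record[1:4], "little"),
        payload=bytes(record[5:28]),
    )


def pack_lfp(samples, start_channel: int) -> bytes:
    """Serialize 13 decimated LFP/EMG samples into one 28-byte record.

    ``samples`` are signed 16-bit ADC codes taken round-robin across
    channels starting at ``start_channel``.
    """
    samples = [int(s) for s in samples]
    if len(samples) != LFP_SAMPLES_PER_PACKET:
        raise ValueError(
            f"LFP packets carry exactly {LFP_SAMPLES_PER_PACKET} samples"
        )
    if not (0 <= start_channel < 2**CHANNEL_BITS):
        raise ValueError("start channel does not fit the 5-bit field")
    rec = bytearray(PACKET_BYTES)
    rec[0] = LFP_TYPE
    rec[1] = start_channel
    for i, s in enumerate(samples):
        if not (-32768 <= s <= 32767):
            raise ValueError(f"sample {s} exceeds the signed 16-bit range")
        rec[2 + 2 * i : 4 + 2 * i] = (s & 0xFFFF).to_bytes(2, "little")
    return bytes(rec)


def unpack_lfp(record: bytes) -> tuple[list[int], int]:
    """Inverse of :func:`pack_lfp`: (samples, start_channel)."""
    if len(record) != PACKET_BYTES:
        raise ValueError(f"LFP record must be {PACKET_BYTES} bytes")
    if record[0] != LFP_TYPE:
        raise ValueError(f"not an LFP/EMG packet (type 0x{record[0]:02x})")
    start_channel = record[1]
    samples = []
    for i in range(LFP_SAMPLES_PER_PACKET):
        raw = int.from_bytes(record[2 + 2 * i : 4 + 2 * i], "little")
        samples.append(raw - 0x10000 if raw >= 0x8000 else raw)
    return samples, start_channel


# ---------------------------------------------------------------------------
# Rate accounting
# ---------------------------------------------------------------------------

def compute_cdrr(
    f_sh: float,
    nfr: float,
    samples_ap: int = SNIPPET_SAMPLES,
    cr: float = COMPRESSION_RATIO,
    f_sl: float = 2_000.0,
) -> float:
    """Per-channel Combined Data Reduction Ratio.

    ``f_sh / (nfr × samples_ap / cr + f_sl)`` — the steady-state ratio of
    raw samples to transmitted sample-equivalents for one channel firing at
    ``nfr`` events/s.
    """
    if f_sh <= 0 or cr <= 0 or nfr < 0 or f_sl < 0:
        raise ValueError("rates must be positive (firing rate non-negative)")
    denom = nfr * samples_ap / cr + f_sl
    if denom == 0:
        raise ZeroDivisionError("reduced stream is empty; CDRR undefined")
    return f_sh / denom


def compute_recording_cdrr(
    f_sh: float,
    duration_s: float,
    n_channels: int,
    n_aps: int,
    samples_ap: int = SNIPPET_SAMPLES,
    cr: float = COMPRESSION_RATIO,
    f_sl: float = 2_000.0,
) -> float:
    """Whole-recording data reduction ratio from an actual spike count.

    ``(f_sh × T × N) / (n_aps × samples_ap / cr + f_sl × T × N)``.
    """
    if f_sh <= 0 or duration_s <= 0 or n_channels <= 0 or cr <= 0 or n_aps < 0:
        raise ValueError("invalid recording parameters")
    denom = n_aps * samples_ap / cr + f_sl * duration_s * n_channels
    if denom == 0:
        raise ZeroDivisionError("reduced stream is empty; CDRR undefined")
    return (f_sh * duration_s * n_channels) / denom


def raw_data_rate(n_channels: int, fs: float, bits: int = 16) -> float:
    """Uncompressed stream rate in bits/s: channels × rate × resolution."""
    if n_channels < 0 or fs < 0 or bits < 0:
        raise ValueError("rate factors must be non-negative")
    return n_channels * fs * bits


def check_link_budget(rate_bps: float, ceiling_bps: float = LINK_BUDGET_BPS) -> dict:
    """Check a data rate against the transceiver's effective ceiling.

    The bound is inclusive: a rate exactly at the ceiling passes.
    """
    if rate_bps < 0:
        raise ValueError("data rate must be non-negative")
    return {
        "rate_bps": float(rate_bps),
        "ceiling_bps": float(ceiling_bps),
        "margin_bps": float(ceiling_bps - rate_bps),
        "pass": bool(rate_bps <= ceiling_bps),
    }


@dataclass
class RateReport:
    """Session-level rate accounting in wire units."""

    f_sh: float
    f_sl: float
    n_channels: int
    nfr: float
    samples_ap: int = SNIPPET_SAMPLES
    cr: float = COMPRESSION_RATIO
    raw_rate_bps: float = field(init=False)
    reduced_rate_bps: float = field(init=False)
    cdrr: float = field(init=False)
    link_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        self.raw_rate_bps = raw_data_rate(self.n_channels, self.f_sh, 16)
        self.cdrr = compute_cdrr(self.f_sh, self.nfr, self.samples_ap,
                                 self.cr, self.f_sl)
        self.reduced_rate_bps = self.raw_rate_bps / self.cdrr
        self.link_ok = check_link_budget(self.reduced_rate_bps)["pass"]

    def to_dict(self) -> dict:
        return {
            "f_sh": self.f_sh, "f_sl": self.f_sl,
            "n_channels": self.n_channels, "nfr": self.nfr,
            "samples_ap": self.samples_ap, "cr": self.cr,
            "raw_rate_bps": self.raw_rate_bps,
            "reduced_rate_bps": self.reduced_rate_bps,
            "cdrr": self.cdrr, "link_ok": self.link_ok,
        }


# ---------------------------------------------------------------------------
# Packet-stream files
# ---------------------------------------------------------------------------

def write_packet_stream(path, packets: list[bytes]) -> int:
    """Write magic bytes plus a sequence of 28-byte records; returns the
    total payload byte count (excluding the magic)."""
    total = 0
    with open(path, "wb") as fh:
        fh.write(STREAM_MAGIC)
        for p in packets:
            if len(p) != PACKET_BYTES:
                raise ValueError("all records must be 28 bytes")
            fh.write(p)
            total += len(p)
    return total


def read_packet_stream(path) -> list[bytes]:
    """Read a packet-stream file back into raw 28-byte records."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if blob[: len(STREAM_MAGIC)] != STREAM_MAGIC:
        raise ValueError(f"{path}: missing packet-stream magic bytes")
    body = blob[len(STREAM_MAGIC):]
    if len(body) % PACKET_BYTES:
        raise ValueError(
            f"{path}: truncated record at byte offset "
            f"{len(STREAM_MAGIC) + len(body) - len(body) % PACKET_BYTES}"
        )
    return [body[i : i + PACKET_BYTES] for i in range(0, len(body), PACKET_BYTES)]
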