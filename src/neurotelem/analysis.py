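"""Offline analyses of reconstructed sessions.

Covers the post-processing applied to telemetered data: re-filtering and
peak-centering of decompressed spike snippets, PCA + k-means spike sorting
per channel, FFT band-power summaries of LFP segments (2-norm normalized
magnitude spectrum), firing-rate binning, and fixed-threshold event
detection gated by an optical-stimulation schedule (a higher threshold
inside pulses rejects stimulation artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import StimSchedule
from .spike_engine import SNIPPET_SAMPLES, PRE_SAMPLES

# Conventional LFP bands (Hz); fully overridable per call.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}


# ---------------------------------------------------------------------------
# Snippet conditioning
# ---------------------------------------------------------------------------

def refilter_and_center(
    snippets: np.ndarray,
    fs: float = 20_000.0,
    band: tuple[float, float] = (300.0, 5_000.0),
    center_index: int = PRE_SAMPLES,
) -> np.ndarray:
    """Band-pass snippets to the AP band and center each on its peak.

    Input is ``(n_snippets, 48)``.  A zero-phase 300–5,000 Hz band-pass
    removes residual low-frequency and mains contamination, then each
    snippet is circularly shifted so its absolute-value peak lands at
    ``center_index``.  Output shape equals input shape.
    """
    x = np.atleast_2d(np.asarray(snippets, dtype=float))
    if x.shape[1] != SNIPPET_SAMPLES:
        raise ValueError(f"snippets must have {SNIPPET_SAMPLES} samples")
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x, axis=1)
    out = np.empty_like(filtered)
    for i, snip in enumerate(filtered):
        peak = int(np.argmax(np.abs(snip)))
        out[i] = np.roll(snip, center_index - peak)
    return out


# ---------------------------------------------------------------------------
# Spike sorting
# ---------------------------------------------------------------------------

@dataclass
class SortedUnits:
    """PCA + k-means sorting result for one channel's snippets."""

    labels: np.ndarray           # cluster id per snippet
    mean_waveforms: np.ndarray   # (k, 48)
    scores: np.ndarray           # (n_snippets, n_components) PC projections
    k: int
    silhouette: float | None = None


def sort_spikes(
    snippets: np.ndarray,
    n_components: int = 2,
    k: int | None = None,
    seed: int = 0,
    k_range: tuple[int, int] = (1, 4),
) -> SortedUnits:
    """Cluster spike snippets into putative units.

    Snippets are projected onto the leading principal components and
    clustered with k-means (10 restarts, fixed seed, so the labeling is
    deterministic and invariant to snippet order).  With ``k=None`` the
    cluster count is chosen by silhouette score over ``k_range``; a best
    silhouette below 0.25 falls back to a single cluster (no evidence of
    more than one waveform shape).
    """
    x = np.atleast_2d(np.asarray(snippets, dtype=float))
    n = x.shape[0]
    if k is not None and k < 1:
        raise ValueError("cluster count must be at least 1")
    if k is not None and n < k:
        raise ValueError(f"need at least k={k} snippets, got {n}")
    n_components = min(n_components, x.shape[1], max(n - 1, 1))
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(x)

    def fit(kk: int) -> np.ndarray:
        km = KMeans(n_clusters=kk, n_init=10, random_state=seed)
        return km.fit_predict(scores)

    sil = None
    if k is None:
        lo, hi = k_range
        best_k, best_sil, best_labels = 1, -1.0, np.zeros(n, dtype=int)
        for kk in range(max(lo, 2), min(hi, n - 1) + 1):
            labels = fit(kk)
            if len(np.unique(labels)) < 2:
                continue
            s = silhouette_score(scores, labels)
            if s > best_sil:
                best_k, best_sil, best_labels = kk, s, labels
        if best_sil < 0.25:
            k, labels, sil = 1, np.zeros(n, dtype=int), best_sil
        else:
            k, labels, sil = best_k, best_labels, best_sil
    else:
        labels = fit(k) if k > 1 else np.zeros(n, dtype=int)

    means = np.vstack([
        x[labels == c].mean(axis=0) if np.any(labels == c) else np.zeros(x.shape[1])
        for c in range(k)
    ])
    return SortedUnits(labels=labels, mean_waveforms=means, scores=scores,
                       k=k, silhouette=sil)


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------

@dataclass
class BandPowerTable:
    """Per-band share of spectral power, as percentages summing to 100."""

    bands: dict[str, tuple[float, float]]
    percentages: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.percentages[name]


def band_power(
    lfp_segment: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    min_duration_s: float = 2.0,
) -> BandPowerTable:
    """Distribute an LFP segment's spectral power across frequency bands.

    The segment is detrended, Hann-windowed and Fourier-transformed; the
    magnitude spectrum is normalized by its 2-norm so squared magnitudes
    sum to one, and each band's power is the sum of squared normalized
    magnitudes at the bin frequencies inside the band (half-open intervals
    ``[lo, hi)`` so adjacent bands never double-count a bin).  Percentages
    are taken over the union of the requested bands.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    x = np.asarray(lfp_segment, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel segment")
    if x.size < min_duration_s * fs:
        raise ValueError(f"segment must span at least {min_duration_s} s")
    for name, (lo, hi) in bands.items():
        if not (0 < lo < hi <= fs / 2):
            raise ValueError(f"band {name!r} outside (0, fs/2]")

    x = sps.detrend(x, type="linear")
    win = np.hanning(x.size)
    spectrum = np.abs(np.fft.rfft(x * win))
    norm = np.linalg.norm(spectrum)
    if norm == 0:
        return BandPowerTable(bands=dict(bands),
                              percentages={n: 0.0 for n in bands})
    spectrum /= norm
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    power = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        power[name] = float(np.sum(spectrum[sel] ** 2))
    total = sum(power.values())
    pct = {n: (100.0 * p / total if total > 0 else 0.0) for n, p in power.items()}
    return BandPowerTable(bands=dict(bands), percentages=pct)


# ---------------------------------------------------------------------------
# Firing rates and gated thresholding
# ---------------------------------------------------------------------------

def firing_rate(
    event_times_s: np.ndarray,
    bin_width_s: float = 0.25,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned firing rate in events/s.

    Returns ``(bin_start_times, rates)``; counts are divided by the bin
    width, and the sum of ``rates × bin_width`` equals the event count.
    """
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    times = np.asarray(event_times_s, dtype=float)
    if duration_s is None:
        duration_s = float(times.max()) + bin_width_s if times.size else bin_width_s
    edges = np.arange(0.0, duration_s + bin_width_s, bin_width_s)
    counts, _ = np.histogram(times, bins=edges)
    return edges[:-1], counts / bin_width_s


def threshold_events_gated(
    signal: np.ndarray,
    thr_in: float,
    thr_out: float,
    stim_schedule: StimSchedule | None = None,
    dead_time: int = SNIPPET_SAMPLES,
) -> np.ndarray:
    """Fixed-threshold detection with a stimulation-gated threshold.

    Samples inside a stimulation pulse are compared against ``thr_in``
    (higher, to reject stimulation artifacts), samples outside against
    ``thr_out``.  Crossings are rising edges of ``|x| ≥ threshold`` with the
    same dead-time suppression as the on-platform detector.  Returns event
    sample indices.
    """
    if thr_in <= 0 or thr_out <= 0:
        raise ValueError("thresholds must be positive")
    x = np.abs(np.asarray(signal, dtype=float))
    thr = np.full(x.size, float(thr_out))
    if stim_schedule is not None and len(stim_schedule):
        thr[stim_schedule.mask(x.size)] = float(thr_in)
    over = x >= thr
    idx = np.flatnonzero(over & ~np.concatenate(([False], over[:-1])))
    out: list[int] = []
    last = -np.inf
    for i in idx:
        if i - last >= dead_time:
            out.append(int(i))
            last = i
    return np.asarray(out, dtype=np.int64)


def emg_differential(wire_a: np.ndarray, wire_b: np.ndarray) -> np.ndarray:
    """Differential EMG: subtract the two wire signals referenced to a
    common distant electrode, canceling shared background noise."""
    a = np.asarray(wire_a, dtype=float)
    b = np.asarray(wire_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("wire signals must have identical shapes")
    return a - b
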