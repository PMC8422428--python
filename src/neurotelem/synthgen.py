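"""Ground-truthed synthetic multimodal extracellular signals.

Emulates a bench playback experiment: action-potential (AP) trains built
from stereotyped biphasic templates, band-limited stochastic local field
potentials (LFP) and electromyogram (EMG), white instrumentation noise, and
optional optical-stimulation artifacts — mixed per channel with the clean
components retained as ground truth so every downstream processing stage can
be scored against what was actually emitted.

Modal conventions (band in Hz, amplitude in microvolts):

========  ============  ================
modality  band          amplitude range
========  ============  ================
AP        300 – 5,000   50 – 500 (peak)
LFP       1 – 500       250 – 5,000 (peak-to-peak)
EMG       10 – 300      50 – 500 (peak-to-peak)
========  ============  ================

All analog amplitudes are in microvolts; conversion to ADC codes happens in
the front-end emulation, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .containers import MultichannelRecording, StimSchedule

SNIPPET_SAMPLES = 48  # one AP waveform: 2.4 ms at 20 ksps
DEFAULT_FS = 20_000.0


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Event times (in samples) of one unit on one channel.

    ``times`` are strictly increasing, separated by at least the refractory
    period used at generation, and fall within the recording duration.
    ``template_id`` selects the waveform shape used when the train is
    rendered into a signal.
    """

    channel: int
    times: np.ndarray
    template_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.channel < 0:
            raise ValueError("channel index must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)


def generate_spike_train(
    rate: float,
    duration: float,
    refractory_ms: float = 2.4,
    seed: int | np.random.Generator = 0,
    channel: int = 0,
    template_id: int = 0,
    fs: float = DEFAULT_FS,
) -> SpikeTrain:
    """Homogeneous Poisson spike train thinned by an absolute refractory period.

    Events are drawn as a Poisson process of intensity ``rate`` and any event
    closer than ``refractory_ms`` to the previously retained event is
    discarded.  The retained process is a renewal process whose mean
    inter-event interval is ``1/rate + refractory``, so the expected count in
    ``duration`` seconds is approximately ``duration / (1/rate + refractory)``.

    Parameters
    ----------
    rate:
        Mean firing rate of the underlying Poisson process, events/s.
    duration:
        Length of the recording in seconds.
    refractory_ms:
        Dead time after each retained event; must cover one full snippet
        (2.4 ms) so rendered waveforms never overlap within a unit.
    seed:
        Integer seed or a ``numpy.random.Generator``.
    """
    if rate < 0:
        raise ValueError("firing rate must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if refractory_ms * fs / 1000.0 < SNIPPET_SAMPLES:
        raise ValueError(
            f"refractory period must cover a {SNIPPET_SAMPLES}-sample snippet"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if rate == 0 or duration == 0:
        return SpikeTrain(channel=channel, times=np.empty(0, dtype=np.int64),
                          template_id=template_id)

    # Draw exponential gaps until the horizon, then thin sequentially.
    n_expected = int(rate * duration * 1.5) + 20
    gaps = rng.exponential(1.0 / rate, size=n_expected)
    t = np.cumsum(gaps)
    while t.size and t[-1] < duration:
        extra = rng.exponential(1.0 / rate, size=n_expected)
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    t = t[t < duration]

    refractory_s = refractory_ms / 1000.0
    kept: list[float] = []
    last = -np.inf
    for ti in t:
        if ti - last >= refractory_s:
            kept.append(ti)
            last = ti
    samples = np.unique(np.round(np.asarray(kept) * fs).astype(np.int64))
    samples = samples[samples < int(round(duration * fs))]
    return SpikeTrain(channel=channel, times=samples, template_id=template_id)


# ---------------------------------------------------------------------------
# Waveform templates
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def ap_template(template_id: int = 0, fs: float = DEFAULT_FS) -> np.ndarray:
    """Unit-amplitude biphasic AP template, 48 samples.

    A sharp negative deflection (extracellular trough) followed by a slower
    positive rebound, with the trough placed near sample 16 so a detector
    that clips 16 pre- / 32 post-crossing samples captures the full shape.
    The template is band-passed to the AP band (300–5,000 Hz) at
    construction so rendered components are spectrally contained, then
    re-normalized to unit peak magnitude.
    """
    n = SNIPPET_SAMPLES
    t = np.arange(n, dtype=float)
    shapes = {
        0: (16.0, 1.6, 24.0, 5.0, 0.45),   # trough pos, trough width, rebound pos/width/frac
        1: (16.0, 2.4, 30.0, 7.0, 0.30),
        2: (16.0, 1.2, 21.0, 3.5, 0.60),
        3: (16.0, 2.0, 27.0, 6.0, 0.40),
    }
    p_tr, w_tr, p_rb, w_rb, frac = shapes[template_id % len(shapes)]
    w = -np.exp(-0.5 * ((t - p_tr) / w_tr) ** 2) + frac * np.exp(-0.5 * ((t - p_rb) / w_rb) ** 2)
    # Spectral containment: confine energy to the AP band.
    sos = sps.butter(4, [300.0, 5000.0], btype="bandpass", fs=fs, output="sos")
    pad = np.zeros(4 * n)
    w = sps.sosfiltfilt(sos, np.concatenate([pad, w, pad]))[pad.size : pad.size + n]
    return w / np.max(np.abs(w))


def render_spike_component(
    trains: list[SpikeTrain],
    n_channels: int,
    n_samples: int,
    amplitudes: dict[int, float],
    fs: float = DEFAULT_FS,
) -> np.ndarray:
    """Place amplitude-scaled templates at every train's event times.

    ``amplitudes`` maps template_id to peak amplitude in microvolts.  Each
    event contributes its template aligned so the trough sits at the event
    time; events whose 48-sample window would run off either edge are
    rendered truncated.
    """
    out = np.zeros((n_channels, n_samples))
    pre = 16
    for train in trains:
        if train.channel >= n_channels:
            raise ValueError(f"train references channel {train.channel} "
                             f"but recording has {n_channels}")
        tmpl = ap_template(train.template_id, fs) * amplitudes[train.template_id]
        for t0 in train.times:
            a = int(t0) - pre
            b = a + SNIPPET_SAMPLES
            sa, sb = max(a, 0), min(b, n_samples)
            out[train.channel, sa:sb] += tmpl[sa - a : sb - a]
    return out


# ---------------------------------------------------------------------------
# Configuration and mixture synthesis
# ---------------------------------------------------------------------------

@dataclass
class SynthesisConfig:
    """Everything needed to synthesize one multimodal recording.

    Amplitude ranges are microvolts: peak amplitude for AP templates,
    peak-to-peak for the stochastic LFP/EMG components.  Band limits are Hz
    and must lie inside (0, fs/2).  A fixed seed makes the output
    bit-identical across runs.
    """

    n_channels: int = 4
    duration: float = 5.0
    fs: float = DEFAULT_FS
    ap_band: tuple[float, float] = (300.0, 5000.0)
    ap_amp_range: tuple[float, float] = (50.0, 500.0)
    lfp_band: tuple[float, float] = (1.0, 500.0)
    lfp_amp_range: tuple[float, float] = (250.0, 5000.0)
    emg_band: tuple[float, float] = (10.0, 300.0)
    emg_amp_range: tuple[float, float] = (50.0, 500.0)
    noise_sigma: float = 10.0
    slow_osc_hz: float = 1.0       # anesthesia-like slow oscillation in the LFP
    slow_osc_frac: float = 0.5     # fraction of LFP peak-to-peak carried by it
    emg_channels: tuple[int, ...] = ()
    stim_schedule: StimSchedule | None = None
    stim_artifact_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_channels <= 32):
            raise ValueError("n_channels must be in 1..32")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        for name in ("ap_amp_range", "lfp_amp_range", "emg_amp_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative (lo, hi) range")
        for name in ("ap_band", "lfp_band", "emg_band"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi < self.fs / 2):
                raise ValueError(f"{name} must lie within (0, fs/2)")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for ch in self.emg_channels:
            if not (0 <= ch < self.n_channels):
                raise ValueError(f"EMG channel {ch} out of range")


@dataclass
class GroundTruth:
    """Clean components and event times behind a synthetic mixture.

    Invariant: ``components['ap'] + components['lfp'] + components['emg'] +
    components['stim'] + components['noise']``, summed in that order, equals
    the emitted mixture bit-exactly.
    """

    trains: list[SpikeTrain]
    components: dict[str, np.ndarray]
    template_amplitudes: dict[int, float]
    stim_schedule: StimSchedule | None = None
    fs: float = DEFAULT_FS

    def spike_times(self, channel: int) -> np.ndarray:
        """All ground-truth event times (samples) on one channel, sorted."""
        times = [tr.times for tr in self.trains if tr.channel == channel]
        if not times:
            return np.empty(0, dtype=np.int64)
        return np.sort(np.concatenate(times))


def _bandlimited_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    band: tuple[float, float],
    fs: float,
) -> np.ndarray:
    """Zero-phase band-passed Gaussian noise, unit-ish variance per channel."""
    lo, hi = band
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, white, axis=1)


def _scale_p2p(x: np.ndarray, target_p2p: np.ndarray) -> np.ndarray:
    """Scale each row so its peak-to-peak equals the target (rows with zero
    swing stay zero)."""
    p2p = x.max(axis=1) - x.min(axis=1)
    factor = np.where(p2p > 0, target_p2p / np.where(p2p > 0, p2p, 1.0), 0.0)
    return x * factor[:, None]


def synthesize_multimodal(
    config: SynthesisConfig,
    trains: list[SpikeTrain] | None = None,
) -> tuple[MultichannelRecording, GroundTruth]:
    """Mix AP, LFP, EMG, stimulation-artifact and noise components.

    Neural channels carry AP templates plus an LFP background; channels
    listed in ``config.emg_channels`` carry an EMG component instead.  The
    returned recording is analog (microvolts); the ground truth holds each
    clean component and the spike trains that generated the AP component.

    If ``trains`` is None, one 50 events/s unit is generated per neural
    channel (a typical cortical firing rate for this kind of playback test).
    """
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration * config.fs))
    n_ch = config.n_channels
    emg_set = set(config.emg_channels)
    neural_channels = [c for c in range(n_ch) if c not in emg_set]

    if trains is None:
        trains = [
            generate_spike_train(
                rate=50.0, duration=config.duration, seed=rng,
                channel=c, template_id=i % 4, fs=config.fs,
            )
            for i, c in enumerate(neural_channels)
        ]
    for tr in trains:
        if tr.channel >= n_ch:
            raise ValueError(f"train channel {tr.channel} outside recording")

    # Per-template peak amplitudes drawn once from the configured range.
    template_ids = sorted({tr.template_id for tr in trains})
    amp_lo, amp_hi = config.ap_amp_range
    template_amps = {tid: float(rng.uniform(amp_lo, amp_hi)) for tid in template_ids}

    ap = render_spike_component(trains, n_ch, n_samples, template_amps, config.fs) \
        if trains and amp_hi > 0 else np.zeros((n_ch, n_samples))

    # LFP: band-limited noise plus a slow oscillation, on neural channels.
    lfp = np.zeros((n_ch, n_samples))
    lfp_lo, lfp_hi = config.lfp_amp_range
    if lfp_hi > 0 and neural_channels:
        base = _bandlimited_noise(rng, len(neural_channels), n_samples,
                                  config.lfp_band, config.fs)
        t = np.arange(n_samples) / config.fs
        phases = rng.uniform(0, 2 * np.pi, size=len(neural_channels))
        slow = np.sin(2 * np.pi * config.slow_osc_hz * t[None, :] + phases[:, None])
        target = rng.uniform(lfp_lo, lfp_hi, size=len(neural_channels))
        mix = _scale_p2p(base, target * (1 - config.slow_osc_frac)) \
            + _scale_p2p(slow, target * config.slow_osc_frac)
        lfp[neural_channels, :] = _scale_p2p(mix, target)

    # EMG: band-limited noise on the designated channels.
    emg = np.zeros((n_ch, n_samples))
    emg_lo, emg_hi = config.emg_amp_range
    if emg_hi > 0 and emg_set:
        rows = sorted(emg_set)
        base = _bandlimited_noise(rng, len(rows), n_samples,
                                  config.emg_band, config.fs)
        target = rng.uniform(emg_lo, emg_hi, size=len(rows))
        emg[rows, :] = _scale_p2p(base, target)

    # Stimulation artifact: decaying step transients at pulse edges.
    stim = np.zeros((n_ch, n_samples))
    if config.stim_schedule is not None and config.stim_artifact_uv > 0:
        tau = int(round(0.5e-3 * config.fs))  # 0.5 ms decay
        kernel = config.stim_artifact_uv * np.exp(-np.arange(4 * tau) / tau)
        for on, off in config.stim_schedule.intervals:
            for edge, sign in ((on, 1.0), (off, -1.0)):
                a, b = edge, min(edge + kernel.size, n_samples)
                if a < n_samples:
                    stim[:, a:b] += sign * kernel[: b - a]

    noise = config.noise_sigma * rng.standard_normal((n_ch, n_samples)) \
        if config.noise_sigma > 0 else np.zeros((n_ch, n_samples))

    mixture = ap + lfp + emg + stim + noise
    rec = MultichannelRecording(data=mixture, fs=config.fs, units="uV")
    truth = GroundTruth(
        trains=list(trains),
        components={"ap": ap, "lfp": lfp, "emg": emg, "stim": stim, "noise": noise},
        template_amplitudes=template_amps,
        stim_schedule=config.stim_schedule,
        fs=config.fs,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Stimulation schedules
# ---------------------------------------------------------------------------

@dataclass
class StimPattern:
    """Description of a repeating optical stimulation pattern.

    A *train* of ``pulses_per_train`` pulses, each ``pulse_width_s`` wide and
    spaced ``pulse_period_s`` start-to-start, repeats every
    ``train_period_s`` over ``span_s`` seconds.  A simple periodic pulse is a
    train of one pulse (``pulse_period_s`` is then ignored).
    """

    pulse_width_s: float = 0.0
    pulse_period_s: float = 0.0
    pulses_per_train: int = 1
    train_period_s: float = 0.0
    span_s: float = 0.0
    start_s: float = 0.0
    fs: float = DEFAULT_FS


def build_stim_schedule(pattern: StimPattern) -> StimSchedule:
    """Expand a pulse pattern into sorted (on, off) sample intervals.

    Trains start at ``start_s`` and repeat at ``train_period_s``; only pulses
    whose onset falls strictly before ``span_s`` are emitted.  Overlapping
    pulses (pulse width ≥ spacing) raise an error.
    """
    p = pattern
    if p.span_s <= 0 or p.pulses_per_train <= 0 or p.pulse_width_s <= 0:
        return StimSchedule(intervals=[], fs=p.fs)
    if p.pulses_per_train > 1 and p.pulse_width_s >= p.pulse_period_s:
        raise ValueError("pulse width must be smaller than the pulse period")
    train_extent = (p.pulses_per_train - 1) * p.pulse_period_s + p.pulse_width_s
    if p.train_period_s <= 0:
        raise ValueError("train period must be positive")
    if p.pulses_per_train >= 1 and train_extent > p.train_period_s:
        raise ValueError("stimulation trains overlap")
    intervals: list[tuple[int, int]] = []
    t_train = p.start_s
    while t_train < p.span_s:
        for k in range(p.pulses_per_train):
            on_s = t_train + k * p.pulse_period_s
            if on_s >= p.span_s:
                break
            on = int(round(on_s * p.fs))
            off = int(round((on_s + p.pulse_width_s) * p.fs))
            intervals.append((on, off))
        t_train += p.train_period_s
    return StimSchedule(intervals=intervals, fs=p.fs)
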