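# Methods

This note documents the models behind each stage, the parameters that
matter, the numerical conventions, and what the synthetic-data tests do and
do not demonstrate.

## Signal model and synthetic data

The generator emulates a bench playback experiment: known waveforms driven
into the recording front-end so every downstream stage can be scored against
ground truth.

**Spike trains.** Homogeneous Poisson processes thinned by an absolute
refractory period (default 2.4 ms, one snippet length, so rendered waveforms
of one unit never overlap). The thinned process is a renewal process with
mean inter-event interval `1/rate + refractory`; tests use
`duration / (1/rate + refractory)` as the expected count. The default unit
rate is 50 events/s, a typical sustained cortical firing rate for this kind
of test.

**AP templates.** Extracellular spike shapes are stereotyped but not
published as numbers, so the generator uses parametric biphasic templates:
a sharp Gaussian trough (width 1.2–2.4 samples) followed by a slower
positive rebound (30–60% of trough amplitude), 48 samples long with the
trough at sample 16. Four shape variants provide distinguishable units for
sorting tests. Each template is band-passed to 300–5,000 Hz at construction
(zero-phase, 4th-order Butterworth) and renormalized, so the rendered AP
component is spectrally contained by construction. Peak amplitudes are drawn
per unit from the configured 50–500 μV range.

**LFP and EMG.** Modeled as band-passed Gaussian noise (4th-order
Butterworth, zero-phase) scaled to a per-channel target peak-to-peak drawn
from the configured range (LFP 1–500 Hz at 250–5,000 μV; EMG 10–300 Hz at
50–500 μV). The LFP additionally carries a ~1 Hz sinusoid holding half of
the target peak-to-peak, mimicking the slow oscillation that dominates
cortical LFP under ketamine–xylazine anesthesia. These are surrogates: they
claim band and amplitude fidelity only, not the spectral shape, nonstationarity
or cross-channel correlation of in vivo signals — so passing tests show the
*chain* handles signals with the right gross statistics, not that it would
perform identically on real recordings.

**Noise and artifacts.** White Gaussian noise (default σ = 10 μV, typical
for tungsten microwires). Optional stimulation artifacts are exponentially
decaying step transients (0.5 ms time constant) at light-pulse edges,
mimicking photoelectric transients. The mixture is the exact left-to-right
float sum AP + LFP + EMG + artifact + noise, and all components are stored,
so decomposition tests are bit-exact.

**Stimulation schedules.** A pattern is (pulse width, intra-train spacing,
pulses per train, train period, span). Trains are placed starting at t = 0;
the two patterns used in optogenetic experiments (500 ms pulses every 5 s;
trains of ten 5 ms pulses at 50 ms spacing every 5.5 s) fall out as special
cases. Pulse placement at t = 0 is a convention; only counts and spacing are
constrained.

## Front end

The analog stage is emulated as the discrete-time bilinear-transform
equivalent of a 1st-order high-pass (configurable 0.1–500 Hz, default
0.25 Hz) cascaded with a 3rd-order Butterworth low-pass (configurable
100 Hz–20 kHz, default 7.5 kHz, leaving anti-aliasing margin below the
10 kHz Nyquist), applied causally. This preserves pass-band behavior at the
frequencies of interest; exact analog phase near Nyquist is not reproduced.
One parameter set serves all 32 channels, as in the shared-filter hardware.

The ADC is a mid-tread, two's-complement, saturating quantizer mapping
±5 mV to the signed 16-bit code range (LSB = 10 mV / 2^16 ≈ 0.153 μV).
Mid-tread means 0 μV → code 0; +5 mV rounds to 32,768 and saturates at
32,767 — saturation is defined behavior, not an error.

## Dual-path separation

Both digital filters are windowed-sinc designs with Kaiser windows, chosen
for the narrowest main lobe at acceptable stop-band attenuation under a hard
tap-count ceiling:

| path    | kind      | cutoff | taps | β   | output rate |
|---------|-----------|--------|------|-----|-------------|
| AP      | high-pass | 300 Hz | 41   | 0.1 | 20 ksps     |
| LFP/EMG | low-pass  | 500 Hz | 39   | 3   | 2 ksps (÷10)|

Conventions fixed here: the windowed-sinc −6 dB point sits at the cutoff;
the low-pass is normalized to exactly unit DC gain; the high-pass is the
spectral inversion of the complementary low-pass (unit gain at Nyquist,
odd tap count required). Taps are exactly symmetric, giving linear phase
with group delay (n_taps − 1)/2 samples. Filtering is floating-point with
an optional 16-bit coefficient-quantization mode; the hardware used fixed
point, but word lengths are not part of this model.

The multiplexed engine models the hardware's shared data path: one
coefficient set and one multiply-accumulate engine with a bank of
per-channel delay-line states visited round-robin. Since channels share no
state, the output is provably identical to direct per-channel convolution —
the test suite asserts sample-exactness against a brute-force convolution
oracle for every channel count 1–32. The first n_taps − 1 output samples are
the causal settling transient.

Cycle budgeting: N_cycles = f_clk / (f_s · N_ch) cycles are available per
sample (31.25 at 20 MHz, 20 ksps, 32 channels); symmetric-coefficient reuse
halves the per-sample multiplication count to ⌈n_taps/2⌉ (21 for 41 taps).
A design is rejected when its reuse-count exceeds the budget.

Decimation keeps every 10th sample starting at index 0 (phase convention
fixed here), relying on the 500 Hz low-pass for anti-aliasing below the
1 kHz post-decimation Nyquist.

## Detection and compression

**Noise estimate.** σ = median(|x|)/0.6745, the MAD estimator, consistent
for Gaussian noise and robust to the spikes themselves. It is refreshed per
consecutive 1 s window (20,000 samples); each window is thresholded with its
own estimate. The threshold multiplier k = 4, the window length and the dead
time are all configurable.

**Detection.** Rising-edge crossings of |x| ≥ k·σ trigger an event: 16
samples before and 32 after the crossing form the 48-sample snippet
(alignment is a convention of this implementation; only the total length is
architecturally fixed). A dead time of one snippet suppresses re-triggers;
crossings too close to the array edges for a full snippet are dropped.
Timestamps are crossing indices modulo 2^24, matching the wire format's
counter. An all-zero window has σ = 0 and is inert by construction. On pure
Gaussian noise a 4σ threshold fires ≈1.3 false events/s/channel — inherent
to threshold detection, which is why precision is only asserted on
calibrated-SNR material.

**Codec.** Each snippet undergoes a 4-level DWT (Symmlet-4 default; db4 and
Haar selectable) with symmetric boundary extension, giving 74 coefficients
for 48 samples. The 184-bit payload is laid out as: 6-bit shared scale
exponent, 74-bit retention bitmap, and the 17 largest-magnitude coefficients
as 6-bit two's-complement mantissas (ties broken by coefficient index, so
the codec is deterministic), zero-padded by 2 bits. The shared exponent is
the smallest power of two bringing the largest retained magnitude into the
±31 mantissa range. 48 × 16 / 184 gives the compression ratio 4.17. The
payload size is a parameter; the error-vs-budget sweep in the tests uses
92/184/368 bits. With quantization disabled the forward/inverse transform
round-trips to better than 1e-9 relative error (perfect reconstruction of
the filter bank).

## Telemetry and reconstruction

Packets are 28 bytes. AP flavor: type byte 0x01, 24-bit little-endian
timestamp, channel in the low 5 bits of byte 4 (high 3 bits reserved zero),
184-bit payload. LFP/EMG flavor: type byte 0x02, start-channel byte, then 13
signed 16-bit little-endian samples taken round-robin across channels. The
13-sample count follows from the 28-byte size and a 2-byte header;
endianness and reserved-bit zeroing are fixed here so round-trips are
bit-exact. LFP/EMG packets carry no timestamps — they are implicitly timed
by stream order, a documented limitation shared with the wire format they
model.

The base station tracks rollovers of the 24-bit counter (epoch increments
whenever a timestamp decreases; the counter wraps every ≈839 s at 20 ksps),
decompresses each AP and writes it at [t−16, t+32) on a zero baseline.
Overlapping snippets resolve last-writer-wins; events outside the session
window are dropped, counted and warned about — never silently. De-interleaving
is the exact inverse of interleaving, asserted sample-exactly in tests.

The CDRR formulas count sample-equivalents (a compressed AP costs
Samples_AP/CR sample-slots): per-channel
`f_SH / (NFR·Samples_AP/CR + f_SL)` and, for a recording,
`(f_SH·T·N) / (n_APs·Samples_AP/CR + f_SL·T·N)`. With no spikes both reduce
to f_SH/f_SL = 10. The link-budget check is inclusive at the 1.4 Mb/s
effective transceiver ceiling.

## Offline analyses

**Re-filter / re-center:** zero-phase 300 Hz–5 kHz band-pass, then a
circular shift placing the absolute peak at sample 16.

**Sorting:** PCA to 2 components, then k-means with 10 restarts and a fixed
seed (deterministic, order-invariant up to label permutation). When k is not
given it is chosen by silhouette score over k ∈ {2..4}, falling back to
k = 1 when the best silhouette is below 0.25 (no evidence for more than one
shape); both fixed-k and selected-k modes are exposed because either could
have been used in practice.

**Band power:** the segment (≥2 s) is linearly detrended, Hann-windowed and
FFT'd; the magnitude spectrum is normalized by its 2-norm; a band's power is
the sum of squared normalized magnitudes over bins in [lo, hi) — half-open
so adjacent bands never share a bin — expressed as a percentage of the
covered bands' total. Default bands: delta 1–4, theta 4–8, alpha 8–12,
beta 12–30, gamma 30–100 Hz (conventional values; fully configurable).

**Gated thresholding:** fixed thresholds of 60 μV inside stimulation pulses
and 45 μV outside (artifact rejection raises the in-pulse level), with the
same dead-time rule as the on-platform detector.

**EMG:** a differential-subtraction helper cancels common-mode background
between two intramuscular wires referenced to a distant electrode.

## Session harness

`run_session` chains all stages and reports detected counts, precision and
recall against ground truth (events matched greedily within ±1 ms after
compensating the AP filter's 20-sample group delay), the recording-level
CDRR evaluated on the session's own detected count, data rates and the
link-budget verdict. Reports carry a schema version and are validated.
Ground-truth spike count ≥ detected count is deliberately *not* an
invariant (false positives exist); precision/recall are asserted only on
calibrated-SNR fixtures (peak 160 μV over σ = 20 μV noise, i.e. SNR 8).

Problem sizes in the test suite (16 channels × 30 s for the end-to-end
session, 30 s single-channel detection runs, 120 s noise segments for
band-power flatness) were chosen as the smallest sizes at which the
Monte-Carlo assertions have comfortable statistical margins.

## Known limitations

- The analog front end omits amplifier noise, crosstalk and SPI timing; the
  DSP model omits fixed-point rounding of the FPGA implementation.
- The adaptive-threshold update rule and on-chip quantizer of the hardware
  platform are proprietary to its firmware lineage; the MAD-based detector
  and top-K wavelet quantizer here are documented substitutes, not claimed
  bit-equivalents.
- Synthetic LFP/EMG are stationary Gaussian surrogates; claims about real
  tissue signals are limited accordingly.
- LFP/EMG packets are timed by stream order only; packet loss would
  misalign channels (no sequence numbers in the 28-byte format).
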