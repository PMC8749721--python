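# Methods

This note documents the models behind `biopad`, the defaults that matter,
what the synthetic-signal generator does and does not emulate, and the
design choices made where the modeled system left them open.

## Front-end unit models

The unit models are closed-form transfer functions, not circuit simulations.
The EEG chain is modeled as a first-order high-pass at 0.5 Hz (the
integral-feedback DC-correction loop, which nulls electrode polarization
voltage), the instrumentation-amplifier gain G = 1 + 19.8 kΩ/Rg (100 at the
designed Rg = 200 Ω), a second-order low-pass at 35 Hz, and a ×2 filter-stage
gain — a ~200× passband plateau between 0.5 and 35 Hz with full DC
rejection. The ADC is the standard bipolar 24-bit Σ-Δ map
V = 2·V_REF·L/(2²³ − 1)/PGA with V_REF = 2.5 V.

Two printed calibrations in the modeled design are internally inconsistent,
and both resolutions are exposed as modes (`ConversionMode`):

* **EDA.** The conductance formula carries a trailing ×10³ that would put
  resting skin conductance in the millisiemens range, three orders of
  magnitude above physiology. The default `consistent` mode drops it:
  ρ = 16.5/(8·U − 3.3) μS, which maps the divider's stated 0.4–2.4 V output
  onto the usual 1–20 μS tonic window (valid only for U > 0.4125 V; the
  decoder maps wire codes below that region to NaN rather than failing).
  `as_printed` keeps the factor verbatim.
* **SKT.** The LMT70's output voltage falls with temperature, but the
  calibration slope is printed positive, which would map its ~900 mV output
  to ≈ 390 °C. The default uses T = −0.1943·V + 213.340 °C, landing the
  870–960 mV range in the physiological 28–44 °C window;
  `as_printed_positive` preserves the printed sign.

A safety diagnostic exposes the skin drive current implied by the divider
algebra, I = (3.3/16)/R₃, which is ~1 μA at R₃ = 200 kΩ — well under the
10 μA design ceiling.

## Packet codec

The frame layout and CRC variant are this package's normative definitions
(`docs/frame_format.md`): the 168-byte total, the 0x7F/0xE6 framing bytes,
and the channel rates are fixed by the modeled protocol, and the 45-byte
peripheral block then admits exactly one field assignment that carries all
eight peripheral channels per tick (PPG wavelengths at one byte each). The
length byte 0xE6 (230) does not equal the 165-byte payload under any obvious
convention; it is treated as a literal magic constant. The CRC is the
reflected-0x31 CRC-8 (init 0x00), a common sensor-stream variant; both
polynomial and init are parameters.

Wire quantization scales are chosen so nominal physiological excursions use
a large fraction of each field's code range while leaving headroom against
clipping during motion artifact: EEG inherits the real chain (1 LSB ≈
0.003 μV at the scalp after the ×200 analog gain), EDA codes span 0–3.3 V of
divider output, SKT codes span 0–1100 mV of sensor output, PPG uses 256
counts/LSB around mid-scale, acceleration 32 LSB/g (±4 g). Decoding a
re-encoded record reproduces every channel within these documented
single-LSB bounds, which the test suite asserts on a full session.

## Filtering

The comb is the notch form with zeros exactly at k·fs/N (k = 0…N/2,
including DC) and poles at radius rh0^(1/N) beneath them; rh0 =
0.96852105385218623 gives ≈ 1 Hz notch bandwidth at 400 Hz sampling. At the
notch frequencies the transfer function is exactly zero, so any finite
attenuation figure is a measurement artifact of a finite grid or finite
observation; the published 20.4 dB depth is therefore treated as a lower
bound, and the package reports a *measured* attenuation — filter a unit
50 Hz sinusoid, compare steady-state RMS after an 8 s settle — which is
finite (≈ 119 dB over a 10 s observation) and exceeds that bound.

Filters are applied as a zero-initial-state direct-form-II recursion
(`scipy.signal.lfilter`; the textbook two-equation recursion is kept in the
test suite as an independent sample-for-sample oracle at 1e−10). Streaming
use is causal with no group-delay compensation, matching a real-time
display; a forward-backward zero-phase option exists for offline analysis
and is used where timing alignment matters (EDA SCR extraction, blink
timing). Peripheral cutoffs are not specified by the modeled design and
default to 5 Hz (EDA, mirroring the analog Sallen-Key stage), 8 Hz (PPG) and
1 Hz (SKT), all 2nd-order Butterworth and config-overridable.

## EEG analysis

PSD estimation uses Welch with Hann windows, 2 s segments, 50% overlap (the
estimator is unspecified in the modeled validation; Welch is the field
default). Band power integrates the PSD trapezoidally with interpolated
band edges; alpha dominance is the ratio of *relative* (8, 13] Hz power,
eyes-closed over eyes-open, on 15 s epochs, making it invariant to common
amplitude scaling. Cross-device PSD comparison z-scores each segment before
correlating (the original normalization is unspecified). The blink detector
(low-pass < 5 Hz, threshold at median + 6·MAD, 0.5 s refractory) is
fixture-validation plumbing, not a published algorithm, and is documented as
such in its docstring.

## EDA analysis

The SNR statistic is 10·log₁₀ of summed periodogram power in (0, 5] Hz over
(5, fs/2] Hz, DC bin excluded, rectangular window (the reference estimator
is unspecified); segmented over 10 s windows with 50% overlap, so a 150 s
record yields 29 segments. SCR extraction follows the printed order —
anti-alias (8th-order low-pass at 8 Hz), decimate to 20 Hz, first difference
scaled by the 20 Hz rate, convolve with a 20-point Bartlett window — with
the window normalized to unit sum so amplitudes stay in μS/s. Event
detection thresholds the SCR signal at median + 4·MAD with a 0.25 s minimum
duration (no numeric threshold is published) and assigns each event the
latest stimulus within 10 s before onset.

## SKT analysis

Smoothing is the three-point weighted moving average y(n) = 0.8·x(n) +
0.1·x(n−1) + 0.1·x(n−2); the first two samples pass through unchanged (edge
behavior is undefined in the source design). The stimulation response is
quantified as the difference of 5 s edge means (end minus start of the
stimulation window) rather than a point difference, for robustness to
sample noise, plus a least-squares recovery slope over the post-stimulus
window.

## PPG analysis

Motion-artifact cancellation is exponentially weighted RLS with the
tri-axial accelerometer as reference. The published method's parameters and
exact "parallel" structure are in an external reference and not printed, so
the defaults here are implementation-chosen and config-exposed: 10 taps per
reference, forgetting factor λ = 0.999, inverse-correlation init
P(0) = I/0.01, applied by default as a cascade of single-reference stages
(x → y → z), with a joint multi-reference "parallel" option. A zero
reference predicts zero artifact, so the signal passes through bit-exactly.
Like any adaptive canceller, steady-state misadjustment scales with the
power of the part of the input the reference cannot explain (the pulse
itself), so measured cancellation depth depends on the artifact-to-pulse
ratio of the fixture.

Pulse-rate tracking: per 8 s window (2 s step), detrend, Hann window,
zero-padded FFT to ≤ 0.02 Hz resolution, search 0.7–3.5 Hz. The first
window takes the global in-band maximum; subsequent windows take the
spectrally significant peak (≥ 25% of the window's in-band maximum — without
a significance floor, a noise ripple inside the collar would pin the tracker
forever) nearest the previous estimate within ±12 BPM; if none qualifies, a
harmonic guard halves a global maximum sitting at twice the previous rate,
else the tracker re-acquires at the global maximum. Estimates are
amplitude-invariant by construction. Agreement metrics are the standard
AAE, Bland-Altman bias ± 1.96·SD limits, and Pearson correlation; ground
truth comes from the simulator's rate track (the hardware validation used a
chest-ECG channel, out of scope here).

## Synthetic-session generator

All generators are pure functions of (config, seed), with per-modality
child seeds spawned from one seed sequence. Defaults encode the modeled
study's conditions:

* **EEG** (2 × 400 Hz): pink (1/f) background at 4 μV RMS; a 10 Hz alpha
  oscillation with ±0.5 Hz slow jitter at 20 μV when eyes are closed and 5%
  of that when open (strong alpha blocking, so the eyes-open spectrum is
  dominated by low-frequency background as in real recordings); biphasic
  300 ms, 100 μV blink transients at 8/min with 1 s dead time; a 10 μV
  50 Hz mains line.
* **EDA** (100 Hz): 5 μS tonic level, 0.3 μS slow sinusoidal drift (80 s
  period), 0.005 μS measurement noise, and bi-exponential SCR kernels
  A·(e^(−t/τ_d) − e^(−t/τ_r)) peak-normalized to their configured
  amplitudes, with τ_r = 0.75 s and τ_d = 3 s (typical electrodermal
  literature values). The resulting filtered segment SNR (~21 dB mean) sits
  in the same regime as real wearable EDA. Out-of-band power is dominated
  by SCR onset transients rather than the noise floor.
* **SKT** (100 Hz): 34 °C baseline, 0.01 °C noise, and a raised-cosine dip
  of the configured depth (default 0.2 °C) developing across the drop
  window; the canonical paradigm (20 s baseline / 60 s sadness scene / 90 s
  rest) completes the dip before the last 5 s of the scene so the edge-mean
  delta equals the injected depth. The generator holds the dipped level
  rather than modeling thermal recovery.
* **PPG + acceleration** (100 Hz): the pulse is a phase-integrated harmonic
  series (relative amplitudes 1.0, 0.4, 0.15 — the strong second harmonic
  exercises the tracker's harmonic guard) following a piecewise-linear BPM
  profile, plus 0.12 Hz baseline wander. Motion bursts are band-limited
  (0.5–4 Hz) noise plus a rhythmic head-sway component whose tempo drifts
  across 0.8–3.2 Hz within each burst — sweeping through the pulse band, the
  classic MA confounder. The artifact enters the PPG through per-axis
  5-tap FIR coupling (12000 counts/g), and motion also shrinks the
  pulsatile amplitude by up to 60% (loosened sensor contact), which is why
  cancellation is required rather than merely helpful during bursts.

The default 6-minute session alternates 30 s rests with 60 s scenes (joy,
calmness, sadness, fear), carries stimulus-locked SCRs in each scene, a
0.2 °C SKT dip during the sadness scene, a 60–100 BPM rate profile, and six
15–20 s motion bursts.

**What the generator does not emulate:** real EEG nonstationarity and
artifact diversity (EMG, electrode pops), SCR habituation and
tonic/phasic interaction, vasomotor SKT dynamics and ambient drift, PPG
morphology changes (dicrotic notch, respiratory modulation), and any
emotion-dependent signal structure beyond the injected effects. Passing
parameter-recovery tests therefore demonstrates that the pipelines recover
what they are designed to recover under controlled, label-known conditions —
not field performance on human recordings.

## Numerical choices and degenerate inputs

Filters validate stability (poles strictly inside the unit circle) and
reject non-finite samples. Welch requires at least one full segment; PSD
correlation is undefined (and raises) for constant spectra, as is pulse-rate
agreement for zero-variance series. The SCR and blink detectors return
empty event lists on flat input (MAD = 0) rather than dividing by zero.
Band-split SNR returns +inf with a warning when the noise band is empty of
power. Encoding clips out-of-range physical values to the field's code
range with a warning; decoding sign-extends 24-bit EEG codes and maps
non-physical EDA codes to NaN. Test problem sizes (a single 6-minute
session, 10–60 s filter fixtures, 1000-frame codec sweeps) keep the full
suite around ten seconds while leaving every statistic comfortably clear of
its threshold.
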