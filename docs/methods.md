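# Methods

This note documents the models behind `wismux`, the parameter choices that
matter, and what the synthetic experiments do and do not establish.

## Sampling model

One multiplexer slot lasts T_slot = 1/f_mux (1.67 µs at 600 kHz). The first
`settle_fraction` (10 %) is dead time for settling; the remainder,
T_int = 1.5 µs, is the windowed-integration aperture. The sampler response
is the unit-DC-gain boxcar |sinc(f·T_int)|; its noise-equivalent bandwidth is
NEB = 1/(2T_int). The normalization is forced by NEB = 333 kHz at
T_int = 1.5 µs, and `neb_wis_quadrature` confirms the closed form by Simpson
integration over 2000 sinc lobes plus the analytic 1/(2π²x) tail (0.1 %
agreement across T_int from 0.1 µs to 1 ms).

The settle-and-sample comparator assumes a single-pole chain that settles to
relative tolerance `tol` inside the slot, so τ = T_slot/ln(1/tol) and
NEB = 1/(4τ). With equal windows the WIS-to-settling NEB ratio is
ln(1/tol)/2 — 3.45 (≈3.5) at 0.1 % settling. The single-pole assumption is a
modeling choice: the stated tolerance fixes τ only under it.

**Alias folding.** `fold_psd` maps a density to [0, f_nyq] by
S_f(f) = Σ_k S(2k·f_nyq + f) + S(2(k+1)·f_nyq − f), interpolating the
tabulation and treating it as zero above `f_max`. Power is conserved to
<0.5 %. `predict_baseband_noise` chains Johnson density → ×|H|² → fold to
f_s/2 → ÷N_ave → band-integrate. Folding is truncated at f_max = 10/T_int,
which covers >99.9 % of the sinc² power. Averaged slices are treated as
post-hoc averaging of independent samples (fold the per-slice density, then
divide by N_ave) rather than as a longer effective aperture; for white noise
the two agree, and disjoint integration windows make slice noise exactly
independent, giving the 1/√N law the simulator reproduces. Exact boundary
frequencies (f = 0, f_nyq) sit on two fold branches; the affected bins are
measure-zero and irrelevant to band integrals.

## Electrode model

Impedance is tabulated (freq, Re Z, Im Z), interpolated linearly in
log-frequency inside the band and held flat outside it — wideband behavior
is needed for folding while impedance is typically measured only to tens of
kHz. Thermal noise is the one-sided Johnson density 4k_BT·Re{Z(f)}.
Temperatures default to 310 K for in-vivo-like scenes and 295 K for
bench-like scenes.

A series-resistance + parallel-RC interface generates realistic spectra from
two |Z| anchors (≈5 kΩ/2 kΩ at 1/30 kHz for saline; ≈54 kΩ/24 kΩ implanted).
Two magnitude anchors cannot fix three circuit parameters, so the RC corner
is pinned at the geometric mean of the anchor frequencies (≈5.5 kHz) and
(R_s, R_p) are fit by least squares; the anchors are reproduced to <1 %.
Only magnitudes are anchored — the Re/Im split at the anchors is a model
property, not data — so predicted noise from these presets carries that
caveat explicitly. No electrochemistry (CPE exponents, charge transfer) is
modeled.

Colored noise is synthesized in the frequency domain (independent complex
Gaussian bins scaled to the target density, flat extension beyond the
tabulation, inverse rFFT), so aliasing in the acquisition stage emerges
physically rather than being imposed. Averaged Welch estimates match the
target within 5 % across the band.

Offsets drift linearly at 300 µV/s by default (single reported rate); a
seeded random component exists but is off by default.

## Scene synthesis

LFP is a 700 µVpp slow oscillation (1.5 Hz) plus small 20–100 Hz sinusoids
with seeded random phases (defaults 20/15/10 µV at 30/55/85 Hz), chosen so
the <300 Hz peak-to-peak always lands in the 600–800 µV window reported for
cortical activity under ketamine anesthesia. The LFP realization is shared
across electrodes (field potentials are coherent at these pitches).

Multiunit spiking uses a biphasic template (negative trough then a positive
peak at ≈2:1, 1.6 ms support, unit peak-to-peak, default amplitude 16 µVpp).
Widths (σ = 80 µs lobes, 0.2 ms separation) were chosen so the 750–4000 Hz
zero-phase spike filter passes the shape with <10 % peak-to-peak droop,
consistent with cortical multiunit waveforms at 30 kS/s. Event times come
from bursts recurring quasi-periodically at 6 Hz (inter-burst intervals
uniform in [0.8, 1.2]/rate — Poisson burst onsets at this rate merge often
enough to bias the measurable burst rate below the configured one, and
ketamine burst suppression is quasi-periodic), 50 ms bursts with 100 Hz
Poisson events inside, a 1 Hz baseline, and 1 ms refractory deletion. The
defaults put well over half the inter-spike intervals below 20 ms, matching
the reported ISI concentration. Per-electrode firing rates are otherwise
unconstrained by data.

Every (scene seed, electrode, source) triple seeds an independent stream, so
scenes compose additively and any subset of sources can be rendered
reproducibly. Simulation rate: scenes default to 12 MHz (20 samples per
slot); tests mostly use 6 MHz (10 samples per slot), the minimum the
acquisition accepts, to halve synthesis cost. Truth tables record exact
spike trough times.

## Acquisition engine

Per slice: select the electrode from the (contiguous or deterministically
scrambled) slot sequence, discard the settling samples, average the rest,
subtract the DAC-represented offset, add the previous slice's value scaled
by the crosstalk coefficient (presets −60 dB and −20 dB; −60 dB default),
add input-referred circuit noise, quantize. Idle slots are acquired and
discarded.

- **ADC**: 10 bits over ±2.5 mV input-referred (≈1.4 µVrms quantization
  noise) — an assumption, since the reference system's converter parameters
  are not restated here; both are configurable. Saturation is flagged.
- **Offset DAC**: coarse step 130 mV/16 = 8.125 mV; fine step 500 µV with a
  5-bit range covering one coarse step plus overlap. Codes come from a
  4+5-round SAR comparison against the mean probe value with a half-step
  bias, which centers the residual to within ±250 µV for any offset inside
  ±65 mV (verified over 1000 random offsets). Outside the range the codes
  pin and the electrode is flagged saturated. Recalibration every 3.5 s
  bounds drift error by drift_rate·period + 250 µV; probes average several
  frames, so in-band signal perturbs calibration the way it would on real
  hardware.
- **Circuit noise**: 5.5 µVrms per slice, input-referred — the chain's
  grounded-input noise is an *input* to the simulation, not a circuit model.
  It also dithers the quantizer, making quantization effectively additive.
  De-embedding (below) is what removes it, exactly as on the bench.

Demultiplexing averages each electrode's N_ave slices per frame and converts
codes to volts; the cancelled offset stays removed by default (flagged in
metadata) or can be re-added for absolute reconstruction, so either
convention of an external reference system is recoverable.

## Spike pipeline

The "raw" filter approximates a bench recording system: 1st-order 1 Hz
highpass + 4th-order 4.9 kHz lowpass, zero phase (orders are a choice; only
the corners are specified for the reference chain). The spike filter is the
stated 4th-order 750 Hz highpass + 4th-order 4 kHz lowpass Butterworth,
applied forward-backward (zero phase; the design order is quoted, the
magnitude response is applied twice).

Detection places a threshold at −3.0× the plain standard deviation of the
spike-filtered stream (a median/0.6745 robust option exists but is off, as
the plain SD is what the reference analysis used), extracts 1.6 ms snippets
with the crossing at one third of the window (48 samples at 30 kS/s,
crossing at sample 16), and enforces one snippet of dead time. Hoop
isolation keeps events within template ± 1.7× the per-time-point SD at the
template trough and subsequent peak (hoop placement and SD convention are
configuration options; the cited convention is not fully specified).

SNR = (max W̄ − min W̄)/(2·SD_ε) with SD_ε the RMS of the residual matrix
(pooled over events and samples, ddof 0); this pooled convention reproduces
the published per-row SNRs to two decimals. SD_ε = 0 with a structured mean
is reported as undefined rather than a number. Noise floors are the rms of
the spike-filtered stream with event windows excised.

## Noise verification

PSDs are averaged modified periodograms (Hann, 50 % overlap, 0.25 s segments
by default — the estimator is a choice). De-embedding subtracts the
grounded-input density bin-wise, clips negative bins at zero and reports the
clipped count; band rms is the square root of the trapezoidal integral over
500 Hz–5 kHz. Percent error is (measured − predicted)/predicted, rounded to
integers in tables; table means are computed from the per-electrode rows.
When comparing low electrode noise under a larger grounded-input floor,
densities should be averaged across records *before* subtraction — per-record
de-embedding plus clipping biases the band integral upward; the end-to-end
verification does exactly that.

## Test scale and what passing shows

End-to-end Monte-Carlo checks use 20 seeds of 0.4–0.5 s at 12 MHz (theory
agreement, averaging law) and single longer scenes of 4–10 s at 6 MHz
(scramble invariance, budget monotonicity, detection recall); these sizes
give Monte-Carlo errors comfortably inside the stated tolerances. The
detection-recall check runs at the 600 kHz / −3.0σ / 750–4000 Hz operating
point with a saline-grade interface and no circuit noise, i.e. the
well-isolated-events regime: with implanted-grade noise (~4 µVrms floor) a
16 µVpp event's trough sits near 2.5σ and high recall is physically
unattainable at a −3σ threshold — the real system showed exactly this event
loss. Scored recall matches detected trough times to truth within 0.5 ms;
truth events closer than one snippet are shadowed by detector dead time.

The synthetic scenes capture amplitudes, rates, spectra and offsets of the
real preparation but not: multiple discriminable units per electrode, spatial
correlation of spikes across electrodes, electrode nonstationarity beyond
linear drift, movement/stimulation artifacts, or the physical mechanism of
crosstalk (modeled as a single linear coefficient). Passing tests therefore
validates the *signal-processing chain and its noise theory*, not biological
generality. Single-unit sorting, chip-internal circuit behavior (SAR
dynamics, preamp response, area/power figures) and hardware control are out
of scope.
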