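# Methods

## Scope and data model

`calmod` analyzes trace-level two-photon Ca²⁺ imaging of cortical
astrocytes and neurons recorded during behavior. The unit of analysis is a
*session*: a set of ROI fluorescence traces (astrocytic soma AS, processes
AP, gliopil Gp, endfeet AE; neuronal somata with paired neuropil traces)
plus a wheel-speed trace (cm/s) and a whisker motion-energy trace (a.u.),
all on one clock, nominally 10 Hz for 5–10 minutes. Time is stored in
seconds; sample *i* covers the half-open interval `[i/fs, (i+1)/fs)`, and
all intervals (state segments, events) are half-open with the session
starting at 0. Motion correction, denoising, ROI extraction and spike
deconvolution are upstream of this package: it consumes traces, not
images.

## ΔF/F and event detection

Processing per ROI runs detrend → neuropil subtraction → ΔF/F → σ →
events.

**Detrending.** Slow monotone drifts (photobleaching) are removed by
subtracting a fitted line while preserving the trace mean. Two slope
estimators are available. `ols` is the textbook least-squares fit to F.
The default, `baseline`, fits the line to the 10th percentile of F within
~30 s bins: astrocytic transients are long (tens of seconds) and large
(up to ~2 ΔF/F), and when their mass is asymmetric in time the OLS slope
absorbs signal, tilting the baseline by ~10–15% of F₀ and contaminating
every downstream mean; the binned-percentile slope tracks the
fluorescence floor instead. Both estimators remove an exact line exactly.
Traces shorter than four bins fall back to OLS.

**Neuropil subtraction.** Neuronal somata are corrected samplewise as
`F − α·F_np` with α = 0.7 by default (configurable). Astrocytic ROIs pass
through unchanged.

**Baseline and ΔF/F.** F is smoothed with a first-order Savitzky–Golay
filter over the odd sample window nearest 5 s (51 samples at 10 Hz); F₀
is the 10th percentile of the smoothed trace, taken as a single scalar
per ROI. `ΔF/F₀ = (F − F₀)/F₀`, which is invariant to positive rescaling
of F. A scalar F₀ (rather than a rolling baseline) is deliberate: the
separate linear detrend already handles drift, and a scalar keeps the
event amplitude scale interpretable across the session. A non-positive F₀
raises an error, since it indicates wrong input units or offsets.

**Noise.** σ is the minimum over all 5 s sliding windows (stride one
sample) of the sample SD of ΔF/F — the "least noisy 5 s period". It is
computed on ΔF/F, not raw F (configurable window).

**Event detection.** A candidate event exists wherever ΔF/F exceeds
`max(k·σ, A_min)` with k = 2.0 for astrocytic compartments and 2.5 for
neurons. The event extent is the contiguous positive lobe of ΔF/F
containing the suprathreshold sample (zero crossings terminate events;
trace ends act as crossings), so multiple suprathreshold excursions
sharing one positive lobe merge into a single event. Amplitude is the
maximum ΔF/F in the lobe; onset is the first suprathreshold sample;
duration is the lobe length. An optional maximum-duration guard (off by
default) truncates extents.

The absolute amplitude floor `A_min` (default 0.1 ΔF/F) needs
justification. Because σ is the *minimum*-window SD, a bare k·σ threshold
adapts to the noise scale and therefore fires on stationary noise of any
amplitude — simulation shows tens of false events per 5 minutes on pure
Gaussian noise regardless of its SD or smoothness. Real denoised
recordings behave as if an effective amplitude floor exists (knockout
tissue yields near-zero event rates, not a noise-driven floor), so the
detector applies one explicitly: 0.1 ΔF/F is ≈5× the default synthetic
noise SD (0.02 ΔF/F) and ≈2.4× below the smallest per-state mean event
amplitude the presets model (0.24 ΔF/F). Setting `A_min = 0` recovers the
bare threshold rule. When σ = 0 on a nonzero trace the detector warns and
uses the floor alone.

## Behavioral state segmentation

Sessions partition exhaustively into Still, Still-Whisking and
Locomotion; priority Locomotion > StillWhisking > Still.

- **Locomotion**: speed > 1 cm/s; interruptions shorter than 0.5 s are
  merged into locomotion; bouts must then *strictly* exceed 0.5 s or they
  are reclassified as still (which also absorbs the corresponding still
  interruptions).
- **Whisking** (assessed only during stillness, since running implies
  whisking): the motion-energy trace is smoothed with a 0.33 s moving
  average; the baseline W₀ is the 1st percentile of the smoothed trace;
  samples are whisking when the smoothed energy exceeds 1.5 × W₀. The
  multiplicative reading is the default because W₀ is a raw-energy
  percentile and an additive margin would be unit-dependent; an additive
  mode (`W₀ + 1.5`) is provided. Gaps < 0.3 s are merged *before* bouts
  < 0.4 s are dropped — merging last could resurrect sub-minimum
  fragments; the opposite order is available as a config option. Bouts
  are then intersected with still time, and residual fragments under
  0.4 s (smoothing spillover at locomotion edges) are dropped so the
  final segmentation never contains a sub-minimum whisk bout. If W₀ ≤ 0
  the multiplicative threshold degenerates and the detector falls back to
  `W₀ + 1.5·MAD` with a warning.

All bout/gap rules are evaluated on sample counts with a 10⁻⁹ s guard so
that exact boundary durations (e.g. a 0.5 s bout at 10 Hz) resolve
deterministically.

## Modulation indices

Per ROI, `LocMI = (S_loc − S_s)/(S_loc + S_s)` and
`WhiskMI = (S_w − S_s)/(S_w + S_s)`:

- S_loc averages ΔF/F over locomotion bouts strictly longer than 3 s.
- S_w averages over still-whisking bouts of at least 0.4 s; whisking
  during locomotion never contributes.
- S_s averages over still time after removing a ±2 s guard around every
  locomotion bout and keeping only residual segments of at least 2 s. For
  LocMI, S_s includes still-whisking samples (stillness is contrasted
  against locomotion as a whole); for WhiskMI the same qualifying still
  time is used with the whisk bouts themselves excluded. A flag switches
  the LocMI convention.

For nonnegative means the indices lie in [−1, 1] and are invariant to
positive rescaling of ΔF/F. Because ΔF/F can dip below zero, a small
denominator makes the ratio unstable; results with
`|S_active + S_s| < ε` (default ε = 10⁻³ ΔF/F, about the noise floor of
segment means at the default noise level and segment sizes) are flagged
invalid and carry a missing value rather than a clipped one. Indices are
computed from ΔF/F directly, not from detected events.

## Transition metrics

For every locomotion onset whose bout lasts ≥ 3 s, a window from 2 s
before to 7 s after the onset is analyzed (windows with less pre-context,
or clipped by the session end, are marked partial but retained). Per
window, a ROI is excluded when an event spans the onset, when an event
ends within 1 s before it (signal not yet back at baseline — read as the
event's end, not a level criterion), or when any event overlaps the
pre-onset context. Then:

- **Activation rate** per transition: responding included ROIs (≥ 1 event
  onset in `(0, +7]` s) over included ROIs. Excluded ROIs leave both
  numerator and denominator (configurable).
- **Response reliability** per ROI: `RR = RA/n` with RA the number of
  transitions with a post-onset event and n all qualifying transitions of
  the ROI's session; ROIs with n < 3 are emitted as missing. The
  per-window exclusion rules apply to activation/lag analyses, not to RR.
- **Onset lag** per ROI-window: first event onset in `(0, +7]` s minus the
  transition time; summarized per ROI as the mean, and at group level by
  the hierarchical bootstrap median.

## Hierarchical bootstrap

Values are nested (ROIs within mice within genotype groups). Each
bootstrap iteration draws the observed number of mice with replacement,
then within every drawn mouse the observed number of its ROI values with
replacement, and records the mean over all drawn values; 10,000
iterations by default. Two groups are compared by pairing iterations:
`p_one = [#(m_A > m_B) + ½·#(m_A = m_B)]/n_boot` (ties counted one half,
unbiased under exchangeability), and the reported two-sided
`p_boot = 2·min(p_one, 1 − p_one)`, capped at 1; a one-sided mode is
available. Significance is assessed at α = 0.05. Resampling keeps the
observed counts at both levels — the standard hierarchical bootstrap.
Mixed-model fitting is out of scope; the pipeline instead exports tidy
per-event and per-ROI tables (with ROI, compartment, state, mouse, group
columns) shaped for external LME/GLMM tools.

Calibration: with both groups drawn from one nested generative
distribution (5 mice × 8 ROIs, between-mouse SD 0.1, within-mouse SD
0.2), the two-sided rejection rate at α = 0.05 lands within the exact
binomial 95% interval around 0.05 over 200 replicates (measured
0.065–0.090 across generator seeds at n_boot = 1000 — the procedure is
mildly anti-conservative at five mice per group, a known trait of
hierarchical resampling with few top-level units).

## Synthetic sessions

The generator produces complete sessions with known ground truth.

**Behavior.** The latent schedule alternates still bouts (exponential,
mean 20 s, floor 2 s) and locomotion bouts (exponential, mean 8 s, floor
1.5 s; each occurring with probability `loc_bout_prob`). Wheel speed is
~3 cm/s with smooth jitter (clipped ≥ 1.5 cm/s) during locomotion and
sub-1 cm/s jitter otherwise. Whisk bouts (exponential, mean 1.5 s, floor
0.6 s, at a configurable rate per minute of stillness) are placed inside
still bouts with 0.5 s margins; whisker motion energy is a baseline
(≈1 a.u.) raised to ≈4 a.u. during whisk bouts and throughout locomotion.
Motion energy is generated directly as a smoothed nonnegative energy
trace; video pixel differencing is emulated, not simulated from frames.

**Fluorescence.** Each ROI trace is
`F = F₀·(1 + Σ kernels + shared) + bleach·t + noise` with F₀ = 100 a.u.,
bleach −0.02 a.u./s, and i.i.d. Gaussian noise of 2 a.u. (0.02 ΔF/F) —
post-denoising-like noise; shot noise is upstream. Events form a Poisson
process whose rate, mean amplitude and mean duration switch with the true
behavioral state per compartment (amplitudes/durations normal with CV
0.25, floored at 0.02 ΔF/F and 0.5 s). The kernel rises in one sample and
decays exponentially with τ = duration/3 (≈5% left at the nominal
duration); detection needs only threshold and zero crossings, so the
kernel shape is a deliberate stand-in, not a biophysical claim.
Astrocytic ROIs share a smoothed common drive scaled so the noise-floor
correlation of a ROI pair equals `corr_level` (0.3 wild-type-like, 0.1
knockout-like). Neurons receive `α_true·F_np` of a shared slowly
fluctuating neuropil trace (α_true = 0.7) and emit the paired F_np.
Optionally, events can be injected at a fixed (jittered) lag after every
locomotion onset (`onset_locked`), used to validate lag recovery; it is
off by default because the preset event rates are state-homogeneous.

**Presets.** The per-compartment × state event tables of the
wild-type-like and knockout-like presets follow reported per-state event
frequencies, amplitudes and durations for the two genotypes (e.g. AS:
0.69/1.92/2.91 events/min across Still/Still-Whisking/Locomotion
wild-type-like vs 0.06/0.03/0.34 knockout-like). They are defaults that
emulate the regimes, not claims of exact reproduction. Neuronal per-state
amplitudes and durations are not reported; the presets use typical
somatic indicator values (0.4–0.55 ΔF/F, 2–2.5 s). The knockout preset
uses state-flat neuronal rates so its *generative* neuronal locomotion
modulation is ≈ 0, matching the qualitative contrast the pipeline is
meant to detect. Default cohorts are 6 wild-type-like and 5
knockout-like mice, 2 sessions each, with 3/5/6/1/5 ROIs per
AS/AP/Gp/AE/Neuron per session and 300 s sessions — a deliberately
compact field of view that keeps a full dual-cohort analysis fast while
preserving the nested structure.

**Ground truth** records the schedule, every drawn event, α_true, and the
analytic stationary mean ΔF/F per state (`rate·amplitude·τ`), from which
true modulation indices satisfy the defining identity exactly.

**What the generator does not emulate.** (1) Onset-locked bursting:
per-state homogeneous Poisson rates reproduce per-state frequencies but
not the tight event-locking to locomotion onsets seen in vivo, so
synthetic activation rates (~0.2–0.35) and reliabilities are far below
in-vivo wild-type values (~0.98/0.70). (2) Whisking modulation: the
modeled astrocytic kernels (τ ≈ 3–6 s) are much longer than whisk bouts
(~1.5 s), so a stationary rate increase inside bouts barely raises the
within-bout mean — emergent WhiskMI is ≈ 0 rather than ~0.3. Expressing
realistic whisking modulation would need onset-locked fast kernels.
(3) The ratio structure of LocMI means a pure rate scaling leaves the
generative index high even in the knockout regime; the low observed
knockout LocMI emerges from noise-dominated segment means, matching the
qualitative in-vivo pattern (collapsed means, wide spread) but not any
particular printed value. Passing tests therefore validate the estimator
chain against its own ground truth and direction-level genotype
contrasts, not in-vivo effect sizes.

## Numerical choices

- Savitzky–Golay and moving-average windows are forced to odd sample
  counts nearest their nominal lengths.
- Interval rules compare sample counts against `threshold·fs` with a
  10⁻⁹ guard; strict (">") vs inclusive ("≥") follows the stated rule for
  each filter (locomotion bouts strict, whisk/still minima inclusive).
- σ uses the unbiased sample SD (ddof 1).
- Bootstrap reproducibility: all resampling flows through
  `numpy.random.Generator` seeded per call; identical inputs and seed
  give identical p_boot.
- Degenerate inputs: empty still or active sample sets and near-zero
  denominators yield invalid (missing) modulation results; transitions
  with no included ROIs yield missing activation rates; zero-variance
  traces yield missing correlations. Missing means missing — never 0.

## Validation experiments

The test suite and `scripts/acceptance.py` recompute, from scratch:
brute-force oracle equivalence of the segmenter (1000 random traces) and
event detector (constructed traces); ≥95% recovery of injected ≥3σ
transients with exact span-maximum amplitudes and a silent false-positive
budget on default noise; modulation recovery on 100 synthetic ROIs with
configured state means (median |error| ≤ 0.02, against 1/3 for means
2m vs m) — generated at the ΔF/F level, since pushing a still-state
pedestal through the percentile baseline would re-zero it and change the
analytic truth; bootstrap type-I calibration; and the end-to-end genotype
contrast (markedly lower astrocytic event frequency and LocMI in the
knockout-like cohort with p_boot < 0.05; wild-type neuronal LocMI > 0 vs
knockout ≈ 0).
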