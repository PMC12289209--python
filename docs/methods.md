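# Methods

## Scope and model

`squidtag` estimates the daily movement energetics of free-ranging squid
from animal-borne tag data. The measurement chain rests on four models:

1. **Fin magnetometry.** A magnet on one lateral fin modulates the field at
   the tag magnetometer monotonically with fin elevation (dorsal = closer =
   stronger). Only *relative* fin position is meaningful — the coupling is
   uncalibrated — so one fin stroke (upstroke + downstroke) is one crest in
   the summed-magnitude signal, and the fin-beat frequency is the crest
   rate. Metachronal finning gives a sustained ~0.8–1.3 Hz sinusoid; jets
   give slower (~0.4–0.7 Hz) high-amplitude fin cycles.
2. **Activity and gait.** Behaviour is assumed to decompose into four
   states: finning, jetting, "other" low-frequency movement, and passive
   gliding. Gliding is operationally an *absence*: no detected fin strokes
   and |dynamic surge| < 0.10 g for ≥ 5 consecutive seconds. Active data are
   separable by dominant frequency because the per-animal frequency
   distribution is bimodal.
3. **Respirometry.** In a sealed swim tunnel the dissolved-oxygen decline
   is linear; the animal's rate is the slope minus the microbial background
   slope, times system volume. Across animals, mass-specific rate follows a
   power law in wet mass (linear in log–log).
4. **Energetic transfer.** Laboratory rates transfer to field temperature
   multiplicatively with q10 = 2; gliding is costed by a population-specific
   constant proxy; daily budgets rescale recorded state fractions to 24 h.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| smoothing window | 30 | samples (0.3 s at 100 Hz) | matches the detector's training conditioning; centred to avoid phase lag |
| inter-fin artefact gap | 4 | s | doubly isolated crests are orientation changes, not strokes |
| annotation match tolerance | 0.25 | s | well under half a fin period; one-to-one nearest-time greedy matching |
| surge threshold | 0.10 | g | separates high-amplitude jets from background movement |
| min glide duration | 5 | s | an inactive *state* requires sustained quiet, not one quiet window |
| FFT window / pad | 5 s / 10,000 | samples | bin spacing 100/10500 ≈ 0.0095 Hz |
| q10 (T1 = 18.8 °C) | 2 | – | standard ectotherm temperature coefficient; laboratory reference temperature |
| glide proxy | 134.5 | mg O₂ kg⁻¹ h⁻¹ | mean of standard (86) and hovering (183) rates from the same population |
| O₂ gas density | 1.428 | mg ml⁻¹ | STP density; converts mg O₂ budgets to the ml-based prey conversion |
| prey conversion | 4 | mg fish per ml O₂ | ecological conversion for squid foraging |

## Design choices where the design was open

- **Width reference level.** The peak detector names prominence and width
  bounds without a reference level; width is measured at half prominence
  (scipy's `rel_height=0.5`), the conventional choice.
- **Optimiser success rule.** A grid combination succeeds when it marks
  100 % of annotated crests; extra detections do not disqualify it (the
  training criterion is recall-only), but precision of the averaged setting
  is reported, and `require_no_false_positives=True` tightens the rule.
  The averaged setting need not itself be recall-1, so its per-segment
  recall is re-measured and reported.
- **Short quiet runs.** Quiet (inactive) windows shorter than 5 s occur
  naturally between the crests of slow fin cycles — one crest per ~2.2 s at
  jet-cycle frequencies — so by default they are absorbed into the
  surrounding active run (`short_inactive="merge"`); splitting them out as
  unclassified (`"unclassified"`) is available but fragments every
  low-frequency bout below the 5 s FFT window, leaving jets and "other"
  unclassifiable.
- **Dynamic surge.** The postural/gravitational component is a centred
  0.5 s running mean of the surge axis, subtracted from the signal; the
  window is configurable. Threshold comparisons use |dynamic surge|.
- **Frequency split.** Gaussian KDE (Silverman bandwidth) on the pooled
  per-animal dominant frequencies; the split is the density minimum between
  the two highest modes, with a warning + configurable fallback (0.75 Hz)
  when bimodality is absent.
- **Volume correction.** `M = (|animal| − |control|) · V` uses the full
  system volume by default; subtracting animal body volume (mass / 1.06
  kg l⁻¹) is available but is a < 0.2 % correction in a 1485 l tunnel.
- **Mixed model.** Natural logs; per-animal random intercepts via REML
  (statsmodels `MixedLM`), falling back to OLS with a warning when animals
  have single observations or the fit fails. Marginal r² is fixed-effect
  variance over total (fixed + random + residual) variance. Slope
  confidence intervals use a t reference with (animals − 2) degrees of
  freedom — mass is a between-animal covariate, and the large-sample normal
  undercovers badly with ~7 animals.
- **Saturation QC.** Air-saturated O₂ concentration from the
  Garcia–Gordon (1992) solubility fit (Benson–Krause coefficients),
  salinity default 35, nominal seawater density 1.025 kg l⁻¹.
- **q10 scope.** Only model-predicted finning rates are q10-transferred;
  the glide proxy is used as-is because its source rates were measured on
  the field population at field-relevant conditions. Consequently the
  glide-cheaper-than-finning ordering is guaranteed only for ambient
  temperatures in the field-to-laboratory range (≈ 13.8–18.8 °C); far
  colder water could push corrected finning predictions below the
  uncorrected proxy for the heaviest animals.
- **Uncosted states.** Jets and "other" were never elicited in the
  respirometer, so their time is excluded from the costed total and
  reported as an uncosted fraction; the budget is deliberately partial and
  excludes growth, digestion and oxygen-debt repayment.

## The synthetic generator

`synthetic.simulate_recording` renders a behaviour script into 100 Hz
accelerometer/magnetometer and 1 Hz depth/temperature streams with ground
truth. It emulates:

- additive sinusoidal field modulation at the scripted fin frequency
  (finning draws around the field mean 1.12 ± 0.19 Hz), one fin event per
  completed cycle at the crest;
- jet cycles below the split frequency with one Gaussian surge pulse
  (> 0.10 g) per cycle, peaking at the end of the fin downstroke;
- glides with a flat fin channel, sub-threshold dynamic acceleration, and
  depth increasing at the scripted sink rate;
- a smooth stationary orientation wander (low-pass filtered noise, ~8 s
  correlation scale) that rotates the 1 g gravity vector and drifts the
  magnetometer baseline, making dynamic-surge extraction non-trivial;
- per-channel Gaussian sensor noise, default s.d. 5 % of fin amplitude
  (signal-to-noise ≈ 20);
- isolated orientation artefacts injectable into glides with > 4 s
  clearance from every true fin event;
- linear respirometry DO declines with animal- and mass-dependent slopes
  plus microbial background.

It does **not** simulate thrust hydrodynamics, fin-angle kinematics in
physical units (the magnet coupling is uncalibrated in reality too),
3-D tracks, light, or tag slippage. Passing recovery tests on this
generator therefore demonstrates that the chain inverts its own signal
model under realistic noise, drift and artefact structure — not that it is
robust to every failure mode of real deployments (biofouling, variable
coupling gain, mixed gaits within a window).

## Numerical notes

- The moving averages (conditioning, surge) are centred with shrinking
  edge windows; detections therefore carry no phase lag, but peaks in the
  first/last half-window can lose prominence and edge cycles may be missed
  (≲ 1 event per bout).
- `dominant_frequency` is the maximum-magnitude non-DC bin of the
  Hann-tapered, zero-padded real FFT. Zero-padding sets bin *spacing*
  (0.0095 Hz), not resolving power: below ~0.375 Hz the 5 s window holds
  fewer than two cycles and the negative-frequency image of the Hann main
  lobe biases the peak by up to ~0.07 Hz (phase-dependent). All gait
  frequencies of interest (jets ≳ 0.4 Hz, finning 0.8–1.3 Hz) lie in the
  band where worst-case error is ≤ 0.006 Hz.
- The optimiser prefilters all local maxima once per segment and applies
  prominence/width thresholds as per-combination masks (memoised by
  selected subset); this is exactly equivalent to running the peak detector
  per combination (asserted in tests) and makes 10⁴–10⁵-combination grids
  cheap.
- Constant DO traces return slope 0 with r² reported as 1 (nothing to
  explain); constant FFT segments raise rather than return a spurious bin.
- Problem sizes in the test-and-reproduction suite: 10-minute deployments
  (10 replicates) for detection recovery, 500 s scripted deployments
  (5 seeds) for budget recovery, 10,000-combination grids for the
  optimiser contract, and 100 replicates of 7 animals × 2–3 trials for
  slope coverage — sizes at which every recovery statistic is stable
  from seed to seed.

## Known limitations

- Fin-event *shape* descriptors (prominence, width) are in arbitrary units
  and not comparable across deployments without the same conditioning.
- The frequency split is computed per recording; pooling across animals is
  possible by concatenating dominant-frequency collections before
  `find_split_frequency`.
- Daily budgets extrapolate recorded state fractions to 24 h; recordings
  shorter than a diel cycle inherit any diel bias of the recording window.
- The reference two-point mass-scaling model used when no trials are
  supplied carries no uncertainty; fit a real model for inference.
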