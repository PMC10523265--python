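# Methods

This note documents the models, conventions and design choices behind
`photocif`: what the analysis computes, what the synthetic generator
emulates, and where the open decisions were made.

## Signal model and correction

Two-channel fibre photometry is modelled as

    F465(t) = (g·a(t) + c465) · B(t) + m(t) + ε465(t)
    F405(t) =           c405  · B(t) + m(t) + ε405(t)

where `a(t)` is latent AgRP population activity, `g` the sensor gain,
`c465`/`c405` channel offsets (background + autofluorescence), `B(t)` a
double-exponential photobleaching envelope shared by both channels, `m(t)`
an additive motion-artifact series **numerically identical** in both
channels, and `ε` white measurement noise.

The correction `ΔF/F = (F465 − F405)/F405` is applied exactly as written —
no isosbestic fitting, no smoothing.  Under the model the numerator cancels
`m(t)` exactly and the bleach envelope cancels in the ratio; the only
artifact leakage is through the `F405` denominator, of relative size
`m/c405`.  The default parameters keep that leakage at ~1% of the ΔF/F
fluctuation scale while the artifact still dominates the raw 465 channel in
a quiet session, which is exactly the regime the correction is for.  A
regression-scaled variant (`fit_isosbestic_dff`, CLI `--fit-isosbestic`)
exists for comparison and is off by default.

## Normalisation and peri-event conventions

* z-scores use the **sample (n−1) SD** of the baseline window; baselines
  with SD ≤ 1e−12 raise a degenerate-baseline error.
* All windows, baselines included, are **half-open `[start, end)`** on the
  sample grid, so adjacent windows never share a sample.
* Peri-event rows are re-normalised **per event** to their own baseline
  (−10…0 min for food alignment, −10…0 s for bouts); session-level
  baselining (e.g. the 10-min home-cage period before context transfer) is
  the same operation applied once to the whole trace.
* Events whose full window leaves the recording are dropped, counted and
  logged — never padded.
* Feeding bouts, not animals, are the rows of the bout-triggered analysis.
* Time is seconds internally; minute-labelled windows are converted at the
  interface.  The analysis rate is 20 Hz (all time constants of interest
  are ≥ 0.5 s; vendor-native kHz acquisition is out of scope), tracking
  25 Hz.

## Latent activity model

    a(t) = tonic(state)
         + ν·A_novel·exp(−Δentry/τ_novel)                (context transfer)
         − A_drop·(1 − e^(−Δfood/τ_fast))·e^(−Δfood/τ_slow)   (food)
         − per-bout dips (onset τ_on, recovery τ_bout)
         ± optogenetic envelope terms
         + OU(σ_ou, τ_ou),  clipped at 0.

Defaults (arbitrary units / seconds): tonic fed 1.0, fasted 5.0;
A_drop 3.0 with τ_fast 10 s (sensory drop) and τ_slow 1200 s (sustained
post-ingestive component); per-bout dip 1.0 with τ_on 0.5 s and recovery
τ_bout 10 s; novelty 2.0 with τ_novel 60 s, scaled by ν = 1 for a first
transfer, 0.4 for a familiar test context and 0.25 during training (the
animals are habituated to both contexts before training); OU noise σ 0.5,
τ 5 s (exact AR(1) discretisation, stationary start).  These magnitudes are
qualitative: they give z-scale food responses of a few baseline SDs, the
size typical of AgRP GCaMP recordings, and are not fitted to any dataset.

Optogenetic drive is modelled at the analysis rate by its **envelope**: a
20 Hz, 1 s ON / 3 s OFF train cannot be resolved at 20 S/s, so excitation
adds `A_stim × duty` (duty = 0.25) during the envelope, with 1-s
exponential edges; constant-light inhibition clamps the deterministic drive
toward a floor (0.2 a.u.).  Overlapping envelopes are rejected.

Render defaults: gain 10, offsets 1500 (both channels), white noise SD 1,
bleach 0.5% at τ 300 s plus 1% at τ 3000 s, motion artifacts as half-sine
pulses (1.5 s, amplitude 25 × U(0.5, 1.5)) at 6/min.  A multiplicative
artifact mode exists and is off by default.  These were chosen analytically
(see Signal model above) so that artifact rejection is a property of the
design, with the raw-channel artifact correlation evaluated on a quiet fed
session — in a food session the programmed suppression step, not the
artifact model, dominates raw-channel variance.

Model-implied ground truth for recovery checks comes from the forward model
itself: the programmed z-scale suppression is the baseline-minus-post mean
of the deterministic drive divided by the stationary baseline SD
√(σ_ou² + 2·σ_noise²/g²), and the programmed ΔF/F bout dip is
`g·A_bout/c405`.

## Behaviour generator and metrics

Tracking is a heading-persistent random walk (mean speed 6 cm/s) reflected
at the arena walls of a 40 × 40 cm arena, with the position pinned inside
the food zone during scheduled bouts.  Labels come from a dwell-time Markov
chain over {sniffing_food, walking, stationary, rearing, grooming} with
'eating' forced during bouts.  Bout schedules default to 5–10 s bouts at
least 30 s apart, starting ≥ 60 s after food — off the steep part of the
sensory drop, and far enough apart that recovery tails stay out of
neighbouring bout baselines.

Zone geometry: food disc (default radius 6 cm — the receptacle's immediate
surround, configurable, no canonical value exists), approach annulus
extending 5 cm beyond it, floor elsewhere; the three zones partition the
arena, so per-zone durations sum exactly to the session length.  An entry
counts only after 0.2 s continuously inside the zone (hysteresis against
boundary chatter; commercial trackers do not publish their rule, so this is
a package choice).  A never-entered zone reports latency equal to the
session length with an explicit `not_reached` flag.  Eating bouts are
maximal eating runs with gaps < 2 s merged and merged runs < 1 s discarded;
both thresholds are configurable because no standard definition exists.
Barcode dominant-label ties break toward the earlier label in the canonical
vocabulary order.

## Cohort model and statistics

Per mouse: three training sessions (context A) and two counterbalanced test
sessions (A, B).  Test intake in B is `base + noise` and in A is
`B + effect(group) + noise`; a standard-normal per-mouse trait `u` enters
training intake (`mean(group) + 0.1·u` g) and the A−B noise
(`0.15·(ρ·u + √(1−ρ²)·ζ)` g), so corr(training intake, discrimination) is
programmed at ρ per group.  Defaults: fed / ghrelin / fasted groups of
10 / 10 / 9 mice, training means 0.15 / 0.35 / 0.8 g per 30-min session,
test base 0.3 g, noise SD 0.15 g, effects 0 / 0.05 / 0.3 g, ρ = 0.2 / 0.2 /
0.59 (fasted R² ≈ 0.35 in expectation).  Negative intake draws are
truncated at 0 g and counted in a logged warning.  Session bundles
(photometry + tracking) are rendered for the first 4 mice per group by
default; intake records cover all mice.

The headline inference is the sign-flip permutation test on paired A−B
differences: exact enumeration of all 2ⁿ sign patterns for n ≤ 12
(p = #{|null mean| ≥ |observed mean|}/2ⁿ, identity included), otherwise
Monte-Carlo with the add-one estimator (1 + hits)/(1 + resamples).  It
replaces repeated-measures ANOVA machinery deliberately: the scientific
claim (within-animal A > B) is a paired location test, and the permutation
version is exact at these sample sizes without distributional assumptions.
A paired t-test is reported alongside as a parametric cross-check, and Holm
adjustment is applied across groups.  Rejection uses p ≤ α; with continuous
data the exact test's achievable levels are multiples of 2/2ⁿ, so its
realised type-I error at α = 0.05, n = 10 is 50/1024 ≈ 0.049.

## Pipeline, formats, determinism

CSV is the interchange dialect (UTF-8, '.' decimal); a session bundle is
one directory with `photometry.csv`, `events.csv`, `tracking.csv`,
`labels.csv` and `meta.yaml`, plus cohort-level `intake.csv`.  Run
configuration is a schema-validated YAML block (unknown keys rejected);
every written CSV carries `#` header lines with the package version, a hash
of the scientific configuration (output path excluded) and the seed.  One
user seed expands into named sub-streams via SeedSequence spawn keys hashed
from stream labels, so the whole run — and each stage in isolation — is a
pure function of (config, seed), and repeated runs are byte-identical.
Analysis windows follow the configured session timeline (baseline =
context-to-food interval, post-food span split in two), which reproduces
the −10…0 / 0–10 / 10–20 min layout at the default timing and scales
consistently for shortened sessions.  No hierarchical binary export is
provided; desk-scale cohorts stay comfortably within CSV.

## What the generator does and does not emulate

It emulates the features the analysis must be robust to: state-dependent
tonic activity, food-evoked and per-bout suppression, novelty transients,
channel-shared motion artifacts, photobleaching, stochastic feeding
schedules, and cohort-level intake effects with a training-test coupling.
It does **not** emulate GCaMP biophysics (indicator kinetics, saturation,
spiking), pharmacokinetics, hemodynamic or spectral crosstalk,
multiplicative-artifact regimes (present but off by default), tracking
identity errors, or inter-mouse parameter heterogeneity beyond the intake
trait.  Passing tests therefore demonstrate that the analysis correctly
decodes this model class — not that it is robust to every failure mode of
real rigs; on real data the unfitted ΔF/F in particular inherits the usual
caveat that unequal channel gains leave a scaled artifact residual.

## Problem sizes

Default sessions are 40 min at 20 Hz (48 000 samples per channel).
Recovery checks use 10 sessions (suppression) and 8 sessions / ≥ 50 bouts
(bout dip); permutation calibration uses 1000 null and 500 alternative
cohorts of n = 10, with the exact n ≤ 12 branch.  These sizes give
Monte-Carlo SEs comfortably inside the stated tolerances (15% / 25% /
±2 percentage points) while keeping a full run in the seconds-to-minutes
range on a single CPU.
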