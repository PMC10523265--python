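# photocif

Analysis pipeline for **context-induced feeding (CIF)** experiments:
fibre-photometry correction and peri-event quantification of AgRP neuron
population activity, video-derived behaviour metrics, and the cohort-level
feeding statistics — together with a synthetic cohort generator that gives
every stage a programmable ground truth.

CIF is conditioned over-eating: a mouse trained to eat palatable food in
context A while hungry will later, when sated, eat more in context A than in
a familiar but untrained context B.  AgRP neurons in the arcuate
hypothalamus encode the hunger state that drives this learning — tonically
elevated by fasting and rapidly suppressed by food — and their population
activity is monitored with a GCaMP sensor through two-channel fibre
photometry.  The package is for researchers who run (or want to prototype
analysis for) such experiments and need a tested, reproducible path from
raw two-channel traces, tracking and intake records to the standard
readouts.

## The core computations

**Isosbestic correction.**  The calcium-dependent channel (465 nm) and the
calcium-independent isosbestic channel (405 nm) are combined as

    ΔF/F = (F_465 − F_405) / F_405

which cancels additive artifacts shared by both channels (motion, ambient
light) and the common photobleaching envelope.  The subtraction is applied
verbatim; a regression-scaled variant is available behind an explicit flag.

**Baseline z-scoring and peri-event analysis.**  Signals are expressed as

    z = (x − x̄₀) / S₀

with x̄₀, S₀ the mean and sample SD of a defined baseline window, then
aligned to repeated events — context transfer, food presentation, feeding
bout onset — on a common grid, each event re-normalised to its own
pre-event baseline (−10…0 min for food presentation, −10…0 s for bouts),
and summarised as half-open window means (0–10 / 10–20 min; 0–5 / 5–10 s).

**Behaviour metrics.**  From tracking and a six-label ethogram: per-zone
entry frequency, occupancy duration and first-entry latency (food zone,
5 cm approach annulus, remaining floor), total distance and mean velocity,
behavioural barcoding (% time per label, per-bin dominant label), and
eating-bout segmentation (merge gaps < 2 s, keep bouts ≥ 1 s).

**CIF statistics.**  Context discrimination is each animal's A − B intake
difference.  Group-level inference uses a **sign-flip permutation test** on
the paired differences (exact enumeration of all 2ⁿ sign patterns for
n ≤ 12, Monte-Carlo otherwise), Holm-adjusted across groups, plus OLS of
discrimination on mean training intake (slope, intercept, R²).

**Synthetic cohorts.**  A forward model with interpretable parameters —
fasted/fed tonic levels, a food-evoked suppression kernel
(1 − e^(−t/τ_fast)) · e^(−t/τ_slow), per-bout dips, novelty transients,
optogenetic envelopes, OU noise, shared motion artifacts, double-exponential
bleaching, and programmed per-group intake effects — generates sessions and
cohorts that the analysis stages must decode back.

## Worked example

```python
import numpy as np, photocif as pc

params = pc.AgrpParams()
protocol = pc.Protocol.training(state="fasted", rng=np.random.default_rng(1))
trace = pc.simulate_activity(params, protocol, seed=1)
session, truth = pc.render_photometry(trace, params, seed=1)

dff = pc.compute_dff(session.f465, session.f405)
m = pc.build_perievent(dff, session.time, session.event_times("food"),
                       pre=600.0, post=1199.95, baseline=(-600.0, 0.0))
wm = pc.window_means(m, [("baseline", -600.0, 0.0), ("0-10 min", 0.0, 600.0),
                         ("10-20 min", 600.0, 1199.9)])
print(wm[["window", "mean"]])
```

prints (seed 1):

```
     window      mean
   baseline -0.000000
   0-10 min -4.477861
  10-20 min -2.811879
```

i.e. the baseline window is centred at 0 by construction and food
presentation suppresses AgRP activity by ≈ 4.5 baseline-SD units over the
first 10 min, relaxing toward baseline thereafter — the generator's
programmed sensory drop plus sustained post-ingestive component, read back
by the pipeline.  `examples/` contains one short script per capability
(session simulation, photometry analysis, behaviour metrics, CIF
statistics, end-to-end pipeline), and the `photocif` CLI exposes
`simulate | photometry | behavior | report | run` for shell use.

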