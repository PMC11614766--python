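# Methods

This note documents the models, conventions and design choices behind
`tewskit`: what each stage computes, which knobs matter, what the synthetic
cohort generator does and does not emulate, and where the design was genuinely
open.

## Problem setting

The package targets *continuous* early warning of septic shock: an hourly risk
score per ICU stay, thresholded into an alarm stream, judged by whether alarms
arrive inside a clinically useful window before each shock onset. The unit of
evaluation is the *shock event* (an episode onset), not the stay or the
stay-hour. Two event-based metrics drive everything:

- `TER = (# events with >=1 timely alarm) / (# events)`,
- `TAR = timely / (timely + false)` over classified alarms,

with an alarm *timely* when it falls in `[onset + earliest, onset + latest]`
(defaults −8 and 0 hours) of an eligible episode, *in-shock excluded* when it
falls strictly after an onset and at or before that episode's end, and *false*
otherwise. Alarms during ongoing shock reflect genuinely elevated risk, so
they count in neither the numerator nor the denominator of TAR. The per-stay
variants average per-stay TER/TAR over stays that experienced shock;
`TAR_stay` omits stays with no classified alarms (undefined ratio; a flag
switches to counting them as zero).

Conventions worth stating explicitly:

- An alarm at the onset hour itself (t = 0) is timely when `latest = 0`, even
  though the hour is in shock: in-shock exclusion applies strictly after
  onset.
- An alarm inside the windows of several episodes is attributed to the
  earliest matching onset; an episode counts as warned when any timely alarm
  lies inside *its* window. This prevents one alarm from silently double-
  counting while keeping the warned-event definition local to each event.
- TER is reported as `None` when no eligible events exist; TAR is 0 when no
  alarms were classified.

## Hourly feature matrix

Hour `h` covers minutes `[60h, 60(h+1))` from ICU admission (half-open,
left-closed; a record exactly at admission belongs to hour 0; a record exactly
at discharge on a whole-hour boundary is kept in the last bin). Cleaning
precedes binning: values outside per-variable plausibility bounds are dropped
(heart rate 0–300 bpm and similarly clinician-plausible ranges for the rest,
all overridable), point records outside the admission–discharge interval are
dropped, interval records must lie entirely inside it, and anything beyond two
days outside the stay is removed unconditionally. GCS components are aligned
per charting timestamp (nearest earlier record, else nearest later), and
urine output is corrected for bladder irrigation by cumulative
irrigant-out-minus-irrigant-in, clamped at zero (negative corrected volumes
are logged; the clamp is our choice — the correction rule does not address
them).

Per measurement variable and hour the matrix carries mean/median/max/min, a
presence flag (1 iff at least one raw value fell in the bin), and slope
features `mean(h) − mean(h−K)` for `K ∈ {1,3,5}` (0 when `h − K < 0`). Volume
variables (urine) are summed per bin; drug and ventilation intervals become
per-hour activity flags (an interval overlaps a bin under the half-open rule,
endpoint inclusive) plus a maximum vasopressor dose rate. No derived features
for age, drug or ventilator items.

Imputation is class-specific: labs and GCS forward-fill then backward-fill
within the stay (a lab value persists until the next draw); vitals, height and
weight interpolate linearly between measured hours with nearest-value
extension at the edges; a variable never recorded in a stay becomes all zeros
with presence 0 throughout. Presence flags are never changed by imputation.
One ordering choice: slopes are computed *after* imputation, on the imputed
hourly means. Computing differences on un-imputed means would leave NaNs that
no later step could fill coherently, and the persisted-lab semantics of the
slope then matches the persisted-lab semantics of the level.

## Sepsis-3 annotation

Suspected infection is the conjunction of antibiotics given, a blood culture
drawn and an infection ICD code issued (prefix matching on a configured code
list; no temporal pairing window is imposed between antibiotics and cultures,
though one is configurable). Sepsis onset is the first hour total SOFA ≥ 2,
defined only for suspected-infection stays. SOFA uses the consensus tiers for
the six organ systems with these operational choices:

- vasopressor dose rates are read as norepinephrine-equivalent µg/kg/min
  (≤ 0.1 scores 3, > 0.1 scores 4); a vasopressor without a recorded rate maps
  to the minimum vasopressor tier (2);
- the renal urine criterion uses rolling 24-hour totals once a full day of
  history exists, otherwise the creatinine tier stands alone;
- MAP is derived as `(SBP + 2·DBP)/3` where not charted; a stay with no GCS
  at all is treated as neurologically normal (total 15) rather than letting
  the all-zero imputation score 4.

Shock hours are hours with imputed lactate ≥ 2 mmol/L and an active
vasopressor, gated to hours at or after sepsis onset; episodes are maximal
runs of such hours (a single non-shock hour ends an episode; the separation
gap is configurable). Lactate persistence follows lab imputation, so one
elevated draw persists until the next draw. Exclusions: missing required
variables (SBP, DBP, PaO2, FiO2, GCS, bilirubin, platelets, creatinine,
lactate — GCS counts if any component was charted), no sepsis onset, or
shock before sepsis. The shock-before-sepsis screen runs on the *ungated*
shock-hour set. Note that under consensus scoring an active vasopressor alone
yields SOFA ≥ 2, so this exclusion can only fire when the SOFA inputs and the
shock inputs disagree in timing (as they can in heterogeneous real extractions);
the branch is kept and unit-tested with an injected SOFA panel.

## Data-task engineering

Labels: hour `h` is positive iff some onset `o` satisfies
`o − pw ≤ h ≤ o − 1`. The onset hour itself is labelled 0 — at onset the
event is no longer in the future; whether an onset-hour alarm counts timely is
the evaluation window's business, not the label's. Training masks: with a
finite training window `tw`, in-shock hours beyond `onset + tw` are dropped
from training (post-episode recovery hours are retained); with first-shock
focus, everything strictly after `first_onset + tw` (or after the first
episode's end when `tw = "all"`) is dropped. One documented edge: when the
first episode is shorter than the finite windows, the `tw = "all"` focus
cutoff (episode end) can be stricter than the `tw = 2` cutoff, so mask
monotonicity in `tw` holds only for episodes spanning the finite windows.

The split is by stay (all hours inherit the stay's partition), stratified by
shock status so each partition's prevalence tracks the cohort's, with exact
largest-remainder apportionment of the 70/10/10/10 fractions (every partition
within one stay of its quota) and fully deterministic under the seed.

## Modelling harness

Seven learners are registered: histogram gradient boosting, LightGBM,
XGBoost, random forest, logistic regression (standard-scaled), CART, and
multinomial naive Bayes behind a min–max scaler (the learner requires
non-negative inputs; slope features are signed). Hyperparameters are each
ecosystem's defaults with fixed seeds. SMOTE and ADASYN are implemented in
the package: both synthesise minority rows by interpolating towards random
minority k-nearest neighbours (k = 5), ADASYN allocating synthetic counts
proportionally to the majority share of each minority point's neighbourhood.
Oversampling touches training rows only; isotonic or sigmoid calibration maps
are fitted on the dedicated calibration partition only.

Thresholds are selected on validation by an exhaustive sweep over every
distinct score plus {0, 1} — exact for step-function metrics — maximising TER
subject to `TAR ≥ 0.2`, ties towards the higher threshold; when no candidate
meets the floor the max-TAR threshold is returned flagged infeasible. The
sweep exploits the fact that an hour's would-be classification does not depend
on the threshold, so only counts of hours above the threshold change.

The setting search runs in phases: fit every (model, pw, tw, fsf) cell plain;
keep cells clearing TER ≥ 0.9 and TAR ≥ 0.2 on validation in the −8..0
window; of those, keep cells whose validation AUPRC is at least the mean
AUPRC of the kept set (the comparison is `>=`, so a singleton kept set
survives its own mean); then expand survivors over oversampler × calibrator
variants and keep variants still clearing the floors. Hard-voting ensembles
alarm when strictly more than half the members alarm, with even ties alarming
(conservative); soft voting thresholds the unweighted mean calibrated score,
the threshold chosen on validation. AUPRC is computed for raw scorers only —
a hard-voting ensemble has no score.

Misalignment between event-based and conventional metrics follows the
quantile procedure: with `p` the fraction of plain settings meeting the
clinical floors (set C), the discrepancy of metric `m` is the fraction of C
strictly below the empirical `(1 − p)` quantile of `m` over all plain
settings. The quantile uses linear interpolation and ties at the quantile
count as achieving it (so a degenerate all-equal metric yields discrepancy 0);
the convention is ours, since quantile rules are not unique.

## Synthetic cohort generator

Each stay draws a length (36–96 h), personal baselines, and AR(1) noise
(lag-1 coefficient 0.7) per variable. A shock-destined stay (prevalence 0.37)
enters a deterioration ramp of 6–12 h during which MAP falls (~22 mmHg at
effect size 1), heart rate and lactate rise, platelets fall and creatinine
rises, all scaled by `effect_size`; a clinician-response model issues a fluid
bolus at MAP < 70, which aborts the progression with probability 0.2
(treated near-misses with no onset), and otherwise starts a vasopressor when
the pressure reaches shock range, which together with the lactate crossing
realises an onset under exactly the definition the annotator detects. Cleared
episodes recur with probability 0.15. Sepsis-only stays carry mild stable
organ dysfunction (low platelets, raised creatinine) so the cohort has
sepsis-positive, shock-negative controls; a tenth of non-shock stays carry no
infection markers and exercise the exclusion path. Vitals are sampled hourly,
labs every 4 h plus event-driven draws at clinical responses, urine hourly,
GCS 4-hourly; every observation is dropped with the missingness probability
(0.1). Ground truth (onset runs, ramp starts, intervention hours, aborted
flags) is derived from the *emitted* record — replicating the hourly-mean /
forward-fill lactate handling and the interval-overlap rule — so information
lost to sampling is reflected in the truth rather than charged to the
detector. With `effect_size = 0` the ramp vanishes and onsets become abrupt:
events exist but carry no advance signal.

What the generator does not emulate: demographic confounding, inter-variable
physiological coupling beyond the scripted drifts, waveforms, nosocomial
timelines, charting artefacts beyond uniform thinning, or the weak diffuse
lead-time signal of real EHR data. Passing tests on this cohort demonstrate
the *mechanics* of the pipeline (definitions, invariants, recoverability),
not clinical performance.

## Problem sizes and observed behaviour

The test suite and the acceptance script run the pipeline at deliberately
modest sizes — 240-stay cohorts for the end-to-end search (24-cell grid of
{LightGBM, logistic regression} × pw {4,8,12} × tw {0,all} × fsf {0,1}),
1,000 stays for the annotation round trip, 150-stay cohorts over three seeds
for the scheme-trend analysis — chosen so the whole chain re-runs from
scratch in minutes on one CPU while keeping dozens of events per evaluation.

One directional finding from the scheme-trend analysis deserves note. On this
generator, averaged over the grid and a matched absolute threshold ladder,
mean TAR falls as the prediction window widens (0.86 → 0.80 → 0.63 across
pw 4/8/12), as expected: more positive labels raise alarm propensity ahead of
(and away from) onsets. Mean TER, however, does not rise with pw here — it is
essentially saturated (0.99 → 0.96 → 0.96). Two generator properties explain
this: the deterioration ramp is at most 12 h, so wide prediction windows
label pre-ramp hours that carry no signal and dilute the learner; and the
onset hour itself exhibits definitional shock physiology (elevated lactate
with an active vasopressor flag), so even narrow-window models warn nearly
every event within −8..0, leaving no headroom for a rising-TER effect. A
rising TER with pw should be expected only when the lead-time signal is weak
and diffuse relative to the evaluation window, which is the real-EHR regime,
not this generator's.

## Known limitations

- The annotator and generator share the hourly lactate-persistence
  convention; against data with a different lab-carry-forward policy the
  onset timing can shift by up to the inter-draw gap.
- `TER_stay` under all-shocks evaluation and `TER` under first-shock
  evaluation are related but not identical quantities under these
  definitions; both are reported and neither is derived from the other.
- The hard-voting ensemble exposes no continuous score, so score-based
  metrics (AUPRC/AUROC) apply to its members only.
- Deep-learning scorers, sub-hourly resampling and unit conversion are out of
  scope; inputs must arrive in the canonical units of the schema.
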