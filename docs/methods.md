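# Methods

## The prediction problem

Myasthenia gravis fluctuates: weakness can worsen over days into an
exacerbation requiring urgent care. The analysis asks whether signals a
patient already produces at home — per-minute wearable vitals, weekly
spirometry/breath-count self-tests, weekly symptom questionnaires — carry
a recognizable signature in the days before a dated deterioration, and
whether a deliberately simple, auditable model can raise a useful alarm
before onset. Model capacity is kept minimal on purpose: with a cohort
of tens of subjects and a handful of events, anything richer than a
K-parameter linear combiner would mostly fit noise.

## Event definition and daily targets

Three event subtypes anchor the analysis: a ≥ 3-point increase of the
QMG total (ocular items excluded) between two consecutive examinations,
dated at the later one; an MG-related hospitalization; a self-reported
exacerbation whose date is adjudicated upstream and consumed as input.
Same-subject same-day duplicates collapse with priority
hospitalization > qmg > self_report (hospitalization dates are the most
objectively anchored). The daily target is 1 on days
`onset−7 … onset−1` — the window absorbs onset-timing uncertainty and
keeps every positive day strictly pre-onset — and 0 elsewhere,
including the onset day itself. Post-onset days stay in the false-alarm
denominator by default (a configurable blanking window exists but
defaults to 0).

The ocular-item mask is caller-configurable and defaults to the first
two QMG items (ptosis, diplopia), since the instrument's ocular items
are not enumerated in a machine-readable form anywhere in the inputs.

## Preprocessing

Per-minute SpO₂ keeps only minutes with a same-minute pulse sample
(pulse is the more stable channel) and drops every maximal run of ≥ 60
consecutive identical values — a stuck-sensor plateau. The rule is
strict equality at device resolution; a gap in the minute grid breaks a
run, and the 59/60 boundary is pinned by test. Step samples inside
wheelchair or flagged double-counting intervals are removed by interval
union. Vitals aggregate to daily means; step counts to daily sums
(activity accumulates). Weekly instruments are placed on the day grid
(same-day repeats averaged) and linearly interpolated on strictly
interior gaps only — leading/trailing days stay missing, so no
pre-study dynamics are invented. Finally each subject-signal is
z-scored by its own mean and population (n-denominator) SD over the
whole series; a constant series maps to zeros with a warning. Both
conventions (denominator; whole-series vs baseline-only statistics) are
immaterial downstream because the sliding Pearson correlation is
invariant to per-subject positive affine maps — an invariance asserted
to 1e-9 in the tests — but they are fixed and documented so the panel
itself is reproducible.

## Templates and similarity

For each signal, each training event with a complete in-study day range
`onset−T … onset−1` contributes its baseline-subtracted window; the
template is the position-wise mean, ignoring missing positions (an
event window with a missing day still informs the other positions;
dropping whole windows would waste the scarcest resource, events). The
subject baseline is the mean from study start to `min(first_onset − 7,
30) − 1`; with no events, the first 30 days ("one month" is fixed at 30
days). A first onset within 7 days leaves no clean baseline and falls
back to the pre-onset days with a warning.

The similarity at day *t* correlates the trailing *T*-day segment with
the template and maps *R* to (R+1)/2. Days without a complete segment —
the first *T−1* days, or any segment touching a missing value — and
zero-variance segments get the neutral value 0.5 and an invalid flag:
neutral keeps the classifier input rectangular and encodes "no
evidence", while the flags let sensitivity analyses exclude those days.
A zero-variance *template* is rejected outright (correlation against it
is undefined everywhere). Pearson on mismatched supports is ill-defined,
so partially missing segments are not patched; upstream interpolation
makes them rare.

## Classifier

With K similarity series, output(t) = (1/K) Σ wᵢ sᵢ(t) under wᵢ ≥ 0 and
mean(w) = 1 — a convex combination, so the output inherits [0,1] and
reads as a probability. The fit maximizes pooled-SD Cohen's d between
pre-event and other training days, pooling days across subjects (a
per-subject weighting is available but not default). d(w) reduces to
(w·a)/√(w·Cₚw) for the class-mean difference a and pooled scatter Cₚ,
is scale-invariant in w, and costs O(K²) per evaluation after one pass
over the data. Optimization is multi-start SLSQP on the scaled simplex:
starts are the uniform vector, every one-hot corner, eight Dirichlet
draws (seeded) and the ridge-regularized LDA direction; each solution
passes through an exact projection (clip at 0, rescale to mean 1), and
the best candidate is kept, with ties broken toward the smallest
Euclidean norm for determinism. The corner and uniform starts make the
returned objective provably ≥ both references; a 10⁻³ line-search
oracle pins K = 2 accuracy. A zero pooled SD is floored at 10⁻¹².
Neutral-filled (invalid) similarity days are included in training by
default, matching the input distribution at deployment.

## Evaluation

LOSO-CV: for each held-out subject, baselines, templates and weights
derive from the other subjects only; held-out similarities are computed
against the training templates. A fold whose training set has no usable
event is skipped and recorded. Pooled held-out outputs feed the
event-level ROC: thresholds sweep the observed output values (plus a
sentinel above the maximum), false alarms pool label-0 days across
subjects (7 × flagged fraction per week), and an event is detected if
any day strictly inside its pre-onset window is flagged. The area is
the trapezoid over the full [0,7] false-alarm support, anchored at both
ends by the sentinel and the all-positive threshold; an oracle scoring
the true labels attains exactly 7. Operating-point sensitivities are
read off the curve by linear interpolation (ties at equal rates resolve
to the best sensitivity attained there).

The null predictor draws independent daily Bernoulli alarms with the
training positive-day proportion, under the same folding; its AUROC is
averaged over 100 draws (the number of draws is a free choice; the
spread is reported alongside the mean). Confidence intervals for AUROC,
sensitivities and signal importances are subject-level (or fold-level,
for importances) percentile bootstraps with B = 1000. The
assessment-interval experiment thins one signal to every k-th day,
re-interpolates, and re-runs the univariate evaluation.

## Synthetic cohorts

The generator emulates the study conditions: 30 subjects followed 84
days; SpO₂/pulse at 1/min, steps continuously (per-minute Poisson
counts), PPMs/PROMs weekly; per-subject event counts Poisson(0.8)
truncated at 3 with ≥ 14-day spacing and onsets from day 15 (so the
first event leaves a clean baseline and a full pre-onset window); about
half of subjects deteriorate at the default rate. Each subject-signal
follows a latent daily mean = subject baseline (drawn from population
mean/SD, making the z-transform nontrivial) + day-to-day noise + the
planted effect; cadence sampling happens afterwards, so weekly
instruments undersample the same dynamics — deliberately mirroring how
weekly questionnaires miss fast pre-onset changes. Planted profile
shapes follow the observed pre-deterioration averages: SpO₂ falls to a
minimum in the last 1–2 days, pulse and steps rise (~3 and ~2 days out)
then drop, FVC declines steadily across the whole 10-day span, SBCT
bottoms ~2 days out, MG-ADL/MG-QoL15r peak ~3 days out and stay high,
SSQ bottoms ~3 days out; all profiles vanish earlier than 10 days
before onset. Effect magnitudes are free parameters (no printed scale
exists to copy); the default peak is 1 baseline-SD and the recovery
experiments use 2. Profiles scale by the between-subject baseline SD,
and default day-noise SDs are at most the baseline SDs, so "a 2-SD
effect" is comparable across signals. QMG examinations are planted so
the consecutive-pair rule recovers exactly the intended qmg-subtype
events. Artifact injection (stuck-SpO₂ plateaus, pulse dropout leaving
unpaired SpO₂ minutes, flagged whole-day step inflations) is logged as
ground truth; rates are expected counts per subject-study.

What the generator does *not* model: circadian structure, autocorrelated
day-to-day noise, informative missingness, therapy changes, or any
demographic structure. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own assumptions — not
clinical performance on real cohorts, whose headline numbers are not
reproducible without the (undeposited) patient data.

## Problem sizes and numerical choices

The recovery and downsampling studies (100 and 50 seeds of the full
LOSO pipeline at 30 subjects × 84 days) generate wearables at daily
cadence: the planted effect lives on the latent daily mean, so daily
sampling is statistically equivalent for this daily-resolution analysis
while keeping the full studies to a few minutes on one CPU; the
per-minute path and its filters are exercised separately on smaller
cohorts. Key tolerances: feasibility 1e-9; sliding-correlation vs naive
oracle 1e-10; affine invariance 1e-9; SLSQP ftol 1e-12 with projection;
correlation values clipped to [−1, 1] against rounding. All randomness
flows from explicit seeds through fixed SeedSequence splitting, so
cohorts, fits and bootstraps are reproducible bit-for-bit.

## Known limitations

Templates are averaged across subjects, not personalized; events closer
than T days to study start cannot contribute windows; the linear
classifier cannot express signal interactions; the custom AUROC has no
standard probabilistic interpretation (it is an area under a
rate-vs-sensitivity curve, not a concordance probability); and with
pooled false-alarm days, subjects with more wear time weigh more in the
false-alarm rate. These mirror the method's intended simplicity rather
than implementation constraints.
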