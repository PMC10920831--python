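# Methods

`feedscope` analyses neural population recordings made while an animal
forages: miniscope calcium traces or fiber-photometry signals from a
GABAergic midbrain population, together with markerless pose tracking and
scored behavior epochs, during assays in which the animal approaches and
eats a food source. This note describes the models and procedures the
package implements, the choices made where the underlying analysis design
left them open, and what the synthetic-data generator does and does not
emulate.

## Behavioral classification from pose

Speed is a central-difference displacement over the frame interval,
optionally boxcar-smoothed (default 0.2 s); edge samples take the nearest
interior estimate.

**Approach** epochs are maximal intervals during which the head moves
continuously toward the food target: sample-to-sample distance to the
target is non-increasing up to a jitter tolerance, speed stays at or above
`min_speed` (default 2 cm/s) at every sample, and the total decrease in
distance over the interval is at least `min_decrease` (default 10 cm).
"Continuous movement toward the target" is not well-defined at the sample
level for noisy tracker output, so a per-step backtrack allowance of 0.5 cm
is applied; without it, sub-millimetre tracking jitter fragments every run
into useless slivers. Head position defaults to the midpoint of the two ear
coordinates (the nose is a configurable alternative), and the velocity
criterion is evaluated on the head; both choices are exposed because either
convention is defensible.

**Rearing** is a geometric threshold: in a circular arena, head distance
from the centre above `radius − wall_margin` (margin default 2 cm, an
artifact choice — only "a minimum distance" is implied by the assay); in a
rectangular arena, a vertical-coordinate threshold. Contiguous
supra-threshold runs merge into epochs.

**Eating** cannot be recovered from pose coordinates (it is scored
manually in real experiments), so eat epochs are always ingested from
epoch tables; the synthetic generator supplies them with the session.

Epoch intervals are half-open `[start, end)`, time is zero-based seconds,
and rasterization onto any time base resolves overlaps with the fixed
priority eat > approach > rear so ties are deterministic.

## Trace preprocessing and event-locked quantification

Cells enter the analysis only if their variance is at least 10% of the
maximum variance among non-outlier cells. The outlier rule is not part of
the source convention and is defined here as variance above Q3 + 1.5·IQR
across cells, applied in two passes (flag outliers, then take the maximum
among the rest) so one extreme cell cannot silently discard the population.

Peri-event tensors hold trace segments `[t − pre, t + post)` on the trace
grid; events whose windows would be truncated by the session edges are
dropped and counted. Eating modulation is the per-cell mean over events of
(mean activity in the 5 s after onset − mean activity in the 5 s before).
The 5-s windows are a package default chosen to match the multi-second
pre-eating activation the recordings show; they are configurable.

Mean peak amplitude averages strict local maxima (both neighbours
smaller); plateaus count once at their first sample; a trace with no
maxima reports 0 with a flag.

## Isosbestic photometry correction

The 405-nm reference channel is calcium-independent, so motion and
bleaching artifacts appear in it exactly as they contaminate the 470-nm
signal. The correction fits `sig470 ~ a + b·ref405` by ordinary least
squares over the whole session (a robust fit is available behind a flag)
and returns `(sig470 − fit)/fit`, a df/F-scale series with mean ≈ 0. Any
artifact that is an affine function of the reference is removed exactly; a
constant reference carries no information and triggers a fallback to
baseline-percentile df/F (10th percentile) with a warning.

## Population geometry

Samples (time points) are points in cell space. For embeddings, traces are
z-scored per cell by default (raw optional), PCA is fit on all session
samples, behavior-labeled samples are retained, and the top three
components are kept. Component signs follow the convention that the
largest-magnitude loading is positive.

The silhouette uses Euclidean distances with
`s(i) = (b(i) − a(i))/max(a(i), b(i))`; singleton clusters contribute 0 by
convention. Chance is a label-permutation null (a circular-shift variant
is available behind a flag); the observed score's percentile within the
null is reported.

Cross-assay conservation concatenates co-registered cells' activity from
the two assays and, for each behavior, measures Mahalanobis distances of
one assay's samples against the other assay's cluster
(`d_M(y) = sqrt((y − μ)ᵀ Σ⁻¹ (y − μ))`, sample mean and covariance of the
reference cluster). Because the direction of the measurement is not fixed
by the design, both directions are computed and pooled. Distances default
to the full n-dimensional co-registered space with a PC-space option. A
singular covariance is ridge-regularized (`Σ + λI`, `λ = 1e-6 × mean
diagonal`) with a warning. Note the package returns the distance, not the
squared distance some toolboxes report; every downstream comparison is
rank-based, so the monotone transform changes nothing. Per-behavior
distances are compared with a two-tailed rank-sum test, plus Euclidean
distances of pooled samples to their cluster centre as a second view of
the same contrast.

## Decoding and cell classification

Matched-sample decoding takes all trace samples in the 2 s after each
onset of the target behavior as positives and an equal number of samples
drawn uniformly (without replacement) from outside that behavior's epochs
as negatives, so chance is 50%. "Samples following onset by 2 s" is read
as the whole `(onset, onset + 2 s]` window; the single-sample reading is
available behind a flag. Sessions with fewer than five epochs of the
behavior are excluded. Cross-validation uses five contiguous-in-time
folds; training rows within 10 s of the validation block are dropped, so
temporally autocorrelated activity cannot leak across the split. The
classifier is softmax (multinomial logistic) regression with only a small
ridge penalty; features are z-scored per cell by default.

Cell classification fits, per cell, a Gaussian identity-link GLM of the
trace on a 0/1 behavior indicator. The family is a deliberate choice: with
a binary indicator the behavior coefficient equals the in-behavior minus
out-of-behavior mean df/F, which keeps the bootstrap interpretable (other
links can be plugged in). The null redraws epoch start times uniformly 100
times — durations preserved, non-overlap and session bounds enforced, one
shuffled schedule per iteration shared by all cells — and rebuilds the
coefficient. A cell is "+" if its coefficient exceeds at least 95% of the
null values, "−" if at least 95% exceed it, otherwise "ns"; exact ties
count against significance. With 100 shuffles the per-tail granularity
makes the realized false-positive rate slightly above the nominal 5%,
which is why the calibration bound is 8% per tail.

Cross-assay similarity of encoding is quantified by Spearman correlation
of per-cell GLM weights over co-registered pairs and by Pearson
correlation of concatenated event-averaged peri-onset profiles; two
profile correlations are compared by the Fisher r-to-z transform,
`z = (atanh r₁ − atanh r₂)/sqrt(1/(n₁−3) + 1/(n₂−3))`.

## Statistics and the report

Comparisons default to two-tailed Wilcoxon signed-rank / rank-sum tests
(exact rank distributions at n ≤ 25 per group, normal approximation
above); one-sample t-tests are used against stated constants such as the
50% chance level. p-values are adjusted within declared families by the
Benjamini–Hochberg step-up ("the" FDR method here, since only the family
of procedures is fixed by convention); the report declares its families
explicitly: `conservation` (cross-assay distance comparisons), `decoding`
(fold accuracies vs 50%), `correlations` (cross-assay weight and profile
correlations).

`run_pipeline` chains generator → behavior → traces → geometry → decoding
→ classification → correlations, derives every stage seed from the single
config seed, and writes `results.json` (byte-stable under a fixed
config), a per-cell class table, a four-panel summary figure, and a log
with seeds and version.

## The synthetic generator

The generator is the package's test bed: it emulates all five input kinds
with planted ground truth.

Behavior follows repeating foraging cycles: wander to a start point 15 cm
from the food target (at 1.5 cm/s, below the approach speed criterion),
run straight to the target at 3 cm/s (approach, 5 s), eat at the target
(8 s), wander to the wall, rear (3 s). Pose is sampled at 30 frames/s,
with 0.01-cm Gaussian tracker jitter; nose, ears and tailbase are rigid
offsets from the head so the ear midpoint reproduces the planted head
path exactly. This realizes the 10-cm / 2-cm/s rule by construction, and
the approach detector recovers ≥ 90% of planted epochs.

Activity is a Poisson event train at `base_rate` (0.4 events/s) times a
per-cell per-behavior multiplier, convolved with a double-exponential
indicator kernel (rise 0.2 s, decay 1.5 s — a slow GCaMP6s-like
time-scale; the source analyses never model trace generation, so any slow
kernel serves) and sampled at 7.5 samples/s (30 frames/s video
temporally downsampled by four), plus i.i.d. Gaussian df/F noise
(sd 0.05). Cell types: 30% eat− (eat multiplier 0.2), 10% eat+
(multiplier 3), 20% approach+ (multiplier 3), 40% unmodulated (all
multipliers exactly 1); modulated multipliers carry lognormal jitter
(σ = 0.25) so cross-session weight correlations are non-degenerate. The
eat−-heavy composition mirrors the recorded population, in which eating
suppresses more cells than it recruits.

Assay pairs share per-cell multipliers for the labels in `overlap`
(default analyses use `{eat}`: a conserved eating ensemble with
assay-specific approach encoding) and redraw the rest; the
co-registration map pairs each cell with itself with a configurable
dropout.

Photometry: both channels carry a shared smoothed-Gaussian artifact
(timescale 2 s, amplitude 0.1 a.u.) plus channel noise; the 470-nm
channel adds behavior-locked transients (amplitude 0.5 a.u.) from the
same indicator kernel.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: spatial footprints and
source-extraction cross-talk, non-Poisson firing (bursting,
refractoriness), slow drift and bleaching in the traces, pose-tracking
identity swaps and dropouts beyond Gaussian jitter, behavior that does
not follow the scripted cycle, and co-registration errors other than
random pair dropout.

## Numerical choices and problem sizes

Default test and demonstration runs use 20–50 cells and 5–30-minute
sessions; calibration suites use 50–100 replicate seeds. These sizes give
stable statistics for every check while keeping the whole suite fast.
Tolerances: oracle equivalences at 1e-9–1e-12; the GLM closed form at
1e-10; calibration bands as stated per check (decoder chance ±3
percentage points, silhouette chance ±0.02, classifier tails ≤ 8%).

## Known limitations

The cross-assay conservation comparison follows the time-point-level
design of the source analyses: every trace sample is treated as an
independent observation in the rank-sum test. Calcium samples are
strongly autocorrelated (the indicator kernel spans ~11 samples at
7.5 samples/s) and behaviors differ in epoch count and duration, so this
test is anti-conservative — under a no-modulation configuration it
reliably reports a difference driven purely by sampling structure. The
package keeps the comparison faithful to that design and reports it with
its direction flag; treat its p-values as descriptive rather than
calibrated, and rely on the planted-truth recovery suites (which compare
against matched synthetic nulls) for calibrated statements. The decoding
and correlation families do not share this defect and hold their nominal
levels under the global null.

The bootstrap onset randomization preserves epoch durations and count but
not inter-epoch dependence (e.g., eating always following approach), so
its null is slightly broader than a behavior-structure-preserving null
would be.
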