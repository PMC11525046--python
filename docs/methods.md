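# Methods

This note documents the models, estimators, numerical choices and known
limitations of `rdlg`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

All times are seconds on one session clock; intervals are half-open
`[start, end)`; sample `i` of a signal occurs at `t0 + i/rate`.  Half-open
intervals make event sets closed under concatenation and make restriction
idempotent.  Events, states and OFF periods live in `IntervalSet`s that are
sorted and non-overlapping within one kind after merging.

## Sleep scoring

`EMG_z` is the 20–150 Hz Butterworth band-pass of the EMG, rectified,
smoothed with a 50-ms-SD Gaussian and z-scored over the session.  Wake is
`EMG_z ≥ 0.5` (the wake threshold is configurable; 0.5 SD separates the
generator's wake bursts by a wide margin).  The theta/delta ratio is the
6–10 Hz over 1–4 Hz Welch band power in 256-sample windows; the LFP is
first decimated to 125 Hz because at 1250 Hz a 256-sample window spans
0.2 s and cannot resolve 1–4 Hz from 6–10 Hz at all — decimation keeps the
"power in 256 samples" semantics while giving 0.5 Hz resolution.  Among
immobility, NREM is ratio < 2 and REM is ratio ≥ 2.  Before applying the
30-s minimum-stage rule, state flickers shorter than 5 s are absorbed into
the longer neighbouring stage (otherwise a 2-s blip fragments a long stage
into sub-minimum pieces that all become "other"); stages shorter than 30 s
become "other", and 5 s of "other" pads each boundary between differing
stages.  The hypnogram tiles the session exactly.

`state_rate_ratio` implements (FR_a − FR_b)/(FR_a + FR_b); both rates zero
is undefined and returns NaN.

## Event detection

Ripples and spindles are detected on the *normalized squared envelope*: the
band-passed signal is squared, Gaussian-smoothed and z-scored.  The
smoothing SD is 10 ms for the 140–250 Hz band and 25 ms for 10–20 Hz — the
squared 13-Hz spindle carrier leaves a 26-Hz ripple that 10-ms smoothing
does not remove, which would split supra-threshold runs.  Ripples: runs
above 1 SD, gaps < 20 ms merged first, duration 15–200 ms, peak > 4 SD.
Spindles: runs above 2.5 SD, gaps < 400 ms merged, duration > 500 ms and
≤ 3 s, peak > 5 SD.  Sharp waves use the absolute z-excursion of the 5–40 Hz
channel-average (polarity depends on referencing), > 2.5 SD for 20–400 ms.
Delta waves: on the low-passed (0–4 Hz) z-scored cortical LFP `D(t)`,
candidates are positive local maxima; onset is the preceding upward zero
crossing and end the following trough; events must last 150–450 ms and
satisfy `D(peak) > 2 ∧ D(end) ≤ 0` or `D(peak) > 1 ∧ D(end) < −1.5`.
SWRs are ripples that overlap a sharp wave with the ripple peak inside the
valid states (NREM in sleep, immobility in the task); SWR onset and peak are
the ripple's.  A cortical (delta/spindle) event pairs with its nearest
preceding SWR when its peak follows the ripple peak by 0–250 ms; each
cortical event is used once.  SWR size classes partition retained events at
envelope peaks of 4, 6 and 10 SD.  OFF periods are maximal gaps > 100 ms in
the pooled spikes of ≥ 5 RSC units, merged when separated by < 5 ms; the
implementation is exact to spike resolution and is checked against a
literal oracle.

## Synthetic recordings

The generator is the package's test bed and defines the study conditions.

**LFP.**  1/f background (spectral shaping of white noise, α = 1, 0.5-Hz
floor), plus state-dependent oscillations: 8-Hz theta in REM (and weaker in
wake) and a bounded 2-Hz slow component in NREM.  Two deliberate departures
from plain Gaussian noise make SD-unit thresholds behave the way they do on
real recordings: (a) the 140–250 Hz background envelope is flattened to
constant-envelope phase noise — in real CA1 that band's floor is dense
multiunit activity with a stable envelope, whereas sparse inserted events
over a Gaussian band background would leave z-scored tails that cross a
4-SD rule dozens of times per 10 minutes, making precision ≥ 0.9
unattainable for *any* detector; (b) the cortical 10–20 Hz Gaussian
background is attenuated to 15% so spindles dominate their own band (beats
between a spindle and an equal-power band floor otherwise split the
supra-threshold run).

**Events.**  Ripples are Gaussian-windowed 180-Hz bursts (55–100 ms) with a
simultaneous half-cosine sharp-wave deflection; delta waves are triphasic
(leading dip, main peak, after-trough — the dip pins the onset zero
crossing, the trough carries the amplitude clauses); spindles are 13-Hz
carriers under a plateau envelope with soft 50-ms edges and a mild central
crest (waxing–waning), so the sustain and peak rules see the intended
durations.  Amplitudes are requested in detection-SD units and calibrated
*per event* against the detectors' own normalized transforms by a short
fixed-point iteration (4 passes), because inserted events contribute to the
very normalization that defines their amplitude.  Default peaks: ripples
6–12 SD, sharp waves 6–9 SD, delta 5–6.5 SD, spindles ≈ 6 SD with the
plateau at ≈ 0.72 of peak power.  Spindle amplitudes obey a feasibility
budget: with duty fraction f of a z-scored band spent inside events, the
mean event z cannot exceed 1/√f; the defaults sit well inside it.

**Spikes.**  Inhomogeneous Poisson on a 1-ms grid:
rate = baseline × state factor × peri-SWR kernel × reactivation factor ×
coupling factor, with per-event lognormal kernel-gain jitter (the
event-to-event variability that the GLM stage exploits).  Coupling
("RSC→CA1") multiplies the target rate by the mean-normalized, 20-ms
smoothed, lag-shifted *realized* source spike rate, so the dependency in
the data is causal.  Template reactivation multiplies rates by
`1 + w_i · a_k · g(t − t_k)` at SWR k (Gaussian g, SD 40 ms), with weights
`w ∈ {±1}` balanced per region so that nonspecific co-excitation at SWRs
does not masquerade as template reactivation.  With all modulations off,
1-s spike counts have Fano factors within [0.8, 1.2] (tested).

**Task.**  A figure-8 maze with a 30 × 6 cm stem, alternating L/R trials
(5% errors), 25-Hz position frames, smoothly varying run speed
(16–24 cm/s), pauses at delay and reward.  Units carry 2-D Gaussian place
fields with trial-type gains (splitters), pure fields (location cells),
`rate = a + b·speed` tuning (speed cells), or none; a shared 100-ms-block
latent during run epochs expresses the co-firing template.

**Waveforms.**  Two families by trough-to-peak duration (wide 0.6–0.8 ms,
narrow 0.2–0.4 ms) with per-unit idiosyncratic shape parameters (trough
width, peak and pre-peak amplitudes — real units are individually
recognizable, and without this any same-family units would be clones),
replicated across phases with amplitude drift and additive noise quoted as
a fraction of peak-to-trough amplitude, on 8 channels.

What the generator does *not* emulate: electrode drift physics, spike
sorting errors, non-Poisson bursting, theta phase precession, behavioral
variability beyond speed noise, and volume conduction.  Passing tests
therefore show the *analysis chain* is correct and calibrated under the
stated statistical structure, not that it is robust to every pathology of
real recordings.

## Peri-SWR statistics

PSTHs use 1-ms bins over ±1 s around SWR onset, z-scored to the
−1 … −0.5 s baseline and smoothed with a 20-ms Gaussian; sessions need ≥ 50
SWRs separated by ≥ 300 ms (greedy earliest-first selection).  The
modulation score is the summed squared deviation of the (smoothed) PSTH
from the mean shuffled PSTH inside ±200 ms (RSC) or 0–100 ms (CA1); p is
the +1-corrected fraction of shuffle scores at or above the real score.

Two design points in the shuffle differ from a naive reading of the
procedure, both forced by calibration/power analysis:

1. *Per-event* circular shifts instead of one whole-train shift per
   shuffle.  A whole-train shift moves a genuine peri-SWR response to a
   different lag but keeps it aligned across events, so the shuffled PSTHs
   contain bumps as sharp as the real one and the test has essentially no
   power against exactly the alternative it exists to detect (verified
   empirically).  Independent per-window shifts destroy alignment while
   preserving each window's spike count.
2. Full-circle rotations (shift up to the window half-width) rather than
   ±0.5 s.  Restricted rotations on the ±1 s circle are not
   measure-preserving for the joint null and make the test conservative
   (measured type-I ≈ 1.8% at nominal 5%); full-circle rotation gives exact
   exchangeability under a homogeneous train (measured ≈ 4–5%).

The power condition used in validation is a 6-Hz unit with a 2× Gaussian
rate bump (SD 60 ms) at −60 ms — the broad pre-SWR modulation cortical
units show — with 55 SWRs.

Size-stratified activity uses a one-way ANOVA across SWR size classes of
the per-event population rate in configurable windows (−100–0, 0–50,
200–300 ms).  OFF-period timing reports onset/offset probability per lag
bin around SWR onsets and compares durations of OFF periods starting
within 400 ms after a SWR against the rest (two-sided rank-sum).

## Reactivation

Pairwise CA1–RSC correlations are Pearson r on 50-ms counts per phase;
task-run significance classes come from 100 circular-shift surrogates of
the CA1 counts (two-sided 5%).  The template is
`C = Z_CA1(run)ᵀ Z_RSC(run) / n_bins` on 100-ms z-scored counts (the
cell-pair correlation matrix; ensembles need ≥ 4 cells per region, silent
cells are excluded first).  Sleep counts are z-scored with NREM statistics;
`R(t) = z_CA1(t) C z_RSC(t)ᵀ` is z-scored over the epoch.  Peri-SWR
reactivation averages R in ±1 s windows around SWR onsets; the null redraws
the same number of onsets uniformly 100 times; significance is a one-sided
signed-rank of per-event lag-0 R against the shuffle-mean lag-0 value (a
degenerate shuffle equal to the real onsets yields p = 0.5 by convention).

## GLM direction analysis

Predictors are ensemble spike counts (≥ 5 cells) in a 100-ms window
relative to SWR onset; the target is one cell's count in 0–100 ms; cells
must spike in > 50 SWRs.  Poisson GLM with log link (small ridge penalty
for numerical stability; degenerate folds refit with a stronger penalty and
flagged), 5-fold CV with random equal-size folds.  Error is the mean
absolute difference between predicted and actual counts; baseline error
permutes the actual test-fold counts (100 times); gain = mean baseline
error / mean real error, with gain ≡ 1 when both errors are 0 (all-silent
fold).  Control gains re-run the identical pipeline on whole-set
permutations that pair one SWR's predictors with another's target.
Significance per window/direction: two-sided rank-sum of real vs control
gains across predicted cells.  The binomial variant predicts 0/1 SWR
occupancy of 100-ms bins with a logistic GLM and class-stratified folds.

The validation condition couples CA1 to the RSC ensemble at a 50-ms lag
(RSC leading), with the RSC peri-SWR kernel at −50 ms (SD 20 ms, 3× gain,
lognormal event-gain jitter σ = 0.6): the kernel is kept narrow so that the
−200…−100 ms window carries essentially no event-gain information and the
window-specificity of the method is actually testable.

## Cell typing and tracking

RSC units: waveforms normalized by peak-to-trough amplitude on the
−0.2…+0.8 ms window, PCA (SVD) to 3 components, Ward/Euclidean hierarchical
clustering cut at 3 clusters, clusters mapped to wide/narrow by mean
trough-to-peak with the middle cluster joining the nearer centroid
(flagged).  CA1 units: narrow interneuron at trough-to-peak ≤ 0.425 ms;
pyramidal at > 0.425 ms with ACG `tau_rise` ≤ 6 ms; otherwise unclassified.
`tau_rise` comes from a bounded least-squares fit of
`a·exp(−x/τ_d) − b·exp(−x/τ_r) + c·exp(−x/τ_b) + d` to the 0.5-ms/±50-ms
autocorrelogram; flat ACGs fail the rise-amplitude floor and return NaN.

Matching compares same-channel candidates with three local similarities
`max(0, 1 − |pre−post|/pre)` (trough-to-peak duration, trough-to-peak
amplitude, pre-peak-to-trough amplitude) and three global ones after DTW
alignment (in-package dynamic programming with a 20% Sakoe–Chiba band;
unconstrained DTW lets dissimilar shapes align too well): 1 − max pointwise
distance of the warped normalized waveforms, their Pearson correlation, and
the warping scale factor len(original)/len(warped).  Waveforms get a
3-point smoothing before comparison (mean waveforms are smooth at the
sample scale).  Score = (1/5)‖local‖₂ + (4/5)‖global‖₂.  A pre unit's best
candidate is auto-accepted if correlation ≥ 0.95 and duration similarity
≥ 0.7 *and* the runner-up trails by ≥ 0.02 — score-margin ambiguities are
exported with a review flag instead of auto-accepted, replacing the manual
curation step of the original workflow.  Post units claimed twice keep the
larger score.  Three-phase tracking intersects pre/post and task/post
acceptances on the post unit.

## Spatial coding

Rate maps: 0.36-cm bins (as published; unusually fine for the maze, kept
configurable), speed filter 3 cm/s, > 200 spikes required, spike and
occupancy maps smoothed with a 5 × 5 Gaussian kernel before division, and
an occupancy floor of 50 ms per bin (rates in barely-visited bins of a
thin track are unstable).  Place fields are connected components of bins
≥ 2× the mean rate with ≥ 40 bins and a bounding box ≤ 7 × 7 bins.  Stem
analysis: firing rate per correct trial in three 10-cm subareas; two-way
ANOVA (subarea × trial type, α = 0.05): splitter = trial-type main effect
or interaction; location-related = subarea effect only.  Under the null the
splitter rule fires at the compound rate 1 − 0.95² ≈ 0.0975.

Speed score: |Pearson r| between the 250-ms-smoothed per-frame firing rate
and running speed over frames at 5–35 cm/s (the published verbal definition
— correlating a function of speed with speed — is circular; the
instantaneous-rate correlation is the form used across the speed-cell
literature, and the binned tuning curve is reported descriptively).  The
p-value uses an autocorrelation-corrected effective sample size (both
series are serially dependent; the naive n would make the t-test vacuous).
A unit is a speed cell if the score exceeds the 99th percentile of 100
circular shifts of the rate along the trajectory *and* p < 0.01.  Shifts
are drawn between 10 s and session length − 10 s: the score decorrelates
over only ~1 s of shift, so shifts confined to a 10–30 s band would give
~20 effective null draws and inflate the percentile rule's false-positive
rate several-fold.  Speed cells are removed from the stem-cell labels.

## Pipeline

`rdlg run` simulates (or reads) a pre-sleep / task / post-sleep recording,
then executes scoring → detection → typing/tracking → PSTH/modulation →
reactivation → GLM → spatial → pre/post contrasts, writing TSV/JSON outputs
stamped with the config hash and seed.  All floats are written at fixed
precision and all randomness flows from the seed, so reruns are
byte-identical.  The default end-to-end run uses reduced shuffle counts
(20–200 instead of 100–1000) and 400-s sleep phases; the stage-level
functions default to the published counts.  Pre/post contrasts report SWR,
SWR–delta and SWR–spindle incidence per NREM minute and OFF-duration
summaries; with a single session pair the paired signed-rank test is marked
underpowered rather than computed.

## Validation problem sizes

The validation suite (`rdlg.validation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses: one
10-minute session with 60 ripples/sharp waves, 80 delta waves and 30
spindles for detector fidelity; 1,000 random rasters for the OFF oracle;
20 seeds × 400 s for sleep scoring; 400 Poisson units at 200 shuffles
(type I) and 60 bump units (power) for the modulation test; 50 + 50 seeds
of 300-s sleep for reactivation; 30 seeds × 450 s, 7 target cells, 25
control shuffles × 25 baseline permutations per cell for the GLM; 50 seeds
of 18 units for tracking; 50 seeds of 40 units for cell typing; 100 task
seeds for the spatial classifiers.  These sizes were chosen so the whole
suite runs on one CPU in well under an hour while keeping Monte-Carlo
error small relative to every asserted margin.

## Known limitations

* The detectors assume the config-named channels; channel selection by
  ripple power across a probe is not implemented.
* The delta-wave candidate segmentation (zero crossing → peak → trough) is
  one of several possible readings of onset/peak/end extraction.
* The GLM uses raw predictor counts with an intercept; no spline bases or
  regularization paths.
* Reactivation implements only the template-matching form — no PCA/ICA
  assembly extraction, no explained-variance statistics.
* Manual curation of unit matches is replaced by review flags plus the
  exported similarity audit table; borderline matches require a human.
* The 0.36-cm rate-map bin size is kept as published; place-field bounding
  box limits at that resolution admit only very compact fields, so
  location-related cells are identified by the stem ANOVA rather than by
  field detection.
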