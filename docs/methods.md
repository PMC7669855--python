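# Methods

This note documents the models, parameter defaults and numerical choices
behind `caneeg`, and what the synthetic-data tests do and do not establish
about real recordings.

## The analysis problem

Eight dogs viewed pictures from eight stimulus categories — dog and human
faces in aggressive, neutral and happy expressions (AD, ND, HD, AH, NH,
HH), household objects (OB) and phase-scrambled faces (S) — while
7-channel EEG (F3, F4, T3, T4, Cz, P3, P4) was sampled at 512 Hz. The
package answers two questions about such data: *whether* and *when* the
single-trial EEG carries category information (decoding with permutation
inference), and which channels/latencies show species and expression
effects in the averaged evoked responses (sliding-window ANOVA), plus
*where* the dominant evoked response is generated (dipole modelling).

## Epochs and preprocessing

Epochs are `trials × channels × samples` tensors in μV on a millisecond
time axis relative to stimulus onset; the sample count of a span is
`ceil(span·fs/1000)` so the requested span is fully covered (at 512 Hz the
860-ms decoding span gives 441 samples and therefore 43 complete 20-ms
bins, i.e. 301 = 7 × 43 whole-epoch features; truncating instead of
rounding up would lose the 43rd bin).

- **Filtering.** The band-pass (2–40 Hz for the ERP stream, 2–25 Hz for
  decoding and source modelling) is a 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`), with odd-reflection padding of three
  time constants of the high-pass edge, capped at the epoch length. The
  design is verified against frequency-response oracles (DC rejection,
  pass-band gain within 5%, ≥ 20 dB stop-band loss) rather than assumed.
- **Trigger-leak removal.** Per trial and channel, the least-squares
  projection onto `[intercept, leak template]` is subtracted; the residual
  is orthogonal to the regressor by construction.
- **Artifact rejection** flags (never drops) trials whose absolute
  deviation from their own within-window mean exceeds the threshold
  (100 μV in −150…350 ms for the ERP stream; 50 μV for the source
  stream) on any channel. Deviation-from-mean was chosen over raw
  amplitude because it is invariant to DC offsets on filtered data; the
  decoding stream deliberately keeps all trials.
- **Baseline correction** subtracts the −150…0 ms mean per trace
  (idempotent by construction).
- **Binning** is defined on the time axis, not on sample counts: 20 ms at
  512 Hz is 10.24 samples, so half-open 20-ms bins contain 10 or 11
  samples; a trailing partial bin is dropped.

## Sliding-window repeated-measures ANOVA

Per channel and 16-ms window (4-ms steps over 0–250 ms → 59 windows), the
per-subject window-mean amplitudes of the six face conditions enter a
two-way fully within-subject ANOVA (species 2 × expression 3); the error
term of each effect is its interaction with subjects. The sums of squares
are computed in closed form and vectorized over channels, windows and
simulated replicates; the arithmetic is cross-checked against a
general-purpose repeated-measures ANOVA implementation in the tests. No
sphericity correction is applied by default; Greenhouse–Geisser is
available behind a flag (epsilon from the subject-level covariance of the
orthonormalized effect contrasts, clipped to `[1/df, 1]`; note that the
correction only moves p-values upward where it matters, i.e. in the
rejection region — for F below its null mean a smaller-df F distribution
can lower p slightly). Per-window p-values are uncorrected; only runs of
at least two step-adjacent significant windows are reported, merged to
`[first start, last end)` intervals with the p-range and run-averaged
condition means. Planned contrasts are two-sided paired-samples t tests on
n−1 df, with the zero-variance case resolved to `t = 0, p = 1` when the
differences vanish.

## Decoding and permutation inference

One linear-kernel C-SVM (C = 1, configurable; an L1-regularized logistic
regression is available behind the same interface) per unordered category
pair, evaluated with seeded, stratified 10-fold cross-validation; feature
standardization statistics come from the training folds only. Accuracy is
the unweighted mean of fold accuracies. Time-resolved decoding fits one
classifier per 20-ms bin (7 features) reusing a single fold assignment
across bins so temporal profiles are not fold-resampling noise. For
throughput the cross-validation core calls scikit-learn's low-level libsvm
binding directly (same optimizer as `SVC(kernel="linear")`; the test suite
asserts fold-by-fold prediction equivalence), which makes the
permutation studies below roughly 5× faster.

Null distributions shuffle the labels of the whole dataset once per
permutation before the CV loop (200 permutations by default), re-drawing
the stratified folds from the permuted labels. Alignment is what makes the
maximum statistic valid: permutation index *r* means the same relabelling
for every classifier of a subject — interval classifiers of one task
literally share the permuted label vector, and distinct tasks draw from
per-index seed substreams. The family threshold is the *m*-th largest of
the per-index maxima with `m = floor(alpha_eff · (n_perm + 1))` and
significance strictly above it, which bounds the family-wise error at
`m/(n_perm+1) ≤ alpha_eff` under exchangeability; `alpha_eff = alpha /
n_subjects` implements the Bonferroni correction across subjects. When
`alpha_eff` falls below the permutation resolution (`m < 1`, e.g. α/8 with
only 100 permutations) the largest null maximum is used — a
resolution-limited, conservative-in-practice fallback (ties at discrete
accuracies also push the procedure conservative). The pooled null
accuracies provide the empirical chance interval (central 95% by default);
pooling across a subject's classifiers is one defined choice among several
the phrase "empirical chance level" admits.

Aggregation reports `100 · significant cells / total cells` per interval
(out of 56 = 8 subjects × 7 scrambled-vs-other tasks) and per task
division (species, expression, combined — each with object-vs-scrambled
as the reference group), with exact additive decomposition over disjoint
groups.

## Three-shell sphere forward model and dipole fitting

The forward model is the analytic series solution for a current dipole in
concentric conducting spheres (brain/skull/scalp radii 35/39/45 mm by
default, conductivities 0.3/0.006/0.3 S/m). For each Legendre order the
radial two-point boundary-value system (continuity of potential and radial
current at the interfaces; zero current at the scalp) is solved with radii
normalized to the scalp radius; only the right-hand side depends on dipole
eccentricity, so the per-order surface factors are computed once per model
and the lead field for thousands of candidate locations is a single
vectorized recurrence over orders (60 by default; the eccentricity cap of
0.95 · brain radius keeps the truncation error below 10⁻⁸ relative).
Potentials are average-referenced — the sphere solution is naturally so,
and a physical reference electrode is a linear transform of it. With all
conductivities equal the series matches a closed-form homogeneous-sphere
solution derived independently via generating functions, which in turn
reduces to the textbook central-dipole formula `3(q·r̂)/(4πσR²)`; this
dual derivation anchors the implementation.

Electrode positions were not published for the setup being emulated; an
idealized 7-electrode layout on the upper scalp shell (F3/F4
antero-lateral, T3/T4 temporal, P3/P4 postero-lateral, Cz vertex) ships as
a documented, user-replaceable default.

Fitting scans a regular volumetric grid (2-mm spacing) inside the brain
shell, solving the moment linearly at every candidate (a 10⁻¹² ridge keeps
degenerate geometries solvable), then refines from the best five grid
points with Nelder–Mead on location; a refinement step leaving the shell
is projected back with a warning. GOF is the percentage of
average-referenced topography variance explained.

**Layout-limited sensitivity.** Seven average-referenced electrodes give
exactly six measurements for the dipole's six parameters, so the fit is an
exact inverse: noiseless recovery is sub-millimetre, but location error
grows linearly with sensor noise (measured median ≈ 1.5 mm at 1% noise,
≈ 6.5 mm at 5% over random interior dipoles). Fitted locations from
few-channel montages should be read with that pull-back in mind.

## The synthetic-data generator

Each trial is `gain · template(category) + pink + white noise
[+ artifact] [+ trigger leak]`, where the template is a sum of Gaussian
bumps (latency, width, per-channel amplitude, category set). Defaults
emulate the study conditions: 8 subjects, 128–155 trials per category
(drawn uniformly), 512 Hz, epochs −150…710 ms; posterior responses at 105
and 140 ms evoked at full amplitude by structured images and reduced
amplitude by scrambled ones, a face-selective 120-ms component (3.5 μV), a
dog/human difference at ~72 ms and an aggressive-expression component at
~150 ms; pink (1/f) noise of 10 μV plus 3 μV white noise per sample;
multiplicative log-normal trial gain (sd 0.2, mean 1) for trial-to-trial
amplitude variability, which the underlying recordings do not quantify —
it is a free parameter; 2% artifact trials carrying a ~190 μV bump;
optional trigger-leak square pulse over the 500-ms stimulus duration.
Component amplitudes were calibrated once so whole-epoch face-vs-scrambled
decoding averages near 60% across subjects with object-vs-scrambled a few
points above chance — the ordering and scale reported for canine
recordings — and then frozen.

The pink-noise spectrum is shaped in the frequency domain and scaled by a
Parseval-exact analytic factor, so `noise_sd` is the true per-sample
standard deviation (verified to 5%). The master seed spawns per-subject
substreams (`numpy` `SeedSequence`), making every output bit-reproducible
and subjects regenerable in isolation.

**What passing tests show — and don't.** The generator's noise is
Gaussian, stationary and independent across channels and trials; real EEG
has correlated, non-stationary, artifact-laden noise, eye/muscle activity
and volume-conducted cross-channel structure. Calibration results (type-I
rates, FWER control, chance-level coverage) therefore validate the
*procedures* under exchangeability, not the effect sizes one would obtain
from real dogs; the planted-effect detection results demonstrate
sensitivity under known ground truth only.

## Reduced problem sizes

The shipped calibration studies use deliberately scaled-down designs
chosen to exercise the full inference path at desk scale: the family-wise
error study runs 50 replicates of 3 tasks × 5 intervals with 60 trials
per class, 100 permutations and 5-fold CV; ERP null calibration uses 120
simulated experiments at the full 7 × 59 window grid; the demo pipeline
uses 2 subjects with 12–14 trials per category and 20 permutations. The
statistical machinery is identical at full scale — only the Monte-Carlo
resolution changes.

## Known limitations

- No ICA and no manual artifact review: amplitude rejection is the only
  cleaning step, by design (reproducibility over completeness).
- The sphere model ignores real head geometry and the thick extracranial
  musculature of dogs beyond a single scalp conductivity; with 7
  electrodes the source fit is exactly determined (see above).
- Clustering of fitted dipoles across time points into sources is left to
  the user on the exported table; the criteria involve judgment the
  package does not automate.
- The stimulus images themselves (luminance/contrast statistics) are out
  of scope; species effects in the simulation are planted neural
  differences, silent on low-level visual confounds.
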