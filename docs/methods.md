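# Methods

This note documents the models implemented in `condyn`, the defaults they
ship with, what the synthetic-data generator does and does not emulate, and
the numerical choices a maintainer would want to know about.

## Experiment model

A block is a sequence of 120 conditioned-stimulus presentations, half CS+
and half CS−, in a pseudo-random order constrained so that no more than four
consecutive trials share a condition. The CS lasts 1 s. The first four CS+
trials are always reinforced; of the remaining 56 CS+ trials exactly
round(0.25 × 56) = 14 are reinforced, chosen uniformly at random — an
exact-count assignment, so the nominal 25% rate is reproduced in every
block rather than in expectation. On reinforced trials the US starts 0.5 s
after CS onset and the two co-terminate 1 s later, so the reinforced CS
duration is 1.5 s. Intertrial intervals are drawn from a normal with mean
4.6 s and sd 1.5 s, truncated at a floor of 1.5 s (the truncation raises the
realised mean by ≈ 0.07 s); one interval follows every trial. Reinforced
CS+ trials are excluded from every analysis because their responses are
contaminated by the US; an `exclude_post_us` option additionally drops
trials immediately following a US.

## β-series GLM

Each stimulus is a separate regressor: a boxcar of the stimulus duration
convolved with the canonical double-gamma HRF (peak delay 6 s, undershoot
delay 16 s, unit dispersions, undershoot ratio 1/6, 32-s support,
peak-normalised), sampled at volume-onset times on a 16× oversampled grid.
US events get their own regressors by default (configurable), followed by
any nuisance columns, the cosine drift basis, and an intercept.

* **High-pass filter.** Drift removal regresses out a discrete-cosine basis
  whose periods exceed the 128-s cutoff (k_max = ⌊2·N·TR/cutoff⌋ functions).
  The same basis enters the design matrix as confounds so data and model are
  treated consistently. Basis functions sum to zero over the scan grid, so
  voxel means are untouched. Frequency separation is imperfect near the
  cutoff: a 256-s cosine keeps ≈ 5% of its rms amplitude (with larger
  pointwise edge ringing), a 20-s cosine passes with ≈ 2% rms distortion.
* **Global scaling** divides each scan by a reference mean and multiplies by
  100. For whole-brain data the reference is the scan's own spatial mean.
  For an ROI matrix extracted from a larger acquisition, the reference must
  be the acquisition-wide mean (`RoiTimeSeries.global_signal`): within a
  functionally homogeneous ROI the spatial mean *is* the evoked signal, and
  scaling by it would regress the task response out of the data. The
  simulator therefore provides a whole-brain reference signal alongside each
  ROI. Scaling can be disabled (`--no-global-scaling`) as a control.
* **Estimator.** Plain per-voxel OLS (`numpy.linalg.lstsq`); a ridge option
  exists but is off by default. One GLM contains all trials of a block (the
  all-trials variant of the β-series approach) rather than iterating
  one-trial-vs-rest models. Rank deficiency raises an error naming the
  offending columns; a condition number above 10⁶ logs a warning. With zero
  noise and drift the planted amplitudes are recovered to ≈ 1e-12 relative
  error because the simulator and the GLM share the same event-regressor
  construction — the round trip is a linear-algebra identity, which is
  exactly what makes it a sharp regression test for both sides.

## Trial dynamics

The ROI-level response is the mean β across voxels per analysed trial. The
early/late split uses time on task (onset < 336 s = 5.6 min), not trial
counts, so the interleaving cannot favour a condition; per-subject
differentials (CS+ − CS−) are compared with a paired t-test across subjects
and Benjamini–Hochberg correction across the measure set. Smoothing is a
Nadaraya–Watson estimator with a Gaussian kernel whose width is expressed in
trials (default σ = 5 trials × the mean inter-trial spacing; a sensitivity
utility re-runs at σ ∈ {3, 5, 8}); weights renormalise at the block edges,
so no padding is needed. The kernel bandwidth default is a conventional
middle ground: small enough to retain a change point at mid-block, large
enough to suppress single-trial noise. The per-trial contrast series feeding
the change-point analysis is the smoothed difference evaluated at each
unpaired CS+ trial onset (the CS− curve must be interpolated because the two
conditions never share a trial; a raw-β variant is available). Differencing
removes constant condition-independent offsets exactly; slowly varying
drifts cancel only approximately, because the two conditions sample the
drift at different onsets (verified to leak < 5% of a linear drift).

## Change-point analysis

The CUSUM chart cumulates deviations from the series mean (S₀ = Sₙ = 0 by
construction). The magnitude of change is the chart's range; significance
comes from 1000 random reorderings of the series, counting strictly smaller
permuted magnitudes (ties count against significance), with a 95% threshold.
The change-point estimator is the earliest index maximising |Sᵢ|: the
absolute value handles rising and falling shifts symmetrically, since a
monotone shift produces a one-signed chart. Indices are reported 1-based
within the analysed series. Under an iid null the test rejects ≈ 5% of
series; a mean shift of twice the noise sd at mid-series is located with a
median error below 5 trials. Note that for a gradual (ramp-like) decline the
estimator lands where the series crosses its mean — systematically after the
onset of the decline; the planted and estimated change points therefore
agree in ordering across subjects, not in absolute trial number.

Cross-ROI concordance treats subject-level change points (subjects × ROIs)
with a one-way ANOVA (ROI as factor, df = (k−1, k(n−1))) and a PCA on the
correlation matrix — correlation, not covariance, so ROIs with different
change-point variances contribute equally; eigenvalue fractions sum to 1 and
equal 1/k for independent columns. PC1 scores (sign fixed so the dominant
loading is positive) are correlated with a per-subject covariate, here the
heart-rate conditioning effect.

## Sliding-window RSA

Windows of 50 analysed trials, stepped by 2, slide over the chronological
sequence of unpaired CS+ and CS− trials (reinforced trials are removed
before windowing, keeping condition counts balanced; a 120-trial block with
25% pairing yields 102 analysed trials and hence 27 windows, an unreinforced
block the full ⌊(120−50)/2⌋+1 = 36). Within a window, each condition's voxel
patterns are averaged and the two mean patterns Pearson-correlated;
D = 1 − r. Group curves Fisher-z average r across subjects before
re-transforming (|r| = 1 is clipped to 1 − 1e−6 with a warning); per-subject
curves and slopes stay on the 1 − r scale, since z-averaging is a
group-level operation. Slopes are OLS against window index (windows are
equally spaced in trials). Windows with a zero-variance mean pattern yield
an undefined correlation and are recorded as missing. A minimum of 4 voxels
is enforced — pattern correlations from fewer voxels are too unstable to
interpret.

## Heart rate

Input is an RR-interval series (R-peak detection is upstream). Intervals
outside a 0.2–3 s guard are flagged and their rate linearly interpolated
from neighbours, keeping the rate defined over every trial window.
Instantaneous HR is 60/RR, piecewise constant over each interval. Binning
(−1 to +5 s around onset, 1-s bins) weights each interval by the fraction of
the bin it occupies — an exact time-weighted mean, which matches dense
numerical integration to 1e-9 for piecewise-constant rates. Baseline
correction subtracts the prestimulus bin. The scalar per-trial response is
the mean change over the 1–4-s post-onset bins (the deceleration window;
configurable), chosen to cover the orienting deceleration's typical latency.
Downstream dynamics reuse the trial-dynamics machinery unchanged. Because HR
is sampled at beat resolution (~0.9 s at rest), narrow rate bumps are
attenuated by ~10% relative to the underlying continuous rate — a property
of the measurement, not of the binning.

## Synthetic cohort: what is emulated, and what is not

Each ROI's BOLD matrix is baseline (100) + Σ trials amplitude × pattern ×
HRF-regressor + US responses + optional polynomial drift + white noise; the
voxel pattern of a trial is (1−c)·shared + c·condition-specific with
separation c ∈ [0, 1], patterns have unit mean (so the ROI-mean β equals the
planted amplitude) and ±80% voxel-to-voxel spread. The RR series integrates
a rate function (baseline 70 bpm minus Gaussian deceleration bumps per CS,
amplitude per condition, latency 2.5 s, width 1.5 s, plus step noise held
for 0.25 s); beats fall where the integrated rate accumulates one beat.

The default acquisition truth plants: a CS+/CS− amplitude difference of 1.0
(in units of the BOLD noise sd × 2) that is flat until a change point near
trial 60 and then declines linearly to zero; pattern separation decaying
linearly across the block in insula/dACC but not amygdala; and a 5-vs-1 bpm
deceleration difference whose excess follows the same decline. Subjects are
coupled by a standard-normal latent factor: change points shift by ±18
trials/sd (±5 jitter across ROIs), HR deceleration by ±1.5 bpm/sd, and the
convergence endpoint by ±0.3/sd — so later-adapting subjects also show
stronger orienting and slower representational convergence, giving the
concordance statistics real structure to recover. These couplings yield
cohort-level effects of the same order as those reported in this literature
(pairwise slope correlations of ~0.1–0.6 across seeds at n = 18); at that
sample size the slope-concordance estimates remain seed-to-seed variable,
which is a faithful property of the regime, not an artifact.

Noise defaults (BOLD white noise sd 0.5, i.e. single-trial ROI-mean β noise
≈ 0.4; HR step noise 2 bpm) put per-trial effects near the detection
threshold while leaving group effects at n = 18 clearly detectable — the
regime in which these designs operate. Not emulated: spatially correlated
or physiological (cardiac/respiratory) noise, motion, susceptibility
artifacts, HRF variability across regions and subjects, raw ECG morphology,
and non-stationary noise. Passing tests therefore demonstrate correctness of
the estimators under the stated forward model, not robustness to every
artifact of real recordings.

## Problem sizes and determinism

All randomness flows from explicit seeds (`numpy` `SeedSequence` spawning
per subject and stage); reports embed the config and seeds, and re-running a
config is byte-identical. Simulation-based tests use the sizes stated in
their docstrings — e.g. 200 replicates for change-point recovery and
estimator-bias checks, 1000 null series for permutation calibration, 50
replicate cohorts for the end-to-end null calibration — chosen to give the
binomial/CI bounds quoted in the assertions. The full default pipeline (18
subjects, 3 ROIs, 1000 permutations) runs in well under a minute on one
core.

## Known limitations

* The CUSUM estimator's lag on ramp-shaped declines (above) means absolute
  change-point trial numbers should be interpreted relative to the series
  analysed, not as the onset of the underlying process.
* Collinearity between a reinforced CS+ regressor and its US regressor
  (onsets 0.5 s apart) is intrinsic to the paradigm; the package warns and
  relies on the exclusion of reinforced trials downstream.
* Global scaling of ROI matrices requires an acquisition-wide reference
  signal; without one the package falls back to the ROI spatial mean, which
  is only appropriate for whole-brain matrices.
* The per-subject RSA slope is computed on the 1 − r scale; a Fisher-z
  variant would weight extreme correlations differently (both behave
  identically for |r| ≲ 0.5).
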