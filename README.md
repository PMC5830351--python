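# condyn — single-trial conditioning-dynamics analysis

`condyn` analyses how the brain's and the heart's responses to a conditioned
threat cue evolve over a long differential-conditioning session. It is aimed
at researchers working with event-related fMRI and concurrent ECG in
classical fear-conditioning paradigms, where a CS+ (partially reinforced by
an aversive US) is interleaved with a CS− that is never reinforced, and where
the scientific question is not *whether* a region discriminates CS+ from CS−
but *when that discrimination fades* — the adaptation of the salience network
(amygdala, insula, dorsal anterior cingulate).

The pipeline implements four analyses end to end:

1. **β-series estimation.** Every stimulus gets its own GLM regressor — a
   boxcar of its duration convolved with the canonical double-gamma HRF
   h(t) = g(t; 6, 1) − g(t; 16, 1)/6, peak-normalised — after global scaling
   (each scan's mean set to 100) and discrete-cosine high-pass filtering
   (cutoff 1/128 Hz). Per voxel, OLS yields one β per trial: the β-series.
2. **Trial dynamics and change points.** ROI-mean β values per trial are
   split into early (t < 5.6 min) and late periods (paired t-tests across
   subjects, Benjamini–Hochberg FDR), smoothed over trial time with a
   Gaussian kernel, and differenced (CS+ − CS−). The decline of the
   differential is located with a CUSUM chart
   S₀ = 0, Sᵢ = Sᵢ₋₁ + (xᵢ − x̄); its range max S − min S is tested against
   1000 random reorderings (significant when > 95% of permuted ranges are
   smaller), and the change point is argmaxᵢ |Sᵢ|. Cross-ROI concordance of
   subject-level change points uses a one-way ANOVA and a PCA on the
   correlation matrix, with PC1 scores correlated against each subject's
   heart-rate conditioning effect.
3. **Sliding-window RSA.** In windows of 50 analysed trials (step 2), the
   mean voxel patterns of CS+ and CS− are Pearson-correlated; dissimilarity
   D = 1 − r. Group curves average r on the Fisher-z scale. Endpoint tests
   compare the first and last 10 windows; per-subject dissimilarity slopes
   are compared across ROIs and against the univariate amygdala adaptation
   slope.
4. **Heart-rate orienting.** RR intervals become an instantaneous rate
   (60/RR, piecewise constant), averaged into exact time-weighted 1-s bins
   from −1 to +5 s around each onset and baseline-corrected by the
   prestimulus bin. The CS-locked deceleration difference is analysed with
   the same early/late and smoothing machinery as the BOLD series.

Because such datasets are rarely shareable, the package ships a first-class
synthetic-data generator (`condyn.synth`) that reproduces the paradigm —
120-trial blocks, the first 4 CS+ trials always paired, 25% pairing among the
remaining CS+ trials, US onset 0.5 s after CS+ onset, ITI 4.6 ± 1.5 s,
TR = 1.98 s — and plants known amplitude dynamics, pattern convergence, and
heart-rate deceleration, so every stage is testable against ground truth.

## Worked example

```python
from condyn.pipeline import RunConfig, run_full

report = run_full(RunConfig())   # 18 synthetic subjects, seed 7
for row in report["early_late"]:
    print(row["name"], round(row["t"], 2), f'{row["p_fdr"]:.2e}')
```

With the default configuration this prints (t and FDR-corrected p of the
early-vs-late paired test on the CS+ − CS− differential):

```
amygdala 16.87 1.05e-11
insula 16.76 1.05e-11
dacc 13.76 1.61e-10
hr -5.84 1.99e-05
```

All three regions show a significantly larger differential early than late —
the planted adaptation — and the heart-rate deceleration difference (negative
= CS+ slows the heart more) shrinks correspondingly. The same report carries
the group change points (trial 26 of the 42 analysed CS+ trials, permutation
confidence 100%), the change-point concordance (F(2,51) = 0.51, p = 0.60:
no ROI difference; PC1 = 86% of variance; PC1 scores vs heart-rate effect
r = −0.91), the RSA endpoint tests (insula t = 3.85, p = 0.0013; dACC
t = 4.11, p = 0.0007; amygdala flat, t = 1.46, p = 0.16 — the amygdala truth
plants no pattern convergence), and the dissimilarity-slope concordance with
the amygdala adaptation slope (r = 0.43, p = 0.078 at this seed).

A command-line interface mirrors the stages
(`condyn simulate | betas | dynamics | changepoint | rsa | hr | concordance |
run-all | validate`); `condyn run-all --seed 7 --out-dir out/` writes
`report.json` and the subject × ROI change-point matrix.

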