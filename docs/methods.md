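# Methods

## Task schedule

The conditioning run consists of 280 trials at a fixed 6-s
onset-to-onset spacing (28 min): 100 sucrose-cue, 100 no-solution-cue
and 80 saliva-cue trials. The probabilistic contingency — 20% of
sucrose-cue trials delivering no solution and 20% of no-solution-cue
trials delivering sucrose — is enforced as an exact count
(`round(p_violation · n)`), not a binomial draw: the proportion is a
design ratio, and exact counts make the delivered-US marginals
invariants (they always equal the cue counts, because violations swap
outcomes pairwise between the two conditions). The first 10 trials are
a fixed congruent sucrose block that establishes the cue–taste
association before any violation; all remaining trials are fully
shuffled by the seed. The 20% violation quota is taken of all 100
sucrose-cue trials but placed only among the 90 non-fixed ones; a
switch (`violations_from_all=False`) selects the alternative reading in
which the quota applies to the non-fixed trials only. The saliva
pairing is deterministic — no violation is defined for the neutral
control. Within a trial the cue appears at trial onset and the taste is
delivered 2 s later, when the cue disappears.

## TD model

Stimuli use a complete serial compound: each cue carries a separate
weight at each of the within-trial time bins (default three 1-s bins:
cue onset, cue, taste), and the cue indicator stays on from onset
through the US bin. Without that persistence the US-bin error could
never propagate to the cue and no learning would occur. Value is
V̂(t) = Σᵢ wᵢxᵢ(t); the error is δ(t) = r(t) + γV̂(t+1) − V̂(t) with
γ = 0.99 and V̂ ≡ 0 beyond the last bin; weights update once per trial
in batch, Δwᵢ = α Σₜ xᵢ(t)δ(t). Rewards are 1 for sucrose, 0 for
no solution and 0 for saliva (the neutral control therefore carries
identically zero PE). Weights persist across the whole run; there is no
block reset.

Because the US-bin weight update depends only on the US-bin error, a
congruent sucrose run has the closed form δₙ(US) = (1 − α)ⁿ⁻¹ and
w(US) after n trials = 1 − (1 − α)ⁿ; both are verified against a naive
brute-force simulation to 1e−12.

The per-trial regressor value is the absolute error at the US bin,
|δ(US)| — the event actually modelled is reward receipt/omission, and
the absolute value reflects response strength without separating
positive from negative errors. Both the within-trial reduction (US bin
rather than a max over bins) and the exclusion of the learned cue-onset
response from the regressor are modelling choices; the bin taken is
configurable. The learning rate is selected from {0.2, 0.5, 0.7} by
maximising the mean first-level R² across subjects; zero-variance
subjects are flagged and excluded from the mean.

## First-level GLM

The |PE| series is placed as amplitude-modulated impulses at the US
onsets on a 0.05-s grid (both the 6-s trial spacing and the 2.1-s TR
are integer multiples), convolved with the canonical double-gamma HRF
(nilearn's glover kernel, rescaled to unit peak so parameter estimates
are on the event-amplitude scale), and sampled at the volume times
(default TR 2.1 s, 800 volumes). The model operates on one time series
per anatomical ROI — the group analysis consumes ROI-mean parameter
estimates, so voxel/NIfTI handling is deliberately out of scope. The
fit is OLS with an intercept (optional Legendre drift columns); no
prewhitening, because serial correlation affects efficiency rather than
unbiasedness and group-level inference is bootstrap-based. Rank
deficiency raises an error naming the collinear columns.

## Genetics

Eight loci are handled: rs1800497 (Taq1A, A1/A2), rs1799732 (−141C
Del/Ins), the D1 SNPs rs686/rs4532/rs5326, COMT rs4680 (Met/Val), and
the DAT (9R/10R) and DRD4 (7R/4R) repeat classes. Ordinal codes follow
major-allele dosage — minor homozygote 1, heterozygote 2, major
homozygote 3 — which reproduces the printed D2 coding (Del/Del = 1 …
Ins/Ins = 3; A1/A1 = 1 … A2/A2 = 3) and is applied to the other loci by
analogy; every locus's map is overridable via `LocusDef.coding_map`,
and the repeat polymorphisms are treated as two-class (risk-repeat
presence) biallelic systems. Missing genotypes propagate as missing and
subjects are dropped per model (complete case), never imputed.

Hardy–Weinberg equilibrium is tested with the exact conditional test
(sum of the probabilities of all heterozygote counts, given the allele
totals, that are no more probable than the observed one) rather than
the χ² approximation, which is unreliable at n = 33. The implementation
works in log-space with renormalisation; tests compare it against an
independent enumeration oracle in exact rational arithmetic. Because
the test statistic is discrete its p-values are super-uniform, not
uniform: calibration is therefore checked against the exactly
enumerated null distribution of the p-value
(`hwe_pvalue_null_distribution`, a binomial mixture over allele counts)
plus a one-sided bound on the rejection rate, rather than against the
continuous uniform, which any correct discrete exact test would fail
at large sample counts.

The summary score is raw BMI + code(−141C) + code(Taq1A).

## Group-level statistics

Each ROI's PE estimate is regressed on a predictor grouping with all
predictors entered simultaneously: D2 (BMI, −141C code, Taq1A code),
D1 (BMI + three D1 SNP codes), OTHER (BMI + COMT/DAT/DRD4 codes), and
SUMMARY (the summary score alone). Standardized β are computed from
z-scored variables (a lone predictor's β equals the Pearson r); the
model F-test comes from statsmodels OLS.

Inference is a case-resampling bootstrap, B = 1000 by default, with
percentile CIs and sign-count p-values p = 2·(min(#{β* ≤ 0},
#{β* ≥ 0}) + 1)/(B + 1), capped at 1 — the +1 guards the small-sample
floor 2/(B+1). Degenerate resamples (rank-deficient or zero-variance
columns) are redrawn and counted. B and the percentile interval type
are conventional defaults; neither is prescribed by the analysis being
modelled. Measured over 24 000 pooled null checks at n = 33, the
realised size of this test at nominal 0.05 is ≈ 0.069 — the familiar
mild liberality of percentile-type bootstrap tests at small n; users
wanting exact small-sample control should prefer the CI over the
p-value.

Collinearity is screened per predictor with VIF = 1/(1 − R²ⱼ) from
auxiliary regressions (tolerance = 1/VIF); VIF > 5 is flagged, a
constant or duplicated column reports an infinite VIF. Normality is
screened with Shapiro–Wilk at α = 0.05 on the dependent variable and
continuous predictors (BMI, age, summary score — ordinal genotype codes
are never transformed); failures are replaced by average ranks, an
idempotent transform. Model p-values are Bonferroni-adjusted within
each grouping across the ROI family; the default family is the 8 ROIs
(4 bilateral regions × 2 hemispheres), configurable since the original
family size is a judgement call. An exploratory reduced D1 model
(rs686 + rs4532 on the left accumbens) is provided as a clearly
labelled post-hoc routine outside the corrected family. An optional age
covariate can be appended to any grouping (default off).

## Synthetic data

The generator emulates the cohort the analysis assumes: n = 33 by
default; BMI ~ truncated normal (mean 21.6, sd 1.4, bounds
[18.1, 24.2]); age ~ truncated normal (24.3, 7.3, [16, 43]); genotypes
drawn as two independent allele draws (HWE by construction) with
literature-typical European-ancestry frequencies (Taq1A A1 0.20, −141C
Del 0.11, rs686 0.37, rs4532 0.30, rs5326 0.15, COMT Met 0.48, DAT 9R
0.27, DRD4 7R 0.20) — configurable, since the modelled study does not
publish its allele counts. Ground truth is linear: the true PE slope in
the signal ROIs (bilateral putamen by default) is
1.0 + Σⱼ effectⱼ·z(predictorⱼ) + ε, with default standardized effects
BMI −0.5, −141C +0.4, Taq1A −0.45 (magnitudes in the 0.4–0.55 range;
the sign pattern is what recovery tests assert, since the magnitudes of
the modelled study are real-data quantities) and residual sd 0.3; all
other ROIs are intercept + noise. ROI BOLD is slope × convolved |PE|
regressor + stationary AR(1) noise (ρ = 0.3, marginal sd σ = 1 by
default) — a minimal realistic autocorrelation model.

Truth tables are emitted separately from the observed tables and the
analysis path consumes only the latter (asserted by test). What the
generator does *not* emulate: image-level structure (voxels, motion,
physiological noise), linkage between loci, genotype–BMI correlation,
nonlinear or interaction effects, and menstrual-cycle or session
effects. Passing recovery tests therefore demonstrates the estimators
are correct under the assumed model, not that the model captures all
structure of real data.

## Problem sizes and numerical choices

Recovery checks use a 500-subject cohort (sign recovery and null-effect
bounds), 10-subject cohorts for learning-rate selection, 2 500 null
cohorts (B = 1000) for the bootstrap size estimate, and 500 draws at
n = 60 for HWE calibration — sizes chosen so Monte-Carlo error is small
relative to the margins being checked. Determinism is end-to-end: every
stage is seeded, per-stage seeds derive from one global seed, and
repeated runs produce byte-identical outputs. Floating-point
comparisons in tests use 1e−12 for closed forms and 1e−8 for pipeline
identities; the HWE implementation tolerates 1e−12 relative slack when
classifying probability ties, matching the exact-arithmetic oracle to
better than 1e−10.

## Known limitations

* OLS first level without prewhitening understates single-subject
  standard errors under autocorrelated noise; only point estimates are
  propagated to the group stage, so group inference is unaffected.
* The bootstrap p-value is mildly liberal at n = 33 (see above).
* VNTR coding as two-class risk-repeat dosage is a simplification of
  multi-allelic repeat systems.
* The events file does not carry the generating seed; reading one back
  reconstructs the trial sequence but not the generator state.
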