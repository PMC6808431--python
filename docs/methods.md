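# Methods

This note documents the statistical models the package implements, the
synthetic-data generator's assumptions, the numerical choices, and known
limitations. Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## The analysis

### Glycoprotein imputation

Each glycoprotein concentration (AAT, AGP, HP, TF; natural-log scale) is
modelled as a sparse linear function of NMR metabolite features plus
age, sex (coded 1 = men, 2 = women), and BMI. All continuous inputs are
natural-log transformed and standardised to the training cohort's mean
and SD (sample SD, n−1; age standardised without log; sex passed through
as a category code). Derived-ratio NMR features are excluded by name
before training because missingness in numerators/denominators
propagates.

The lasso penalty λ is tuned by 10-fold cross-validation: the grid runs
from λ_max (the smallest λ zeroing all slopes, max|Xᵀ(y−ȳ)|/n) down to
λ_max·10⁻⁴, 100 log-spaced points, descending. Fold assignment is a
seeded random permutation with fold sizes differing by ≤ 1; the seed is
recorded in the CV report. Per λ, held-out MSE and Spearman ρ are
computed in each test fold; the SE of the mean MSE is SD(fold MSEs)/√10.
The **one-SE rule** selects the largest λ whose mean MSE is ≤
min(mean MSE) + SE(argmin); ties break toward the larger λ (the sparser
model), consistent with the rule's purpose. The final model is refit at
that λ on the full training data.

Models are serialised as JSON with both coefficient conventions:
standardised (relative contributions) and raw log-scale (directly
applicable to a new cohort without re-standardising to that cohort's own
moments, which would silently shift predictions). Prediction is on the
log scale; concentrations are obtained by exponentiation. Applied
models flag samples with any missing input (`incomplete-inputs`) and
imputed values outside the assay validity ranges — 0.64–2.58 mg/L (AAT),
362–1,880 mg/L (AGP), 0.14–3.95 mg/L (HP) — as `out-of-range`; both are
excluded with counts logged. Accuracy is reported as CV-mean Spearman ρ,
in-sample ρ, their difference (the overfit gap), and r² (squared Pearson
between predicted and observed log-standardised values; note r² is
sign-blind, so ρ is the accuracy gate).

The solver is scikit-learn coordinate descent. The CV path uses
tolerance 1e-6 (fold-averaged scores don't resolve finer differences);
the final fit uses 1e-10 and matches an independent naive coordinate-
descent oracle to < 1e-6 per coefficient. Because the NMR features are
strongly collinear, the *selected feature set is not unique* across
retraining seeds; only accuracy metrics are treated as reproducible.

### Outcome aggregation

An outcome is a three-digit ICD-10 code or an inclusive range (e.g.
I70–I79); a record matches if its 3-character prefix falls in the set.
Main and side diagnoses count equally. Incident = first matching event
in (baseline age, baseline age + 8]; prevalent = any matching event at
or ≤ baseline age (a boundary event is prevalent, not incident — the
retrospective window is read inclusively). Event-free persons are
censored at baseline + 8 years. ICD-9-looking (all-numeric) codes are
rejected at load time with a pointer to upstream GEM conversion.
Eligibility: an outcome is analysed only with ≥ 20 incident cases in
*every* cohort, counted within the subset of persons whose biomarker was
successfully imputed (so family sizes differ per biomarker); prevalent
adjustment is per cohort at ≥ 10 prevalent cases.

### Cox scan, meta-analysis, FDR, replication

Cox models use age as the analysis timescale: delayed entry at baseline
age (left truncation), exit at first event or censoring, Efron tie
handling (lifelines default). The biomarker enters log-standardised, so
β is the log HR per 1 SD. Continuous covariates (BMI, SBP, alcohol,
citrate, albumin, VLDL diameter, optionally CRP) are log-standardised;
sex and smoking are categorical; a prevalent-case indicator is added
when the outcome qualifies. Pregnant women are excluded once, upstream
of all scans. Zero-event or non-converged fits are skipped and excluded
from the FDR family (family size is therefore data-dependent).

Fixed-effects meta-analysis: β̂ = Σwᵢβᵢ/Σwᵢ, w = SE⁻², pooled SE =
(Σw)^(−1/2), two-sided normal p. Storey–Tibshirani q-values are computed
per (biomarker × cohort) family: π0(λ) = #{p>λ}/(m(1−λ)) on λ =
0.05…0.95 (step 0.05), smoothed by a cubic spline and evaluated at
λ = 0.95; estimates above 1 (routine sampling noise under sparse signal)
are clamped to 1, non-positive estimates fall back to 1 with a warning
(either way the correction becomes exactly Benjamini–Hochberg, the
documented fallback); families with m < 10 skip smoothing and use
π0 = 1.
q(pᵢ) = min over t ≥ pᵢ of π0·m·t/#{p ≤ t}. An association is
**significant and replicable** iff q < 0.05/3 (Bonferroni over the three
glycoproteins) in both cohorts and in the meta-analysis. Sensitivity
scans re-fit with CRP as an extra covariate and, separately, in the
subset excluding each outcome's prevalent cases.

### Transcriptional stage

Probes are collapsed to genes by taking the per-sample maximum across a
gene's probes. Genes are ranked by Pearson correlation with AAT after
residualising both expression and log AAT on age and sex (constant genes
get r = 0 by convention; rank ties break by stable gene-id order). The
enrichment score walks the descending list, adding a hit gene's r and
subtracting 1/N_total per miss; the reported ES is the larger-magnitude
extremum of the running sum (maximum or minimum), so negative enrichment
is representable. A config switch offers the canonical GSEA weighting
(hits normalised by the set's Σ|r|, misses by 1/(N − set size)); the
literal unnormalised form is the default. For inference, the AAT sample
labels are permuted (default 1,000 times), the ranking recomputed, and
ES re-evaluated: NES = ES / mean|permutation ES| (the magnitude mean is
used because signed extrema can average near zero and destabilise the
ratio; null-set NES then has magnitude ≈ 1 by construction), empirical p
uses the add-one convention (b+1)/(m+1), and BH-FDR is applied within
each gene-set collection separately.

Module eigengenes are the first principal-component score of the
module's probe submatrix (probes standardised), sign-aligned to
correlate positively with mean module expression, then standardised.
Standardised log AAT is regressed on the eigengene with age and sex
adjustment; β is the change in SD of AAT per SD of coordinated module
expression (the regression direction follows the primary description of
the procedure; the opposite direction differs only by the ratio of the
two SDs, both 1 here). Bonferroni thresholds follow family size: 0.0025
for a 20-module family, ≈1.45×10⁻⁴ for 346. The core-membership test
compares each module probe's |correlation| with the eigengene to the
null of all out-of-module probes (two-sided on |r|; the procedure is
silent on signedness), add-one empirical p, BH within module, core at
FDR < 0.05.

## The synthetic-data generator

The generator's defaults are the study conditions; they are not tuned
per test.

* **Panel**: multivariate log-normal via a Gaussian copula (Cholesky of
  the target correlation matrix on the log scale) with marginals
  moment-matched to natural-scale means/SDs: GlycA 1.30 ± 0.18 mmol/L,
  AAT 1.19 ± 0.20, AGP 789 ± 203, HP 1.09 ± 0.49, TF 2.65 ± 0.38 (the
  published unit labels, mg/L, are mirrored verbatim even where g/L
  would be more plausible for AAT/HP/TF). Default correlations: GlycA
  with AGP 0.64, HP 0.59, AAT 0.33, TF 0.26; AGP–TF −0.04; remaining
  pairs in the moderate 0.12–0.52 band. Non-PSD matrices are rejected
  outright (no silent nearest-PSD repair), naming the offending
  eigenvalue.
* **NMR features** (149, first one GlycA itself): log-scale features are
  linear in five latent information channels — GlycA directly, plus one
  noisy proxy per glycoprotein — four uninformative latent factors, and
  per-feature noise. The proxy information shares are solved jointly
  (coordinate-wise bisection) so that the best linear predictor of each
  glycoprotein from *all* channels attains exactly the configured R²
  ceiling (defaults 0.43/0.64/0.56/0.18 for AAT/AGP/HP/TF), accounting
  for the cross-correlation of the analytes. Features are mapped to
  plausible natural concentration scales; the lowest
  `detection_limit_quantile` fraction of each feature is set to exactly
  zero to exercise the detection-limit path.
* **Events**: per outcome, a constant-in-age baseline hazard times
  exp(β·z) over the standardised log panel. Event ages are drawn by
  inverse-CDF sampling with left truncation at baseline age; a second
  independent draw populates the retrospective window (20 years for the
  first cohort, 10 for the second). Hospital discharge and death are not
  distinguished. Each outcome consumes its own seeded uniform stream, so
  rescaling a baseline hazard with the same seed strictly grows the
  event set, and adding outcomes never perturbs the panel. Default
  outcomes mirror the headline associations (heart failure I50 at HR
  1.60/SD AAT, influenza-pneumonia at 1.37, liver disease at 1.81, a
  chronic-respiratory outcome on HP, and a null fracture outcome).
* **Covariates**: age uniform 25–74, 53% women, log-normal BMI/SBP/
  alcohol/citrate/albumin/VLDL diameter, 25% smoking; CRP is log-normal
  with configurable log-scale correlation to GlycA (default 0.4), so
  confounding/mediation scenarios are constructible; a small pregnancy
  fraction exercises the exclusion rule.
* **Expression**: modules of probes sharing a latent profile
  (loading 0.8, noise SD 0.6); module m's latent is β_m·z_AAT plus
  orthogonal noise so the eigengene regression recovers β_m (default
  0.23 for the first module, 0 elsewhere). Each module's first gene
  carries a duplicate probe; ≥ 200 unstructured background probes
  provide the membership null.

What the generator does **not** emulate: NMR spectral artefacts and
platform batch effects, age-varying baseline hazards and competing
risks, ICD-10 comorbidity structure, non-linear metabolite-glycoprotein
relationships, and count-level microarray noise. Passing tests
demonstrate the *procedures* are implemented correctly and recover known
truths under the assumed structure — not that the published cohort
estimates would be reproduced on real data, which are not publicly
deposited.

## Problem sizes and numerical choices

The test suite and acceptance script run at the study's own sizes where
the check is about those conditions (626 training samples; 4,540 + 7,321
cohort split with 100 replicates for CI coverage; n = 10,000 for
calibration recovery) and at reduced sizes elsewhere (the end-to-end
pipeline test runs at ~6% scale; GSEA permutation checks use 100–200
gene universes with 100–720 permutations), chosen so each check still
measures what it claims with comfortable margins. Other numerics:
solver tolerances as above; Wald p-values from the normal approximation;
CI = exp(β ± 1.96·SE); eigengene via SVD; empirical permutation p-values
always use the add-one convention.

## Known limitations

* The membership permutation test is anti-conservative for small or
  incoherent modules: the eigengene is fit on the module's own probes,
  so even pure-noise probes correlate with it (top-eigenvalue inflation)
  above the out-of-module null. The implementation follows the stated
  procedure; the test suite documents the bias direction.
* Lasso feature selection under collinearity is non-unique; model
  accuracy, not feature identity, is the reproducible quantity.
* The Cox scan treats death from other causes as ordinary censoring at
  end of follow-up; the generator produces no competing deaths.
* Imputed-biomarker hazard ratios are attenuated relative to the
  generative per-SD truth by measurement noise (regression dilution),
  increasingly so when the training cohort is small; the acceptance
  recovery check therefore measures the survival machinery on the
  directly observed biomarker, and the pipeline demonstrates the
  imputed path end to end.
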