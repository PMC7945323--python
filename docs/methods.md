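# Methods

## Scope and data model

The package implements the analysis layer of a post-GWAS causal
dissection for a rare binary disease (MacTel-style case/control cohort)
together with a synthetic-cohort generator that supplies inputs with the
statistical structure the analyses assume. Three tables drive
everything: an instrument-weights table per trait (SNP, effect allele,
other allele, per-allele weight), a subjects × SNPs dosage matrix with
case/control status, sex and one genotype principal component, and a
long-format longitudinal retinal-phenotype table keyed by (patient, eye,
visit, phenotype, ETDRS subfield).

## Synthetic cohort generator

**Genotypes.** Independent SNPs in Hardy–Weinberg equilibrium; each
SNP's MAF is uniform on a configurable range (default 0.05–0.5) and
dosages are Binomial(2, MAF) effect-allele counts. No LD is simulated:
the downstream methods assume independent, pre-clumped instruments, so
LD would add cost without exercising any code path. Allele pairs are
drawn from the non-palindromic combinations only, so the default data
never triggers the palindromic-drop rule (which is tested with
hand-built fixtures instead).

**Traits.** Each quantitative trait is its genetic component
Σ w·g plus a Gaussian residual; residuals may be correlated across
traits, and instrument sets may share SNPs. The reference architecture
has six traits: serine (5 instruments), glycine (9 instruments, 4 shared
with serine plus residual correlation 0.5 — this is what makes the
conditional-selection stage informative), threonine (3, a null control),
T2D (20 small effects), and arteriolar/venular calibre (2 each, one
shared). Effect sizes ~0.1–0.35 per allele in trait-SD units are typical
of metabolite GWAS hits.

**Disease.** Liability threshold: L = Σ<sub>t</sub> c<sub>t</sub>·G<sub>t</sub>
+ 0.25·sex + 0.25·PC1 + N(0,1), with status 1 above the liability
quantile matching the configured prevalence. The causal coefficients act
on the *genetic* component of each trait, matching the MR identification
assumption (instruments affect disease only through the trait). Defaults
are c<sub>serine</sub> = −0.5 (protective) and c<sub>T2D</sub> = +0.15.
The generator then keeps a random subset of cases of exactly the target
size plus controls filling the cohort (default 476 : 1733 in 2209),
mimicking the case-enriched study design rather than population
sampling. The simulation prevalence defaults to 0.1: what the estimators
see is the case:control composition, not the population rate, and a
liability pool at a realistic rare-disease prevalence (≈0.05–0.1%) would
need millions of subjects to yield ~476 cases for no statistical gain.
Logistic-regression odds ratios on the enriched cohort remain valid
because case-control sampling only shifts the intercept.

**Retina.** Per (patient, eye, visit) a K-vector of latent factor scores
is generated as genetic shift (per-predictor factor effects applied to
dosages or scores) + patient random intercept (SD 0.7) + eye intercept
nested in patient (SD 0.4) + visit noise (SD 0.3); phenotype series
values are loadings × factors + measurement noise (SD 0.5), with a
missing-completely-at-random fraction (default 5%) blanked. Visit counts
are 1 + Poisson(mean − 1) per eye (default mean 3.6) with 0.5–2 year
gaps. The default loading matrix is sparse: each of the 119 series
(phenotype × subfield on the 9-subfield ETDRS grid) loads 0.6–0.9 on one
of the 30 factors plus small Gaussian cross-loadings. What this does
*not* emulate: ordinal/graded measurements (everything is continuous),
informative missingness, disease-progression trends over time, and
spatial correlation between neighbouring subfields beyond what shared
factors induce. Passing tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to those
real-data features.

**Seeding.** One master seed; each stage (genotypes, traits, retina,
loadings) derives an independent child stream keyed by a CRC32 of the
stage name, so stages can be regenerated independently and every output
is bit-reproducible from (config, seed).

## Allele scores

Instrument weights are harmonised to the cohort's counted allele by
exact or complement-strand allele matching, sign-flipping the weight
when the cohort counts the other allele; strand-ambiguous palindromic
(A/T, C/G) SNPs are dropped and counted rather than frequency-inferred.
Missing dosages are mean-imputed per SNP — the conventional allele-score
choice, keeping the score defined for every subject (the alternative,
dropping subjects, is noted as an assumption; the generator emits
complete data by default so the choice is rarely exercised).
Standardization is within the pooled analysis cohort (cases + controls)
with the sample SD, so odds ratios read "per SD of the cohort score
distribution"; means/SDs are stored for an exact inverse transform.

## Mendelian randomisation

Logistic regression (maximum likelihood via statsmodels) of status on
one standardized score + sex + PC1 (+ any conditioning scores); Wald SE
and p for the score term; 95% CIs as exp(β ± 1.96·se). Rank-deficient
designs (e.g. conditioning a score on itself) are rejected before
fitting. Conditional selection FDR-adjusts within each round across the
remaining candidates — the per-round family reading of "until no score
is significant after FDR correction" — and selects the
smallest-adjusted-p candidate below α = 0.05.

The Egger regression is unweighted by default (matching a "simple
regression line" convention); supplying disease-effect SEs switches to
inverse-variance WLS, and the two coincide when all SEs are equal. At
least 3 instruments are required; a constant trait-effect vector is
rejected as unidentifiable. Inputs must be oriented to trait-increasing
alleles; the pipeline does this by flipping disease effects by the sign
of the harmonised weight.

The quintile odds-ratio contrast bins the pooled (cases + controls)
score distribution into quintiles and forms the 2×2 cross-product OR of
the lowest vs top bin with Woolf SE; a zero cell raises an error rather
than applying a continuity correction.

## Genome-wide scans

Per-SNP logistic models share the covariate block (intercept, sex, PC1,
conditioning PRSs), so the fits are batched: a chunked Newton–Raphson
solves all per-SNP models simultaneously (256 SNPs per chunk keeps the
design tensor ~25 MB). Convergence is a 1e−10 max-step tolerance with a
50-iteration cap; diverging parameters (separation) or singular Hessians
mark the SNP unconverged and its row missing. A 10,000-SNP scan on 2000
subjects runs in ~15 s on one core and matches statsmodels' ML fits to
~1e−15. Monomorphic SNPs are skipped with a logged reason. In
interaction mode the dosage × partner product is added (dosage × dosage
for a SNP partner, i.e. additive × additive) and the interaction
coefficient's Wald test is the reported row. λ is
median(χ²₁)/0.4549364; peaks are called greedily below 5×10⁻⁸ with a
1 Mb masking window (index window when positions are absent), ties
broken lexicographically by SNP id for determinism.

## Endophenotypes

Cleaning drops phenotype × subfield series with missingness above a cap
(default 20%), then imputes: within-eye linear interpolation over visit
time (interior gaps only), then the eye's series median, then the cohort
series median — a rule that respects the longitudinal structure before
falling back to cross-sectional summaries. The factor model is
maximum-likelihood factor analysis (scikit-learn) with varimax rotation
on per-series standardized data (population-SD convention, matching the
FA likelihood so a noiseless rank-K structure yields communalities
summing to 1). One row per (eye, visit) is the observation unit; K is a
required user choice (default 30 to match the reference architecture),
never inferred. Factors are oriented so their strongest series loads
positively and ordered by explained variance. Scores are
regression-method posterior means E[f|x] = (I + ΛᵀΨ⁻¹Λ)⁻¹ΛᵀΨ⁻¹x from
stored loadings and scaling constants, so new data are scorable without
refitting. Each factor is tagged with the ETDRS subfields of its strong
loadings (|λ| ≥ 0.3), flagging the "MacTel area" (subfield 5, temporal
inner) and "progression areas" (subfields 2–4).

## Endophenotype association

REML linear mixed models: endophenotype ~ predictor with random
intercepts for patient and eye-within-patient (variance component on
eye id). Predictors are additively coded risk-allele dosages or
standardized PRSs; no fixed covariates by default (sex/PC1 available as
options), and visit time enters only through the random structure.
Random slopes are deliberately not fitted — the default model claims
only the nested-intercept structure. A variance component estimated at
numerical zero sets a boundary flag rather than failing. Multiplicity
over the predictor × endophenotype grid is one global family corrected
by the two-stage adaptive Benjamini–Hochberg procedure (statsmodels
`fdr_tsbh`), with adjusted values floored at the raw p so the procedure
is never reported as anti-conservative. Loci are clustered on their
coefficient profiles by complete-linkage agglomerative clustering on
Euclidean distances (both configurable), exported as a Newick merge
tree.

## Numerical and design notes

- Logistic fits: statsmodels Newton, 100-iteration cap; non-convergence
  and separation raise a `FitError` with diagnostics rather than
  returning silent estimates.
- The batched scan solver and the statsmodels path are cross-checked in
  tests; the scan never reuses statsmodels internally, keeping the
  conformance check a genuine dual route.
- BH and two-stage adaptive BH come from statsmodels and are tested
  against a from-the-definition step-up oracle.
- Degenerate inputs are first-class: zero-variance scores, all-missing
  SNPs, fully missing phenotype tables, empty instrument overlaps,
  sparse 2×2 tables and <3-instrument Egger calls each raise a typed
  error.

## Problem sizes for verification

The calibration/recovery experiments (`mactelkit.evaluation`, run by
both `tests/test_acceptance.py` and `scripts/acceptance.py`) use: 100
replicate cohorts of n = 2000 (400 cases) for MR sign recovery at
liability coefficient 0.5; 200 such cohorts for the null type-I error;
100 two-trait cohorts with 8/10 shared instruments (score correlation
≈0.8) for conditional selection; 500 20-instrument replicates for Egger
calibration; one 10,000-SNP null cohort for scan inflation; a 40-series
× 5-factor retina (200 patients) for loading recovery, a 119 × 30
configuration being structurally identical but slower; and 50 LMM
replicates of 400 patients × 2 eyes × 3 visits with a 0.4-per-allele
effect. The demo pipeline uses 1200 subjects (260 cases) and 60 SNPs,
sized so the serine selection is reliably powered while the full run
stays under ~10 s.

## Known limitations

- Two-sample summary-statistic MR estimators (IVW, weighted median,
  mode) are out of scope; only the individual-level allele-score method
  is implemented.
- No LD simulation, reference-panel clumping, or annotation of loci;
  peak windows are positional only.
- The generator's retinal phenotypes are continuous and
  missing-completely-at-random; ordinal grades and informative
  missingness would need an extension.
- Endophenotypes get systematic ids (`endo_00`, ...); clinical naming
  is a documentation concern outside the model.
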