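# mactelkit

Post-GWAS causal dissection for macular telangiectasia type 2
(MacTel)-style case/control cohorts: polygenic allele scores,
individual-level Mendelian randomisation with conditional selection and
Egger pleiotropy testing, PRS-conditioned and interaction genome-wide
scans, and factor-analysis retinal endophenotypes with linear
mixed-model association.

MacTel is a rare bilateral macular degeneration whose risk loci point at
serine/glycine metabolism, retinal vascular calibre and type 2 diabetes.
The scientific question the pipeline addresses is *which of these
correlated traits actually drives disease*. Because the real genotypes
are access-controlled, the package ships a seeded synthetic-cohort
generator that reproduces the statistical structure those analyses rely
on (shared instruments between serine and glycine, a liability-threshold
disease model with case enrichment, latent-factor retinal phenotypes on
the 9-subfield ETDRS grid), so every stage is fully testable.

## The statistics

**Allele scores.** For a trait with externally estimated per-allele
weights *w<sub>j</sub>* on independent instrument SNPs, each subject's
score is *S<sub>i</sub>* = Σ<sub>j</sub> *w<sub>j</sub> g<sub>ij</sub>*
over harmonised dosages, standardized within the cohort. Logistic
regression of case status on the score (adjusting for sex and the first
genotype PC) gives the MR estimate: log-odds per score SD.

**Conditional selection.** The most significant score is iteratively
added as a covariate and the remaining scores re-tested, FDR-adjusting
(Benjamini–Hochberg) within each round, until nothing survives at 5%.
A trait whose score merely proxies a causal one (serine vs glycine)
drops out once the causal score is conditioned on.

**Egger test.** Regressing the instruments' disease effects on their
trait effects, *b<sub>y</sub>* = *b*₀ + *b*₁ *b<sub>x</sub>*, a nonzero
intercept *b*₀ flags directional pleiotropy; the unweighted ("simple
regression line") fit is the default, inverse-variance weighting is an
option.

**Scans.** Per-SNP logistic models — dosage + sex + PC1 + conditioning
PRSs, optionally a dosage × PRS interaction term — fitted by a batched
Newton–Raphson; genomic inflation λ = median(χ²)/0.4549 and greedy peak
calling at 5×10⁻⁸.

**Endophenotypes.** Longitudinal retinal measurements (phenotype ×
ETDRS subfield series over visits on both eyes) are cleaned, imputed,
and collapsed by maximum-likelihood factor analysis with varimax
rotation into latent endophenotypes; association with risk-allele
dosages or PRSs uses REML linear mixed models with random intercepts
for patient and eye-within-patient, corrected by a two-stage adaptive
Benjamini–Hochberg procedure, and loci are clustered on their
coefficient profiles.

## Worked example

```bash
mactelkit run --out-dir demo --seed 1
```

runs the bundled demo configuration (1200 subjects, 260 cases, 60 SNPs,
six traits with serine causally protective and T2D weakly causal) and
writes every stage output under `demo/`. Highlights of what it prints
(`mr_marginal.tsv`, `mr_conditional.tsv`, `quintile_or.tsv`,
`lambda_gc.tsv`):

```
            target    beta     or  ci_low  ci_high      p  p_fdr
            serine -0.5017 0.6055  0.5199   0.7052 0.0000 0.0000
           glycine -0.3460 0.7075  0.6107   0.8196 0.0000 0.0000
         threonine -0.0361 0.9646  0.8371   1.1114 0.6176 0.7399
               t2d  0.0704 1.0729  0.9319   1.2353 0.3277 0.6553
arteriolar_calibre  0.0237 1.0240  0.8903   1.1777 0.7399 0.7399
   venular_calibre -0.0352 0.9655  0.8376   1.1128 0.6276 0.7399
selected: ['serine']
quintile:  trait    or  ci_low  ci_high   p
          serine 5.861   3.532    9.723 0.0
      model  lambda_gc
conditional     1.0268
```

Read: the serine PRS is strongly protective (OR 0.61 per SD); glycine
looks associated marginally but is *not* selected once serine is
conditioned on — its signal came from shared instruments — and the
lowest serine-PRS quintile carries ~5.9-fold odds versus the top
quintile. The genome-wide scan conditioned on serine and glycine PRSs
is well calibrated (λ ≈ 1.03). The clustering stage then groups the
serine instrument SNP with the serine PRS by their endophenotype
coefficient profiles (`locus_clusters.nwk`).

The same stages are available individually (`mactelkit simulate`,
`score`, `mr`, `scan`, `endopheno`, `endo-assoc`) and as library
functions under `mactelkit.*`.

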