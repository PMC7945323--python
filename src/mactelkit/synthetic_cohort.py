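"""Seeded synthetic cohorts with the structure the downstream stages assume.

Real MacTel genotypes are access-controlled, so every analysis stage in
this package is exercised on simulated data that reproduces the relevant
statistical structure: independent instrument SNPs in Hardy-Weinberg
equilibrium, genetically determined quantitative traits (serum
metabolites, vascular calibre, T2D liability) built from those SNPs, a
liability-threshold disease model with configurable causal trait
effects, case enrichment to a case:control ratio typical of a rare-
disease cohort (~476:1733), and a longitudinal retinal-phenotype table
generated from latent factors measured on the 9 ETDRS subfields over
repeated visits on both eyes.

Serine and glycine are modelled as genetically correlated: their
instrument sets share SNPs and their residuals are correlated, which is
what makes the conditional Mendelian-randomisation stage informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .containers import CohortGenotypes, InstrumentSet, validate_retinal_table
from .errors import ConfigurationError, DimensionError, SamplingError

__all__ = [
    "TraitArchitecture", "SimulationConfig", "default_config",
    "simulate_genotypes", "simulate_traits_and_disease", "simulate_cohort",
    "simulate_retina", "default_retina_loadings", "instrument_sets",
]

# non-palindromic allele pairs only: the scoring stage drops A/T and C/G
# SNPs, so the generator avoids emitting them by default
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class TraitArchitecture:
    """Genetic architecture of one quantitative trait.

    ``snp_indices`` point into the simulated SNP panel; index sets may
    overlap across traits (shared instruments are how the serine/glycine
    genetic correlation is induced).  ``residual_corr`` maps other trait
    names to the correlation of the non-genetic residuals.
    """

    name: str
    snp_indices: list
    effects: list
    residual_sd: float = 1.0
    residual_corr: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.snp_indices) != len(self.effects):
            raise ConfigurationError(
                f"trait {self.name}: snp_indices and effects lengths differ")
        if self.residual_sd < 0:
            raise ConfigurationError(
                f"trait {self.name}: residual_sd must be non-negative")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with one master seed.

    Defaults emulate the study conditions this package targets: a cohort
    of 2209 subjects with 476 cases, per-trait instrument sets of 2-50
    SNPs, a causal (protective) serine effect on a liability-threshold
    disease with a smaller T2D contribution, and 119 retinal phenotype
    series generated from 30 latent factors on the 9-subfield ETDRS grid.
    """

    n_subjects: int = 2209
    n_cases_target: int | None = 476
    n_snps: int = 120
    maf_range: tuple = (0.05, 0.5)
    traits: list = field(default_factory=list)
    causal_effects: dict = field(default_factory=dict)
    disease_prevalence: float = 0.1
    sex_effect: float = 0.25
    pc1_effect: float = 0.25
    liability_noise_sd: float = 1.0
    # retinal stage
    n_patients_retina: int = 455
    n_phenotypes: int = 119
    n_factors: int = 30
    n_visits_mean: float = 3.6
    retina_patient_sd: float = 0.7
    retina_eye_sd: float = 0.4
    retina_visit_sd: float = 0.3
    retina_noise_sd: float = 0.5
    retina_missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_snps", "n_patients_retina",
                     "n_phenotypes", "n_factors"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_visits_mean <= 0:
            raise ConfigurationError("n_visits_mean must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi < 1")
        if not 0 < self.disease_prevalence < 1:
            raise ConfigurationError("disease_prevalence must lie in (0, 1)")
        if self.n_cases_target is not None and not \
                0 < self.n_cases_target < self.n_subjects:
            raise ConfigurationError(
                "n_cases_target must lie in (0, n_subjects)")
        if not 0 <= self.retina_missing_fraction < 1:
            raise ConfigurationError(
                "retina_missing_fraction must lie in [0, 1)")
        trait_names = {t.name for t in self.traits}
        if len(trait_names) != len(self.traits):
            raise ConfigurationError("trait names must be unique")
        for t in self.traits:
            for j in t.snp_indices:
                if not 0 <= j < self.n_snps:
                    raise ConfigurationError(
                        f"trait {t.name}: snp index {j} outside panel "
                        f"of {self.n_snps} SNPs")
            for other in t.residual_corr:
                if other not in trait_names:
                    raise ConfigurationError(
                        f"trait {t.name}: residual_corr names unknown "
                        f"trait {other!r}")
        for name in self.causal_effects:
            if name not in trait_names:
                raise ConfigurationError(
                    f"causal_effects names undefined trait {name!r}")

    @property
    def trait_names(self) -> list:
        return [t.name for t in self.traits]

    def pool_size(self) -> int:
        """Subjects to simulate before case enrichment.

        Enrichment keeps all liability-threshold cases, so the pool must
        be large enough for the expected case yield to exceed the target
        with margin.
        """
        if self.n_cases_target is None:
            return self.n_subjects
        need = int(math.ceil(self.n_cases_target / self.disease_prevalence))
        return max(self.n_subjects, int(need * 1.3))


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The reference cohort architecture.

    Six traits: serine (5 instruments), glycine (9 instruments, 4 shared
    with serine, residual correlation 0.5), threonine (3, a null control
    trait), T2D (20 small-effect instruments), and arteriolar/venular
    calibre (2 instruments each, one shared).  Causal liability effects:
    serine -0.5 (protective) and T2D +0.15; all other traits are
    non-causal and pick up signal only through sharing.
    """
    traits = [
        TraitArchitecture("serine", [0, 1, 2, 3, 4],
                          [0.35, 0.30, 0.28, 0.25, 0.22],
                          residual_sd=1.0, residual_corr={"glycine": 0.5}),
        TraitArchitecture("glycine", [1, 2, 3, 4, 5, 6, 7, 8, 9],
                          [0.28, 0.26, 0.24, 0.20, 0.30, 0.26, 0.22,
                           0.20, 0.18],
                          residual_sd=1.0, residual_corr={"serine": 0.5}),
        TraitArchitecture("threonine", [10, 11, 12], [0.30, 0.25, 0.22]),
        TraitArchitecture("t2d", list(range(13, 33)),
                          [0.08, 0.09, 0.10, 0.10, 0.11, 0.11, 0.12, 0.12,
                           0.12, 0.13, 0.13, 0.13, 0.14, 0.14, 0.15, 0.15,
                           0.16, 0.16, 0.17, 0.18]),
        TraitArchitecture("arteriolar_calibre", [33, 34], [0.30, 0.25]),
        TraitArchitecture("venular_calibre", [34, 35], [0.28, 0.24]),
    ]
    cfg = dict(
        traits=traits,
        causal_effects={"serine": -0.5, "t2d": 0.15},
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def simulate_genotypes(config: SimulationConfig,
                       n_subjects: int | None = None) -> CohortGenotypes:
    """Draw a dosage matrix under Hardy-Weinberg equilibrium.

    Each SNP gets a minor-allele frequency uniform on ``maf_range``;
    dosages are Binomial(2, maf) counts of the effect allele.  Sex is
    Bernoulli(1/2) and PC1 standard normal.  Deterministic given the
    config seed.
    """
    rng = stage_rng(config.seed, "genotypes")
    n = config.pool_size() if n_subjects is None else n_subjects
    s = config.n_snps
    mafs = rng.uniform(*config.maf_range, size=s)
    dosages = rng.binomial(2, mafs, size=(n, s)).astype(float)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=s)
    eff = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oth = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    return CohortGenotypes(
        subject_ids=np.array([f"S{i:06d}" for i in range(n)]),
        snp_ids=np.array([f"rs{10001 + 13 * j}" for j in range(s)]),
        effect_alleles=eff,
        other_alleles=oth,
        dosages=dosages,
        sex=rng.integers(0, 2, size=n).astype(float),
        pc1=rng.standard_normal(n),
        chrom=np.repeat("1", s),
        pos=(np.arange(s) * 500_000 + 100_000).astype(int),
        mafs=mafs,
    )


def _genetic_components(genotypes: CohortGenotypes,
                        config: SimulationConfig) -> pd.DataFrame:
    comps = {}
    for t in config.traits:
        g = genotypes.dosages[:, t.snp_indices]
        comps[t.name] = g @ np.asarray(t.effects, float)
    return pd.DataFrame(comps, index=genotypes.subject_ids)


def _residual_cov(config: SimulationConfig) -> np.ndarray:
    k = len(config.traits)
    sds = np.array([t.residual_sd for t in config.traits])
    cov = np.diag(sds ** 2)
    names = config.trait_names
    for i, t in enumerate(config.traits):
        for other, rho in t.residual_corr.items():
            j = names.index(other)
            cov[i, j] = cov[j, i] = rho * sds[i] * sds[j]
    try:
        np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError:
        raise ConfigurationError(
            "residual_corr entries do not form a positive-definite "
            "covariance") from None
    return cov


def simulate_traits_and_disease(
        genotypes: CohortGenotypes, config: SimulationConfig,
) -> tuple[pd.DataFrame, CohortGenotypes]:
    """Trait values, liability-threshold status, and case enrichment.

    Each trait is its genetic component plus a (possibly cross-trait
    correlated) Gaussian residual.  Disease liability sums the causal
    trait coefficients applied to the *genetic* trait components, the
    sex and PC1 nuisance effects, and unit-free Gaussian noise; subjects
    above the liability quantile matching the configured prevalence are
    cases.  When ``n_cases_target`` is set, the returned cohort keeps a
    random subset of cases of exactly that size plus controls filling up
    ``n_subjects``, mimicking a case-enriched study design rather than
    population sampling.

    Returns the trait table (aligned to the returned cohort) and a copy
    of the genotypes restricted to the sampled subjects with ``status``
    filled in.
    """
    rng = stage_rng(config.seed, "traits")
    n = genotypes.n_subjects
    gcomp = _genetic_components(genotypes, config)
    k = len(config.traits)
    if k:
        cov = _residual_cov(config)
        # svd handles the semi-definite case (zero residual SDs) too
        resid = rng.multivariate_normal(np.zeros(k), cov, size=n,
                                        method="svd")
    else:
        resid = np.zeros((n, 0))
    traits = gcomp + resid

    liability = rng.normal(0.0, config.liability_noise_sd, size=n)
    for name, c in config.causal_effects.items():
        liability += c * gcomp[name].to_numpy()
    liability += config.sex_effect * genotypes.sex
    liability += config.pc1_effect * genotypes.pc1
    threshold = np.quantile(liability, 1.0 - config.disease_prevalence)
    status = (liability > threshold).astype(int)

    if config.n_cases_target is None:
        out = replace(genotypes, status=status)
        if n != config.n_subjects:
            keep = np.sort(rng.choice(n, size=config.n_subjects,
                                      replace=False))
            out = out.subset_subjects(keep)
            out = replace(out, status=status[keep])
            traits = traits.iloc[keep]
        return traits, out

    cases = np.flatnonzero(status == 1)
    controls = np.flatnonzero(status == 0)
    n_ctrl = config.n_subjects - config.n_cases_target
    if cases.size < config.n_cases_target or controls.size < n_ctrl:
        raise SamplingError(
            f"pool of {n} subjects yielded {cases.size} cases and "
            f"{controls.size} controls; cannot enrich to "
            f"{config.n_cases_target}:{n_ctrl} — raise disease_prevalence "
            "or the pool size")
    keep = np.sort(np.concatenate([
        rng.choice(cases, size=config.n_cases_target, replace=False),
        rng.choice(controls, size=n_ctrl, replace=False),
    ]))
    out = genotypes.subset_subjects(keep)
    out = replace(out, status=status[keep])
    return traits.iloc[keep], out


def simulate_cohort(config: SimulationConfig,
                    ) -> tuple[CohortGenotypes, pd.DataFrame]:
    """Genotypes -> traits -> liability -> enriched case/control cohort."""
    pool = simulate_genotypes(config)
    traits, cohort = simulate_traits_and_disease(pool, config)
    return cohort, traits


def instrument_sets(config: SimulationConfig,
                    genotypes: CohortGenotypes) -> dict:
    """Emit the per-trait instrument-weight tables the generator used.

    These stand in for externally estimated genome-wide-significant
    weights (SNP id, effect allele, other allele, per-allele weight),
    i.e. the table an analyst would download from the trait GWAS.
    """
    out = {}
    for t in config.traits:
        idx = np.asarray(t.snp_indices, int)
        out[t.name] = InstrumentSet(
            trait_name=t.name,
            table=pd.DataFrame({
                "snp_id": genotypes.snp_ids[idx],
                "effect_allele": genotypes.effect_alleles[idx],
                "other_allele": genotypes.other_alleles[idx],
                "weight": np.asarray(t.effects, float),
                "source_pvalue": np.full(idx.size, 1e-9),
            }),
            genome_wide=True,
        )
    return out


def default_retina_loadings(config: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            ) -> np.ndarray:
    """A sparse phenotypes x factors loading matrix.

    Phenotype series are assigned round-robin to factors with a primary
    loading in [0.6, 0.9] and small Gaussian cross-loadings, so every
    factor carries at least one strong series and the matrix is
    recoverable by factor analysis.
    """
    rng = rng or stage_rng(config.seed, "retina-loadings")
    p, k = config.n_phenotypes, config.n_factors
    lam = rng.normal(0.0, 0.04, size=(p, k))
    primary = np.arange(p) % k
    lam[np.arange(p), primary] = rng.uniform(0.6, 0.9, size=p)
    return lam


def _series_labels(n_phenotypes: int) -> pd.DataFrame:
    """Phenotype series j -> (name, ETDRS subfield) labels."""
    names = [f"ph{j // 9:03d}" for j in range(n_phenotypes)]
    subfields = [(j % 9) + 1 for j in range(n_phenotypes)]
    return pd.DataFrame({"phenotype": names, "subfield": subfields})


def simulate_retina(config: SimulationConfig,
                    true_loadings: np.ndarray,
                    genetic_effects: dict | None = None,
                    predictors: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, dict]:
    """Longitudinal retinal phenotypes generated from latent factors.

    Per (patient, eye, visit) the K-vector of factor scores is the
    patient's genetic shift (``genetic_effects`` applied to the
    ``predictors`` values), a patient random intercept, an eye random
    intercept nested in patient, and visit-level noise; phenotype values
    are ``loadings @ factors`` plus measurement noise, with a
    missing-completely-at-random fraction blanked out.

    Returns the long-format table plus a ``truth`` dict holding the
    factor-score table and the predictor values, for recovery tests.
    """
    rng = stage_rng(config.seed, "retina")
    lam = np.asarray(true_loadings, float)
    if lam.shape[0] != config.n_phenotypes:
        raise DimensionError(
            f"loadings have {lam.shape[0]} rows; config.n_phenotypes is "
            f"{config.n_phenotypes}")
    if lam.shape[1] != config.n_factors:
        raise DimensionError(
            f"loadings have {lam.shape[1]} columns; config.n_factors is "
            f"{config.n_factors}")
    k = config.n_factors
    n_pat = config.n_patients_retina
    patients = np.array([f"RP{i:05d}" for i in range(n_pat)])

    genetic_effects = genetic_effects or {}
    if predictors is None:
        # standalone use: simulate an additive dosage per named predictor
        predictors = pd.DataFrame(
            {name: rng.binomial(2, 0.3, size=n_pat).astype(float)
             for name in genetic_effects}, index=patients)
    else:
        predictors = predictors.reindex(patients)
        missing = [p for p in genetic_effects if p not in predictors.columns]
        if missing:
            raise DimensionError(
                f"predictors table lacks columns for effects: {missing}")

    shift = np.zeros((n_pat, k))
    for name, eff in genetic_effects.items():
        eff = np.asarray(eff, float)
        if eff.shape != (k,):
            raise DimensionError(
                f"genetic effect for {name!r} must be a length-{k} vector")
        shift += np.outer(predictors[name].to_numpy(float), eff)

    labels = _series_labels(config.n_phenotypes)
    rows = []
    factor_rows = []
    for i, pat in enumerate(patients):
        b_pat = rng.normal(0.0, config.retina_patient_sd, size=k)
        for eye in ("OD", "OS"):
            b_eye = rng.normal(0.0, config.retina_eye_sd, size=k)
            n_visits = 1 + rng.poisson(max(config.n_visits_mean - 1.0, 0.0))
            t = 0.0
            for v in range(n_visits):
                if v > 0:
                    t += rng.uniform(0.5, 2.0)
                f = (shift[i] + b_pat + b_eye
                     + rng.normal(0.0, config.retina_visit_sd, size=k))
                values = lam @ f + rng.normal(
                    0.0, config.retina_noise_sd, size=config.n_phenotypes)
                rows.append((pat, eye, v, round(t, 3), values))
                factor_rows.append((pat, eye, v, f))

    frames = []
    for pat, eye, v, t, values in rows:
        df = labels.copy()
        df.insert(0, "visit_time", t)
        df.insert(0, "visit_index", v)
        df.insert(0, "eye", eye)
        df.insert(0, "patient_id", pat)
        df["value"] = values
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if config.retina_missing_fraction > 0:
        mask = rng.random(len(table)) < config.retina_missing_fraction
        table.loc[mask, "value"] = np.nan
    validate_retinal_table(table)

    factors = pd.DataFrame(
        [(p, e, v) for p, e, v, _ in factor_rows],
        columns=["patient_id", "eye", "visit_index"])
    factors = pd.concat(
        [factors, pd.DataFrame([f for *_, f in factor_rows],
                               columns=[f"factor_{j:02d}" for j in range(k)])],
        axis=1)
    truth = {"factors": factors, "predictors": predictors,
             "loadings": lam, "series": labels}
    return table, truth
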