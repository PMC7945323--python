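"""Scan statistics: conformance with reference logistic fits, null
calibration, inflation factor closed forms, and peak calling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api
from scipy import stats

from mactelkit.association_scan import (ScanResult, call_peaks,
                                        genomic_inflation, scan)
from mactelkit.errors import DomainError
from mactelkit.synthetic_cohort import (SimulationConfig, TraitArchitecture,
                                        default_config, simulate_cohort,
                                        simulate_genotypes,
                                        simulate_traits_and_disease)

from conftest import make_cohort


@pytest.fixture(scope="module")
def null_cohort():
    """2000 subjects, no causal SNPs, enriched to 400 cases."""
    cfg = default_config(seed=21, n_subjects=2000, n_cases_target=400,
                         n_snps=300, traits=[], causal_effects={})
    cohort, _ = simulate_cohort(cfg)
    return cohort


def test_scan_coefficients_match_statsmodels_oracle(null_cohort):
    cohort = null_cohort
    res = scan(cohort)
    y = cohort.status.astype(float)
    base = np.column_stack([np.ones(cohort.n_subjects), cohort.sex,
                            cohort.pc1])
    for j in range(20):
        X = np.column_stack([base, cohort.dosages[:, j]])
        fit = sm_api.Logit(y, X).fit(disp=0)
        row = res.table.iloc[j]
        assert row["beta"] == pytest.approx(fit.params[3], abs=1e-6)
        assert row["se"] == pytest.approx(fit.bse[3], abs=1e-6)


def test_interaction_coefficient_matches_statsmodels(null_cohort):
    cohort = null_cohort
    rng = np.random.default_rng(2)
    partner = rng.standard_normal(cohort.n_subjects)
    res = scan(cohort, conditioning_scores={"prs": partner},
               interaction_with="prs")
    y = cohort.status.astype(float)
    base = np.column_stack([np.ones(cohort.n_subjects), cohort.sex,
                            cohort.pc1, partner])
    for j in (0, 5, 11):
        g = cohort.dosages[:, j]
        X = np.column_stack([base, g, g * partner])
        fit = sm_api.Logit(y, X).fit(disp=0)
        row = res.table.iloc[j]
        assert row["model"] == "interaction"
        assert row["beta"] == pytest.approx(fit.params[5], abs=1e-6)


def test_interaction_partner_snp_excluded_from_scan(null_cohort):
    cohort = null_cohort
    partner = cohort.snp_ids[3]
    res = scan(cohort, interaction_with=partner)
    assert partner not in set(res.table["snp_id"])


def test_null_scan_rejection_rate_and_lambda(null_cohort):
    res = scan(null_cohort)
    frac = float((res.table["p"] < 0.05).mean())
    assert abs(frac - 0.05) < 0.03
    assert 0.8 < res.lambda_gc < 1.2  # 300 SNPs: generous band


def test_causal_snp_attains_minimum_p():
    cfg = SimulationConfig(
        n_subjects=2000, n_cases_target=400, n_snps=50,
        traits=[TraitArchitecture("expo", [7], [1.0], residual_sd=0.0)],
        causal_effects={"expo": 0.6}, disease_prevalence=0.2, seed=23)
    cohort, _ = simulate_cohort(cfg)
    res = scan(cohort)
    best = res.table.loc[res.table["p"].idxmin(), "snp_id"]
    assert best == cohort.snp_ids[7]


def test_conditioning_on_causal_score_attenuates_its_snp():
    """Conditioning the scan on a score built from the causal SNP must
    drive that SNP's p toward the null (the independence logic used to
    separate loci from metabolic drivers)."""
    cfg = SimulationConfig(
        n_subjects=2000, n_cases_target=400, n_snps=50,
        traits=[TraitArchitecture("expo", [7], [1.0], residual_sd=0.0)],
        causal_effects={"expo": 0.6}, disease_prevalence=0.2, seed=24)
    cohort, _ = simulate_cohort(cfg)
    marginal = scan(cohort)
    g = cohort.dosages[:, 7]
    rng = np.random.default_rng(0)
    proxy = g + rng.normal(0, 0.3, g.size)  # near-collinear score proxy
    prs = (proxy - proxy.mean()) / proxy.std(ddof=1)
    cond = scan(cohort, conditioning_scores={"expo_prs": prs})
    p_marg = marginal.table.set_index("snp_id").loc[cohort.snp_ids[7], "p"]
    p_cond = cond.table.set_index("snp_id").loc[cohort.snp_ids[7], "p"]
    assert p_marg < 1e-8
    assert p_cond > 1e4 * p_marg  # massively attenuated


def test_pure_noise_covariate_leaves_betas_stable(null_cohort):
    rng = np.random.default_rng(6)
    noise = rng.standard_normal(null_cohort.n_subjects)
    plain = scan(null_cohort)
    noisy = scan(null_cohort, conditioning_scores={"noise": noise})
    merged = plain.table.merge(noisy.table, on="snp_id",
                               suffixes=("_plain", "_noisy"))
    shift = merged["beta_noisy"] - merged["beta_plain"]
    within = np.abs(shift) < 2 * merged["se_plain"]
    assert within.mean() > 0.95
    assert abs(np.median(shift)) < 0.02


def test_monomorphic_snps_skipped_with_reason():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, size=(200, 3)).astype(float)
    d[:, 1] = 0.0
    cohort = make_cohort(d, status=rng.integers(0, 2, 200),
                         sex=rng.integers(0, 2, 200),
                         pc1=rng.standard_normal(200))
    res = scan(cohort)
    assert list(res.skipped_monomorphic) == ["rs1"]
    assert set(res.table["snp_id"]) == {"rs0", "rs2"}


# ---- genomic inflation ----------------------------------------------------

def test_lambda_is_one_when_median_p_is_half():
    p = [0.1, 0.25, 0.5, 0.75, 0.9]
    assert genomic_inflation(p) == pytest.approx(1.0, abs=1e-6)


def test_lambda_closed_form_for_constant_p():
    lam = genomic_inflation([0.001] * 7)
    assert lam == pytest.approx(stats.chi2.isf(0.001, 1) / 0.4549364,
                                rel=1e-9)


def test_lambda_near_one_for_uniform_p():
    rng = np.random.default_rng(4)
    lam = genomic_inflation(rng.random(10_000))
    assert 0.95 < lam < 1.05


def test_lambda_rejects_bad_domain():
    with pytest.raises(DomainError):
        genomic_inflation([])
    with pytest.raises(DomainError):
        genomic_inflation([0.0, 0.5])


# ---- peak calling ---------------------------------------------------------

def _scan_result(p, pos=None, snp_ids=None):
    n = len(p)
    table = pd.DataFrame({
        "snp_id": snp_ids or [f"rs{j:03d}" for j in range(n)],
        "chrom": "1",
        "pos": pos if pos is not None else np.arange(n) * 100_000,
        "beta": 0.0, "se": 1.0, "p": p, "n": 100, "model": "marginal",
        "interaction_partner": "",
    })
    return ScanResult(table=table, lambda_gc=1.0, model="marginal")


def test_no_peaks_above_threshold():
    res = _scan_result([0.5, 1e-6, 0.2])
    assert call_peaks(res, threshold=5e-8) == []


def test_two_signals_in_one_window_yield_one_lead():
    p = [0.5] * 10
    p[4], p[5] = 1e-12, 1e-10
    res = _scan_result(p)
    leads = call_peaks(res, threshold=5e-8, window_bp=1_000_000)
    assert leads == ["rs004"]


def test_planted_peaks_match_bruteforce_oracle():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.01, 1, size=200)
    for j in (10, 90, 170):
        p[j] = 10.0 ** -rng.uniform(9, 15)
    res = _scan_result(p)
    leads = call_peaks(res, threshold=5e-8, window_bp=1_000_000)

    # oracle: exhaustive greedy on the definition
    remaining = set(range(200))
    expected = []
    while True:
        cands = [j for j in remaining if p[j] < 5e-8]
        if not cands:
            break
        best = min(cands, key=lambda j: (p[j], f"rs{j:03d}"))
        expected.append(f"rs{best:03d}")
        pos = best * 100_000
        remaining = {j for j in remaining
                     if abs(j * 100_000 - pos) > 1_000_000}
    assert leads == expected
    assert sorted(leads) == ["rs010", "rs090", "rs170"]


def test_tie_break_is_lexicographic_by_snp_id():
    res = _scan_result([1e-12, 0.5, 1e-12],
                       pos=[0, 10_000_000, 20_000_000],
                       snp_ids=["rsB", "rsA", "rsAA"])
    leads = call_peaks(res, threshold=5e-8, window_bp=1_000_000)
    assert leads == ["rsAA", "rsB"]
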