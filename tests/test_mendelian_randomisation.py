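"""MR machinery: logistic association vs an IRLS oracle, BH adjustment
vs its definition, conditional selection, Egger exactness, quintile OR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mactelkit.containers import ScoreMatrix
from mactelkit.errors import (DomainError, FitError,
                              InsufficientInstrumentsError,
                              SparseTableError)
from mactelkit.genetic_scores import build_scores
from mactelkit.mendelian_randomisation import (AssociationResult,
                                               conditional_selection,
                                               egger_test, fdr_adjust,
                                               fit_score_association,
                                               quintile_odds_ratio)
from mactelkit.synthetic_cohort import (default_config, instrument_sets,
                                        simulate_cohort)

from conftest import irls_logistic, make_cohort


def _score_matrix(columns: dict, n):
    names = list(columns)
    return ScoreMatrix(subject_ids=np.array([f"S{i}" for i in range(n)]),
                       trait_names=names,
                       scores=np.column_stack([columns[t] for t in names]),
                       standardized=True)


def _standardize(x):
    return (x - x.mean()) / x.std(ddof=1)


def test_association_result_or_and_ci_transforms():
    r = AssociationResult(target="serine", beta=-0.65, se=0.06,
                          p_raw=1e-10, n=2209)
    assert r.or_value == pytest.approx(np.exp(-0.65), abs=1e-12)
    assert r.ci_low == pytest.approx(np.exp(-0.65 - 1.96 * 0.06), abs=1e-9)
    assert r.ci_high == pytest.approx(np.exp(-0.65 + 1.96 * 0.06), abs=1e-9)
    # the published serine coefficient exponentiates to the published OR
    assert round(r.or_value, 2) == 0.52


def test_logistic_fit_matches_irls_oracle_on_small_fixture():
    rng = np.random.default_rng(7)
    n = 50
    score = _standardize(rng.standard_normal(n))
    sex = rng.integers(0, 2, n).astype(float)
    pc1 = rng.standard_normal(n)
    eta = -0.3 + 0.8 * score + 0.2 * sex
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    cohort = make_cohort(np.zeros((n, 1)), status=y.astype(int),
                         sex=sex, pc1=pc1)
    sm = _score_matrix({"t": score}, n)
    res = fit_score_association(sm, cohort, "t")
    X = np.column_stack([np.ones(n), score, sex, pc1])
    beta, se = irls_logistic(X, y.astype(float))
    assert res.beta == pytest.approx(beta[1], abs=1e-6)
    assert res.se == pytest.approx(se[1], abs=1e-6)


def test_sign_symmetry_negating_score_negates_beta():
    rng = np.random.default_rng(8)
    n = 300
    score = _standardize(rng.standard_normal(n))
    y = (rng.random(n) < 1 / (1 + np.exp(-0.7 * score))).astype(int)
    cohort = make_cohort(np.zeros((n, 1)), status=y,
                         sex=rng.integers(0, 2, n), pc1=rng.standard_normal(n))
    r1 = fit_score_association(_score_matrix({"t": score}, n), cohort, "t")
    r2 = fit_score_association(_score_matrix({"t": -score}, n), cohort, "t")
    assert r2.beta == pytest.approx(-r1.beta, abs=1e-9)
    assert r2.p_raw == pytest.approx(r1.p_raw, abs=1e-9)


def test_conditioning_score_on_itself_is_rank_deficient():
    rng = np.random.default_rng(9)
    n = 200
    score = _standardize(rng.standard_normal(n))
    y = rng.integers(0, 2, n)
    cohort = make_cohort(np.zeros((n, 1)), status=y,
                         sex=rng.integers(0, 2, n),
                         pc1=rng.standard_normal(n))
    sm = _score_matrix({"t": score}, n)
    with pytest.raises(FitError, match="rank"):
        fit_score_association(sm, cohort, "t", extra_covariate_scores=["t"])


# ---- FDR ------------------------------------------------------------------

def _bh_bruteforce(p):
    """Step-up BH from the definition: adj_i = min over j>=i (ranked)
    of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, ranked[i] * m / (i + 1))
        adj[i] = running
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def test_fdr_single_p_unchanged_and_saturation():
    assert fdr_adjust([0.37])[0] == pytest.approx(0.37)
    np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)


def test_fdr_matches_bruteforce_definition():
    p = [0.01, 0.02, 0.03, 0.04]
    np.testing.assert_allclose(fdr_adjust(p), _bh_bruteforce(p), atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
def test_fdr_matches_bruteforce_on_random_inputs(p):
    adj = fdr_adjust(p)
    np.testing.assert_allclose(adj, _bh_bruteforce(p), atol=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-15)


def test_fdr_rejects_out_of_domain():
    with pytest.raises(DomainError):
        fdr_adjust([0.5, 1.5])
    with pytest.raises(DomainError):
        fdr_adjust([])


# ---- conditional selection ------------------------------------------------

def test_no_significant_candidate_gives_empty_selection():
    rng = np.random.default_rng(10)
    n = 400
    y = rng.integers(0, 2, n)
    cohort = make_cohort(np.zeros((n, 1)), status=y,
                         sex=rng.integers(0, 2, n),
                         pc1=rng.standard_normal(n))
    sm = _score_matrix(
        {f"t{j}": _standardize(rng.standard_normal(n)) for j in range(3)}, n)
    selected, trace = conditional_selection(sm, cohort, sm.trait_names)
    assert selected == []
    assert len(trace) == 1


def test_two_independent_causal_traits_both_selected(small_cohort):
    """serine (strong) and t2d (weak) are the causal traits in the
    default architecture; selection finds serine first."""
    cfg, cohort, _ = small_cohort
    sm = build_scores(cohort, instrument_sets(cfg, cohort))
    selected, trace = conditional_selection(sm, cohort, sm.trait_names)
    assert selected and selected[0] == "serine"
    assert len(trace) == len(selected) + 1 or len(trace) == len(selected)


# ---- Egger ----------------------------------------------------------------

def test_egger_exact_proportionality_gives_zero_intercept():
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    fit = egger_test(bx, 0.3 * bx)
    assert fit.intercept == pytest.approx(0.0, abs=1e-10)
    assert fit.slope == pytest.approx(0.3, abs=1e-10)


def test_egger_recovers_constant_pleiotropic_offset():
    bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    fit = egger_test(bx, 0.3 * bx + 0.1)
    assert fit.intercept == pytest.approx(0.1, abs=1e-10)
    assert fit.slope == pytest.approx(0.3, abs=1e-10)


def test_egger_weighted_reduces_to_ols_with_equal_ses():
    rng = np.random.default_rng(11)
    bx = rng.uniform(0.05, 0.5, 10)
    by = 0.25 * bx + rng.normal(0, 0.02, 10)
    unw = egger_test(bx, by)
    w = egger_test(bx, by, disease_effect_ses=np.full(10, 0.3))
    assert w.intercept == pytest.approx(unw.intercept, abs=1e-10)
    assert w.slope == pytest.approx(unw.slope, abs=1e-10)


def test_egger_requires_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        egger_test([0.1, 0.2], [0.03, 0.06])


def test_egger_slope_calibration_under_noise():
    """Slope within 2 SEs of the generating value in >= 95% of
    replicates; intercept test holds its size under no pleiotropy."""
    rng = np.random.default_rng(12)
    hits = 0
    rejects = 0
    n_rep = 300
    for _ in range(n_rep):
        bx = rng.uniform(0.05, 0.5, 20)
        by = 0.25 * bx + rng.normal(0, 0.05, 20)
        fit = egger_test(bx, by)
        if abs(fit.slope - 0.25) < 2 * fit.slope_se:
            hits += 1
        if fit.intercept_p < 0.05:
            rejects += 1
    assert hits / n_rep >= 0.90
    assert abs(rejects / n_rep - 0.05) <= 0.03


# ---- quintile odds ratio --------------------------------------------------

def test_quintile_or_cross_product_oracle():
    # 100 subjects: quintile bins of 20; arrange cases so the contrast
    # table is a=30? -> use a direct construction with known 2x2 counts
    score = np.concatenate([np.full(40, -2.0) + np.arange(40) * 1e-3,
                            np.linspace(-1, 1, 120),
                            np.full(40, 2.0) + np.arange(40) * 1e-3])
    # bottom quintile = 40 lowest, top quintile = 40 highest
    status = np.zeros(200, dtype=int)
    status[:30] = 1          # 30 cases, 10 controls in the bottom bin
    status[160:170] = 1      # 10 cases, 30 controls in the top bin
    r = quintile_odds_ratio(score, status)
    assert r.or_value == pytest.approx(9.0, rel=1e-12)
    assert r.se == pytest.approx(np.sqrt(1/30 + 1/10 + 1/10 + 1/30))


def test_quintile_or_null_score_within_two_ses():
    rng = np.random.default_rng(13)
    score = rng.standard_normal(5000)
    status = rng.integers(0, 2, 5000)
    r = quintile_odds_ratio(score, status)
    assert abs(r.beta) < 2 * r.se


def test_quintile_or_zero_cell_raises():
    score = np.linspace(0, 1, 50)
    status = (score < 0.2).astype(int)  # all cases in the bottom bin
    with pytest.raises(SparseTableError):
        quintile_odds_ratio(score, status)
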