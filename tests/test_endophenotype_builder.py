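"""Cleaning/imputation rules and the factor model: recovery of known
loadings, score round trips, degenerate inputs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from mactelkit.containers import RETINAL_COLUMNS
from mactelkit.endophenotype_builder import (clean_and_impute,
                                             fit_endophenotypes,
                                             pivot_series,
                                             score_endophenotypes)
from mactelkit.errors import DataError, DomainError, SchemaError
from mactelkit.synthetic_cohort import (SimulationConfig,
                                        default_retina_loadings,
                                        simulate_retina)


def _long_table(values, phenotype="ph0", subfield=1, patient="P0",
                eye="OD"):
    """One series observed over visits 0..len-1 at yearly spacing."""
    rows = [(patient, eye, v, float(v), phenotype, subfield, val)
            for v, val in enumerate(values)]
    return pd.DataFrame(rows, columns=RETINAL_COLUMNS)


def test_clean_without_missing_is_identity():
    t = _long_table([1.0, 2.0, 3.0])
    out, report = clean_and_impute(t)
    np.testing.assert_allclose(out["value"], [1.0, 2.0, 3.0])
    assert report.n_missing_before == 0
    assert report.n_imputed_interpolation == 0
    assert report.dropped_series == []


def test_interior_gap_is_linearly_interpolated_in_time():
    # visits at t = 0, 1, 2, 3 with value missing at t=2; linear in time
    # between (1, 4.0) and (3, 8.0) gives 6.0
    t = _long_table([2.0, 4.0, np.nan, 8.0])
    out, report = clean_and_impute(t, max_missing_fraction=0.5)
    assert report.n_imputed_interpolation == 1
    assert out.loc[out["visit_index"] == 2, "value"].item() == \
        pytest.approx(6.0)


def test_leading_gap_falls_back_to_eye_median():
    t = _long_table([np.nan, 4.0, 6.0, 8.0])
    out, report = clean_and_impute(t, max_missing_fraction=0.5)
    assert report.n_imputed_interpolation == 0
    assert report.n_imputed_eye_median == 1
    assert out.loc[out["visit_index"] == 0, "value"].item() == \
        pytest.approx(6.0)  # median of 4, 6, 8


def test_missing_whole_eye_falls_back_to_cohort_median():
    t1 = _long_table([np.nan, np.nan], patient="P0")
    t2 = _long_table([3.0, 5.0, 7.0], patient="P1")
    t = pd.concat([t1, t2], ignore_index=True)
    out, report = clean_and_impute(t, max_missing_fraction=0.5)
    assert report.n_imputed_cohort_median == 2
    assert (out.loc[out["patient_id"] == "P0", "value"] == 5.0).all()


def test_overmissing_series_dropped_to_target_count():
    """143 series, 24 of them above the missingness cap -> 119 kept."""
    rng = np.random.default_rng(31)
    frames = []
    for j in range(143):
        name, sub = f"m{j // 9:03d}", (j % 9) + 1
        for pat in range(6):
            vals = rng.normal(size=4)
            t = _long_table(vals, phenotype=name, subfield=sub,
                            patient=f"P{pat}")
            if j < 24:  # plant heavy missingness in the first 24 series
                t.loc[t.index[:3], "value"] = np.nan
            frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    out, report = clean_and_impute(table, max_missing_fraction=0.2)
    assert report.n_series_before == 143
    assert report.n_series_after == 119
    assert len(report.dropped_series) == 24


def test_fully_missing_table_raises():
    t = _long_table([np.nan, np.nan, np.nan])
    with pytest.raises(DataError):
        clean_and_impute(t)


# ---- factor model ---------------------------------------------------------

def _factor_cfg(**kw):
    base = dict(n_subjects=10, n_cases_target=None, n_snps=2,
                n_patients_retina=120, n_phenotypes=40, n_factors=5,
                n_visits_mean=2.5, retina_missing_fraction=0.0,
                retina_noise_sd=0.3, seed=33)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="module")
def fitted_model():
    cfg = _factor_cfg()
    lam = default_retina_loadings(cfg)
    table, truth = simulate_retina(cfg, lam)
    model = fit_endophenotypes(table, n_factors=5, seed=0)
    return cfg, table, truth, model


def test_known_loadings_recovered(fitted_model):
    """Factor scores correlate > 0.9 with the generating factors after
    greedy alignment on absolute correlation."""
    _, table, truth, model = fitted_model
    scores = score_endophenotypes(model, table)
    merged = scores.merge(truth["factors"],
                          on=["patient_id", "eye", "visit_index"])
    est = merged[model.factor_names].to_numpy()
    true = merged[[f"factor_{k:02d}" for k in range(5)]].to_numpy()
    C = np.corrcoef(est.T, true.T)[:5, 5:]
    r, c = linear_sum_assignment(-np.abs(C))
    assert np.abs(C[r, c]).mean() > 0.9


def test_no_empty_factors(fitted_model):
    *_, model = fitted_model
    assert (np.abs(model.loadings).max(axis=0) > 0.1).all()


def test_sign_convention_strongest_series_loads_positively(fitted_model):
    *_, model = fitted_model
    for k in range(model.loadings.shape[1]):
        j = np.argmax(np.abs(model.loadings[:, k]))
        assert model.loadings[j, k] > 0


def test_pure_noise_data_has_no_dominant_factor():
    cfg = _factor_cfg(n_phenotypes=30, n_factors=3, retina_noise_sd=1.0,
                      retina_patient_sd=0.0, retina_eye_sd=0.0,
                      retina_visit_sd=0.0, seed=34)
    table, _ = simulate_retina(cfg, np.zeros((30, 3)))
    model = fit_endophenotypes(table, n_factors=3, seed=0)
    p = len(model.series)
    n_obs = len(pivot_series(table))
    se = np.sqrt(2.0 / n_obs)  # rough SE of a correlation eigenvalue share
    assert model.variance_explained().max() < 1 / p + 3 * se + 0.05


def test_rank_one_structure_single_factor_explains_everything():
    rng = np.random.default_rng(35)
    signal = rng.standard_normal(60)
    rows = []
    for j in range(6):
        for i, s in enumerate(signal):
            rows.append((f"P{i}", "OD", 0, 0.0, f"c{j}", 1,
                         (j + 1) * s))
    table = pd.DataFrame(rows, columns=RETINAL_COLUMNS)
    model = fit_endophenotypes(table, n_factors=1, seed=0)
    assert model.variance_explained()[0] > 0.99


def test_score_roundtrip_and_column_order_invariance(fitted_model):
    _, table, _, model = fitted_model
    s1 = score_endophenotypes(model, table)
    shuffled = table.sample(frac=1.0, random_state=0)
    s2 = score_endophenotypes(model, shuffled)
    m = s1.merge(s2, on=["patient_id", "eye", "visit_index"],
                 suffixes=("_a", "_b"))
    for k in model.factor_names:
        np.testing.assert_allclose(m[f"{k}_a"], m[f"{k}_b"], atol=1e-8)


def test_centred_observation_scores_zero(fitted_model):
    _, table, _, model = fitted_model
    rows = []
    for s, mu in zip(model.series, model.means):
        name, sub = s.rsplit("|", 1)
        rows.append(("PX", "OD", 0, 0.0, name, int(sub), mu))
    mean_obs = pd.DataFrame(rows, columns=RETINAL_COLUMNS)
    scores = score_endophenotypes(model, mean_obs)
    np.testing.assert_allclose(
        scores[model.factor_names].to_numpy(), 0.0, atol=1e-10)


def test_hand_computed_regression_score_toy_model():
    """3 phenotypes, 1 factor: posterior mean from explicit algebra."""
    from mactelkit.endophenotype_builder import EndophenotypeModel
    lam = np.array([[0.8], [0.6], [0.4]])
    psi = np.array([0.36, 0.64, 0.84])
    model = EndophenotypeModel(
        series=["a|1", "b|1", "c|1"], factor_names=["endo_00"],
        loadings=lam, psi=psi,
        means=np.zeros(3), sds=np.ones(3))
    x = np.array([1.0, -0.5, 0.25])
    rows = [("P0", "OD", 0, 0.0, n, 1, v)
            for n, v in zip("abc", x)]
    table = pd.DataFrame(rows, columns=RETINAL_COLUMNS)
    got = score_endophenotypes(model, table)["endo_00"].iloc[0]
    num = float((lam[:, 0] / psi) @ x)
    den = 1.0 + float((lam[:, 0] ** 2 / psi).sum())
    assert got == pytest.approx(num / den, abs=1e-10)


def test_incomplete_table_and_bad_k_rejected(fitted_model):
    _, table, _, model = fitted_model
    holed = table.copy()
    holed.loc[holed.index[0], "value"] = np.nan
    with pytest.raises(DataError, match="complete"):
        fit_endophenotypes(holed, n_factors=3)
    with pytest.raises(DomainError):
        fit_endophenotypes(table, n_factors=40)


def test_scoring_missing_series_names_them(fitted_model):
    _, table, _, model = fitted_model
    partial = table[table["phenotype"] != "ph000"]
    with pytest.raises(SchemaError, match="ph000"):
        score_endophenotypes(model, partial)


def test_subfield_tags_flag_mactel_and_progression_areas(fitted_model):
    *_, model = fitted_model
    tags = model.subfield_tags()
    assert set(tags["factor"]) == set(model.factor_names)
    got = {int(s) for row in tags["subfields"] for s in row.split(",")}
    assert got <= set(range(1, 10))
    # flags must be consistent with the tag lists
    for _, row in tags.iterrows():
        subs = {int(s) for s in row["subfields"].split(",")}
        assert row["mactel_area"] == (5 in subs)
        assert row["progression_area"] == bool(subs & {2, 3, 4})
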