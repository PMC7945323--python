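import numpy as np
import pandas as pd
import pytest

from mactelkit.containers import CohortGenotypes, InstrumentSet
from mactelkit.synthetic_cohort import (SimulationConfig, TraitArchitecture,
                                        default_config, simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest enriched case/control cohort with the default trait
    architecture (serine causal, T2D weakly causal)."""
    cfg = default_config(seed=11, n_subjects=800, n_cases_target=180)
    cohort, traits = simulate_cohort(cfg)
    return cfg, cohort, traits


def make_cohort(dosages, status=None, sex=None, pc1=None,
                effect_alleles=None, other_alleles=None, snp_ids=None):
    """Hand-built cohort for unit tests."""
    dosages = np.asarray(dosages, float)
    n, s = dosages.shape
    return CohortGenotypes(
        subject_ids=np.array([f"S{i}" for i in range(n)]),
        snp_ids=np.array(snp_ids if snp_ids is not None
                         else [f"rs{j}" for j in range(s)]),
        effect_alleles=np.array(effect_alleles if effect_alleles is not None
                                else ["A"] * s),
        other_alleles=np.array(other_alleles if other_alleles is not None
                               else ["G"] * s),
        dosages=dosages,
        sex=np.zeros(n) if sex is None else np.asarray(sex, float),
        pc1=np.zeros(n) if pc1 is None else np.asarray(pc1, float),
        status=None if status is None else np.asarray(status, int),
    )


def make_instruments(trait, snp_ids, weights, effect_alleles=None,
                     other_alleles=None):
    n = len(snp_ids)
    return InstrumentSet(
        trait_name=trait,
        table=pd.DataFrame({
            "snp_id": snp_ids,
            "effect_allele": effect_alleles or ["A"] * n,
            "other_allele": other_alleles or ["G"] * n,
            "weight": weights,
            "source_pvalue": [1e-9] * n,
        }))


def irls_logistic(X, y, max_iter=100, tol=1e-12):
    """Hand-rolled iteratively reweighted least squares for logistic
    regression — the independent oracle for the model fits."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    cov = np.linalg.inv(X.T @ (X * (1 / (1 + np.exp(-(X @ beta))) *
                                    (1 - 1 / (1 + np.exp(-(X @ beta)))))[:, None]))
    se = np.sqrt(np.diag(cov))
    return beta, se
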