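"""Collapse longitudinal retinal phenotypes into latent endophenotypes.

Spatial retinal measurements arrive as a long table keyed by (patient,
eye, visit, phenotype, ETDRS subfield).  Cleaning drops phenotype x
subfield series whose missingness exceeds a cap and imputes the rest —
within-eye linear interpolation over visit time, falling back to the eye
median and then the cohort series median, a rule chosen to respect the
longitudinal structure.  The complete observation x series matrix is
standardized and reduced by maximum-likelihood factor analysis with
varimax rotation; each factor is an *endophenotype*, a latent trait
summarising correlated raw measurements.  Loadings are exportable and
new observations can be scored (regression-method posterior means)
without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .containers import (MACTEL_AREA_SUBFIELD, PROGRESSION_AREA_SUBFIELDS,
                         validate_retinal_table)
from .errors import DataError, DomainError, SchemaError

__all__ = ["CleaningReport", "EndophenotypeModel", "clean_and_impute",
           "fit_endophenotypes", "score_endophenotypes", "pivot_series"]

OBS_KEY = ["patient_id", "eye", "visit_index", "visit_time"]


def _series_label(phenotype: str, subfield: int) -> str:
    return f"{phenotype}|{int(subfield)}"


def pivot_series(table: pd.DataFrame) -> pd.DataFrame:
    """Long table -> observations x (phenotype|subfield) series matrix."""
    t = table.assign(
        series=[_series_label(p, s)
                for p, s in zip(table["phenotype"], table["subfield"])])
    wide = t.set_index(OBS_KEY + ["series"])["value"].unstack("series")
    return wide


@dataclass
class CleaningReport:
    """Counts from :func:`clean_and_impute`."""

    n_series_before: int
    n_series_after: int
    dropped_series: list
    n_missing_before: int
    n_missing_after: int
    n_imputed_interpolation: int
    n_imputed_eye_median: int
    n_imputed_cohort_median: int


def clean_and_impute(table: pd.DataFrame, max_missing_fraction: float = 0.2,
                     ) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop over-missing series and impute the remaining gaps.

    A phenotype x subfield series with more than ``max_missing_fraction``
    of its cells missing is removed entirely (the report lists them).
    Remaining missing cells are imputed, in order of preference: linear
    interpolation over visit time within the same eye, the same eye's
    series median, then the cohort-wide series median.  The returned
    long table is complete.
    """
    validate_retinal_table(table)
    if table["value"].isna().all():
        raise DataError("retinal phenotype table is fully missing")
    df = table.copy()
    df["series"] = [_series_label(p, s)
                    for p, s in zip(df["phenotype"], df["subfield"])]
    frac = df.groupby("series")["value"].apply(lambda v: v.isna().mean())
    dropped = sorted(frac.index[frac > max_missing_fraction])
    n_before = frac.size
    df = df[~df["series"].isin(dropped)].copy()
    if df.empty:
        raise DataError("every series exceeded the missingness cap")
    n_missing_before = int(df["value"].isna().sum())

    # rule 1: within-eye linear interpolation over visit_time (interior only)
    df = df.sort_values(["patient_id", "eye", "series", "visit_time"])
    values = df["value"].to_numpy(float).copy()
    times = df["visit_time"].to_numpy(float)
    n_interp = 0
    for pos in df.groupby(["patient_id", "eye", "series"],
                          sort=False).indices.values():
        v = values[pos]
        if not np.isnan(v).any():
            continue
        t = times[pos]
        if np.unique(t).size != t.size:  # duplicate times: skip this rule
            continue
        s = pd.Series(v, index=t).interpolate(method="index",
                                              limit_area="inside")
        filled = s.to_numpy()
        n_interp += int((np.isnan(v) & ~np.isnan(filled)).sum())
        values[pos] = filled
    df["value"] = values

    # rule 2: eye median of the series
    eye_med = df.groupby(["patient_id", "eye", "series"])["value"] \
                .transform("median")
    n_eye = int((df["value"].isna() & eye_med.notna()).sum())
    df["value"] = df["value"].fillna(eye_med)

    # rule 3: cohort median of the series
    cohort_med = df.groupby("series")["value"].transform("median")
    n_cohort = int((df["value"].isna() & cohort_med.notna()).sum())
    df["value"] = df["value"].fillna(cohort_med)

    if df["value"].isna().any():
        raise DataError("imputation left missing cells (a series with no "
                        "observed values survived the missingness cap)")
    report = CleaningReport(
        n_series_before=int(n_before),
        n_series_after=int(n_before - len(dropped)),
        dropped_series=list(dropped),
        n_missing_before=n_missing_before,
        n_missing_after=int(df["value"].isna().sum()),
        n_imputed_interpolation=n_interp,
        n_imputed_eye_median=n_eye,
        n_imputed_cohort_median=n_cohort,
    )
    out = df.drop(columns=["series"]).sort_index()
    return out, report


@dataclass
class EndophenotypeModel:
    """Fitted factor model: loadings, uniquenesses, scaling constants.

    ``loadings`` is series x factors (the weight each phenotype series
    has on each endophenotype); ``psi`` the per-series unique variances;
    ``means``/``sds`` the per-series standardization constants.  Each
    factor is oriented so its largest-|loading| series loads positively.
    """

    series: list
    factor_names: list
    loadings: np.ndarray
    psi: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    score_method: str = "regression"
    rotation: str = "varimax"

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.series,
                            columns=self.factor_names)

    def variance_explained(self) -> np.ndarray:
        """Share of total standardized variance carried by each factor."""
        return (self.loadings ** 2).sum(axis=0) / len(self.series)

    def subfield_tags(self, loading_threshold: float = 0.3) -> pd.DataFrame:
        """ETDRS subfields each endophenotype draws on.

        A factor is tagged with the subfields of every series loading
        above the threshold (falling back to its single strongest
        series), and flagged when those include the MacTel-onset area
        (subfield 5) or the progression areas (2-4).
        """
        subf = np.array([int(s.rsplit("|", 1)[1]) for s in self.series])
        rows = []
        for k, name in enumerate(self.factor_names):
            lam = np.abs(self.loadings[:, k])
            strong = lam >= loading_threshold
            if not strong.any():
                strong = lam == lam.max()
            tags = sorted(set(subf[strong]))
            rows.append({
                "factor": name,
                "subfields": ",".join(map(str, tags)),
                "mactel_area": MACTEL_AREA_SUBFIELD in tags,
                "progression_area": any(t in PROGRESSION_AREA_SUBFIELDS
                                        for t in tags),
            })
        return pd.DataFrame(rows)


def fit_endophenotypes(table: pd.DataFrame, n_factors: int,
                       seed: int = 0, rotation: str = "varimax",
                       ) -> EndophenotypeModel:
    """Maximum-likelihood factor analysis of the complete series matrix.

    Each series is standardized first, so loadings live on the
    correlation scale.  ``n_factors`` is a required choice (scree or
    interpretability are the usual guides); it must be smaller than the
    number of series.  Deterministic given ``seed``.
    """
    wide = pivot_series(table)
    if wide.isna().any().any():
        raise DataError("factor analysis requires a complete table; run "
                        "clean_and_impute first")
    p = wide.shape[1]
    if not 0 < n_factors < p:
        raise DomainError(
            f"n_factors must lie in (0, {p}) for {p} series")
    X = wide.to_numpy(float)
    means = X.mean(axis=0)
    # ddof=0 matches the factor-analysis likelihood's variance convention,
    # so a noiseless rank-K structure yields communalities summing to 1
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [wide.columns[j] for j in np.flatnonzero(sds == 0)]
        raise DataError(f"constant (degenerate) series: {bad}")
    Z = (X - means) / sds
    fa = FactorAnalysis(n_components=n_factors,
                        rotation=None if rotation == "none" else rotation,
                        random_state=seed, max_iter=2000)
    fa.fit(Z)
    lam = fa.components_.T.copy()  # series x factors
    psi = np.maximum(fa.noise_variance_.copy(), 1e-8)
    # orient each factor so its strongest series loads positively
    for k in range(n_factors):
        j = np.argmax(np.abs(lam[:, k]))
        if lam[j, k] < 0:
            lam[:, k] = -lam[:, k]
    # order factors by explained variance for a stable, meaningful layout
    order = np.argsort(-(lam ** 2).sum(axis=0), kind="stable")
    lam = lam[:, order]
    return EndophenotypeModel(
        series=list(wide.columns),
        factor_names=[f"endo_{k:02d}" for k in range(n_factors)],
        loadings=lam,
        psi=psi,
        means=means,
        sds=sds,
        rotation=rotation,
    )


def score_endophenotypes(model: EndophenotypeModel, table: pd.DataFrame,
                         ) -> pd.DataFrame:
    """Regression-method factor scores for each (patient, eye, visit).

    Standardizes with the model's stored constants and computes the
    posterior factor means ``E[f|x] = (I + L' Psi^-1 L)^-1 L' Psi^-1 x``,
    so new observations are scorable without refitting.  Missing series
    raise :class:`SchemaError`; individual missing cells are treated as
    mean-level (zero after standardization).
    """
    wide = pivot_series(table)
    missing = [s for s in model.series if s not in wide.columns]
    if missing:
        raise SchemaError(f"table lacks model series: {missing}")
    wide = wide[model.series]
    Z = (wide.to_numpy(float) - model.means) / model.sds
    Z = np.nan_to_num(Z, nan=0.0)
    lam, psi = model.loadings, model.psi
    tmp = lam / psi[:, None]
    M = np.eye(lam.shape[1]) + lam.T @ tmp
    B = tmp @ np.linalg.inv(M)
    scores = Z @ B
    out = wide.index.to_frame(index=False)
    return pd.concat(
        [out, pd.DataFrame(scores, columns=model.factor_names)], axis=1)
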