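"""Individual-level Mendelian randomisation with allele scores.

The causal question — does genetically predicted trait abundance drive
disease risk? — is addressed with the allele-score method for
individual-level data: the standardized polygenic score for each
candidate exposure is tested against case/control status by logistic
regression, adjusting for sex and the first genotype principal
component.  Supporting procedures:

* Benjamini-Hochberg FDR adjustment across the score family;
* iterative conditional selection — the most significant score is added
  as a covariate and all remaining scores re-tested, repeating until no
  score survives FDR correction, which separates primary causal signals
  from traits that merely share instruments with them;
* the Egger intercept test for directional pleiotropy, regressing the
  instruments' disease effects on their trait effects: a nonzero
  intercept flags direct SNP-to-disease paths bypassing the exposure;
* a quintile odds-ratio contrast of the score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .containers import CohortGenotypes, ScoreMatrix
from .errors import (DomainError, FitError, InsufficientInstrumentsError,
                     SparseTableError)

__all__ = [
    "AssociationResult", "EggerFit", "fit_score_association", "fdr_adjust",
    "conditional_selection", "egger_test", "quintile_odds_ratio",
    "results_frame",
]

_Z95 = 1.96  # Wald 95% multiplier on the log-odds scale


@dataclass
class AssociationResult:
    """One score (or SNP) association: log-odds coefficient and derived
    odds-ratio quantities.

    ``beta`` is per standard deviation for scores, per effect allele for
    SNPs.  The OR and its CI are deterministic transforms of (beta, se).
    """

    target: str
    beta: float
    se: float
    p_raw: float
    n: int
    covariates: list = field(default_factory=list)
    p_fdr: float | None = None

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - _Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + _Z95 * self.se))

    def as_dict(self) -> dict:
        return {
            "target": self.target, "beta": self.beta, "se": self.se,
            "or": self.or_value, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p_raw, "p_fdr": self.p_fdr,
            "n": self.n, "covariates": ",".join(self.covariates),
        }


@dataclass
class EggerFit:
    """Egger regression of instrument disease effects on trait effects.

    ``intercept`` estimates the average directional pleiotropy of the
    instrument set; ``slope`` is the Egger causal-effect estimate.
    """

    trait: str
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    intercept_p: float
    slope_p: float
    n_instruments: int
    weighted: bool = False


def results_frame(results) -> pd.DataFrame:
    """Tabulate AssociationResults in the reporting column layout."""
    return pd.DataFrame([r.as_dict() for r in results])


def _logit_fit(X: np.ndarray, y: np.ndarray, target_col: int,
               target: str, covariates, n: int) -> AssociationResult:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(
            f"design matrix is rank deficient fitting {target!r} "
            "(duplicated or collinear covariates)",
            {"rank": int(np.linalg.matrix_rank(X)), "ncol": X.shape[1]})
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # separation, singular Hessian
        raise FitError(f"logistic fit failed for {target!r}: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError(f"logistic fit did not converge for {target!r}",
                       {"mle_retvals": fit.mle_retvals})
    return AssociationResult(
        target=target,
        beta=float(fit.params[target_col]),
        se=float(fit.bse[target_col]),
        p_raw=float(fit.pvalues[target_col]),
        n=n,
        covariates=list(covariates),
    )


def fit_score_association(scores: ScoreMatrix, genotypes: CohortGenotypes,
                          trait: str,
                          extra_covariate_scores=()) -> AssociationResult:
    """Logistic regression of disease status on one standardized score.

    The model is ``status ~ score + sex + pc1 [+ conditioning scores]``;
    the returned coefficient, Wald SE and p-value belong to the score
    term.  Conditioning scores are named in ``extra_covariate_scores``
    and looked up in the same matrix.
    """
    if not scores.standardized:
        raise FitError("scores must be standardized before association "
                       "testing (odds ratios are per score SD)")
    y = np.asarray(genotypes.status, float)
    if genotypes.status is None or len(np.unique(y)) < 2:
        raise FitError("status must contain both cases and controls")
    cols = [scores.column(trait), genotypes.sex, genotypes.pc1]
    covariates = ["sex", "pc1"]
    for name in extra_covariate_scores:
        cols.append(scores.column(name))
        covariates.append(name)
    X = sm.add_constant(np.column_stack(cols), prepend=True)
    return _logit_fit(X, y, target_col=1, target=trait,
                      covariates=covariates, n=len(y))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise DomainError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def conditional_selection(scores: ScoreMatrix, genotypes: CohortGenotypes,
                          candidate_traits, alpha: float = 0.05,
                          ) -> tuple[list, list]:
    """Forward selection of scores independently associated with disease.

    Round r fits every remaining candidate conditioned on all previously
    selected scores, FDR-adjusts the round's p-values as one family, and
    moves the smallest-adjusted-p candidate to the selected list if it
    clears ``alpha``; stops when no candidate passes or none remain.

    Returns the ordered selected list and the per-round trace (a list of
    lists of :class:`AssociationResult`, with ``p_fdr`` filled in; a
    candidate whose fit failed appears with NaN statistics).
    """
    if not candidate_traits:
        raise DomainError("need at least one candidate trait")
    remaining = list(candidate_traits)
    selected: list = []
    trace: list = []
    while remaining:
        round_results = []
        for trait in remaining:
            try:
                res = fit_score_association(scores, genotypes, trait,
                                            extra_covariate_scores=selected)
            except FitError:
                res = AssociationResult(target=trait, beta=np.nan, se=np.nan,
                                        p_raw=np.nan, n=genotypes.n_subjects,
                                        covariates=["sex", "pc1", *selected])
            round_results.append(res)
        ok = [r for r in round_results if np.isfinite(r.p_raw)]
        if ok:
            adj = fdr_adjust([r.p_raw for r in ok])
            for r, a in zip(ok, adj):
                r.p_fdr = float(a)
        trace.append(round_results)
        passing = [r for r in ok if r.p_fdr < alpha]
        if not passing:
            break
        best = min(passing, key=lambda r: (r.p_fdr, r.p_raw))
        selected.append(best.target)
        remaining.remove(best.target)
    return selected, trace


def egger_test(instrument_effects_on_trait, instrument_effects_on_disease,
               disease_effect_ses=None, trait: str = "") -> EggerFit:
    """Egger regression: disease effect = b0 + b1 * trait effect.

    Effect vectors must be aligned by SNP with disease effects oriented
    to the trait-increasing allele.  With ``disease_effect_ses`` the fit
    is inverse-variance weighted; otherwise it is the simple (unweighted)
    regression, which is the default reporting convention here.  At
    least three instruments are required for a finite intercept test.
    """
    bx = np.asarray(instrument_effects_on_trait, float)
    by = np.asarray(instrument_effects_on_disease, float)
    if bx.shape != by.shape or bx.ndim != 1:
        raise DomainError("effect vectors must be 1-D and aligned by SNP")
    if bx.size < 3:
        raise InsufficientInstrumentsError(
            f"Egger regression needs >= 3 instruments, got {bx.size}")
    if np.ptp(bx) == 0:
        raise DomainError(
            "instrument effects on the trait are all equal; Egger "
            "intercept and slope are not separately identifiable")
    X = sm.add_constant(bx, prepend=True, has_constant="add")
    if disease_effect_ses is not None:
        se = np.asarray(disease_effect_ses, float)
        if se.shape != by.shape or np.any(se <= 0):
            raise DomainError("disease effect SEs must be positive and "
                              "aligned with the effects")
        fit = sm.WLS(by, X, weights=1.0 / se**2).fit()
        weighted = True
    else:
        fit = sm.OLS(by, X).fit()
        weighted = False
    return EggerFit(
        trait=trait,
        intercept=float(fit.params[0]), slope=float(fit.params[1]),
        intercept_se=float(fit.bse[0]), slope_se=float(fit.bse[1]),
        intercept_p=float(fit.pvalues[0]), slope_p=float(fit.pvalues[1]),
        n_instruments=int(bx.size), weighted=weighted,
    )


def quintile_odds_ratio(score, status, contrast: tuple = (0, 4),
                        ) -> AssociationResult:
    """Odds ratio contrasting two quintile bins of the score.

    Quintile edges come from the pooled (cases + controls) score
    distribution.  The default contrast compares membership of the
    lowest quintile (bin 0) against the top quintile (bin 4) in a 2x2
    table with the cross-product OR and Woolf SE; a zero cell raises
    :class:`SparseTableError` rather than applying a continuity
    correction.
    """
    s = np.asarray(score, float)
    y = np.asarray(status, int)
    lo_bin, ref_bin = contrast
    if not (0 <= lo_bin <= 4 and 0 <= ref_bin <= 4 and lo_bin != ref_bin):
        raise DomainError("contrast bins must be distinct quintiles 0..4")
    edges = np.quantile(s, [0.2, 0.4, 0.6, 0.8])
    bins = np.searchsorted(edges, s, side="right")
    a = int(np.sum((bins == lo_bin) & (y == 1)))  # cases, contrast bin
    b = int(np.sum((bins == lo_bin) & (y == 0)))
    c = int(np.sum((bins == ref_bin) & (y == 1)))  # cases, reference bin
    d = int(np.sum((bins == ref_bin) & (y == 0)))
    if min(a, b, c, d) == 0:
        raise SparseTableError(
            f"2x2 quintile table has an empty cell (a={a}, b={b}, c={c}, "
            f"d={d}); odds ratio undefined without continuity correction")
    log_or = np.log(a * d / (b * c))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = log_or / se
    from scipy.stats import norm
    p = float(2 * norm.sf(abs(z)))
    return AssociationResult(
        target=f"quintile[{lo_bin}] vs quintile[{ref_bin}]",
        beta=float(log_or), se=se, p_raw=p, n=a + b + c + d,
        covariates=[],
    )
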