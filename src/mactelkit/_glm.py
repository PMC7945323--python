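"""Vectorised logistic-regression fitting for per-SNP scans.

A genome-wide scan fits one small logistic model per SNP; looping over a
general-purpose GLM implementation dominates runtime, so the Newton
iterations are batched across SNPs.  Each SNP shares the covariate block
(intercept, sex, PC1, conditioning scores) and contributes one or two
SNP-specific columns (dosage, and optionally a dosage x partner
interaction).  Models are fitted independently; the batching is purely a
memory layout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["batched_logistic", "BatchedLogisticResult"]


class BatchedLogisticResult:
    """Per-model coefficients and Wald statistics from a batched fit.

    Attributes
    ----------
    beta, se : (S, k) arrays of estimates and standard errors.
    converged : (S,) boolean; False marks separation / singular Hessians.
    n_iter : (S,) Newton iterations used.
    """

    def __init__(self, beta, se, converged, n_iter):
        self.beta = beta
        self.se = se
        self.converged = converged
        self.n_iter = n_iter


def batched_logistic(X: np.ndarray, y: np.ndarray, *, max_iter: int = 50,
                     tol: float = 1e-10) -> BatchedLogisticResult:
    """Fit S independent logistic regressions by Newton-Raphson.

    Parameters
    ----------
    X : (S, n, k) design tensor — one (n, k) design matrix per model.
    y : (n,) binary outcome shared across models.
    max_iter, tol : Newton step count cap and convergence tolerance on
        the max absolute parameter update.

    Notes
    -----
    Convergence is declared per model; models whose Hessian becomes
    singular, or whose parameters diverge (a symptom of separation), are
    flagged unconverged and their estimates set to NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    S, n, k = X.shape
    beta = np.zeros((S, k))
    active = np.ones(S, dtype=bool)
    n_iter = np.zeros(S, dtype=int)
    ok = np.ones(S, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Xa = X[idx]
        eta = np.einsum("snk,sk->sn", Xa, beta[idx])
        np.clip(eta, -30.0, 30.0, out=eta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = np.einsum("snk,sn->sk", Xa, y[None, :] - mu)
        hess = np.einsum("snk,sn,snj->skj", Xa, w, Xa)
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # isolate the singular models and retry the rest one by one
            step = np.full_like(grad, np.nan)
            for j in range(len(idx)):
                try:
                    step[j] = np.linalg.solve(hess[j], grad[j])
                except np.linalg.LinAlgError:
                    pass
        bad = ~np.isfinite(step).all(axis=1)
        diverged = np.abs(beta[idx] + step).max(axis=1) > 1e3
        failed = bad | diverged
        if failed.any():
            ok[idx[failed]] = False
            active[idx[failed]] = False
            good = ~failed
            idx = idx[good]
            step = step[good]
        if idx.size == 0:
            continue
        beta[idx] += step
        n_iter[idx] += 1
        done = np.abs(step).max(axis=1) < tol
        active[idx[done]] = False

    # unconverged-at-cap models are kept active=True at exit
    ok &= ~active

    se = np.full((S, k), np.nan)
    good = np.flatnonzero(ok)
    if good.size:
        Xg = X[good]
        eta = np.einsum("snk,sk->sn", Xg, beta[good])
        np.clip(eta, -30.0, 30.0, out=eta)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        hess = np.einsum("snk,sn,snj->skj", Xg, w, Xg)
        try:
            cov = np.linalg.inv(hess)
            var = np.einsum("skk->sk", cov)
        except np.linalg.LinAlgError:
            var = np.full((good.size, k), np.nan)
        with np.errstate(invalid="ignore"):
            se[good] = np.sqrt(np.where(var > 0, var, np.nan))
    beta = np.where(ok[:, None], beta, np.nan)
    return BatchedLogisticResult(beta, se, ok, n_iter)
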