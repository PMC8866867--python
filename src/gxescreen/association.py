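"""Per-variant logistic-regression inference for the GxE screen.

The screening model for a variant with additive minor-allele dosage G,
binary exposure E and ancestry covariates PC1..PCk is

    full:    logit P(case) = b0 + sum_j c_j PC_j + b_E E + b_G G + b_GE G*E
    reduced: logit P(case) = b0 + sum_j c_j PC_j + b_E E

The 2-degree-of-freedom joint test of (b_G, b_GE) is a likelihood-ratio
test between the two fits; the 1df interaction test is a Wald test of
b_GE in the full model (a likelihood-ratio variant is available).
Stratum-specific genotypic odds ratios come from per-stratum fits of
status on G alone and support the cross-over classification (ORs on
opposite sides of 1).

Fitting is iteratively reweighted least squares (Newton scoring).  A
batched IRLS — vectorized over variants with per-observation 0/1 weights
for per-variant complete-case missingness — drives the genome scan and
the null-calibration simulations; the single-fit path is the reference
implementation and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import expit

from .containers import MISSING, Cohort, VariantRecord

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NON_CONVERGED = "non_converged"
STATUS_DEGENERATE = "degenerate"


class DegenerateDesignError(ValueError):
    """Raised when a design matrix is rank deficient or an outcome one-class."""


@dataclass
class ModelFit:
    """A maximum-likelihood logistic fit."""

    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class ScanResult:
    """Association output for one variant."""

    variant: VariantRecord
    status: str
    n_used: int = 0
    lrt_joint: Optional[float] = None
    p_joint: Optional[float] = None
    beta_GE: Optional[float] = None
    se_GE: Optional[float] = None
    p_GE: Optional[float] = None
    or_exposed: Optional[float] = None
    or_unexposed: Optional[float] = None


def _loglik(eta: np.ndarray, y: np.ndarray, w: Optional[np.ndarray] = None) -> np.ndarray:
    ll = y * eta - np.logaddexp(0.0, eta)
    if w is not None:
        ll = ll * w
    return ll.sum(axis=-1)


def fit_logistic(design: np.ndarray, outcome: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-8) -> ModelFit:
    """Maximum-likelihood logistic regression by IRLS with step halving.

    ``converged`` is True iff the maximum absolute score drops below
    ``tol`` within ``max_iter`` iterations; the covariance is the inverse
    observed information at the final iterate.  Raises
    :class:`DegenerateDesignError` on a rank-deficient design (naming the
    collinear column) or a one-class outcome.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.ndim != 2 or y.shape != (x.shape[0],):
        raise ValueError("design must be (n, p) and outcome length n")
    if np.unique(y).size < 2:
        raise DegenerateDesignError("outcome contains a single class")
    n, p = x.shape
    # pivoted QR exposes the first dependent column
    from scipy.linalg import qr

    r = qr(x, mode="r", pivoting=True)
    diag = np.abs(np.diag(r[0]))[: min(n, p)]
    rank = int((diag > diag[0] * max(n, p) * np.finfo(float).eps).sum()) if diag.size else 0
    if rank < p:
        col = int(r[1][rank])
        raise DegenerateDesignError(f"design column {col} is collinear")

    beta = np.zeros(p)
    eta = x @ beta
    ll = _loglik(eta, y)
    converged = False
    n_iter = 0
    info = np.eye(p)
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        score = x.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-12, None)
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the likelihood monotone
        for _ in range(30):
            cand = beta + step
            eta_c = x @ cand
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta, eta, ll = cand, eta_c, ll_c
    # under (quasi-)separation the score still vanishes while beta diverges;
    # fitted log-odds beyond +/-20 mark a non-existent MLE
    if np.max(np.abs(eta)) > 20:
        converged = False
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return ModelFit(coefficients=beta, covariance=cov, log_likelihood=float(ll),
                    converged=converged, n_iterations=n_iter)


def fit_logistic_batch(design: np.ndarray, outcome: np.ndarray,
                       weights: Optional[np.ndarray] = None,
                       max_iter: int = 40, tol: float = 1e-8):
    """IRLS vectorized over a batch of logistic models.

    Parameters
    ----------
    design
        Array of shape (B, n, p).
    outcome
        Shape (n,) or (B, n) binary outcomes.
    weights
        Optional (B, n) 0/1 observation weights (complete-case masks).

    Returns
    -------
    beta : (B, p), cov : (B, p, p), loglik : (B,), converged : (B,) bool
    """
    x = np.asarray(design, dtype=float)
    b_, n, p = x.shape
    y = np.broadcast_to(np.asarray(outcome, dtype=float), (b_, n))
    w = None if weights is None else np.asarray(weights, dtype=float)

    beta = np.zeros((b_, p))
    converged = np.zeros(b_, dtype=bool)
    ridge = np.eye(p) * 1e-10
    info = np.broadcast_to(np.eye(p), (b_, p, p)).copy()
    for _ in range(max_iter):
        eta = np.einsum("bnp,bp->bn", x, beta)
        mu = expit(eta)
        resid = y - mu
        if w is not None:
            resid = resid * w
        score = np.einsum("bnp,bn->bp", x, resid)
        converged |= np.abs(score).max(axis=1) < tol
        if converged.all():
            break
        wirls = np.clip(mu * (1 - mu), 1e-12, None)
        if w is not None:
            wirls = wirls * w
        info = np.einsum("bnp,bn,bnq->bpq", x, wirls, x)
        step = np.linalg.solve(info + ridge, score[:, :, None])[:, :, 0]
        beta[~converged] += step[~converged]
    eta = np.einsum("bnp,bp->bn", x, beta)
    loglik = _loglik(eta, y, w)
    mu = expit(eta)
    wirls = np.clip(mu * (1 - mu), 1e-12, None)
    if w is not None:
        wirls = wirls * w
    info = np.einsum("bnp,bn,bnq->bpq", x, wirls, x)
    cov = np.linalg.inv(info + ridge)
    return beta, cov, loglik, converged


def _design_full(g, e, covariates):
    n = len(g)
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    return np.column_stack([np.ones(n), cov, e, g, g * e])


def _design_reduced(e, covariates):
    n = len(e)
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    return np.column_stack([np.ones(n), cov, e])


def _variant_vectors(cohort: Cohort, variant: str):
    ids = [v.id for v in cohort.genotypes.variants]
    try:
        i = ids.index(variant)
    except ValueError:
        raise KeyError(f"unknown variant {variant!r}") from None
    return cohort.genotypes.variants[i], cohort.genotypes.calls[i].astype(float)


def joint_2df_test(cohort: Cohort, variant: str, exposure: str,
                   covariates: Optional[np.ndarray] = None):
    """2df likelihood-ratio joint test of the G and GxE terms.

    Compares the full model against the reduced model on the same
    complete-case sample subset; p comes from the chi-square distribution
    with 2 degrees of freedom.  Returns ``(lrt, p)`` or ``(None, None)``
    for a degenerate variant (monomorphic G or an empty exposure stratum).
    """
    rec, g = _variant_vectors(cohort, variant)
    y = cohort.samples.status.astype(float)
    e = cohort.samples.exposure(exposure).astype(float)
    mask = g != MISSING
    g, y, e = g[mask], y[mask], e[mask]
    cov = None if covariates is None else np.asarray(covariates, float)[mask]
    if np.unique(g).size < 2 or np.unique(e).size < 2:
        return None, None
    full = fit_logistic(_design_full(g, e, cov), y)
    red = fit_logistic(_design_reduced(e, cov), y)
    lrt = max(0.0, 2.0 * (full.log_likelihood - red.log_likelihood))
    return float(lrt), float(stats.chi2.sf(lrt, 2))


def interaction_test(cohort: Cohort, variant: str, exposure: str,
                     covariates: Optional[np.ndarray] = None, method: str = "wald"):
    """1df test of the GxE coefficient in the full model.

    The default is a Wald test (beta/se squared against chi-square 1df);
    ``method="lrt"`` refits without the interaction term instead.  Returns
    ``(beta_GE, se_GE, p_GE)``; raises :class:`DegenerateDesignError` when
    the interaction column is collinear (e.g. constant exposure) or G is
    monomorphic within an exposure stratum.
    """
    rec, g = _variant_vectors(cohort, variant)
    y = cohort.samples.status.astype(float)
    e = cohort.samples.exposure(exposure).astype(float)
    mask = g != MISSING
    g, y, e = g[mask], y[mask], e[mask]
    cov = None if covariates is None else np.asarray(covariates, float)[mask]
    for stratum in (0, 1):
        if np.unique(g[e == stratum]).size < 2:
            raise DegenerateDesignError(
                f"genotype not polymorphic in exposure stratum {stratum}")
    full = fit_logistic(_design_full(g, e, cov), y)
    beta = float(full.coefficients[-1])
    se = float(full.se[-1])
    if method == "wald":
        p = float(stats.chi2.sf((beta / se) ** 2, 1))
    elif method == "lrt":
        no_int = np.column_stack([_design_reduced(e, cov), g])
        red = fit_logistic(no_int, y)
        lrt = max(0.0, 2.0 * (full.log_likelihood - red.log_likelihood))
        p = float(stats.chi2.sf(lrt, 1))
    else:
        raise ValueError("method must be 'wald' or 'lrt'")
    return beta, se, p


def stratum_specific_or(cohort: Cohort, variant: str, exposure: str,
                        conf_level: float = 0.95):
    """Per-stratum genotypic odds ratios (status ~ G, no covariates).

    Returns ``(or_exposed, or_unexposed, ci_exposed, ci_unexposed,
    crossover)`` where ``crossover`` is True when the two odds ratios lie
    on opposite sides of 1 — the pattern in which the risk allele's effect
    reverses with exposure.
    """
    rec, g = _variant_vectors(cohort, variant)
    y = cohort.samples.status.astype(float)
    e = cohort.samples.exposure(exposure).astype(float)
    mask = g != MISSING
    g, y, e = g[mask], y[mask], e[mask]
    z = stats.norm.ppf(0.5 + conf_level / 2)
    out = {}
    for stratum in (1, 0):
        sel = e == stratum
        ys, gs = y[sel], g[sel]
        if sel.sum() == 0 or np.unique(ys).size < 2 or np.unique(gs).size < 2:
            raise DegenerateDesignError(
                f"exposure stratum {stratum} lacks cases/controls or polymorphic G")
        fit = fit_logistic(np.column_stack([np.ones(sel.sum()), gs]), ys)
        slope, se = float(fit.coefficients[1]), float(fit.se[1])
        out[stratum] = (np.exp(slope), (np.exp(slope - z * se), np.exp(slope + z * se)))
    or_exp, ci_exp = out[1]
    or_unexp, ci_unexp = out[0]
    crossover = (or_exp - 1.0) * (or_unexp - 1.0) < 0
    return float(or_exp), float(or_unexp), ci_exp, ci_unexp, bool(crossover)


def genome_scan(cohort: Cohort, exposure: str,
                covariates: Optional[np.ndarray] = None,
                alpha1: float = 0.05, exhaustive: bool = False,
                chunk_size: int = 2048) -> list[ScanResult]:
    """Joint 2df test for every variant; interaction follow-up below ``alpha1``.

    Runs the batched IRLS over variants in chunks.  Interaction statistics
    and stratum odds ratios are computed for variants whose joint p falls
    below ``alpha1`` (all variants when ``exhaustive``).  Per-variant
    degeneracies become status codes; the scan never aborts.
    """
    store = cohort.genotypes
    y = cohort.samples.status.astype(float)
    e = cohort.samples.exposure(exposure).astype(float)
    cov = np.empty((len(y), 0)) if covariates is None else np.asarray(covariates, float)
    n = len(y)
    base = np.column_stack([np.ones(n), cov, e])  # reduced design, shared
    p_red = base.shape[1]
    results: list[ScanResult] = []

    for start in range(0, store.n_variants, chunk_size):
        chunk = slice(start, min(start + chunk_size, store.n_variants))
        calls = store.calls[chunk].astype(float)
        b_ = calls.shape[0]
        mask = calls != MISSING
        g = np.where(mask, calls, 0.0)
        x_full = np.empty((b_, n, p_red + 2))
        x_full[:, :, :p_red] = base[None]
        x_full[:, :, p_red] = g
        x_full[:, :, p_red + 1] = g * e[None]
        w = mask.astype(float)
        # degenerate: monomorphic G (complete case) or single-stratum exposure
        poly = np.array([np.unique(calls[i][mask[i]]).size > 1 for i in range(b_)])
        estrat = np.array([np.unique(e[mask[i]]).size > 1 for i in range(b_)])
        ok = poly & estrat

        bf, cf, llf, convf = fit_logistic_batch(x_full, y, weights=w)
        if mask.all():
            # reduced model is variant-independent when nothing is missing
            _, _, llr1, convr1 = fit_logistic_batch(base[None], y)
            llr = np.full(b_, llr1[0])
            convr = np.full(b_, convr1[0])
        else:
            xr = np.broadcast_to(base, (b_, n, p_red))
            _, _, llr, convr = fit_logistic_batch(xr, y, weights=w)
        lrt = np.clip(2.0 * (llf - llr), 0.0, None)
        p_joint = stats.chi2.sf(lrt, 2)
        beta_ge = bf[:, -1]
        se_ge = np.sqrt(cf[:, -1, -1])
        p_ge = stats.chi2.sf((beta_ge / se_ge) ** 2, 1)

        for i in range(b_):
            rec = store.variants[chunk][i] if isinstance(chunk, list) else store.variants[start + i]
            n_used = int(mask[i].sum())
            if not ok[i]:
                results.append(ScanResult(variant=rec, status=STATUS_DEGENERATE,
                                          n_used=n_used))
                continue
            if not (convf[i] and convr[i]):
                results.append(ScanResult(variant=rec, status=STATUS_NON_CONVERGED,
                                          n_used=n_used, lrt_joint=float(lrt[i]),
                                          p_joint=float(p_joint[i])))
                continue
            res = ScanResult(variant=rec, status=STATUS_OK, n_used=n_used,
                             lrt_joint=float(lrt[i]), p_joint=float(p_joint[i]))
            if exhaustive or p_joint[i] < alpha1:
                res.beta_GE = float(beta_ge[i])
                res.se_GE = float(se_ge[i])
                res.p_GE = float(p_ge[i])
                try:
                    or_e, or_u, _, _, _ = stratum_specific_or(cohort, rec.id, exposure)
                    res.or_exposed, res.or_unexposed = or_e, or_u
                except DegenerateDesignError:
                    pass  # interaction stats stand; stratum ORs unavailable
            results.append(res)
    return results
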