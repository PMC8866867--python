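"""Variant-level quality control and ancestry principal components.

Filters mirror standard post-imputation practice for interaction scans:
hard-call genotype probabilities (most-likely genotype retained only when
its probability strictly exceeds 0.9), drop variants with imputation
quality below 0.5, drop variants out of Hardy-Weinberg equilibrium in
controls (exact conditional test, p < 1e-4), and drop variants with minor
allele frequency below 10% — interaction tests on rarer variants are
underpowered and error-prone.  Filters are applied in the fixed order
quality -> HWE -> MAF with first-failing-rule attribution so report counts
are deterministic.

Ancestry PCs use the Patterson/Price/Reich normalization: each variant row
is centered by twice its allele frequency and scaled by the binomial
standard deviation sqrt(2 p (1 - p)); missing calls are mean-imputed first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, Cohort, GenotypeStore

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    """Variant-filter thresholds; defaults follow common post-imputation practice."""

    hard_call_min: float = 0.9   # strict inequality
    quality_min: float = 0.5
    hwe_alpha: float = 1e-4
    maf_min: float = 0.10
    hwe_stratum: str = "controls"  # or "all"

    def __post_init__(self) -> None:
        if not 0 <= self.hard_call_min <= 1:
            raise ValueError("hard_call_min must be a probability")
        if not 0 <= self.hwe_alpha <= 1:
            raise ValueError("hwe_alpha must be a probability")
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be a frequency")
        if self.hwe_stratum not in ("controls", "all"):
            raise ValueError("hwe_stratum must be 'controls' or 'all'")


@dataclass
class QcReport:
    """Per-filter exclusion counts and per-variant pass/fail attribution."""

    n_input: int
    n_pass: int
    excluded: dict[str, int] = field(default_factory=dict)
    table: pd.DataFrame | None = None  # id, pass, fail_reason, quality, hwe_p, maf

    def __post_init__(self) -> None:
        if self.n_pass + sum(self.excluded.values()) != self.n_input:
            raise ValueError("exclusion counts do not reconcile with input total")


def hard_call(triplet, min_prob: float = 0.9) -> int:
    """Convert one genotype-probability triplet to a hard call.

    Returns the argmax genotype when its probability strictly exceeds
    ``min_prob``, else ``MISSING`` (-1).
    """
    t = np.asarray(triplet, dtype=float)
    if t.shape != (3,):
        raise ValueError("triplet must have three entries")
    if np.any(t < 0):
        raise ValueError("negative genotype probability")
    if abs(t.sum() - 1.0) > 1e-6:
        raise ValueError("triplet must sum to 1")
    g = int(np.argmax(t))
    return g if t[g] > min_prob else MISSING


def hard_call_matrix(probabilities: np.ndarray, min_prob: float = 0.9) -> np.ndarray:
    """Vectorized :func:`hard_call` over a (variants, samples, 3) array."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative genotype probability")
    g = p.argmax(axis=2)
    top = np.take_along_axis(p, g[:, :, None], axis=2)[:, :, 0]
    return np.where(top > min_prob, g, MISSING).astype(np.int8)


def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts, enumerates every heterozygote
    count they allow, and sums the probabilities of all configurations no
    more probable than the observed one.  Returns a p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = min(2 * n_hom_major + n_het, 2 * n_hom_minor + n_het)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(h) up to the common conditioning constant:
    # n! 2^h / (hom_rare! h! hom_common!) * n_rare! n_common! / (2n)!
    logp = hets * np.log(2.0) - (gammaln(hom_rare + 1) + gammaln(hets + 1)
                                 + gammaln(hom_common + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def minor_allele_frequency(calls) -> float:
    """Frequency of the rarer allele among non-missing calls (always <= 0.5)."""
    c = np.asarray(calls)
    obs = c[c != MISSING]
    if obs.size == 0:
        raise ValueError("all calls are missing")
    f = obs.sum() / (2 * obs.size)
    return float(min(f, 1.0 - f))


def genotype_counts(calls) -> tuple[int, int, int]:
    """Complete-case genotype counts (hom major, het, hom minor)."""
    c = np.asarray(calls)
    return (int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum()))


def apply_variant_filters(cohort: Cohort,
                          thresholds: QcThresholds | None = None) -> tuple[Cohort, QcReport]:
    """Hard-call (when probability triplets are present) and filter variants.

    Filters run in the order quality -> HWE (in the configured stratum) ->
    MAF; each excluded variant is attributed to the first rule it fails.
    A cohort with no survivors is returned with a warning, not an error.
    """
    th = thresholds or QcThresholds()
    store = cohort.genotypes
    if store.n_variants == 0:
        raise ValueError("cohort has no variants")
    if store.probabilities is not None:
        calls = hard_call_matrix(store.probabilities, th.hard_call_min)
    else:
        calls = store.calls.copy()

    status = cohort.samples.status
    stratum = np.ones(len(status), bool) if th.hwe_stratum == "all" else (status == 0)

    rows = []
    keep = []
    excluded = {"quality": 0, "hwe": 0, "maf": 0}
    for i, v in enumerate(store.variants):
        qual = v.quality
        hwe_p = np.nan
        maf = np.nan
        reason = None
        if qual is not None and qual < th.quality_min:
            reason = "quality"
        if reason is None:
            counts = genotype_counts(calls[i, stratum])
            if sum(counts) > 0:
                hwe_p = hwe_exact_p(*counts)
                if hwe_p < th.hwe_alpha:
                    reason = "hwe"
        if reason is None:
            obs = calls[i][calls[i] != MISSING]
            if obs.size == 0:
                reason = "maf"
            else:
                maf = minor_allele_frequency(calls[i])
                if maf < th.maf_min:
                    reason = "maf"
        if reason is None:
            keep.append(i)
        else:
            excluded[reason] += 1
        rows.append({"id": v.id, "pass": reason is None, "fail_reason": reason,
                     "quality": qual, "hwe_p": hwe_p, "maf": maf})

    table = pd.DataFrame(rows)
    report = QcReport(n_input=store.n_variants, n_pass=len(keep),
                      excluded=excluded, table=table)
    logger.info("QC: %d/%d variants pass (quality %d, HWE %d, MAF %d excluded)",
                len(keep), store.n_variants,
                excluded["quality"], excluded["hwe"], excluded["maf"])
    if not keep:
        warnings.warn("no variants survive QC filters", stacklevel=2)

    surv = store.subset_variants(keep)
    surv = GenotypeStore(variants=surv.variants, calls=calls[keep],
                         sample_ids=surv.sample_ids, probabilities=None)
    for v, i in zip(surv.variants, keep):
        obs = calls[i][calls[i] != MISSING]
        v.maf = minor_allele_frequency(calls[i]) if obs.size else None
    filtered = Cohort(genotypes=surv, samples=cohort.samples, truth=cohort.truth)
    return filtered, report


def compute_ancestry_pcs(calls: np.ndarray, k: int) -> np.ndarray:
    """Top-k ancestry principal-component scores from a dosage matrix.

    Rows (variants) are mean-imputed, centered by twice the allele
    frequency, and scaled by sqrt(2 p (1 - p)); scores are the top right
    singular directions scaled by their singular values, one row per sample.
    Raises on monomorphic variants (zero scale).
    """
    c = np.asarray(calls, dtype=float)
    if c.ndim != 2:
        raise ValueError("calls must be a variants x samples matrix")
    n_var, n_samp = c.shape
    if not 1 <= k <= min(n_var, n_samp):
        raise ValueError("k must be within the matrix dimensions")
    c = np.where(c == MISSING, np.nan, c)
    row_mean = np.nanmean(c, axis=1)
    inds = np.where(np.isnan(c))
    if inds[0].size:
        c[inds] = row_mean[inds[0]]
    p = row_mean / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        raise ValueError(f"monomorphic variant at row {int(np.nonzero(mono)[0][0])}")
    m = (c - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    _, s, vt = np.linalg.svd(m, full_matrices=False)
    return vt[:k].T * s[:k]
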