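"""Two-stage GxE screening: threshold calibration, region clustering, selection.

Stage 1 screens every variant with the 2df joint test at ``alpha1``
(default 0.05).  Stage 2 tests the interaction term alone, but only among
stage-1 survivors — and because the two statistics share the interaction
component, the stage-2 p-values of survivors are enriched near zero.  The
second-stage threshold ``t`` is therefore calibrated by Monte-Carlo
simulation: the empirical ``conditional_level`` quantile of the
interaction p-values among null tests passing stage 1, so that the
conditional type-I error P(p_GE < t | p_joint < alpha1) equals the target.
Were the two tests independent, t would equal alpha1 x conditional_level
(0.0025 at the defaults); dependence can only raise it.

Finally, suggestive variants are clustered into regions by genomic
proximity and ``t`` is Bonferroni-divided by the region count to give the
genome-wide significance level for the interaction p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .association import ScanResult, STATUS_OK, fit_logistic_batch
from .core_io import _chrom_sort_key
from .synthetic import SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class CalibrationConfig:
    """Settings of the null-simulation threshold calibration."""

    alpha1: float = 0.05
    conditional_level: float = 0.05
    n_null_tests: int = 100_000
    cohort_template: SimulationConfig = field(default_factory=SimulationConfig)
    regime: str = "cohort"  # "cohort" (logistic fits) or "independent" (chi-square draws)
    chunk_size: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha1 <= 1 or not 0 < self.conditional_level < 1:
            raise ValueError("alpha1 and conditional_level must lie in (0, 1]")
        if self.regime not in ("cohort", "independent"):
            raise ValueError("regime must be 'cohort' or 'independent'")
        t = self.cohort_template
        if t.causal_effects and any(b != 0 for bs in t.causal_effects.values() for b in bs):
            raise ValueError("cohort_template must be a global null (all G/GxE betas zero)")


@dataclass
class CalibrationResult:
    """A calibrated second-stage threshold with its Monte-Carlo precision."""

    threshold_t: float
    n_passed_stage1: int
    monte_carlo_se: float
    config: CalibrationConfig


@dataclass
class LocusCluster:
    """A run of suggestive variants merged by genomic proximity."""

    region_id: str
    chrom: str
    start: int
    end: int
    members: list[str]
    lead: str  # smallest p_joint; ties by position then id


@dataclass
class ScreenReport:
    """Final output of the two-stage selection."""

    n_suggestive_regions: int
    adjusted_threshold: Optional[float]
    significant: list[tuple[str, str, float]]  # (variant id, region id, p_GE)
    suggestive: list[tuple[str, str, float]]
    alpha1: float
    threshold_t: float
    suggestive_level: float
    window_kb: float | None = None


def simulate_null_tests(n_tests: int, template: SimulationConfig,
                        seed: int = 0, chunk_size: int = 2000) -> np.ndarray:
    """Draw (p_joint, p_GE) pairs for independent null single-variant tests.

    Each test is one synthetic cohort at the template's sample size with a
    single variant: MAF uniform on the template range, Hardy-Weinberg
    genotypes, Bernoulli exposure, standard-normal ancestry covariates.
    Under the global null the case/control labels are independent of all
    predictors, so sampling predictors given the fixed case/control split
    is exactly the rejection-sampling cohort distribution.

    Returns an (n_tests, 2) array of (p_joint, p_GE).
    """
    rng = np.random.default_rng(seed)
    n = template.n_cases + template.n_controls
    y = np.concatenate([np.ones(template.n_cases), np.zeros(template.n_controls)])
    lo, hi = template.maf_range
    k = template.n_pcs
    out = np.empty((n_tests, 2))
    done = 0
    while done < n_tests:
        b_ = min(chunk_size, n_tests - done)
        maf = rng.uniform(lo, hi, size=b_)
        g = rng.binomial(2, maf[:, None], size=(b_, n)).astype(float)
        e = rng.binomial(1, template.exposure_prevalence, size=(b_, n)).astype(float)
        pcs = rng.standard_normal((b_, n, k)) if k else np.empty((b_, n, 0))
        x_full = np.concatenate([
            np.ones((b_, n, 1)), pcs, e[:, :, None], g[:, :, None],
            (g * e)[:, :, None],
        ], axis=2)
        x_red = x_full[:, :, : k + 2]  # intercept + PCs + E
        bf, cf, llf, _ = fit_logistic_batch(x_full, y)
        _, _, llr, _ = fit_logistic_batch(x_red, y)
        lrt = np.clip(2.0 * (llf - llr), 0.0, None)
        p_joint = stats.chi2.sf(lrt, 2)
        wald = bf[:, -1] ** 2 / cf[:, -1, -1]
        p_ge = stats.chi2.sf(wald, 1)
        out[done:done + b_, 0] = p_joint
        out[done:done + b_, 1] = p_ge
        done += b_
    return out


def simulate_independent_tests(n_tests: int, seed: int = 0) -> np.ndarray:
    """(p_joint, p_GE) pairs with independent G and GxE chi-square components.

    The joint statistic is X_G + X_GE with X_G and X_GE independent 1df
    chi-squares; p_joint is its 2df tail probability and p_GE the 1df tail
    of X_GE alone.  Because the 1df critical value at alpha1 x
    conditional_level exceeds the 2df critical value at alpha1, the GE
    rejection region then lies inside the stage-1 region, so the
    calibrated threshold converges to alpha1 x conditional_level (0.0025
    at the defaults).  Dependence between the two coefficient estimates in
    real designs can only enlarge it.
    """
    rng = np.random.default_rng(seed)
    x_g = rng.chisquare(1, size=n_tests)
    x_ge = rng.chisquare(1, size=n_tests)
    p_joint = stats.chi2.sf(x_g + x_ge, 2)
    p_ge = stats.chi2.sf(x_ge, 1)
    return np.column_stack([p_joint, p_ge])


def _quantile_mc_se(values: np.ndarray, q: float) -> float:
    """Asymptotic Monte-Carlo SE of the empirical q-quantile.

    Var ~= q(1-q) / (m f(x_q)^2); the density is estimated by a central
    difference of the empirical quantile function.
    """
    m = values.size
    h = min(0.04, q / 2, (1 - q) / 2)
    spread = np.quantile(values, q + h) - np.quantile(values, q - h)
    if spread <= 0:
        return float("nan")
    f = 2 * h / spread
    return float(np.sqrt(q * (1 - q) / m) / f)


def calibrate_stage2_threshold(config: CalibrationConfig) -> CalibrationResult:
    """Calibrate the second-stage threshold by null simulation.

    Simulates ``n_null_tests`` independent null tests, keeps those with
    joint p below ``alpha1``, and returns the empirical
    ``conditional_level`` quantile (linear interpolation) of their
    interaction p-values, with its Monte-Carlo standard error.
    """
    if config.regime == "independent":
        pairs = simulate_independent_tests(config.n_null_tests, seed=config.seed)
    else:
        pairs = simulate_null_tests(config.n_null_tests, config.cohort_template,
                                    seed=config.seed, chunk_size=config.chunk_size)
    retained = pairs[pairs[:, 0] < config.alpha1, 1]
    if retained.size < 100:
        raise ValueError(
            f"only {retained.size} null tests passed stage 1; increase n_null_tests")
    t = float(np.quantile(retained, config.conditional_level))
    se = _quantile_mc_se(retained, config.conditional_level)
    logger.info("calibrated stage-2 threshold t=%.5g (MC se %.2g) from %d/%d "
                "stage-1 survivors", t, se, retained.size, config.n_null_tests)
    return CalibrationResult(threshold_t=t, n_passed_stage1=int(retained.size),
                             monte_carlo_se=se, config=config)


def empirical_conditional_type1(null_results: np.ndarray, alpha1: float,
                                t: float) -> float:
    """Fraction of tests with p_GE < t among tests with p_joint < alpha1."""
    pairs = np.asarray(null_results, dtype=float)
    if pairs.size == 0:
        raise ValueError("empty null sample")
    passed = pairs[pairs[:, 0] < alpha1]
    if passed.size == 0:
        raise ValueError("no tests pass stage 1")
    return float((passed[:, 1] < t).mean())


def cluster_regions(results: Sequence[ScanResult], p_threshold: float,
                    window_kb: float = 500.0) -> list[LocusCluster]:
    """Greedily merge suggestive variants into regions by genomic proximity.

    Variants with joint p below ``p_threshold`` are sorted by position and
    consecutive ones on the same chromosome within ``window_kb`` are merged.
    The cluster count is the Bonferroni denominator of the screen.
    """
    window_bp = window_kb * 1000.0
    sugg = [r for r in results
            if r.p_joint is not None and r.p_joint < p_threshold]
    sugg.sort(key=lambda r: (_chrom_sort_key(r.variant.chrom), r.variant.pos,
                             r.variant.id))
    clusters: list[LocusCluster] = []
    current: list[ScanResult] = []

    def _close(group: list[ScanResult]) -> None:
        lead = min(group, key=lambda r: (r.p_joint, r.variant.pos, r.variant.id))
        clusters.append(LocusCluster(
            region_id=f"{group[0].variant.chrom}:{group[0].variant.pos}-{group[-1].variant.pos}",
            chrom=group[0].variant.chrom,
            start=group[0].variant.pos, end=group[-1].variant.pos,
            members=[r.variant.id for r in group], lead=lead.variant.id))

    for r in sugg:
        if current and (r.variant.chrom != current[-1].variant.chrom
                        or r.variant.pos - current[-1].variant.pos > window_bp):
            _close(current)
            current = []
        current.append(r)
    if current:
        _close(current)
    return clusters


def two_stage_select(results: Sequence[ScanResult], alpha1: float, t: float,
                     clusters: Sequence[LocusCluster],
                     suggestive_level: float = 5e-4,
                     window_kb: float | None = None) -> ScreenReport:
    """Apply the two-stage selection with region-level Bonferroni correction.

    Significant: p_joint < alpha1 and p_GE < t / n_regions.  A suggestive
    tier is reported at ``suggestive_level``.
    """
    n_regions = len(clusters)
    member_region = {vid: c.region_id for c in clusters for vid in c.members}
    if n_regions == 0:
        logger.warning("no suggestive regions; adjusted threshold undefined")
        return ScreenReport(n_suggestive_regions=0, adjusted_threshold=None,
                            significant=[], suggestive=[], alpha1=alpha1,
                            threshold_t=t, suggestive_level=suggestive_level,
                            window_kb=window_kb)
    adjusted = t / n_regions
    significant, suggestive = [], []
    for r in results:
        if r.status != STATUS_OK or r.p_joint is None or r.p_GE is None:
            continue
        if r.p_joint >= alpha1:
            continue
        region = member_region.get(r.variant.id, "")
        if r.p_GE < adjusted:
            significant.append((r.variant.id, region, r.p_GE))
        elif r.p_GE < suggestive_level:
            suggestive.append((r.variant.id, region, r.p_GE))
    significant.sort(key=lambda x: x[2])
    suggestive.sort(key=lambda x: x[2])
    return ScreenReport(n_suggestive_regions=n_regions, adjusted_threshold=adjusted,
                        significant=significant, suggestive=suggestive,
                        alpha1=alpha1, threshold_t=t,
                        suggestive_level=suggestive_level, window_kb=window_kb)


def calibration_sweep(base: CalibrationConfig,
                      prevalences: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
                      maf_ranges: Sequence[tuple[float, float]] = ((0.1, 0.5),),
                      ) -> list[tuple[float, tuple[float, float], CalibrationResult]]:
    """Sensitivity of the calibrated threshold to exposure prevalence and MAF.

    Re-runs the calibration over a grid, seeding each cell deterministically
    from the base seed.  Returns (prevalence, maf_range, result) triples.
    """
    out = []
    for i, prev in enumerate(prevalences):
        for j, mr in enumerate(maf_ranges):
            tpl = replace(base.cohort_template, exposure_prevalence=prev,
                          maf_range=mr)
            cfg = replace(base, cohort_template=tpl,
                          seed=(base.seed * 1000 + i * 37 + j * 11) % (2**31 - 1))
            out.append((prev, mr, calibrate_stage2_threshold(cfg)))
    return out
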