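"""Synthetic case-control cohorts with gene, exposure and GxE effects.

The generator emulates the statistical structure of a small case-control
GxE study: biallelic variants in Hardy-Weinberg proportions at MAFs drawn
from a configurable range, independent binary periconceptional exposures,
null ancestry covariates, and a prospective logistic disease model

    logit P(case) = beta_0 + beta_E * E + sum_v (beta_G,v * G_v + beta_GE,v * G_v * E)

with ascertainment by rejection sampling until exact case/control quotas
are met.  Imputation artifacts (genotype-probability triplets and
per-variant quality scores) can be layered on afterwards so the QC stage
is exercisable end-to-end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import Cohort, GenotypeStore, SampleTable, VariantRecord


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; one integer seed determines everything.

    Defaults mirror the analysis design this package targets: 344 cases and
    194 controls, common variants (MAF uniform on [0.10, 0.5]), binary
    exposures of prevalence 0.3, five ancestry covariates.
    """

    n_cases: int = 344
    n_controls: int = 194
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.10, 0.5)
    exposure_prevalence: float = 0.3
    exposure_names: tuple[str, ...] = ("alcohol", "smoking", "vitamin")
    causal_exposure: str = "alcohol"
    beta_0: float = -2.0
    beta_E: float = 0.0
    causal_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_pcs: int = 5
    structure: Optional[float] = None  # two-subpopulation allele-frequency divergence
    spacing_bp: int = 50_000
    cluster_size: int = 1
    cluster_gap_bp: int = 1_000_000
    chrom: str = "1"
    max_batches: int = 2000
    batch_size: int = 8192
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 < self.exposure_prevalence < 1):
            raise ValueError("exposure_prevalence must be in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if self.causal_exposure not in self.exposure_names:
            raise ValueError(f"causal exposure {self.causal_exposure!r} not in exposure_names")

    def to_json(self) -> str:
        d = asdict(self)
        d["causal_effects"] = {k: list(v) for k, v in self.causal_effects.items()}
        return json.dumps(d, indent=2)


def generate_variants(n_variants: int, maf_range=(0.10, 0.5), seed: int = 0, *,
                      spacing_bp: int = 50_000, cluster_size: int = 1,
                      cluster_gap_bp: int = 1_000_000, chrom: str = "1",
                      rng: Optional[np.random.Generator] = None) -> list[VariantRecord]:
    """Draw variant records with uniform MAFs on a synthetic genetic map.

    Positions advance by ``spacing_bp`` within clusters of ``cluster_size``
    consecutive variants and jump by ``cluster_gap_bp`` between clusters,
    so region clustering is exercisable without an LD model.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_variants < 0:
        raise ValueError("n_variants must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    variants = []
    pos = 1
    for i in range(n_variants):
        if i > 0:
            pos += cluster_gap_bp if (cluster_size > 0 and i % cluster_size == 0) else spacing_bp
        variants.append(VariantRecord(id=f"var{i + 1:06d}", chrom=chrom, pos=pos,
                                      ref="A", alt="B", maf=float(mafs[i])))
    return variants


def _draw_batch(cfg: SimulationConfig, mafs: np.ndarray, beta_g: np.ndarray,
                beta_ge: np.ndarray, rng: np.random.Generator, size: int):
    """Simulate one population batch: genotypes, exposures, PCs, subpop, status."""
    if cfg.structure is not None:
        subpop = rng.integers(0, 2, size=size)
        shift = cfg.structure / 2.0
        p = np.clip(mafs[:, None] + np.where(subpop == 0, -shift, shift)[None, :],
                    0.01, 0.99)
        geno = rng.binomial(2, p)
    else:
        subpop = None
        geno = rng.binomial(2, mafs[:, None], size=(len(mafs), size))
    expo = rng.binomial(1, cfg.exposure_prevalence,
                        size=(len(cfg.exposure_names), size))
    pcs = rng.standard_normal((cfg.n_pcs, size)) if cfg.n_pcs else None
    e_causal = expo[cfg.exposure_names.index(cfg.causal_exposure)]
    eta = cfg.beta_0 + cfg.beta_E * e_causal
    if beta_g.any() or beta_ge.any():
        eta = eta + beta_g @ geno + beta_ge @ (geno * e_causal[None, :])
    status = rng.binomial(1, expit(eta))
    return geno, expo, pcs, subpop, status


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a cohort with exactly ``n_cases`` cases and ``n_controls`` controls.

    Individuals are drawn from the population model and accumulated by
    rejection until both quotas are filled; raises if ``max_batches``
    population batches do not suffice (degenerate baseline log-odds).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    variants = generate_variants(
        cfg.n_variants, cfg.maf_range, rng=rng, spacing_bp=cfg.spacing_bp,
        cluster_size=cfg.cluster_size, cluster_gap_bp=cfg.cluster_gap_bp,
        chrom=cfg.chrom,
    )
    mafs = np.array([v.maf for v in variants])
    vid_index = {v.id: i for i, v in enumerate(variants)}
    beta_g = np.zeros(cfg.n_variants)
    beta_ge = np.zeros(cfg.n_variants)
    for vid, (bg, bge) in cfg.causal_effects.items():
        if vid not in vid_index:
            raise ValueError(f"causal effect names unknown variant {vid!r}")
        beta_g[vid_index[vid]] = bg
        beta_ge[vid_index[vid]] = bge

    kept: dict[int, list] = {0: [], 1: []}  # status -> list of per-batch column blocks
    n_kept = {0: 0, 1: 0}
    quota = {0: cfg.n_controls, 1: cfg.n_cases}
    for _ in range(cfg.max_batches):
        geno, expo, pcs, subpop, status = _draw_batch(
            cfg, mafs, beta_g, beta_ge, rng, cfg.batch_size)
        for s in (1, 0):
            need = quota[s] - n_kept[s]
            if need <= 0:
                continue
            idx = np.nonzero(status == s)[0][:need]
            if idx.size:
                kept[s].append((geno[:, idx], expo[:, idx],
                                None if pcs is None else pcs[:, idx],
                                None if subpop is None else subpop[idx]))
                n_kept[s] += idx.size
        if n_kept[0] >= quota[0] and n_kept[1] >= quota[1]:
            break
    else:
        raise RuntimeError(
            f"could not fill case/control quotas within {cfg.max_batches} batches; "
            "baseline log-odds beta_0 may be degenerate"
        )

    def _concat(blocks, pos):
        parts = [b[pos] for b in blocks if b[pos] is not None]
        return None if not parts else np.concatenate(parts, axis=-1)

    # cases first, then controls
    blocks = kept[1] + kept[0]
    geno = _concat(blocks, 0)
    expo = _concat(blocks, 1)
    pcs = _concat(blocks, 2)
    subpop = _concat(blocks, 3)
    n_total = cfg.n_cases + cfg.n_controls
    status = np.concatenate([np.ones(cfg.n_cases, dtype=np.int64),
                             np.zeros(cfg.n_controls, dtype=np.int64)])

    sample_ids = [f"S{i + 1:06d}" for i in range(n_total)]
    data = {"status": status}
    for k, name in enumerate(cfg.exposure_names):
        data[name] = expo[k]
    cov_names = []
    for k in range(cfg.n_pcs):
        name = f"PC{k + 1}"
        data[name] = pcs[k]
        cov_names.append(name)
    if subpop is not None:
        data["subpop"] = subpop
    table = SampleTable(
        data=pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id")),
        exposure_names=list(cfg.exposure_names),
        covariate_names=cov_names,
    )
    store = GenotypeStore(
        variants=variants,
        calls=geno.astype(np.int8) if cfg.n_variants else
        np.empty((0, n_total), dtype=np.int8),
        sample_ids=sample_ids,
    )
    return Cohort(genotypes=store, samples=table, truth=cfg)


def attach_imputation_artifacts(cohort: Cohort, quality_range=(0.5, 1.0),
                                miscall_rate: float = 0.0,
                                soft_fraction: float = 0.0,
                                seed: int = 0) -> Cohort:
    """Replace hard genotypes with probability triplets plus quality scores.

    Each call becomes a triplet whose argmax equals the true genotype with
    probability ``1 - miscall_rate``.  A fraction ``soft_fraction`` of
    triplets gets a top probability drawn uniformly on (0.5, 0.9) — these
    fail the strict >0.9 hard-call bar — while the rest draw on (0.9, 1.0).
    A per-variant quality score is drawn uniformly on ``quality_range``.
    """
    store = cohort.genotypes
    if store.calls.size == 0:
        raise ValueError("cohort has no genotypes")
    if not 0 <= miscall_rate <= 1 or not 0 <= soft_fraction <= 1:
        raise ValueError("miscall_rate and soft_fraction must be probabilities")
    lo, hi = quality_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("quality_range must lie within [0, 1]")
    rng = np.random.default_rng(seed)
    true = store.calls.astype(np.int64)
    n_var, n_samp = true.shape

    reported = true.copy()
    miss = rng.random(true.shape) < miscall_rate
    if miss.any():
        # move the argmax to one of the two other genotypes, uniformly
        offset = rng.integers(1, 3, size=true.shape)
        reported[miss] = (true[miss] + offset[miss]) % 3

    soft = rng.random(true.shape) < soft_fraction
    top = np.where(soft,
                   rng.uniform(0.5 + 1e-9, 0.9, size=true.shape),
                   rng.uniform(0.9 + 1e-9, 1.0, size=true.shape))
    split = rng.random(true.shape)
    rest = 1.0 - top
    probs = np.empty((n_var, n_samp, 3))
    rep = reported[:, :, None]
    other_lo = np.where(rep == 0, 1, 0)[:, :, 0]
    other_hi = np.where(rep == 2, 1, 2)[:, :, 0]
    probs[:] = 0.0
    np.put_along_axis(probs, rep, top[:, :, None], axis=2)
    np.put_along_axis(probs, other_lo[:, :, None], (rest * split)[:, :, None], axis=2)
    np.put_along_axis(probs, other_hi[:, :, None], (rest * (1 - split))[:, :, None], axis=2)

    variants = []
    quals = rng.uniform(lo, hi, size=n_var)
    for v, q in zip(store.variants, quals):
        variants.append(VariantRecord(id=v.id, chrom=v.chrom, pos=v.pos, ref=v.ref,
                                      alt=v.alt, maf=v.maf, quality=float(q),
                                      flipped=v.flipped))
    new_store = GenotypeStore(variants=variants, calls=store.calls.copy(),
                              sample_ids=list(store.sample_ids),
                              probabilities=probs)
    return Cohort(genotypes=new_store, samples=cohort.samples, truth=cohort.truth)
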