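"""Shared in-memory containers for genotype and phenotype data.

Genotypes are stored as an additive minor-allele dosage matrix
(variants x samples) over {0, 1, 2} with ``-1`` marking a missing call,
optionally accompanied by a genotype-probability triplet per call
(p_hom_major, p_het, p_hom_minor) as produced by imputation software.
Phenotypes, binary exposures and ancestry covariates live in a pandas
DataFrame indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing hard call


@dataclass
class VariantRecord:
    """Identity and per-variant metadata for one biallelic variant."""

    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "B"
    maf: Optional[float] = None
    quality: Optional[float] = None  # imputation-quality (INFO) score; None if genotyped
    flipped: bool = False  # True if dosage orientation was flipped to the minor allele


@dataclass
class GenotypeStore:
    """Ordered variants plus the dosage matrix (and optional probability triplets).

    ``calls`` has shape (n_variants, n_samples) with values in {0, 1, 2, -1};
    ``probabilities``, when present, has shape (n_variants, n_samples, 3) and
    every triplet sums to one within 1e-6.
    """

    variants: list[VariantRecord]
    calls: np.ndarray
    sample_ids: list[str]
    probabilities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.sample_ids)} samples"
            )
        if self.probabilities is not None:
            self.probabilities = np.asarray(self.probabilities, dtype=float)
            if self.probabilities.shape != self.calls.shape + (3,):
                raise ValueError("probability array shape mismatch")
            sums = self.probabilities.sum(axis=2)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("genotype probability triplets must sum to 1 within 1e-6")
            if np.any(self.probabilities < 0):
                raise ValueError("genotype probabilities must be nonnegative")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_variants(self, index: Sequence[int]) -> "GenotypeStore":
        idx = np.asarray(index, dtype=int)
        return GenotypeStore(
            variants=[self.variants[i] for i in idx],
            calls=self.calls[idx],
            sample_ids=list(self.sample_ids),
            probabilities=None if self.probabilities is None else self.probabilities[idx],
        )

    def subset_samples(self, index: Sequence[int]) -> "GenotypeStore":
        idx = np.asarray(index, dtype=int)
        return GenotypeStore(
            variants=list(self.variants),
            calls=self.calls[:, idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            probabilities=None if self.probabilities is None else self.probabilities[:, idx],
        )


@dataclass
class SampleTable:
    """Per-sample phenotype, binary exposures and ancestry covariates.

    ``data`` is indexed by unique sample id and carries a binary ``status``
    column (1=case, 0=control), one binary column per exposure, and the
    covariate columns (ancestry principal components) in order.
    """

    data: pd.DataFrame
    exposure_names: list[str]
    covariate_names: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        for col in ["status", *self.exposure_names]:
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
            vals = self.data[col].to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                row = self.data.index[bad][0]
                raise ValueError(f"column {col!r} is not binary at sample {row!r}")
        for col in self.covariate_names:
            if col not in self.data.columns:
                raise ValueError(f"missing covariate column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def status(self) -> np.ndarray:
        return self.data["status"].to_numpy(dtype=np.int64)

    def exposure(self, name: str) -> np.ndarray:
        if name not in self.exposure_names:
            raise KeyError(f"unknown exposure {name!r}")
        return self.data[name].to_numpy(dtype=np.int64)

    def covariates(self) -> np.ndarray:
        if not self.covariate_names:
            return np.empty((len(self.data), 0))
        return self.data[self.covariate_names].to_numpy(dtype=float)


@dataclass
class Cohort:
    """A genotype store aligned with a sample table; the unit every stage consumes.

    ``truth`` holds the simulation configuration that generated the cohort,
    or None for real data.
    """

    genotypes: GenotypeStore
    samples: SampleTable
    truth: Optional[object] = None

    def __post_init__(self) -> None:
        if self.genotypes.sample_ids != self.samples.sample_ids:
            raise ValueError("genotype and sample tables are not aligned; use align_cohort")

    @property
    def n_samples(self) -> int:
        return self.samples.n_samples

    @property
    def n_variants(self) -> int:
        return self.genotypes.n_variants


def align_cohort(genotypes: GenotypeStore, samples: SampleTable, truth=None) -> Cohort:
    """Intersect a genotype store with a sample table, in sample-table order.

    Samples absent from either side are dropped; raises if the intersection
    is empty.
    """
    geno_index = {sid: i for i, sid in enumerate(genotypes.sample_ids)}
    keep_ids = [sid for sid in samples.sample_ids if sid in geno_index]
    if not keep_ids:
        raise ValueError("no samples shared between genotypes and sample table")
    store = genotypes.subset_samples([geno_index[sid] for sid in keep_ids])
    table = SampleTable(
        data=samples.data.loc[keep_ids],
        exposure_names=list(samples.exposure_names),
        covariate_names=list(samples.covariate_names),
        n_dropped=samples.n_dropped,
    )
    return Cohort(genotypes=store, samples=table, truth=truth)
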