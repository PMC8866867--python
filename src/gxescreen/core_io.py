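"""Readers and writers for genotypes, sample tables and scan results.

Two genotype dialects are supported: VCF (GT calls plus optional GP
probability triplets and a per-variant imputation-quality INFO key) parsed
with cyvcf2, and a minimal tab-separated dosage table (header of sample ids;
one variant per line: id, chrom, pos, then minor-allele dosages with "NA"
for missing).  Only biallelic records are accepted; multi-allelic records
are skipped and counted.  Dosage orientation is recomputed per dataset so
that the coded allele is the minor allele within the file's samples
(MAF <= 0.5 always); applied flips are logged per variant.

No statistics live here.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeStore, SampleTable, VariantRecord

logger = logging.getLogger(__name__)

#: stable column order of the scan-result TSV
SCAN_COLUMNS = [
    "id", "chrom", "pos", "maf", "p_joint", "beta_GE", "se_GE", "p_GE",
    "or_exposed", "or_unexposed", "status",
]


def _chrom_sort_key(chrom: str):
    # numeric chromosomes before lexicographic ones, both deterministic
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def _sort_and_orient(variants, calls, probabilities):
    """Sort by (chrom, pos, id) and flip dosage to the minor allele per variant."""
    order = sorted(
        range(len(variants)),
        key=lambda i: (_chrom_sort_key(variants[i].chrom), variants[i].pos, variants[i].id),
    )
    variants = [variants[i] for i in order]
    calls = calls[order]
    probabilities = None if probabilities is None else probabilities[order]

    n_flipped = 0
    for i, v in enumerate(variants):
        row = calls[i]
        obs = row[row != MISSING]
        freq = obs.sum() / (2 * obs.size) if obs.size else 0.0
        if freq > 0.5:
            row[row != MISSING] = 2 - row[row != MISSING]
            if probabilities is not None:
                probabilities[i] = probabilities[i, :, ::-1]
            v.ref, v.alt = v.alt, v.ref
            v.flipped = True
            freq = 1.0 - freq
            n_flipped += 1
            logger.info("flipped %s to minor-allele orientation", v.id)
        v.maf = float(freq)
    if n_flipped:
        logger.info("flipped %d/%d variants to minor-allele dosage", n_flipped, len(variants))
    return variants, calls, probabilities


def _read_vcf(path: Path, quality_key: str) -> GenotypeStore:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    call_rows: list[np.ndarray] = []
    prob_rows: list[Optional[np.ndarray]] = []
    n_skipped = 0
    seen_ids: set[str] = set()
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.info("skipped multi-allelic record %s at %s:%d", rec.ID, rec.CHROM, rec.POS)
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in seen_ids:
            raise ValueError(f"duplicated variant id {vid!r}")
        seen_ids.add(vid)
        qual = rec.INFO.get(quality_key)
        variants.append(
            VariantRecord(
                id=vid, chrom=str(rec.CHROM), pos=int(rec.POS),
                ref=rec.REF, alt=rec.ALT[0],
                quality=None if qual is None else float(qual),
            )
        )
        call_rows.append(gt_map[rec.gt_types])
        try:
            gp = rec.format("GP")
        except KeyError:
            gp = None
        prob_rows.append(None if gp is None else np.asarray(gp, dtype=float))
    if n_skipped:
        logger.info("skipped %d multi-allelic records in %s", n_skipped, path)
    if not variants:
        raise ValueError(f"no biallelic variants parsed from {path}")
    calls = np.vstack(call_rows)
    if any(p is not None for p in prob_rows):
        probs = np.stack([
            p if p is not None else np.full((len(sample_ids), 3), np.nan)
            for p in prob_rows
        ])
    else:
        probs = None
    variants, calls, probs = _sort_and_orient(variants, calls, probs)
    store = GenotypeStore(variants=variants, calls=calls, sample_ids=sample_ids,
                          probabilities=probs)
    store.n_skipped = n_skipped  # type: ignore[attr-defined]
    return store


def _read_dosage_table(path: Path) -> GenotypeStore:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "chrom", "pos"]:
            raise ValueError(f"{path}: dosage table must start with id, chrom, pos columns")
        sample_ids = header[3:]
        variants: list[VariantRecord] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + len(sample_ids):
                raise ValueError(f"{path}:{lineno}: expected {3 + len(sample_ids)} fields")
            vid = fields[0]
            if vid in seen:
                raise ValueError(f"duplicated variant id {vid!r}")
            seen.add(vid)
            try:
                pos = int(fields[2])
                doses = [MISSING if f == "NA" else int(f) for f in fields[3:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from None
            if any(d not in (0, 1, 2, MISSING) for d in doses):
                raise ValueError(f"{path}:{lineno}: dosage outside {{0,1,2,NA}}")
            variants.append(VariantRecord(id=vid, chrom=fields[1], pos=pos))
            rows.append(doses)
    if not variants:
        raise ValueError(f"no variants parsed from {path}")
    calls = np.array(rows, dtype=np.int8)
    variants, calls, _ = _sort_and_orient(variants, calls, None)
    return GenotypeStore(variants=variants, calls=calls, sample_ids=sample_ids)


def read_genotypes(path, dialect: str = "vcf", quality_key: str = "INFO") -> GenotypeStore:
    """Read a genotype file into a :class:`GenotypeStore`.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"vcf"`` (GT and optional GP fields; imputation quality from the
        INFO key ``quality_key``) or ``"dosage-table"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "vcf":
        return _read_vcf(path, quality_key)
    if dialect == "dosage-table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_samples(path, exposure_names: Iterable[str]) -> SampleTable:
    """Read a TSV sample table, keeping only samples with complete data.

    Rows with a missing status or any missing exposure are dropped and
    counted (``n_dropped``); a non-binary status or exposure value raises.
    Covariate columns are auto-detected as ``PC1``, ``PC2``, ... in numeric
    order.
    """
    exposure_names = list(exposure_names)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "status", *exposure_names]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"sample table missing column {col!r}")
    check_cols = ["status", *exposure_names]
    complete = df[check_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    kept = df[complete].copy()
    for col in check_cols:
        vals = kept[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            sid = kept.loc[bad, "sample_id"].iloc[0]
            raise ValueError(f"non-binary value in column {col!r} at sample {sid!r}")
        kept[col] = kept[col].astype(np.int64)
    pc_cols = sorted(
        (c for c in kept.columns if re.fullmatch(r"PC\d+", c)),
        key=lambda c: int(c[2:]),
    )
    kept = kept.set_index("sample_id")
    if n_dropped:
        logger.info("dropped %d samples with incomplete status/exposure data", n_dropped)
    return SampleTable(
        data=kept,
        exposure_names=exposure_names,
        covariate_names=pc_cols,
        n_dropped=n_dropped,
    )


def write_samples(table: SampleTable, path) -> None:
    """Write a sample table as TSV (inverse of :func:`read_samples`)."""
    df = table.data.reset_index(names="sample_id")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_vcf(store: GenotypeStore, path, quality_key: str = "INFO") -> None:
    """Write a genotype store as an uncompressed VCF with GT (and GP) fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=%s,Number=1,Type=Float,Description="Imputation quality score">\n'
                 % quality_key)
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if store.probabilities is not None:
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,'
                     'Description="Genotype probabilities">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(store.sample_ids) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        fmt = "GT" if store.probabilities is None else "GT:GP"
        for i, v in enumerate(store.variants):
            info = "." if v.quality is None else f"{quality_key}={v.quality:.6g}"
            cols = [v.chrom, str(v.pos), v.id, v.ref, v.alt, ".", "PASS", info, fmt]
            for j in range(store.n_samples):
                cell = gt_str[int(store.calls[i, j])]
                if store.probabilities is not None:
                    cell += ":" + ",".join(f"{p:.8f}" for p in store.probabilities[i, j])
                cols.append(cell)
            fh.write("\t".join(cols) + "\n")


def write_dosage_table(store: GenotypeStore, path) -> None:
    """Write a genotype store in the dosage-table dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "chrom", "pos", *store.sample_ids]) + "\n")
        for i, v in enumerate(store.variants):
            doses = ["NA" if c == MISSING else str(int(c)) for c in store.calls[i]]
            fh.write("\t".join([v.id, v.chrom, str(v.pos), *doses]) + "\n")


def scan_results_frame(results) -> pd.DataFrame:
    """Convert a list of ScanResult objects to a DataFrame in stable column order."""
    rows = []
    for r in results:
        rows.append({
            "id": r.variant.id, "chrom": r.variant.chrom, "pos": r.variant.pos,
            "maf": r.variant.maf, "p_joint": r.p_joint, "beta_GE": r.beta_GE,
            "se_GE": r.se_GE, "p_GE": r.p_GE, "or_exposed": r.or_exposed,
            "or_unexposed": r.or_unexposed, "status": r.status,
        })
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def write_scan_results(results, path) -> None:
    """Write per-variant scan results as TSV with full numeric precision."""
    results = list(results)
    if not results:
        raise ValueError("no scan results to write")
    scan_results_frame(results).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scan_results(path) -> pd.DataFrame:
    """Read a scan-result TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
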