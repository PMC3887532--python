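"""Readers and writers for the external formats the pipeline consumes.

Supported formats: VCF 4.x (via cyvcf2), a HapMap-like tab table with
single-letter IUPAC genotype columns, annotation/phenotype/structure TSVs,
and BED3 interval files. Also houses the consensus rule that merges the
two protein-level predictors into a single deleteriousness class.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (DELETERIOUS, MISSING, SYNONYMOUS, TOLERATED,
                   GenotypeMatrix, PanelError, PanelStructure)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a bi-allelic diploid VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are dropped with a logged count. Non-diploid GT
    entries raise :class:`PanelError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        calls = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            if len(gt) != 3:  # [a0, a1, phased]
                raise PanelError(
                    f"non-diploid genotype for sample {samples[i]} at "
                    f"{v.CHROM}:{v.POS}"
                )
            a0, a1 = gt[0], gt[1]
            calls[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(calls)
    vcf.close()
    if n_multi:
        log.info("dropped %d multi-allelic records from %s", n_multi, path)
    calls_arr = (np.column_stack(rows) if rows
                 else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, snp_ids, np.array(chrom, dtype=object),
                          np.array(pos), np.array(ref, dtype=object),
                          np.array(alt, dtype=object), calls_arr)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=delload\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(matrix.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.line_ids) + "\n")
        for j in range(matrix.n_snps):
            gts = "\t".join(_GT_STR[int(g)] for g in matrix.calls[:, j])
            fh.write(f"{matrix.chrom[j]}\t{matrix.pos[j]}\t{matrix.snp_ids[j]}\t"
                     f"{matrix.ref[j]}\t{matrix.alt[j]}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# HapMap-like tab format

_HET_CODE = {frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
             frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K"}
_HET_DECODE = {v: k for k, v in _HET_CODE.items()}


def read_hapmap(path: str | Path, strict: bool = True) -> GenotypeMatrix:
    """Read the HapMap-like tab table (rs, alleles, chrom, pos, one column
    per line; genotypes as single IUPAC letters, ``N`` for missing).

    In strict mode a genotype letter inconsistent with the declared alleles
    raises; in permissive mode it becomes a missing call.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rs", "alleles", "chrom", "pos"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PanelError(f"hapmap table missing columns {missing_cols}")
    line_ids = [c for c in df.columns if c not in required]
    n_snps = len(df)
    calls = np.full((len(line_ids), n_snps), MISSING, dtype=np.int8)
    ref = np.empty(n_snps, dtype=object)
    alt = np.empty(n_snps, dtype=object)
    for j, (_, row) in enumerate(df.iterrows()):
        try:
            a_ref, a_alt = row["alleles"].split("/")
        except ValueError:
            raise PanelError(f"bad alleles field {row['alleles']!r} at SNP {row['rs']}")
        ref[j], alt[j] = a_ref, a_alt
        het = _HET_CODE.get(frozenset((a_ref, a_alt)))
        for i, lid in enumerate(line_ids):
            g = row[lid]
            if g == "N" or (isinstance(g, float) and np.isnan(g)):
                continue
            if g == a_ref:
                calls[i, j] = 0
            elif g == a_alt:
                calls[i, j] = 2
            elif het is not None and g == het:
                calls[i, j] = 1
            elif strict:
                raise PanelError(
                    f"genotype {g!r} inconsistent with alleles "
                    f"{row['alleles']!r} for line {lid} at SNP {row['rs']}"
                )
            # permissive: leave missing
    return GenotypeMatrix(line_ids, list(df["rs"]),
                          df["chrom"].to_numpy(dtype=object),
                          df["pos"].astype(int).to_numpy(),
                          ref, alt, calls)


def write_hapmap(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the HapMap-like tab format (inverse of :func:`read_hapmap`)."""
    cols = {"rs": matrix.snp_ids,
            "alleles": [f"{r}/{a}" for r, a in zip(matrix.ref, matrix.alt)],
            "chrom": matrix.chrom, "pos": matrix.pos}
    codes = np.empty((matrix.n_lines, matrix.n_snps), dtype=object)
    for j in range(matrix.n_snps):
        het = _HET_CODE.get(frozenset((matrix.ref[j], matrix.alt[j])))
        lut = {0: matrix.ref[j], 2: matrix.alt[j], 1: het or "N", MISSING: "N"}
        for i in range(matrix.n_lines):
            codes[i, j] = lut[int(matrix.calls[i, j])]
    for i, lid in enumerate(matrix.line_ids):
        cols[lid] = codes[i, :]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Predictor merging and congruence

_DEL_CALLS = frozenset(("deleterious", "stop"))


def merge_predictions(sift_call: str, mapp_call: str) -> str:
    """Consensus deleteriousness class from two predictor calls.

    The union rule: a SNP is deleterious if either predictor calls it
    deleterious (or a premature stop); tolerated if at least one predictor
    says tolerated and none says deleterious; unknown if both are missing.
    Symmetric in its two arguments.
    """
    calls = {sift_call, mapp_call}
    bad = calls - {"tolerated", "deleterious", "stop", "missing"}
    if bad:
        raise PanelError(f"unknown predictor call(s) {sorted(bad)}")
    if calls & _DEL_CALLS:
        return DELETERIOUS
    if "tolerated" in calls:
        return TOLERATED
    return "unknown"


def merge_predictions_frame(annotation: pd.DataFrame) -> pd.DataFrame:
    """Fill ``codon_class`` for nonsynonymous rows from sift/mapp calls.

    Rows already marked synonymous are left untouched; everything else gets
    the :func:`merge_predictions` consensus.
    """
    out = annotation.copy()
    is_syn = out["codon_class"].eq(SYNONYMOUS) if "codon_class" in out else \
        pd.Series(False, index=out.index)
    merged = [merge_predictions(s, m)
              for s, m in zip(out["sift_call"].fillna("missing"),
                              out["mapp_call"].fillna("missing"))]
    out["codon_class"] = np.where(is_syn, SYNONYMOUS, merged)
    return out


def predictor_congruence(annotation: pd.DataFrame) -> float:
    """Fraction of doubly-annotated codons where the two predictors agree.

    Agreement is on the binary deleterious-vs-tolerated classification
    (premature stops count as deleterious). Codons with either call missing
    are excluded from numerator and denominator.
    """
    sift = annotation["sift_call"].fillna("missing")
    mapp = annotation["mapp_call"].fillna("missing")
    both = (sift != "missing") & (mapp != "missing")
    if not both.any():
        raise PanelError("no codons with both predictor calls present")
    s_del = sift[both].isin(_DEL_CALLS)
    m_del = mapp[both].isin(_DEL_CALLS)
    return float((s_del == m_del).mean())


# ---------------------------------------------------------------------------
# BED intervals

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3 file (0-based half-open intervals); tolerates unsorted input."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str})
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def interval_flags(matrix: GenotypeMatrix, bed_path: str | Path) -> np.ndarray:
    """Boolean flag per SNP: does the SNP fall in any BED interval?

    A SNP at 1-based position ``p`` on chromosome ``c`` is flagged iff some
    0-based half-open interval ``[start, end)`` on ``c`` satisfies
    ``start < p <= end``. Intervals on chromosomes absent from the matrix
    are ignored; overlapping intervals are merged first.
    """
    bed = read_bed(bed_path)
    flags = np.zeros(matrix.n_snps, dtype=bool)
    pos0 = matrix.pos - 1  # 0-based coordinate of each SNP
    for c, sub in bed.groupby("chrom"):
        snp_idx = np.flatnonzero(matrix.chrom == c)
        if snp_idx.size == 0:
            continue
        # merge overlapping/adjacent intervals
        starts, ends = [], []
        for s, e in zip(sub["start"], sub["end"]):
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        starts_a = np.asarray(starts)
        ends_a = np.asarray(ends)
        p = pos0[snp_idx]
        k = np.searchsorted(starts_a, p, side="right") - 1
        inside = (k >= 0) & (p < ends_a[np.clip(k, 0, None)])
        flags[snp_idx[inside]] = True
    return flags


def interval_annotate(annotation: pd.DataFrame, matrix: GenotypeMatrix,
                      bed_path: str | Path, flag_name: str) -> pd.DataFrame:
    """Add a boolean region-membership column ``flag_name`` to the annotation.

    The annotation is aligned to the matrix SNPs by ``snp_id``.
    """
    flags = pd.Series(interval_flags(matrix, bed_path), index=matrix.snp_ids)
    out = annotation.copy()
    out[flag_name] = annotation["snp_id"].map(flags).fillna(False).astype(bool)
    return out


# ---------------------------------------------------------------------------
# Plain TSV tables

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-SNP annotation TSV (snp_id, gene_id, codon_class,
    sift_call, mapp_call, outgroup_allele plus optional flag columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    if "snp_id" not in df.columns:
        raise PanelError("annotation table lacks a snp_id column")
    for col in df.columns:
        if col.startswith(("phs_selected", "region_")):
            df[col] = df[col].astype(bool)
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    from .core import validate_phenotypes
    df = pd.read_csv(path, sep="\t", dtype={"genotype_id": str, "trait": str,
                                            "environment": str})
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_structure(path: str | Path) -> PanelStructure:
    """Read line group assignments + Q covariates (line_id, group, q1..qk)."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "group": str})
    qcols = [c for c in df.columns if c.startswith("q")]
    return PanelStructure(list(df["line_id"]), df["group"].to_numpy(dtype=object),
                          df[qcols].to_numpy(dtype=float))


def write_structure(structure: PanelStructure, path: str | Path) -> None:
    cols = {"line_id": structure.line_ids, "group": structure.groups}
    for k in range(structure.q.shape[1]):
        cols[f"q{k + 1}"] = structure.q[:, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
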