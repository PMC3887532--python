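"""Core in-memory containers shared across the pipeline.

Genotypes are stored as an integer matrix of alternate-allele dosages
(lines x SNPs, values 0/1/2) with ``MISSING`` (-1) marking no-calls.
Positions are 1-based, following VCF convention; BED intervals are
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Functional classes a coding SNP may be assigned to.
CODON_CLASSES = ("synonymous", "nonsyn_tolerated", "nonsyn_deleterious", "unknown")

#: Vocabulary for per-predictor deleteriousness calls.
PREDICTOR_CALLS = ("tolerated", "deleterious", "stop", "missing")

DELETERIOUS = "nonsyn_deleterious"
TOLERATED = "nonsyn_tolerated"
SYNONYMOUS = "synonymous"


class PanelError(ValueError):
    """Raised for structurally invalid panel inputs."""


@dataclass
class GenotypeMatrix:
    """Bi-allelic genotype calls for a panel of (nominally inbred) lines.

    Parameters
    ----------
    line_ids
        Identifier per line (row).
    snp_ids
        Identifier per SNP (column).
    chrom, pos
        Chromosome label and 1-based position per SNP. Positions must be
        strictly increasing within each chromosome.
    ref, alt
        Reference and alternate allele characters (``ref != alt``).
    calls
        ``(n_lines, n_snps)`` int8 array of alternate-allele dosages in
        {0, 1, 2} with ``MISSING`` for no-calls.
    """

    line_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.snp_ids = list(self.snp_ids)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_lines, n_snps = len(self.line_ids), len(self.snp_ids)
        if self.calls.shape != (n_lines, n_snps):
            raise PanelError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{n_lines} lines x {n_snps} SNPs"
            )
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if arr.shape != (n_snps,):
                raise PanelError(f"{name} has length {arr.shape}, expected {n_snps}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"invalid call {self.calls[i, j]} at line {self.line_ids[i]}, "
                f"SNP {self.snp_ids[j]}"
            )
        same = (self.ref == self.alt)
        if same.any():
            j = int(np.flatnonzero(same)[0])
            raise PanelError(f"ref == alt at SNP {self.snp_ids[j]}")
        # strictly increasing positions within each chromosome (input order)
        if n_snps > 1:
            same_chrom = self.chrom[1:] == self.chrom[:-1]
            nondecr = self.pos[1:] <= self.pos[:-1]
            bad_pos = same_chrom & nondecr
            if bad_pos.any():
                j = int(np.flatnonzero(bad_pos)[0]) + 1
                raise PanelError(
                    f"positions not strictly increasing at SNP {self.snp_ids[j]} "
                    f"({self.chrom[j]}:{self.pos[j]})"
                )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def calls_float(self) -> np.ndarray:
        """Calls as float with ``nan`` in place of missing."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def nonmissing(self) -> np.ndarray:
        """Boolean mask of observed calls."""
        return self.calls != MISSING

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP by allele counting.

        A heterozygous call contributes one allele of each kind; missing
        calls are excluded. Monomorphic-after-missing SNPs may return 0 or 1;
        SNPs with no observed calls return ``nan``.
        """
        obs = self.nonmissing()
        n_alleles = 2 * obs.sum(axis=0)
        alt_count = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt_count / n_alleles, np.nan)

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(line_id)
        except ValueError:
            raise PanelError(f"unknown line id {line_id!r}") from None

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.line_index(l) for l in line_ids]
        return GenotypeMatrix(list(line_ids), self.snp_ids, self.chrom, self.pos,
                              self.ref, self.alt, self.calls[idx, :])

    def subset_snps(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.line_ids,
                              [self.snp_ids[i] for i in idx],
                              self.chrom[idx], self.pos[idx],
                              self.ref[idx], self.alt[idx],
                              self.calls[:, idx])


@dataclass
class PanelStructure:
    """Group assignment per line plus structure covariates (Q) for the MLM.

    ``q`` holds STRUCTURE-style membership covariates, one row per line;
    for hard assignments this is the one-hot group coding with the last
    column dropped (so the intercept stays identifiable).
    """

    line_ids: list[str]
    groups: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.groups = np.asarray(self.groups, dtype=object)
        self.q = np.asarray(self.q, dtype=float)
        n = len(self.line_ids)
        if self.groups.shape != (n,):
            raise PanelError("groups length inconsistent with line_ids")
        if self.q.ndim != 2 or self.q.shape[0] != n:
            raise PanelError("Q matrix rows inconsistent with line_ids")

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def align(self, line_ids: Sequence[str]) -> "PanelStructure":
        """Reorder/subset to the given line ids."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            idx = [pos[l] for l in line_ids]
        except KeyError as e:
            raise PanelError(f"line {e.args[0]!r} missing from structure") from None
        return PanelStructure(list(line_ids), self.groups[idx], self.q[idx, :])


def one_hot_q(groups: Sequence[str], group_order: Sequence[str] | None = None) -> np.ndarray:
    """One-hot group membership with the last group's column dropped."""
    groups = np.asarray(groups, dtype=object)
    if group_order is None:
        group_order = list(dict.fromkeys(groups))
    cols = [np.asarray(groups == g, dtype=float) for g in group_order[:-1]]
    if not cols:
        return np.zeros((len(groups), 0))
    return np.column_stack(cols)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check the (genotype_id, trait, environment, value) long format.

    At most one observation is allowed per (genotype, trait, environment).
    """
    required = ["genotype_id", "trait", "environment", "value"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PanelError(f"phenotype table missing columns {missing_cols}")
    dup = df.duplicated(subset=["genotype_id", "trait", "environment"])
    if dup.any():
        row = df[dup].iloc[0]
        raise PanelError(
            "duplicate phenotype record for "
            f"({row['genotype_id']}, {row['trait']}, {row['environment']})"
        )
    return df
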