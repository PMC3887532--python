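"""Enrichment of deleterious variants among significant associations.

SNP-level and gene-level fold enrichment with two-sided Fisher's exact
tests, matched controls stratified by per-gene SNP counts, a
low-frequency-synonymous specificity control, and the exact cross-trait
sign test on per-trait fold enrichments.

Fold enrichment is the ratio of proportions

    f = [a / (a + b)] / [(a + c) / (a + b + c + d)]

where the 2x2 table counts (significant & deleterious, significant & not,
non-significant & deleterious, non-significant & not). Under the null
f ~ 1, and the Fisher test on the same table supplies the p-value;
enrichment direction is carried by f, the test is two-sided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DELETERIOUS, SYNONYMOUS, PanelError

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """2x2 enrichment summary at SNP or gene level."""

    level: str                 # "snp" | "gene"
    a: int                     # significant & deleterious
    b: int                     # significant & not deleterious
    c: int                     # non-significant & deleterious
    d: int                     # non-significant & not deleterious
    fold: float
    fisher_p: float
    trait: str | None = None
    scan: str | None = None

    @property
    def n_significant(self) -> int:
        return self.a + self.b

    def recompute_fold(self) -> float:
        """Fold enrichment recomputed from the stored counts."""
        return _fold(self.a, self.b, self.c, self.d)


def _fold(a: int, b: int, c: int, d: int) -> float:
    total = a + b + c + d
    sig = a + b
    delete = a + c
    if sig == 0 or delete == 0 or total == 0:
        return float("nan")
    return (a / sig) / (delete / total)


def _fisher(a: int, b: int, c: int, d: int) -> float:
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def _result(level: str, sig: np.ndarray, dele: np.ndarray,
            trait: str | None, scan: str | None) -> EnrichmentResult:
    a = int((sig & dele).sum())
    b = int((sig & ~dele).sum())
    c = int((~sig & dele).sum())
    d = int((~sig & ~dele).sum())
    if a + c == 0:
        log.warning("no deleterious members in the %s universe; fold undefined",
                    level)
    return EnrichmentResult(level=level, a=a, b=b, c=c, d=d,
                            fold=_fold(a, b, c, d),
                            fisher_p=_fisher(a, b, c, d),
                            trait=trait, scan=scan)


def snp_enrichment(results: pd.DataFrame, annotation: pd.DataFrame,
                   genic_only: bool = True,
                   significance_col: str = "significant_p",
                   trait: str | None = None, scan: str | None = None,
                   ) -> EnrichmentResult:
    """Fold enrichment of deleterious SNPs among significant associations.

    The universe is the set of tested SNPs (rows of ``results``),
    restricted to genic SNPs when ``genic_only`` (association enrichment
    is reported for genic regions).
    """
    ann = annotation.set_index("snp_id")
    df = results.merge(annotation[["snp_id", "gene_id", "codon_class"]],
                       on="snp_id", how="left")
    if genic_only:
        df = df[df["gene_id"].notna()]
    if df.empty or not df[significance_col].any():
        raise PanelError("no significant genic SNPs to test")
    sig = df[significance_col].to_numpy(dtype=bool)
    dele = (df["codon_class"] == DELETERIOUS).to_numpy()
    return _result("snp", sig, dele, trait, scan)


def gene_enrichment(results: pd.DataFrame, annotation: pd.DataFrame,
                    significance_col: str = "significant_p",
                    trait: str | None = None, scan: str | None = None,
                    deleterious_genes: set[str] | None = None,
                    gene_universe: Sequence[str] | None = None,
                    ) -> EnrichmentResult:
    """Gene-level fold enrichment.

    The gene universe is every gene with at least one tested SNP. A gene
    is significant iff at least one of its tested SNPs is significant, and
    deleterious iff it contains at least one annotated deleterious SNP —
    tested or not, since most deleterious SNPs sit below the
    allele-frequency filter of the scans.
    """
    df = results.merge(annotation[["snp_id", "gene_id"]], on="snp_id",
                       how="left")
    df = df[df["gene_id"].notna()]
    if gene_universe is None:
        gene_universe = sorted(set(df["gene_id"]))
    if len(gene_universe) == 0:
        raise PanelError("empty gene universe")
    if deleterious_genes is None:
        deleterious_genes = set(
            annotation.loc[annotation["codon_class"] == DELETERIOUS, "gene_id"]
            .dropna())
    sig_genes = set(df.loc[df[significance_col].astype(bool), "gene_id"])
    genes = np.asarray(list(gene_universe), dtype=object)
    sig = np.isin(genes, list(sig_genes))
    dele = np.isin(genes, list(deleterious_genes))
    return _result("gene", sig, dele, trait, scan)


def sign_test(fold_enrichments: Sequence[float]) -> dict:
    """Exact two-sided sign test of H0: P(f > 1) = 1/2.

    Values exactly equal to 1 are excluded (reducing n); the p-value
    doubles the smaller exact binomial tail, capped at 1.
    """
    f = np.asarray(fold_enrichments, dtype=float)
    f = f[np.isfinite(f)]
    n_pos = int((f > 1).sum())
    n_neg = int((f < 1).sum())
    n = n_pos + n_neg
    if n == 0:
        raise PanelError("all fold enrichments tie at exactly 1")
    # exact binomial tails at p = 1/2 via integer summation
    def tail_ge(k: int) -> float:
        return sum(math.comb(n, i) for i in range(k, n + 1)) / 2.0 ** n
    def tail_le(k: int) -> float:
        return sum(math.comb(n, i) for i in range(0, k + 1)) / 2.0 ** n
    p = 2.0 * min(tail_ge(n_pos), tail_le(n_pos))
    return {"n_positive": n_pos, "n_negative": n_neg, "n": n,
            "p_value": min(p, 1.0)}


def matched_gene_control(results: pd.DataFrame, annotation: pd.DataFrame,
                         snp_count_bins: Sequence[float] = (0, 2, 5, 10, np.inf),
                         significance_col: str = "significant_p",
                         low_freq_threshold: float = 0.05,
                         freq_table: pd.DataFrame | None = None,
                         min_genes_per_bin: int = 5,
                         trait: str | None = None, scan: str | None = None,
                         ) -> dict:
    """Gene-level enrichment within strata of per-gene tested-SNP counts,
    plus a low-frequency-synonymous control.

    ``snp_count_bins`` are edges partitioning the gene universe by tested
    SNP count (half-open, right edge exclusive); bins with fewer than
    ``min_genes_per_bin`` genes are skipped with a warning. The control
    analysis replaces "contains a deleterious SNP" with "contains a
    synonymous SNP of derived frequency below ``low_freq_threshold``",
    which requires ``freq_table`` (the polarization output).

    Returns ``{"bins": [per-bin EnrichmentResult], "control":
    EnrichmentResult | None}``.
    """
    df = results.merge(annotation[["snp_id", "gene_id"]], on="snp_id",
                       how="left")
    df = df[df["gene_id"].notna()]
    per_gene = df.groupby("gene_id").size()
    edges = np.asarray(snp_count_bins, dtype=float)

    bin_results: list[EnrichmentResult] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        genes = per_gene[(per_gene >= lo) & (per_gene < hi)].index.tolist()
        if len(genes) < min_genes_per_bin:
            log.warning("SNP-count bin [%g, %g) has %d genes; skipped",
                        lo, hi, len(genes))
            continue
        res = gene_enrichment(results, annotation,
                              significance_col=significance_col,
                              trait=trait, scan=scan, gene_universe=genes)
        bin_results.append(res)

    control = None
    if freq_table is not None:
        syn = annotation.merge(
            freq_table[["snp_id", "derived_freq", "polarized"]], on="snp_id")
        low_syn = syn[(syn["codon_class"] == SYNONYMOUS) & syn["polarized"]
                      & (syn["derived_freq"] < low_freq_threshold)]
        control_genes = set(low_syn["gene_id"].dropna())
        control = gene_enrichment(results, annotation,
                                  significance_col=significance_col,
                                  trait=trait, scan=scan,
                                  deleterious_genes=control_genes)
    return {"bins": bin_results, "control": control}


def enrichment_table(results_by_trait: dict[str, pd.DataFrame],
                     annotation: pd.DataFrame, level: str = "gene",
                     significance_col: str = "significant_p",
                     scan: str | None = None) -> pd.DataFrame:
    """Per-trait enrichment summary (one row per trait) plus the fold
    values needed for the cross-trait sign test."""
    rows = []
    for trait, res in results_by_trait.items():
        try:
            if level == "gene":
                r = gene_enrichment(res, annotation, significance_col,
                                    trait=trait, scan=scan)
            else:
                r = snp_enrichment(res, annotation, True, significance_col,
                                   trait=trait, scan=scan)
        except PanelError as e:
            log.warning("trait %s: %s", trait, e)
            continue
        rows.append({"trait": trait, "scan": scan, "level": level,
                     "n_significant": r.n_significant, "fold": r.fold,
                     "fisher_p": r.fisher_p, "a": r.a, "b": r.b,
                     "c": r.c, "d": r.d})
    return pd.DataFrame(rows)
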