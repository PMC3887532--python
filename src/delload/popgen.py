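"""Population-genetic characterization of a structured inbred panel.

Covers outgroup polarization of the site frequency spectrum, per-class SFS
contrasts, per-SNP multi-group Weir-Cockerham F_ST with frequency-matched
tail comparisons, the joint SFS between groups, identity-by-state and
deleterious-allele-sharing matrices, per-line deleterious load, and
windowed genome summaries.

Allele frequencies are computed by allele counting over non-missing calls;
a heterozygous call contributes one allele of each kind. This keeps the
~1% residual heterozygosity of inbred panels in the counts (callers who
prefer to drop heterozygotes can mask them to missing first).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (DELETERIOUS, MISSING, SYNONYMOUS, TOLERATED,
                   GenotypeMatrix, PanelError, PanelStructure)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Polarization and the SFS

def polarize(matrix: GenotypeMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Derived-allele frequencies using the outgroup allele as ancestral.

    The derived allele is the one *not* matching the outgroup. SNPs whose
    outgroup allele is missing or matches neither allele are flagged
    ``polarized=False`` with an undefined frequency (not an error).

    Returns a table aligned to the matrix SNPs with columns ``snp_id``,
    ``polarized``, ``derived_is_alt``, ``derived_freq`` and ``n_alleles``.
    """
    out_allele = (annotation.set_index("snp_id")["outgroup_allele"]
                  .reindex(matrix.snp_ids))
    out_arr = out_allele.fillna("").to_numpy(dtype=object)
    alt_freq = matrix.alt_freq()
    obs = matrix.nonmissing()
    n_alleles = 2 * obs.sum(axis=0)

    derived_is_alt = out_arr == matrix.ref
    derived_is_ref = out_arr == matrix.alt
    polarized = derived_is_alt | derived_is_ref
    freq = np.where(derived_is_alt, alt_freq, 1.0 - alt_freq)
    freq = np.where(polarized, freq, np.nan)
    return pd.DataFrame({
        "snp_id": matrix.snp_ids,
        "polarized": polarized,
        "derived_is_alt": derived_is_alt,
        "derived_freq": freq,
        "n_alleles": n_alleles,
    })


def derived_dosage(matrix: GenotypeMatrix, polar: pd.DataFrame) -> np.ndarray:
    """Derived-allele dosage matrix (nan for missing or unpolarized SNPs)."""
    d = matrix.calls_float()
    flip = ~polar["derived_is_alt"].to_numpy() & polar["polarized"].to_numpy()
    d[:, flip] = 2.0 - d[:, flip]
    d[:, ~polar["polarized"].to_numpy()] = np.nan
    return d


def _bin_index(freqs: np.ndarray, n_bins: int) -> np.ndarray:
    """Half-open equal-width bins on [0, 1], last bin closed.

    A small absolute tolerance keeps decimal edges exact (0.6 with 10 bins
    belongs to [0.6, 0.7) despite binary floating point).
    """
    idx = np.floor(np.asarray(freqs, dtype=float) * n_bins + 1e-9).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def sfs_by_class(polar: pd.DataFrame, annotation: pd.DataFrame,
                 n_bins: int = 20,
                 classes: Sequence[str] = (SYNONYMOUS, TOLERATED, DELETERIOUS),
                 ) -> pd.DataFrame:
    """Binned derived SFS per functional class, as proportions.

    Bins are half-open on [0, 1] with the last bin closed. Rows are
    classes, columns ``bin_<lower>``; proportions sum to 1 per non-empty
    class. Empty classes yield a row of NaN with a logged warning.
    """
    merged = polar.merge(annotation[["snp_id", "codon_class"]], on="snp_id")
    rows = {}
    for cls in classes:
        freqs = merged.loc[(merged["codon_class"] == cls) & merged["polarized"],
                           "derived_freq"].to_numpy()
        if freqs.size == 0:
            log.warning("no polarized SNPs in class %s; empty spectrum", cls)
            rows[cls] = np.full(n_bins, np.nan)
            continue
        counts = np.bincount(_bin_index(freqs, n_bins), minlength=n_bins)
        rows[cls] = counts / counts.sum()
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"bin_{k / n_bins:.3f}" for k in range(n_bins)])
    out.index.name = "codon_class"
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney frequency contrast

_EXACT_ENUM_LIMIT = 200_000  # max rank-splits to enumerate when ties present


def compare_sfs(freqs_a: Sequence[float], freqs_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value comparing two frequency samples.

    Exact when both samples have <= 50 values: via the exact U distribution
    when there are no ties, or by full enumeration of rank splits when ties
    are present and the split count is manageable. Otherwise the
    tie-corrected normal approximation is used.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PanelError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = a.size <= 50 and b.size <= 50
    if small and not has_ties:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact").pvalue)
    if small and has_ties and math.comb(a.size + b.size, a.size) <= _EXACT_ENUM_LIMIT:
        return _mannwhitney_exact_ties(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def _mannwhitney_exact_ties(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided MWU by enumerating all assignments of pooled values
    (midranks) to the two groups; p = P(|U - E[U]| >= |u_obs - E[U]|)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n = a.size, pooled.size
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST

def fst_per_snp(matrix: GenotypeMatrix, structure: PanelStructure,
                groups_subset: Sequence[str] | None = None,
                polar: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-SNP multi-population Weir-Cockerham (1984) theta.

    Groups contribute alleles by count (a heterozygote supplies one of
    each); per SNP, groups with fewer than two sampled alleles (one line)
    are excluded, and at least two eligible groups are required. SNPs
    monomorphic across the included groups get an undefined (NaN) estimate.

    When ``polar`` is given, reported per-group frequencies are of the
    derived allele (theta itself is orientation-invariant).

    Returns a table with ``snp_id``, ``fst``, ``n_groups_used``,
    ``overall_freq``, ``maf`` and per-group frequency/count columns.
    """
    structure = structure.align(matrix.line_ids)
    names = (list(groups_subset) if groups_subset is not None
             else structure.group_names)
    if len(names) < 2:
        raise PanelError("F_ST needs at least two groups")
    calls = matrix.calls
    obs = calls != MISSING
    r_max = len(names)
    n_g = np.zeros((r_max, matrix.n_snps))     # diploid individuals observed
    p_g = np.zeros((r_max, matrix.n_snps))     # alt-allele frequency
    h_g = np.zeros((r_max, matrix.n_snps))     # observed het fraction
    for k, name in enumerate(names):
        rows = structure.group_mask(name)
        if not rows.any():
            raise PanelError(f"group {name!r} has no lines")
        sub = calls[rows]
        sub_obs = obs[rows]
        cnt = sub_obs.sum(axis=0)
        n_g[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p_g[k] = np.where(cnt > 0,
                              np.where(sub_obs, sub, 0).sum(axis=0) / (2 * cnt),
                              np.nan)
            h_g[k] = np.where(cnt > 0,
                              np.where(sub_obs, sub == 1, False).sum(axis=0) / cnt,
                              np.nan)

    eligible = n_g >= 1
    r = eligible.sum(axis=0).astype(float)
    n_eff = np.where(eligible, n_g, 0.0)
    p_eff = np.where(eligible, np.nan_to_num(p_g), 0.0)
    h_eff = np.where(eligible, np.nan_to_num(h_g), 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_eff.sum(axis=0) / r
        nc = (r * nbar - (n_eff ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_eff * p_eff).sum(axis=0) / (r * nbar)
        s2 = (n_eff * (p_eff - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_eff * h_eff).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)

    invalid = (r < 2) | (nbar <= 1)
    theta = np.where(invalid, np.nan, theta)
    overall = np.where(invalid, np.nan, pbar)

    out = pd.DataFrame({"snp_id": matrix.snp_ids, "fst": theta,
                        "n_groups_used": r.astype(int),
                        "overall_freq": overall,
                        "maf": np.minimum(overall, 1 - overall)})
    if polar is not None:
        flip = (~polar["derived_is_alt"].to_numpy()
                & polar["polarized"].to_numpy())
        for k, name in enumerate(names):
            f = p_g[k].copy()
            f[flip] = 1.0 - f[flip]
            f[~polar["polarized"].to_numpy()] = np.nan
            out[f"freq_{name}"] = f
            out[f"n_{name}"] = n_g[k].astype(int)
    else:
        for k, name in enumerate(names):
            out[f"freq_{name}"] = p_g[k]
            out[f"n_{name}"] = n_g[k].astype(int)
    return out


def fst_pairwise_mean(matrix: GenotypeMatrix, structure: PanelStructure,
                      groups_subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-SNP mean of pairwise two-group theta over all group pairs."""
    structure = structure.align(matrix.line_ids)
    names = (list(groups_subset) if groups_subset is not None
             else structure.group_names)
    acc = np.zeros(matrix.n_snps)
    cnt = np.zeros(matrix.n_snps)
    for g1, g2 in itertools.combinations(names, 2):
        t = fst_per_snp(matrix, structure, [g1, g2])["fst"].to_numpy()
        ok = np.isfinite(t)
        acc[ok] += t[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    return pd.DataFrame({"snp_id": matrix.snp_ids, "fst": mean,
                         "n_pairs_used": cnt.astype(int)})


# ---------------------------------------------------------------------------
# Joint SFS

def group_derived_freqs(matrix: GenotypeMatrix, structure: PanelStructure,
                        polar: pd.DataFrame, group: str) -> np.ndarray:
    """Derived-allele frequency within one group (nan where unpolarized or
    unobserved)."""
    structure = structure.align(matrix.line_ids)
    rows = structure.group_mask(group)
    if not rows.any():
        raise PanelError(f"group {group!r} has no lines")
    d = derived_dosage(matrix, polar)[rows]
    with np.errstate(invalid="ignore"):
        n = 2 * np.sum(~np.isnan(d), axis=0)
        s = np.nansum(d, axis=0)
        return np.where(n > 0, s / n, np.nan)


def joint_sfs(freqs_group_a: np.ndarray, freqs_group_b: np.ndarray,
              n_bins: int = 10) -> np.ndarray:
    """Two-dimensional SFS (proportion matrix) over SNPs with defined
    frequencies in both groups. Entries sum to 1; marginals equal the 1-D
    spectra restricted to the shared SNPs."""
    fa = np.asarray(freqs_group_a, dtype=float)
    fb = np.asarray(freqs_group_b, dtype=float)
    ok = np.isfinite(fa) & np.isfinite(fb)
    if not ok.any():
        raise PanelError("no SNPs with defined frequencies in both groups")
    ia = _bin_index(fa[ok], n_bins)
    ib = _bin_index(fb[ok], n_bins)
    h = np.zeros((n_bins, n_bins))
    np.add.at(h, (ia, ib), 1.0)
    return h / h.sum()


# ---------------------------------------------------------------------------
# Frequency-matched tail comparison and top-F_ST genes

def frequency_matched_compare(fst_table: pd.DataFrame, annotation: pd.DataFrame,
                              n_maf_bins: int = 20, top_quantile: float = 0.99,
                              seed: int = 0,
                              control_classes: Sequence[str] | None = None,
                              ) -> dict:
    """Deleterious vs frequency-matched control SNPs in the top-F_ST tail.

    Control SNPs are resampled (without replacement where bin counts
    allow, with replacement otherwise) to match the deleterious class's
    MAF-bin histogram; MAF bins with deleterious SNPs but no controls are
    dropped with a warning. The tail threshold is the empirical
    ``top_quantile`` of the union of the two matched sets. Returns the 2x2
    counts, each class's tail proportion, the fold ratio and the two-sided
    Fisher p-value.
    """
    rng = np.random.default_rng(seed)
    df = fst_table.merge(annotation[["snp_id", "codon_class"]], on="snp_id")
    df = df[np.isfinite(df["fst"]) & np.isfinite(df["maf"])]
    is_del = df["codon_class"] == DELETERIOUS
    if control_classes is None:
        is_ctrl = ~is_del
    else:
        is_ctrl = df["codon_class"].isin(control_classes)
    del_df = df[is_del]
    ctrl_df = df[is_ctrl]
    if del_df.empty or ctrl_df.empty:
        raise PanelError("both SNP classes must be populated")

    edges = np.linspace(0.0, 0.5, n_maf_bins + 1)
    del_bins = np.clip(np.digitize(del_df["maf"], edges) - 1, 0, n_maf_bins - 1)
    ctrl_bins = np.clip(np.digitize(ctrl_df["maf"], edges) - 1, 0, n_maf_bins - 1)
    kept_del: list[np.ndarray] = []
    kept_ctrl: list[np.ndarray] = []
    n_dropped = 0
    for b in range(n_maf_bins):
        d_idx = np.flatnonzero(del_bins == b)
        if d_idx.size == 0:
            continue
        c_idx = np.flatnonzero(ctrl_bins == b)
        if c_idx.size == 0:
            log.warning("MAF bin %d has deleterious SNPs but no controls; "
                        "dropped", b)
            n_dropped += 1
            continue
        take = rng.choice(c_idx, size=d_idx.size,
                          replace=c_idx.size < d_idx.size)
        kept_del.append(del_df["fst"].to_numpy()[d_idx])
        kept_ctrl.append(ctrl_df["fst"].to_numpy()[take])
    if not kept_del:
        raise PanelError("no MAF bins with both classes present")
    del_fst = np.concatenate(kept_del)
    ctrl_fst = np.concatenate(kept_ctrl)

    threshold = np.quantile(np.concatenate([del_fst, ctrl_fst]), top_quantile)
    a = int((del_fst > threshold).sum())
    b_ = int((del_fst <= threshold).sum())
    c = int((ctrl_fst > threshold).sum())
    d = int((ctrl_fst <= threshold).sum())
    _, p = stats.fisher_exact([[a, b_], [c, d]], alternative="two-sided")
    prop_del = a / max(a + b_, 1)
    prop_ctrl = c / max(c + d, 1)
    return {"a": a, "b": b_, "c": c, "d": d,
            "prop_deleterious": prop_del, "prop_control": prop_ctrl,
            "fold": prop_del / prop_ctrl if prop_ctrl > 0 else np.nan,
            "fisher_p": float(p), "threshold": float(threshold),
            "n_bins_dropped": n_dropped}


def top_fst_genes(fst_table: pd.DataFrame, annotation: pd.DataFrame,
                  top_quantile: float = 0.99,
                  reference_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Genes carrying predicted deleterious SNPs in the top-F_ST tail.

    The threshold is the empirical ``top_quantile`` of the referenced SNP
    set (all SNPs with a defined estimate by default). Returns one row per
    gene with the count of its high-F_ST deleterious SNPs (>= 1).
    """
    df = fst_table.merge(annotation[["snp_id", "gene_id", "codon_class"]],
                         on="snp_id")
    df = df[np.isfinite(df["fst"])]
    ref = df if reference_ids is None else df[df["snp_id"].isin(reference_ids)]
    threshold = np.quantile(ref["fst"], top_quantile)
    hits = df[(df["fst"] > threshold)
              & (df["codon_class"] == DELETERIOUS)
              & df["gene_id"].notna()]
    out = (hits.groupby("gene_id").size().rename("n_high_fst_deleterious")
           .reset_index().sort_values("gene_id").reset_index(drop=True))
    return out


def flagged_counts(annotation: pd.DataFrame, snp_ids: Sequence[str],
                   flag_cols: Sequence[str]) -> tuple[int, float]:
    """Count/fraction of the given SNPs carrying any of the named flags."""
    sub = annotation[annotation["snp_id"].isin(set(snp_ids))]
    if sub.empty:
        return 0, float("nan")
    any_flag = sub[list(flag_cols)].any(axis=1)
    return int(any_flag.sum()), float(any_flag.mean())


def gene_flagged_counts(annotation: pd.DataFrame, gene_ids: Sequence[str],
                        flag_cols: Sequence[str]) -> tuple[int, float]:
    """Count/fraction of the given genes with any SNP carrying any flag."""
    sub = annotation[annotation["gene_id"].isin(set(gene_ids))]
    per_gene = sub.groupby("gene_id")[list(flag_cols)].any().any(axis=1)
    per_gene = per_gene.reindex(list(dict.fromkeys(gene_ids)), fill_value=False)
    if per_gene.empty:
        return 0, float("nan")
    return int(per_gene.sum()), float(per_gene.mean())


# ---------------------------------------------------------------------------
# IBS, sharing, load

def ibs_matrix(matrix: GenotypeMatrix, strict: bool = False) -> pd.DataFrame:
    """Symmetric line-by-line identity-by-state matrix in [0, 1].

    ``IBS(i, j)`` is the mean over SNPs non-missing in both lines of
    ``1 - |g_i - g_j| / 2``. Pairs with no jointly observed SNP get NaN
    (or raise in strict mode). The diagonal is 1 for fully homozygous
    lines.
    """
    if matrix.n_lines < 2:
        raise PanelError("IBS needs at least two lines")
    obs = matrix.nonmissing()
    x = [(np.where(obs, matrix.calls == g, False)).astype(np.float64)
         for g in (0, 1, 2)]
    n_joint = obs.astype(np.float64) @ obs.T.astype(np.float64)
    # sum over SNPs of |gi - gj|: category-pair distances 0/1/2
    dist = (2.0 * (x[0] @ x[2].T + x[2] @ x[0].T)
            + (x[0] @ x[1].T + x[1] @ x[0].T + x[1] @ x[2].T + x[2] @ x[1].T))
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = np.where(n_joint > 0, 1.0 - dist / (2.0 * n_joint), np.nan)
    if strict and not np.isfinite(ibs).all():
        i, j = np.argwhere(~np.isfinite(ibs))[0]
        raise PanelError(f"no jointly observed SNPs for lines "
                         f"{matrix.line_ids[i]} and {matrix.line_ids[j]}")
    return pd.DataFrame(ibs, index=matrix.line_ids, columns=matrix.line_ids)


def deleterious_sharing(matrix: GenotypeMatrix, annotation: pd.DataFrame,
                        polar: pd.DataFrame) -> pd.DataFrame:
    """Pairwise proportion of deleterious SNPs at which both lines carry
    at least one derived allele, among SNPs observed in both."""
    ann = annotation.set_index("snp_id").reindex(matrix.snp_ids)
    is_del = (ann["codon_class"] == DELETERIOUS).to_numpy()
    keep = is_del & polar["polarized"].to_numpy()
    if not keep.any():
        raise PanelError("no polarized deleterious SNPs")
    d = derived_dosage(matrix, polar)[:, keep]
    obs = np.isfinite(d)
    carrier = (np.nan_to_num(d) >= 1) & obs
    both = carrier.astype(np.float64) @ carrier.T.astype(np.float64)
    n_joint = obs.astype(np.float64) @ obs.T.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(n_joint > 0, both / n_joint, np.nan)
    return pd.DataFrame(share, index=matrix.line_ids, columns=matrix.line_ids)


def sharing_ibs_correlation(sharing: pd.DataFrame, ibs: pd.DataFrame,
                            structure: PanelStructure) -> pd.DataFrame:
    """Pearson r between deleterious-allele sharing and IBS, per group pair.

    Correlations are over unordered line pairs within a group (diagonal
    cells) or across two groups (off-diagonal cells). Cells with fewer
    than three pairs, or with a constant vector, are NaN.
    """
    structure = structure.align(list(sharing.index))
    names = structure.group_names
    share = sharing.to_numpy()
    ibs_v = ibs.loc[sharing.index, sharing.columns].to_numpy()
    rows = []
    for g1, g2 in itertools.combinations_with_replacement(names, 2):
        i_idx = np.flatnonzero(structure.group_mask(g1))
        j_idx = np.flatnonzero(structure.group_mask(g2))
        if g1 == g2:
            pairs = list(itertools.combinations(i_idx, 2))
        else:
            pairs = [(i, j) for i in i_idx for j in j_idx]
        xs = np.array([share[i, j] for i, j in pairs])
        ys = np.array([ibs_v[i, j] for i, j in pairs])
        ok = np.isfinite(xs) & np.isfinite(ys)
        xs, ys = xs[ok], ys[ok]
        if xs.size < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(xs, ys).statistic)
        rows.append({"group1": g1, "group2": g2, "n_pairs": int(xs.size),
                     "pearson_r": r,
                     "mean_sharing": float(np.mean(xs)) if xs.size else np.nan})
    return pd.DataFrame(rows)


def per_line_load(matrix: GenotypeMatrix, annotation: pd.DataFrame,
                  polar: pd.DataFrame) -> pd.Series:
    """Fraction of all deleterious SNPs at which each line carries the
    derived allele.

    The denominator is the total number of (polarized) deleterious SNPs;
    missing calls are excluded from the numerator only, so heavily missing
    lines are biased low rather than undefined.
    """
    ann = annotation.set_index("snp_id").reindex(matrix.snp_ids)
    keep = ((ann["codon_class"] == DELETERIOUS).to_numpy()
            & polar["polarized"].to_numpy())
    if not keep.any():
        raise PanelError("no polarized deleterious SNPs")
    d = derived_dosage(matrix, polar)[:, keep]
    carrier = np.nan_to_num(d) >= 1
    all_missing = ~np.isfinite(d).any(axis=1)
    if all_missing.any():
        log.warning("%d line(s) have no observed deleterious calls",
                    int(all_missing.sum()))
    return pd.Series(carrier.sum(axis=1) / keep.sum(), index=matrix.line_ids,
                     name="deleterious_load")


# ---------------------------------------------------------------------------
# Windowed summaries

def window_summary(matrix: GenotypeMatrix, annotation: pd.DataFrame,
                   window_bp: int = 1_000_000,
                   covariates: pd.DataFrame | None = None,
                   region_flag: str | None = None) -> dict:
    """Per-window functional-class composition plus genome-level tests.

    Windows are half-open ``[k*w, (k+1)*w)`` per chromosome; windows with
    zero genic SNPs are reported with NaN proportions. When ``covariates``
    is given (columns ``chrom``, ``window_start`` plus one column per
    covariate), the Pearson correlation of each covariate with the
    per-window proportion of deleterious SNPs among genic SNPs is
    reported; a constant vector yields NaN. When ``region_flag`` names a
    boolean annotation column, a two-sided Fisher test compares
    deleterious vs tolerated counts among nonsynonymous SNPs inside vs
    outside the flagged region.

    Returns ``{"windows": DataFrame, "correlations": DataFrame,
    "region_fisher": dict | None}``.
    """
    if window_bp <= 0:
        raise PanelError("window_bp must be positive")
    ann = annotation.set_index("snp_id").reindex(matrix.snp_ids)
    genic = ann["gene_id"].notna().to_numpy()
    cls = ann["codon_class"].to_numpy(dtype=object)
    win_start = (matrix.pos // window_bp) * window_bp
    df = pd.DataFrame({"chrom": matrix.chrom, "window_start": win_start,
                       "codon_class": cls, "genic": genic})
    g = df[df["genic"]]
    counts = (g.groupby(["chrom", "window_start", "codon_class"]).size()
              .unstack(fill_value=0))
    for c in (SYNONYMOUS, TOLERATED, DELETERIOUS):
        if c not in counts:
            counts[c] = 0
    # include windows that exist in the matrix but hold no genic SNP
    all_windows = (df.groupby(["chrom", "window_start"]).size()
                   .rename("n_snps").reset_index())
    counts = counts.reindex(
        pd.MultiIndex.from_frame(all_windows[["chrom", "window_start"]]),
        fill_value=0)
    total = counts[[SYNONYMOUS, TOLERATED, DELETERIOUS]].sum(axis=1)
    windows = counts.reset_index()
    windows["n_genic"] = total.to_numpy()
    for c in (SYNONYMOUS, TOLERATED, DELETERIOUS):
        with np.errstate(invalid="ignore", divide="ignore"):
            windows[f"prop_{c}"] = np.where(total > 0,
                                            counts[c] / total, np.nan)

    corr_rows = []
    if covariates is not None:
        merged = windows.merge(covariates, on=["chrom", "window_start"],
                               how="inner", validate="one_to_one")
        if len(merged) != len(windows):
            raise PanelError("covariate table does not cover every window")
        y = merged[f"prop_{DELETERIOUS}"].to_numpy()
        for name in [c for c in covariates.columns
                     if c not in ("chrom", "window_start")]:
            x = merged[name].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                corr_rows.append({"covariate": name, "pearson_r": np.nan,
                                  "p_value": np.nan, "n_windows": int(ok.sum())})
            else:
                res = stats.pearsonr(x[ok], y[ok])
                corr_rows.append({"covariate": name,
                                  "pearson_r": float(res.statistic),
                                  "p_value": float(res.pvalue),
                                  "n_windows": int(ok.sum())})
    correlations = pd.DataFrame(corr_rows,
                                columns=["covariate", "pearson_r", "p_value",
                                         "n_windows"])

    region = None
    if region_flag is not None:
        if region_flag not in ann.columns:
            raise PanelError(f"annotation lacks flag column {region_flag!r}")
        nonsyn = np.isin(cls, (TOLERATED, DELETERIOUS))
        inside = ann[region_flag].to_numpy(dtype=bool)
        is_del = cls == DELETERIOUS
        a = int((nonsyn & inside & is_del).sum())
        b = int((nonsyn & inside & ~is_del).sum())
        c = int((nonsyn & ~inside & is_del).sum())
        d = int((nonsyn & ~inside & ~is_del).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        region = {"flag": region_flag, "a": a, "b": b, "c": c, "d": d,
                  "fisher_p": float(p)}
    return {"windows": windows, "correlations": correlations,
            "region_fisher": region}
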