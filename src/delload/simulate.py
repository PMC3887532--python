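"""Synthetic structured inbred panels under the dominance model of heterosis.

The generator emulates the statistical structure the downstream analyses
assume: several genetic groups whose allele frequencies diverge around a
shared ancestral frequency (Balding-Nichols model), nonsynonymous SNPs
split into tolerated and deleterious classes with deleterious derived
alleles skewed rare, near-homozygous inbred genotypes with small residual
heterozygosity and missingness, and phenotypes in which recessive (low-h)
deleterious alleles depress trait values so that hybrids gain from
complementation.

Trait architecture
------------------
Every deleterious SNP ``j`` carries a fitness penalty ``s_j > 0`` drawn
from the configured effect-size distribution, and every trait is
influenced by every deleterious SNP with its own independent penalty draw
(a dense polygenic architecture, the quantitative reading of the
dominance model). Optionally a small number of "major" deleterious genes
per trait can have their penalties multiplied by
``major_effect_multiplier`` to add an oligogenic component; this is off
by default. Environmental noise is added independently per environment;
:func:`env_sd_for_heritability` returns the per-trait noise level that
yields a target single-plot broad-sense heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (DELETERIOUS, MISSING, SYNONYMOUS, TOLERATED,
                   GenotypeMatrix, PanelError, PanelStructure, one_hot_q)

log = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"], dtype=object)


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults describe a panel of 200 inbred lines in four equally sized
    groups genotyped at 10,000 coding SNPs in 2,000 genes, with 25% of SNPs
    nonsynonymous and 20% of those predicted deleterious (500 deleterious
    SNPs, clustered ~2-3 per carrier gene), group divergence F = 0.12
    (giving a mean per-SNP Weir-Cockerham F_ST near 0.08), deleterious
    derived alleles skewed rare (~45% below 5% frequency), recessive-ish
    deleterious action (h = 0.1) with exponential penalties of mean 0.1,
    16 polygenic traits, three environments, and ~1% residual
    heterozygosity and missingness.
    """

    n_groups: int = 4
    lines_per_group: list[int] = field(default_factory=lambda: [50, 50, 50, 50])
    n_snps: int = 10_000
    n_genes: int = 2_000
    n_chromosomes: int = 10
    snp_spacing_bp: int = 10_000
    prop_nonsyn: float = 0.25
    prop_deleterious_of_nonsyn: float = 0.20
    deleterious_snps_per_gene: float = 2.5
    group_divergence_F: list[float] = field(default_factory=lambda: [0.12] * 4)
    #: named ancestral-frequency distribution per class, e.g.
    #: {"deleterious": {"dist": "beta", "a": .3, "b": 1.2}, "other": {...}}
    ancestral_freq_dist: dict = field(default_factory=lambda: {
        "deleterious": {"dist": "beta", "a": 0.3, "b": 1.2},
        "other": {"dist": "beta", "a": 0.5, "b": 0.9},
    })
    effect_size_dist: dict = field(default_factory=lambda: {
        "dist": "exponential", "mean": 0.1})
    dominance_h: float = 0.1
    env_sd: float | list[float] = 1.0
    n_environments: int = 3
    n_traits: int = 16
    causal_genes_per_trait: int = 0
    major_effect_multiplier: float = 1.0
    missing_rate: float = 0.01
    het_rate: float = 0.01
    outgroup_missing_rate: float = 0.02
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lines_per_group) != self.n_groups:
            raise PanelError("lines_per_group length must equal n_groups")
        if any(n <= 0 for n in self.lines_per_group):
            raise PanelError("every group needs at least one line")
        if len(self.group_divergence_F) != self.n_groups:
            raise PanelError("group_divergence_F length must equal n_groups")
        if any(not (0.0 < f < 1.0) for f in self.group_divergence_F):
            raise PanelError("group divergence F must lie in (0, 1)")
        for name in ("prop_nonsyn", "prop_deleterious_of_nonsyn",
                     "missing_rate", "het_rate", "outgroup_missing_rate",
                     "dominance_h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise PanelError(f"{name}={v} outside [0, 1]")
        if self.n_snps < self.n_genes:
            raise PanelError("n_snps must be >= n_genes")
        if self.n_environments < 1:
            raise PanelError("n_environments must be >= 1")
        env = np.atleast_1d(np.asarray(self.env_sd, dtype=float))
        if (env < 0).any():
            raise PanelError("env_sd must be non-negative")

    @property
    def n_lines(self) -> int:
        return int(sum(self.lines_per_group))

    def env_sd_per_trait(self) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(np.asarray(self.env_sd, float)),
                               (self.n_traits,)).copy()


@dataclass
class SimTruth:
    """Ground truth of a simulated panel.

    ``s`` holds the fitness penalty per SNP (zero unless deleterious);
    ``trait_s`` the per-trait effective penalties (n_snps x n_traits) after
    applying the major-gene multipliers. ``alt_is_derived`` records the
    orientation of each SNP so the derived allele can be recovered exactly.
    """

    codon_class: np.ndarray
    gene_id: np.ndarray
    ancestral_allele: np.ndarray
    alt_is_derived: np.ndarray
    s: np.ndarray
    trait_s: np.ndarray
    major_genes: dict[str, list[str]]
    groups: np.ndarray
    q: np.ndarray
    ancestral_freq: np.ndarray
    group_freq: np.ndarray

    @property
    def trait_names(self) -> list[str]:
        return list(self.major_genes)


@dataclass
class SimPanel:
    """Bundle returned by :func:`simulate_genotypes`."""

    genotypes: GenotypeMatrix
    structure: PanelStructure
    truth: SimTruth
    annotation: pd.DataFrame


def _draw_freq(rng: np.random.Generator, spec: dict, size: int) -> np.ndarray:
    dist = spec.get("dist", "beta")
    if dist == "beta":
        p = rng.beta(spec["a"], spec["b"], size=size)
    elif dist == "uniform":
        p = rng.uniform(spec.get("low", 0.0), spec.get("high", 1.0), size=size)
    else:
        raise PanelError(f"unknown frequency distribution {dist!r}")
    # keep Balding-Nichols Beta parameters finite
    return np.clip(p, 1e-4, 1 - 1e-4)


def _draw_effects(rng: np.random.Generator, spec: dict, size: int) -> np.ndarray:
    dist = spec.get("dist", "exponential")
    if dist == "exponential":
        return rng.exponential(spec["mean"], size=size)
    if dist == "gamma":
        return rng.gamma(spec["shape"], spec["scale"], size=size)
    if dist == "constant":
        return np.full(size, float(spec["value"]))
    raise PanelError(f"unknown effect-size distribution {dist!r}")


def _assign_classes(rng: np.random.Generator, cfg: SimConfig,
                    gene_of_snp: np.ndarray) -> np.ndarray:
    """Assign codon classes, clustering deleterious SNPs within genes.

    Deleterious SNPs are concentrated in a subset of genes (on average
    ``deleterious_snps_per_gene`` per carrier gene), mimicking the
    observation that predicted deleterious SNPs co-occur within genes.
    """
    n = cfg.n_snps
    n_nonsyn = int(round(n * cfg.prop_nonsyn))
    n_del = int(round(n_nonsyn * cfg.prop_deleterious_of_nonsyn))
    classes = np.full(n, SYNONYMOUS, dtype=object)

    genes = np.unique(gene_of_snp)
    order = rng.permutation(len(genes))
    chosen: list[int] = []
    per_gene = max(1.0, cfg.deleterious_snps_per_gene)
    placed = 0
    for gi in order:
        if placed >= n_del:
            break
        members = np.flatnonzero(gene_of_snp == genes[gi])
        take = min(len(members), int(round(per_gene)), n_del - placed)
        picked = rng.choice(members, size=take, replace=False)
        chosen.extend(picked.tolist())
        placed += take
    classes[np.asarray(chosen, dtype=int)] = DELETERIOUS

    remaining = np.flatnonzero(classes == SYNONYMOUS)
    n_tol = min(n_nonsyn - placed, len(remaining))
    tol_idx = rng.choice(remaining, size=n_tol, replace=False)
    classes[tol_idx] = TOLERATED
    return classes


def simulate_genotypes(config: SimConfig) -> SimPanel:
    """Simulate a structured panel of doubled-haploid inbred lines.

    Per SNP, an ancestral derived-allele frequency ``p`` is drawn from the
    class-specific distribution; each group's frequency comes from a
    Balding-Nichols Beta with mean ``p`` and variance ``F p(1-p)``. Each
    line is a doubled-haploid draw (homozygous ancestral or derived), after
    which heterozygous and missing calls are injected at the configured
    rates (missingness wins when both hit the same call). Deterministic for
    a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # map SNPs to genes as consecutive blocks, laid out on chromosomes
    gene_of_snp = (np.arange(cfg.n_snps) * cfg.n_genes // cfg.n_snps)
    gene_ids = np.array([f"gene{g:05d}" for g in gene_of_snp], dtype=object)
    per_chrom = -(-cfg.n_snps // cfg.n_chromosomes)  # ceil
    chrom_idx = np.arange(cfg.n_snps) // per_chrom
    chrom = np.array([f"chr{c + 1}" for c in chrom_idx], dtype=object)
    pos = ((np.arange(cfg.n_snps) % per_chrom) + 1) * cfg.snp_spacing_bp

    classes = _assign_classes(rng, cfg, gene_of_snp)
    is_del = classes == DELETERIOUS

    p_anc = np.empty(cfg.n_snps)
    p_anc[is_del] = _draw_freq(rng, cfg.ancestral_freq_dist["deleterious"],
                               int(is_del.sum()))
    p_anc[~is_del] = _draw_freq(rng, cfg.ancestral_freq_dist["other"],
                                int((~is_del).sum()))

    group_names = [f"G{k + 1}" for k in range(cfg.n_groups)]
    group_freq = np.empty((cfg.n_groups, cfg.n_snps))
    for k, f in enumerate(cfg.group_divergence_F):
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        group_freq[k] = rng.beta(a, b)

    line_ids: list[str] = []
    groups: list[str] = []
    blocks: list[np.ndarray] = []
    for k, n_k in enumerate(cfg.lines_per_group):
        derived = rng.random((n_k, cfg.n_snps)) < group_freq[k]
        blocks.append(np.where(derived, 2, 0).astype(np.int8))
        start = len(line_ids)
        line_ids.extend(f"L{start + i:03d}" for i in range(n_k))
        groups.extend([group_names[k]] * n_k)
    derived_dosage = np.vstack(blocks)  # dosage of the *derived* allele

    het = rng.random(derived_dosage.shape) < cfg.het_rate
    miss = rng.random(derived_dosage.shape) < cfg.missing_rate
    derived_dosage[het] = 1
    derived_dosage[miss] = MISSING

    # allele labels: ancestral base + distinct derived base; randomize which
    # of ref/alt is the derived allele so polarization is exercised
    anc_base = rng.choice(_BASES, size=cfg.n_snps)
    shift = rng.integers(1, 4, size=cfg.n_snps)
    base_idx = np.searchsorted(_BASES, anc_base.astype(str))
    der_base = _BASES[(base_idx + shift) % 4]
    alt_is_derived = rng.random(cfg.n_snps) < 0.5
    ref = np.where(alt_is_derived, anc_base, der_base)
    alt = np.where(alt_is_derived, der_base, anc_base)
    calls = derived_dosage.copy()
    flip = ~alt_is_derived
    flip_cols = calls[:, flip]
    observed = flip_cols != MISSING
    flip_cols[observed] = 2 - flip_cols[observed]
    calls[:, flip] = flip_cols

    snp_ids = [f"snp{j:06d}" for j in range(cfg.n_snps)]
    matrix = GenotypeMatrix(line_ids, snp_ids, chrom, pos, ref, alt, calls)
    groups_arr = np.asarray(groups, dtype=object)
    structure = PanelStructure(line_ids, groups_arr,
                               one_hot_q(groups_arr, group_names))

    # per-SNP fitness penalty plus independent per-trait penalty draws
    # (dense architecture: every deleterious SNP affects every trait)
    n_del = int(is_del.sum())
    s = np.zeros(cfg.n_snps)
    s[is_del] = _draw_effects(rng, cfg.effect_size_dist, n_del)
    trait_names = [f"trait{t + 1:02d}" for t in range(cfg.n_traits)]
    del_genes = sorted(set(gene_ids[is_del]))
    trait_s = np.zeros((cfg.n_snps, cfg.n_traits))
    major_genes: dict[str, list[str]] = {}
    for t, trait in enumerate(trait_names):
        trait_s[is_del, t] = _draw_effects(rng, cfg.effect_size_dist, n_del)
        n_major = min(cfg.causal_genes_per_trait, len(del_genes))
        picks = list(rng.choice(np.asarray(del_genes, dtype=object),
                                size=n_major, replace=False)) if n_major else []
        major_genes[trait] = [str(g) for g in picks]
        if picks:
            in_major = np.isin(gene_ids, picks) & is_del
            trait_s[in_major, t] *= cfg.major_effect_multiplier

    truth = SimTruth(codon_class=classes, gene_id=gene_ids,
                     ancestral_allele=anc_base, alt_is_derived=alt_is_derived,
                     s=s, trait_s=trait_s, major_genes=major_genes,
                     groups=groups_arr, q=structure.q,
                     ancestral_freq=p_anc, group_freq=group_freq)

    annotation = _annotation_from_truth(rng, cfg, matrix, truth)
    return SimPanel(matrix, structure, truth, annotation)


def _annotation_from_truth(rng: np.random.Generator, cfg: SimConfig,
                           matrix: GenotypeMatrix, truth: SimTruth) -> pd.DataFrame:
    """Build the SNP annotation table (predictor calls, outgroup allele)."""
    n = matrix.n_snps
    sift = np.full(n, "missing", dtype=object)
    mapp = np.full(n, "missing", dtype=object)
    nonsyn = np.isin(truth.codon_class, (TOLERATED, DELETERIOUS))
    is_del = truth.codon_class == DELETERIOUS
    # predictors call nonsynonymous codons; each flags a true deleterious
    # SNP with probability .8 (at least one always does, so the consensus
    # class is reproduced by the union rule)
    s_hit = rng.random(n) < 0.8
    m_hit = rng.random(n) < 0.8
    neither = ~(s_hit | m_hit)
    s_hit[neither] = True
    sift[nonsyn] = "tolerated"
    mapp[nonsyn] = "tolerated"
    sift[is_del & s_hit] = "deleterious"
    mapp[is_del & m_hit] = "deleterious"

    outgroup = truth.ancestral_allele.copy()
    outgroup[rng.random(n) < cfg.outgroup_missing_rate] = ""
    return pd.DataFrame({
        "snp_id": matrix.snp_ids,
        "gene_id": truth.gene_id,
        "codon_class": truth.codon_class,
        "sift_call": sift,
        "mapp_call": mapp,
        "outgroup_allele": outgroup,
    })


# ---------------------------------------------------------------------------
# Phenotypes

def all_crosses_to_tester(line_ids: Sequence[str], tester_id: str
                          ) -> list[tuple[str, str]]:
    """Cross every line (except the tester itself) to a common tester."""
    return [(l, tester_id) for l in line_ids if l != tester_id]


def random_crosses(line_ids: Sequence[str], n_crosses: int,
                   seed: int = 0) -> list[tuple[str, str]]:
    """A factorial sample of distinct unordered line pairs.

    Emulates a partial-diallel mating design: ``n_crosses`` pairs drawn
    uniformly without repetition from all unordered pairs of panel lines.
    """
    n = len(line_ids)
    if n_crosses > n * (n - 1) // 2:
        raise PanelError("more crosses requested than distinct pairs")
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < n_crosses:
        i, j = rng.choice(n, size=2, replace=False)
        pairs.add((min(i, j), max(i, j)))
    return [(line_ids[i], line_ids[j]) for i, j in sorted(pairs)]


def hybrid_id(parent1: str, parent2: str) -> str:
    return f"{parent1}x{parent2}"


def _derived_dosage(matrix: GenotypeMatrix, truth: SimTruth) -> np.ndarray:
    d = matrix.calls.astype(np.int8).copy()
    flip = ~truth.alt_is_derived
    cols = d[:, flip]
    obs = cols != MISSING
    cols[obs] = 2 - cols[obs]
    d[:, flip] = cols
    return d


def _penalty(dosage: np.ndarray, trait_s: np.ndarray, h: float) -> np.ndarray:
    """Total penalty per individual per trait.

    ``dosage`` is the derived-allele dosage (MISSING contributes nothing);
    homozygous derived costs ``s``, heterozygous costs ``h*s``.
    """
    hom = (dosage == 2).astype(float)
    het = (dosage == 1).astype(float)
    return (hom + h * het) @ trait_s


def simulate_phenotypes(genotypes: GenotypeMatrix, truth: SimTruth,
                        crosses: Sequence[tuple[str, str]], config: SimConfig,
                        ) -> pd.DataFrame:
    """Phenotypes for all inbred lines and the requested hybrid crosses.

    Inbred value: ``baseline - sum_j s_j I(hom derived at j)`` plus
    N(0, env_sd^2) noise independently per environment. Hybrid genotypes
    derive from the two parental homozygous calls; a heterozygous or
    missing parental call makes the hybrid call missing there and the SNP
    contributes no penalty. With ``h < 1`` every hybrid's expected value is
    at least the expected mid-parent value.

    Returns a long-format table (genotype_id, trait, environment, value).
    Selfed crosses reproduce the parental genotype exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    for p1, p2 in crosses:
        if p1 not in genotypes.line_ids or p2 not in genotypes.line_ids:
            raise PanelError(f"cross ({p1}, {p2}) references unknown line")

    d_inbred = _derived_dosage(genotypes, truth)
    env_sd = cfg.env_sd_per_trait()
    trait_names = truth.trait_names or [f"trait{t + 1:02d}"
                                        for t in range(cfg.n_traits)]

    # hybrids: parental het calls are treated as missing (inbreds are
    # nominally homozygous), missing propagates to the hybrid call
    idx = {l: i for i, l in enumerate(genotypes.line_ids)}
    parent = np.where(d_inbred == 1, MISSING, d_inbred)
    hyb_rows = np.empty((len(crosses), genotypes.n_snps), dtype=np.int8)
    hyb_ids: list[str] = []
    for r, (p1, p2) in enumerate(crosses):
        a, b = parent[idx[p1]], parent[idx[p2]]
        ok = (a != MISSING) & (b != MISSING)
        hyb_rows[r] = np.where(ok, (a + b) // 2, MISSING)
        hyb_ids.append(hybrid_id(p1, p2))

    records: list[pd.DataFrame] = []
    for dosage, ids in ((d_inbred, genotypes.line_ids), (hyb_rows, hyb_ids)):
        g = cfg.baseline - _penalty(dosage, truth.trait_s, cfg.dominance_h)
        for e in range(cfg.n_environments):
            noise = rng.normal(0.0, env_sd, size=g.shape)
            for t, trait in enumerate(trait_names):
                records.append(pd.DataFrame({
                    "genotype_id": ids, "trait": trait,
                    "environment": f"env{e + 1}",
                    "value": g[:, t] + noise[:, t]}))
    return pd.concat(records, ignore_index=True)


def env_sd_for_heritability(genotypes: GenotypeMatrix, truth: SimTruth,
                            config: SimConfig, h2: float = 0.5) -> np.ndarray:
    """Per-trait environmental SD giving single-plot heritability ``h2``.

    The genetic variance is that of the noiseless inbred values across
    lines; the returned SD satisfies ``Vg / (Vg + sd^2) = h2``.
    """
    if not (0.0 < h2 < 1.0):
        raise PanelError("h2 must lie in (0, 1)")
    d = _derived_dosage(genotypes, truth)
    g = config.baseline - _penalty(d, truth.trait_s, config.dominance_h)
    vg = g.var(axis=0, ddof=1)
    return np.sqrt(vg * (1.0 - h2) / h2)


# ---------------------------------------------------------------------------
# Truth serialization

def write_truth(truth: SimTruth, matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ground truth as TSVs: <prefix>_snps.tsv and <prefix>_lines.tsv."""
    prefix = str(prefix)
    snp_df = pd.DataFrame({
        "snp_id": matrix.snp_ids,
        "gene_id": truth.gene_id,
        "codon_class": truth.codon_class,
        "ancestral_allele": truth.ancestral_allele,
        "alt_is_derived": truth.alt_is_derived,
        "s": truth.s,
        "ancestral_freq": truth.ancestral_freq,
    })
    for t, trait in enumerate(truth.trait_names):
        snp_df[f"s_{trait}"] = truth.trait_s[:, t]
    snp_df.to_csv(f"{prefix}_snps.tsv", sep="\t", index=False)
    line_df = pd.DataFrame({"line_id": matrix.line_ids, "group": truth.groups})
    for k in range(truth.q.shape[1]):
        line_df[f"q{k + 1}"] = truth.q[:, k]
    line_df.to_csv(f"{prefix}_lines.tsv", sep="\t", index=False)
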