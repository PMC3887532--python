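"""End-to-end recovery study under the dominance model of heterosis.

One replicate simulates the default structured panel (200 lines, four
groups, 10,000 coding SNPs with 500 deleterious), calibrates the
environmental noise to a single-plot broad-sense heritability of 0.5,
crosses the panel in a partial-diallel factorial, runs the
heterozygosity-vs-heterosis scan per trait for both mid-parent and
best-parent heterosis, and summarizes gene-level deleterious enrichment:
per-trait fold enrichments, the cross-trait exact sign test on the
mid-parent folds, and the low-frequency-synonymous specificity control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import association, enrichment, popgen
from .heterosis import genetic_values, heterosis_stats
from .simulate import (SimConfig, env_sd_for_heritability, random_crosses,
                       simulate_genotypes, simulate_phenotypes)


@dataclass
class RecoveryResult:
    """Per-replicate summary of the dominance-model recovery study."""

    mph_folds: list[float]
    bph_folds: list[float]
    mph_sign_p: float
    bph_sign_p: float
    control_significant: int      # traits whose low-freq-syn control enriches
    n_traits: int
    n_significant_mean: float

    @property
    def mean_bph_fold(self) -> float:
        return float(np.nanmean(self.bph_folds))

    @property
    def mean_mph_fold(self) -> float:
        return float(np.nanmean(self.mph_folds))

    def passes(self, alpha: float = 0.01) -> bool:
        """Best-parent enrichment present and the cross-trait sign test
        (mid-parent folds, the published reading) rejects."""
        return self.mean_bph_fold > 1.0 and self.mph_sign_p < alpha


def dominance_recovery_replicate(seed: int, n_crosses: int = 3000,
                                 config: SimConfig | None = None,
                                 target_h2: float = 0.5,
                                 run_control: bool = True) -> RecoveryResult:
    """Run one seeded replicate of the recovery study."""
    cfg = config if config is not None else SimConfig()
    cfg = replace(cfg, seed=seed)
    panel = simulate_genotypes(cfg)
    m, truth = panel.genotypes, panel.truth
    env_sd = env_sd_for_heritability(m, truth, cfg, h2=target_h2)
    cfg = replace(cfg, env_sd=list(env_sd))

    crosses = random_crosses(m.line_ids, n_crosses, seed=seed + 10_000)
    phen = simulate_phenotypes(m, truth, crosses, cfg)
    gv = genetic_values(phen)
    het = heterosis_stats(gv, [(f"{a}x{b}", a, b) for a, b in crosses])

    h, hybrid_ids = association.cross_heterozygosity(m, crosses)
    d = association.cross_distance(m, crosses).to_numpy()
    polar = popgen.polarize(m, panel.annotation) if run_control else None

    mph_folds: list[float] = []
    bph_folds: list[float] = []
    ctrl_sig = 0
    n_sig: list[int] = []
    for trait, sub in het.groupby("trait"):
        by_hybrid = sub.set_index("hybrid_id")
        res_m = association.heterozygosity_scan(
            by_hybrid["mph"].reindex(hybrid_ids).to_numpy(), d, h, m.snp_ids)
        res_b = association.heterozygosity_scan(
            by_hybrid["bph_max"].reindex(hybrid_ids).to_numpy(), d, h,
            m.snp_ids)
        mph_folds.append(
            enrichment.gene_enrichment(res_m, panel.annotation,
                                       trait=trait, scan="mph").fold)
        bph_folds.append(
            enrichment.gene_enrichment(res_b, panel.annotation,
                                       trait=trait, scan="bph").fold)
        n_sig.append(int(res_m["significant_p"].sum()))
        if run_control:
            ctrl = enrichment.matched_gene_control(
                res_m, panel.annotation, freq_table=polar)["control"]
            if (ctrl is not None and np.isfinite(ctrl.fold)
                    and ctrl.fold > 1 and ctrl.fisher_p < 0.05):
                ctrl_sig += 1

    return RecoveryResult(
        mph_folds=mph_folds, bph_folds=bph_folds,
        mph_sign_p=enrichment.sign_test(mph_folds)["p_value"],
        bph_sign_p=enrichment.sign_test(bph_folds)["p_value"],
        control_significant=ctrl_sig, n_traits=len(mph_folds),
        n_significant_mean=float(np.mean(n_sig)))
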