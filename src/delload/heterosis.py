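"""Genetic values and heterosis statistics.

Genetic values are estimated from replicated phenotypes under a
fixed-genotype-effect model with identity residual covariance; with a
single replicate per environment that estimate is the per-genotype mean,
which is what is returned (with the replicate count recorded).

For a hybrid ``ij`` with parental genetic values ``g_i``, ``g_j``:

    MPH_ij     = g_ij - (g_i + g_j) / 2
    BPH_max_ij = g_ij - max(g_i, g_j)
    BPH_min_ij = g_ij - min(g_i, g_j)

so algebraically ``BPH_max <= MPH <= BPH_min`` for every cross. For traits
where smaller values are favourable (flowering time, tassel traits, leaf
angle) the selected best-parent statistic is BPH_min rather than BPH_max.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import PanelError, validate_phenotypes

log = logging.getLogger(__name__)

#: Traits for which lower values are better, so best-parent heterosis is
#: measured against the lower parent (BPH_min).
BPH_MIN_TRAITS = frozenset({
    "days_to_anthesis", "tassel_branch_count", "tassel_angle",
    "upper_leaf_angle",
})


def genetic_values(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-(genotype, trait) genetic values from the long phenotype table.

    Returns columns ``genotype_id``, ``trait``, ``value``, ``n_obs``.
    """
    validate_phenotypes(phenotypes)
    if phenotypes.empty:
        raise PanelError("empty phenotype table")
    out = (phenotypes.groupby(["genotype_id", "trait"], sort=True)["value"]
           .agg(value="mean", n_obs="size").reset_index())
    out["n_obs"] = out["n_obs"].astype(int)
    return out


def heterosis_stats(gvalues: pd.DataFrame,
                    crosses: Sequence[tuple[str, str, str]],
                    traits: Iterable[str] | None = None,
                    bph_min_traits: Iterable[str] = BPH_MIN_TRAITS,
                    ) -> pd.DataFrame:
    """Mid-parent and best-parent heterosis per cross and trait.

    ``crosses`` holds (hybrid_id, parent1_id, parent2_id) triples. Rows
    where the hybrid or either parent lacks a genetic value for a trait
    are skipped with a log entry. The ``bph_selected`` column applies
    BPH_min for traits in ``bph_min_traits`` and BPH_max otherwise.
    Symmetric under swapping the two parents.
    """
    bph_min_traits = set(bph_min_traits)
    lut = gvalues.set_index(["genotype_id", "trait"])["value"]
    trait_list = sorted(set(traits) if traits is not None
                        else set(gvalues["trait"]))
    rows = []
    n_skipped = 0
    for hybrid, p1, p2 in crosses:
        for trait in trait_list:
            try:
                gh = lut[(hybrid, trait)]
                g1 = lut[(p1, trait)]
                g2 = lut[(p2, trait)]
            except KeyError:
                n_skipped += 1
                continue
            mph = gh - (g1 + g2) / 2.0
            bph_max = gh - max(g1, g2)
            bph_min = gh - min(g1, g2)
            rows.append({
                "hybrid_id": hybrid, "parent1_id": p1, "parent2_id": p2,
                "trait": trait, "mph": mph, "bph_max": bph_max,
                "bph_min": bph_min,
                "bph_selected": bph_min if trait in bph_min_traits else bph_max,
            })
    if n_skipped:
        log.info("skipped %d cross/trait combinations lacking genetic values",
                 n_skipped)
    return pd.DataFrame(rows, columns=["hybrid_id", "parent1_id", "parent2_id",
                                       "trait", "mph", "bph_max", "bph_min",
                                       "bph_selected"])
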