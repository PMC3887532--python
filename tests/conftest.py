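import numpy as np
import pytest

import delload as dl


@pytest.fixture(scope="session")
def small_cfg():
    return dl.SimConfig(n_groups=3, lines_per_group=[15, 15, 15], n_snps=600,
                        n_genes=120, group_divergence_F=[0.1] * 3,
                        n_traits=3, n_chromosomes=3, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    """A small structured panel shared across read-only tests."""
    return dl.simulate_genotypes(small_cfg)


def make_matrix(calls, ref=None, alt=None, chrom=None, pos=None):
    """Handmade GenotypeMatrix from a (lines x snps) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_snps = calls.shape
    return dl.GenotypeMatrix(
        line_ids=[f"L{i}" for i in range(n_lines)],
        snp_ids=[f"s{j}" for j in range(n_snps)],
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_snps,
                       dtype=object),
        pos=np.array(pos if pos is not None
                     else np.arange(1, n_snps + 1) * 10),
        ref=np.array(ref if ref is not None else ["A"] * n_snps, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * n_snps, dtype=object),
        calls=calls,
    )
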