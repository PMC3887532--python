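"""Polarization, SFS contrasts, Weir-Cockerham F_ST (against an
independently coded oracle), IBS/sharing/load, and window summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import delload as dl
from delload import popgen
from delload.core import MISSING, PanelError

from conftest import make_matrix


def _ann(matrix, **cols):
    base = {"snp_id": matrix.snp_ids,
            "gene_id": ["g1"] * matrix.n_snps,
            "codon_class": [dl.SYNONYMOUS] * matrix.n_snps,
            "outgroup_allele": ["A"] * matrix.n_snps}
    base.update(cols)
    return pd.DataFrame(base)


class TestPolarize:
    @pytest.mark.parametrize("outgroup,expected_freq,expected_pol", [
        ("A", 0.5, True),    # derived = alt (G), freq of G = 0.5
        ("G", 0.5, True),    # derived = ref (A), freq of A = 0.5
        ("C", np.nan, False),  # outgroup matches neither allele
        ("", np.nan, False),   # outgroup missing
    ])
    def test_orientation(self, outgroup, expected_freq, expected_pol):
        m = make_matrix(np.array([[0], [0], [2], [2]]))
        ann = _ann(m, outgroup_allele=[outgroup])
        out = popgen.polarize(m, ann)
        assert bool(out["polarized"][0]) is expected_pol
        if expected_pol:
            assert out["derived_freq"][0] == pytest.approx(expected_freq)
        else:
            assert np.isnan(out["derived_freq"][0])

    def test_het_counts_one_allele_each_and_missing_excluded(self):
        m = make_matrix(np.array([[1], [2], [MISSING]]))
        out = popgen.polarize(m, _ann(m))
        # alleles observed: (A,G) + (G,G) -> 3 of 4 derived
        assert out["derived_freq"][0] == pytest.approx(0.75)
        assert out["n_alleles"][0] == 4

    def test_counts_partition(self, small_panel):
        out = popgen.polarize(small_panel.genotypes, small_panel.annotation)
        assert out["polarized"].sum() + (~out["polarized"]).sum() == len(out)


class TestSfs:
    def test_direct_binning(self):
        polar = pd.DataFrame({"snp_id": list("abcd"),
                              "polarized": [True] * 4,
                              "derived_freq": [.01, .02, .6, .9]})
        ann = pd.DataFrame({"snp_id": list("abcd"),
                            "codon_class": [dl.SYNONYMOUS] * 4})
        out = popgen.sfs_by_class(polar, ann, n_bins=10,
                                  classes=(dl.SYNONYMOUS,))
        expected = [.5, 0, 0, 0, 0, 0, .25, 0, 0, .25]
        np.testing.assert_allclose(out.loc[dl.SYNONYMOUS].to_numpy(), expected)

    def test_empty_class_is_nan_row(self):
        polar = pd.DataFrame({"snp_id": ["a"], "polarized": [True],
                              "derived_freq": [0.5]})
        ann = pd.DataFrame({"snp_id": ["a"], "codon_class": [dl.SYNONYMOUS]})
        out = popgen.sfs_by_class(polar, ann, n_bins=5)
        assert np.isnan(out.loc[dl.DELETERIOUS]).all()
        assert out.loc[dl.SYNONYMOUS].sum() == pytest.approx(1.0, abs=1e-12)

    def test_rarer_class_loads_first_bin(self, small_panel):
        polar = popgen.polarize(small_panel.genotypes, small_panel.annotation)
        out = popgen.sfs_by_class(polar, small_panel.annotation, n_bins=20)
        assert (out.loc[dl.DELETERIOUS].iloc[0]
                > out.loc[dl.SYNONYMOUS].iloc[0])


class TestCompareSfs:
    def test_identical_multisets_give_p_one(self):
        assert popgen.compare_sfs([.1, .2, .3], [.1, .2, .3]) == 1.0

    def test_extreme_ranking_exact_p(self):
        # 3 vs 3, complete separation: 2 of C(6,3)=20 equally likely rank
        # splits are this extreme on either side -> p = 0.1
        assert popgen.compare_sfs([.01, .02, .03], [.7, .8, .9]) == \
            pytest.approx(0.1)

    def test_matches_full_enumeration_oracle(self):
        a, b = [.05, .31, .4], [.1, .2, .9]
        pooled = np.array(a + b)
        ranks = stats.rankdata(pooled)
        mu = 3 * 3 / 2
        u_obs = ranks[:3].sum() - 6
        hits = sum(abs(ranks[list(c)].sum() - 6 - mu) >= abs(u_obs - mu) - 1e-12
                   for c in itertools.combinations(range(6), 3))
        assert popgen.compare_sfs(a, b) == pytest.approx(hits / 20)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.beta(0.5, 1.5, size=100)
            y = rng.beta(0.5, 1.5, size=100)
            if popgen.compare_sfs(x, y) <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_empty_sample_rejected(self):
        with pytest.raises(PanelError):
            popgen.compare_sfs([], [0.1])


def wc_theta_oracle(counts):
    """Textbook Weir-Cockerham (1984) theta for one SNP.

    ``counts`` is a list of (n_individuals, n_alt_alleles, n_het) per
    population; written independently of the vectorized implementation.
    """
    pops = [(n, alt, het) for n, alt, het in counts if n >= 1]
    r = len(pops)
    if r < 2:
        return np.nan
    nbar = sum(n for n, _, _ in pops) / r
    if nbar <= 1:
        return np.nan
    nc = (r * nbar - sum(n * n for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(alt for _, alt, _ in pops) / (2 * r * nbar)
    s2 = sum(n * (alt / (2 * n) - pbar) ** 2 for n, alt, _ in pops) \
        / ((r - 1) * nbar)
    hbar = sum(het for _, _, het in pops) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    if a + b + c == 0:
        return np.nan
    return a / (a + b + c)


class TestFst:
    def _structure(self, groups):
        ids = [f"L{i}" for i in range(len(groups))]
        return dl.PanelStructure(ids, np.array(groups, dtype=object),
                                 dl.one_hot_q(groups))

    def test_fixed_difference_approaches_one(self):
        calls = np.vstack([np.full((40, 1), 2), np.full((40, 1), 0)])
        m = make_matrix(calls)
        st = self._structure(["A"] * 40 + ["B"] * 40)
        out = popgen.fst_per_snp(m, st)
        assert out["fst"][0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_groups_small_negative(self):
        # equal counts in each group: hand-checkable W-C finite-sample case
        block = np.array([2] * 10 + [0] * 40, dtype=np.int8).reshape(-1, 1)
        m = make_matrix(np.vstack([block, block]))
        st = self._structure(["A"] * 50 + ["B"] * 50)
        got = float(popgen.fst_per_snp(m, st)["fst"][0])
        expected = wc_theta_oracle([(50, 20, 0), (50, 20, 0)])
        assert got == pytest.approx(expected, abs=1e-14)
        assert got <= 0 and abs(got) < 0.05

    def test_matches_independent_oracle_on_random_snps(self):
        rng = np.random.default_rng(31)
        n_per = [12, 20, 8, 15]
        groups = sum(([f"G{k}" for _ in range(n)]
                      for k, n in enumerate(n_per)), [])
        calls = rng.choice([0, 1, 2, MISSING], size=(sum(n_per), 1000),
                           p=[.45, .05, .45, .05]).astype(np.int8)
        m = make_matrix(calls)
        st = self._structure(groups)
        out = popgen.fst_per_snp(m, st)
        for j in rng.choice(1000, size=1000, replace=False):
            counts = []
            for k in range(4):
                rows = np.array(groups) == f"G{k}"
                g = calls[rows, j]
                g = g[g != MISSING]
                counts.append((len(g), int(g.sum()), int((g == 1).sum())))
            expected = wc_theta_oracle(counts)
            got = out["fst"][j]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_flagged_nan(self):
        m = make_matrix(np.zeros((20, 1), dtype=np.int8))
        st = self._structure(["A"] * 10 + ["B"] * 10)
        assert np.isnan(popgen.fst_per_snp(m, st)["fst"][0])

    def test_single_group_rejected(self):
        m = make_matrix(np.zeros((4, 1), dtype=np.int8))
        with pytest.raises(PanelError):
            popgen.fst_per_snp(m, self._structure(["A"] * 4))


class TestJointSfs:
    def test_corner_mass(self):
        out = popgen.joint_sfs([0.0], [0.0], n_bins=5)
        assert out[0, 0] == 1.0
        assert out.sum() == 1.0

    def test_identical_groups_diagonal(self):
        f = np.linspace(0.05, 0.95, 19)
        out = popgen.joint_sfs(f, f, n_bins=10)
        assert np.trace(out) == pytest.approx(1.0)

    def test_marginals_match_one_dimensional_spectra(self, small_panel):
        polar = popgen.polarize(small_panel.genotypes, small_panel.annotation)
        fa = popgen.group_derived_freqs(small_panel.genotypes,
                                        small_panel.structure, polar, "G1")
        fb = popgen.group_derived_freqs(small_panel.genotypes,
                                        small_panel.structure, polar, "G2")
        ok = np.isfinite(fa) & np.isfinite(fb)
        out = popgen.joint_sfs(fa, fb, n_bins=10)
        ha = np.bincount(popgen._bin_index(fa[ok], 10), minlength=10)
        hb = np.bincount(popgen._bin_index(fb[ok], 10), minlength=10)
        np.testing.assert_allclose(out.sum(axis=1), ha / ha.sum(), atol=1e-12)
        np.testing.assert_allclose(out.sum(axis=0), hb / hb.sum(), atol=1e-12)


class TestFrequencyMatchedCompare:
    def _tables(self, del_fst, ctrl_fst, del_maf=None, ctrl_maf=None):
        n_d, n_c = len(del_fst), len(ctrl_fst)
        fst = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n_d + n_c)],
            "fst": list(del_fst) + list(ctrl_fst),
            "maf": list(del_maf if del_maf is not None else [0.25] * n_d)
            + list(ctrl_maf if ctrl_maf is not None else [0.25] * n_c)})
        ann = pd.DataFrame({
            "snp_id": fst["snp_id"],
            "codon_class": [dl.DELETERIOUS] * n_d + [dl.SYNONYMOUS] * n_c})
        return fst, ann

    def test_identical_lists_fold_one(self):
        vals = np.linspace(0, 0.5, 200)
        fst, ann = self._tables(vals, vals)
        out = popgen.frequency_matched_compare(fst, ann, seed=3)
        assert out["fold"] == pytest.approx(1.0)
        assert out["fisher_p"] == 1.0

    def test_matching_preserves_bin_histogram(self):
        rng = np.random.default_rng(8)
        del_maf = rng.uniform(0, 0.5, 150)
        ctrl_maf = rng.uniform(0, 0.5, 3000)
        fst, ann = self._tables(rng.random(150), rng.random(3000),
                                del_maf, ctrl_maf)
        out = popgen.frequency_matched_compare(fst, ann, n_maf_bins=10, seed=1)
        assert out["a"] + out["b"] == 150
        assert out["c"] + out["d"] == 150
        assert out["n_bins_dropped"] == 0

    @staticmethod
    def _rarity_panel(seed, n_lines_per_group, n_del, n_ctrl):
        """Groups diverged identically (F=0.1) for every SNP; deleterious
        SNPs differ from controls only by being rarer."""
        rng = np.random.default_rng(seed)
        n = n_del + n_ctrl
        p = np.empty(n)
        p[:n_del] = np.clip(rng.beta(0.3, 1.2, n_del), 1e-4, 1 - 1e-4)
        p[n_del:] = np.clip(rng.beta(0.5, 0.9, n_ctrl), 1e-4, 1 - 1e-4)
        f = 0.1
        blocks, groups = [], []
        for k in range(3):
            pg = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
            blocks.append(np.where(
                rng.random((n_lines_per_group, n)) < pg, 2, 0).astype(np.int8))
            groups += [f"G{k}"] * n_lines_per_group
        m = make_matrix(np.vstack(blocks))
        st = dl.PanelStructure(m.line_ids, np.array(groups, dtype=object),
                               dl.one_hot_q(groups))
        ann = pd.DataFrame({"snp_id": m.snp_ids,
                            "codon_class": [dl.DELETERIOUS] * n_del
                            + [dl.SYNONYMOUS] * n_ctrl})
        return m, st, ann, n_del

    def test_rarity_alone_shifts_unmatched_but_not_matched(self):
        # finite-sample theta runs slightly lower for rare SNPs, so the
        # unmatched distribution comparison rejects even though every SNP
        # has the same true divergence; matching on MAF removes it
        m, st, ann, n_del = self._rarity_panel(7, 50, 5000, 15_000)
        fst = popgen.fst_per_snp(m, st)
        f = fst["fst"].to_numpy()
        fd = f[:n_del][np.isfinite(f[:n_del])]
        fc = f[n_del:][np.isfinite(f[n_del:])]
        assert fd.mean() < fc.mean()
        assert stats.mannwhitneyu(fd, fc,
                                  alternative="two-sided").pvalue < 0.05
        out = popgen.frequency_matched_compare(fst, ann, seed=0)
        assert out["fisher_p"] > 0.05

    def test_matched_rejection_rate_near_alpha(self):
        rejected = 0
        reps = 40
        for i in range(reps):
            m, st, ann, _ = self._rarity_panel(100 + i, 30, 400, 3600)
            fst = popgen.fst_per_snp(m, st)
            out = popgen.frequency_matched_compare(fst, ann, seed=i)
            rejected += out["fisher_p"] < 0.05
        assert rejected / reps <= 0.125


class TestTopFstGenes:
    def test_single_max_snp(self):
        fst = pd.DataFrame({"snp_id": [f"s{i}" for i in range(100)],
                            "fst": np.linspace(0, 0.9, 100)})
        ann = pd.DataFrame({
            "snp_id": fst["snp_id"],
            "gene_id": ["G"] + ["other"] * 99,
            "codon_class": [dl.SYNONYMOUS] * 100})
        ann.loc[99, "gene_id"] = "G"
        ann.loc[99, "codon_class"] = dl.DELETERIOUS
        out = popgen.top_fst_genes(fst, ann, top_quantile=0.99)
        assert out.set_index("gene_id")["n_high_fst_deleterious"].to_dict() \
            == {"G": 1}

    def test_no_deleterious_in_tail_gives_empty(self):
        fst = pd.DataFrame({"snp_id": ["a", "b"], "fst": [0.1, 0.9]})
        ann = pd.DataFrame({"snp_id": ["a", "b"], "gene_id": ["g1", "g2"],
                            "codon_class": [dl.DELETERIOUS, dl.SYNONYMOUS]})
        assert popgen.top_fst_genes(fst, ann).empty

    def test_bruteforce_recount_on_panel(self, small_panel):
        fst = popgen.fst_per_snp(small_panel.genotypes, small_panel.structure)
        out = popgen.top_fst_genes(fst, small_panel.annotation,
                                   top_quantile=0.9)
        df = fst.merge(small_panel.annotation, on="snp_id")
        df = df[np.isfinite(df["fst"])]
        thr = np.quantile(df["fst"], 0.9)
        brute = (df[(df["fst"] > thr) & (df["codon_class"] == dl.DELETERIOUS)]
                 .groupby("gene_id").size())
        assert out.set_index("gene_id")["n_high_fst_deleterious"].to_dict() \
            == brute.to_dict()


class TestIbsAndSharing:
    def test_ibs_reference_values(self):
        m = make_matrix(np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1], [0, 2, 0]]))
        ibs = popgen.ibs_matrix(m).to_numpy()
        assert ibs[0, 1] == 1.0
        assert ibs[0, 2] == pytest.approx(1 / 3)   # 0,0,1 matches of weight
        assert ibs[0, 3] == pytest.approx((1 + 1 + 0.5) / 3)
        assert np.allclose(ibs, ibs.T)

    def test_opposite_homozygotes_zero(self):
        m = make_matrix(np.array([[0, 0], [2, 2]]))
        assert popgen.ibs_matrix(m).to_numpy()[0, 1] == 0.0

    def test_het_pair_half(self):
        m = make_matrix(np.array([[0], [1]]))
        assert popgen.ibs_matrix(m).to_numpy()[0, 1] == 0.5

    def test_invariant_to_snp_order(self, small_panel):
        m = small_panel.genotypes
        perm = np.random.default_rng(0).permutation(m.n_snps)
        shuffled = make_matrix(m.calls[:, perm])
        np.testing.assert_allclose(popgen.ibs_matrix(m).to_numpy(),
                                   popgen.ibs_matrix(shuffled).to_numpy(),
                                   atol=1e-12)

    def test_sharing_fraction_and_disjoint(self):
        calls = np.array([[2, 2, 0, 0, 0], [2, 2, 0, 0, 0],
                          [0, 0, 2, 2, 2]], dtype=np.int8)
        m = make_matrix(calls)
        ann = _ann(m, codon_class=[dl.DELETERIOUS] * 5)
        polar = popgen.polarize(m, ann)
        sh = popgen.deleterious_sharing(m, ann, polar).to_numpy()
        assert sh[0, 1] == pytest.approx(2 / 5)
        assert sh[0, 2] == 0.0

    def test_sharing_tracks_ibs_and_group_structure(self):
        # with strong group divergence, lines of a group share more
        # deleterious alleles with each other than across groups, and
        # sharing tracks IBS over all pairs
        cfg = dl.SimConfig(n_groups=2, lines_per_group=[25, 25], n_snps=4000,
                           n_genes=800, group_divergence_F=[0.45, 0.45],
                           n_traits=1, seed=19)
        panel = dl.simulate_genotypes(cfg)
        polar = popgen.polarize(panel.genotypes, panel.annotation)
        ibs = popgen.ibs_matrix(panel.genotypes)
        sh = popgen.deleterious_sharing(panel.genotypes, panel.annotation,
                                        polar)
        corr = popgen.sharing_ibs_correlation(sh, ibs, panel.structure)
        corr = corr.set_index(["group1", "group2"])
        within_share = (corr.loc[("G1", "G1"), "mean_sharing"]
                        + corr.loc[("G2", "G2"), "mean_sharing"]) / 2
        assert within_share > corr.loc[("G1", "G2"), "mean_sharing"]
        iu = np.triu_indices(50, k=1)
        pooled_r = stats.pearsonr(sh.to_numpy()[iu], ibs.to_numpy()[iu])
        assert pooled_r.statistic > 0.5


class TestPerLineLoad:
    def test_direct_fraction(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[0, :5] = 2
        m = make_matrix(calls)
        ann = _ann(m, codon_class=[dl.DELETERIOUS] * 100)
        load = popgen.per_line_load(m, ann, popgen.polarize(m, ann))
        assert load["L0"] == pytest.approx(0.05)
        assert load["L1"] == 0.0

    def test_all_missing_line_zero(self):
        calls = np.vstack([np.full((1, 10), MISSING, dtype=np.int8),
                           np.full((1, 10), 2, dtype=np.int8)])
        m = make_matrix(calls)
        ann = _ann(m, codon_class=[dl.DELETERIOUS] * 10)
        load = popgen.per_line_load(m, ann, popgen.polarize(m, ann))
        assert load["L0"] == 0.0

    def test_group_mean_loads_track_configured_frequencies(self, small_panel):
        # expectation: mean carrier rate equals the mean deleterious
        # derived frequency of the group (doubled haploids carry at
        # p, not 2p(1-p)+p^2)
        polar = popgen.polarize(small_panel.genotypes, small_panel.annotation)
        load = popgen.per_line_load(small_panel.genotypes,
                                    small_panel.annotation, polar)
        is_del = small_panel.truth.codon_class == dl.DELETERIOUS
        pol = polar["polarized"].to_numpy() & is_del
        for k, name in enumerate(small_panel.structure.group_names):
            rows = small_panel.structure.group_mask(name)
            expected = small_panel.truth.group_freq[k][pol].mean()
            got = load[np.asarray(rows)].mean() * is_del.sum() / pol.sum()
            assert got == pytest.approx(expected, abs=0.05)


class TestWindowSummary:
    def test_single_window_proportions(self, small_panel):
        m = small_panel.genotypes.subset_snps(np.arange(10))
        ann = small_panel.annotation.iloc[:10]
        out = popgen.window_summary(m, ann, window_bp=10 ** 9)
        w = out["windows"]
        assert len(w) == 1
        props = w[[f"prop_{c}" for c in
                   (dl.SYNONYMOUS, dl.TOLERATED, dl.DELETERIOUS)]].iloc[0]
        assert props.sum() == pytest.approx(1.0)

    def test_constant_covariate_undefined(self, small_panel):
        out0 = popgen.window_summary(small_panel.genotypes,
                                     small_panel.annotation, 500_000)
        cov = out0["windows"][["chrom", "window_start"]].copy()
        cov["recomb"] = 1.0
        out = popgen.window_summary(small_panel.genotypes,
                                    small_panel.annotation, 500_000,
                                    covariates=cov)
        assert np.isnan(out["correlations"]["pearson_r"]).all()

    def test_region_fisher_calibrated_under_uniform_assignment(self,
                                                               small_panel):
        rng = np.random.default_rng(3)
        pvals = []
        ann = small_panel.annotation.copy()
        for _ in range(200):
            ann["region_r"] = rng.random(len(ann)) < 0.3
            out = popgen.window_summary(small_panel.genotypes, ann,
                                        10 ** 9, region_flag="region_r")
            pvals.append(out["region_fisher"]["fisher_p"])
        pvals = np.asarray(pvals)
        assert (pvals < 0.05).mean() <= 0.1
        assert pvals.mean() > 0.3
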