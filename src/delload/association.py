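"""Genome scans: mixed-linear-model association for inbred genetic values
and the heterozygosity-vs-heterosis fixed-effect scan.

The inbred scan follows the EMMA family of mixed models,

    g = 1*mu + M*theta + S*beta + Z*u + e,   u ~ N(0, sigma_u^2 K),
                                              e ~ N(0, sigma_e^2 I),

with the kinship K approximated by identity-by-state. The variance-
component ratio delta = sigma_e^2 / sigma_u^2 is estimated once by REML on
the null model (no marker) and reused for every marker test (the
EMMAX/P3D approximation), which makes each per-SNP test a generalized
least-squares t-test in the eigenspace of K.

The hybrid scan regresses a heterosis measure on per-locus hybrid
heterozygosity with the genetic distance to the tester as a covariate,

    PH = 1*mu' + D*beta + H*theta + e',

by ordinary least squares, SNP by SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core import MISSING, GenotypeMatrix, PanelError

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["snp_id", "beta", "se", "p_value", "maf", "n_used",
                  "significant_p", "significant_fdr"]


def bh_fdr(p_values: Sequence[float], q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise PanelError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise PanelError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# Null-model REML

@dataclass
class MLMNullFit:
    """REML fit of the no-marker mixed model, with the eigen-cache of K."""

    delta: float
    sigma_u2: float
    sigma_e2: float
    loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    x: np.ndarray          # fixed-effect design [1, S]
    y: np.ndarray
    k: np.ndarray
    line_ids: list[str] | None = None

    @property
    def h2(self) -> float:
        """Narrow-sense heritability implied by the variance components."""
        return self.sigma_u2 / (self.sigma_u2 + self.sigma_e2)


def _reml_loglik(delta: float, lam: np.ndarray, yt: np.ndarray,
                 xt: np.ndarray, logdet_xtx: float) -> tuple[float, float]:
    """Restricted log-likelihood at a given delta, and the implied sigma_u2."""
    n, p = xt.shape
    w = lam + delta
    xw = xt / w[:, None]
    xtwx = xt.T @ xw
    beta = np.linalg.solve(xtwx, xw.T @ yt)
    resid = yt - xt @ beta
    rss = float(resid @ (resid / w))
    sigma_u2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma_u2) + 1)
                 + np.log(w).sum() + logdet_xtwx - logdet_xtx)
    return ll, sigma_u2


def fit_null_mlm(y: Sequence[float], s: np.ndarray | None, k: np.ndarray,
                 line_ids: Sequence[str] | None = None,
                 grid_size: int = 100,
                 delta_bounds: tuple[float, float] = (1e-5, 1e5),
                 ) -> MLMNullFit:
    """REML estimate of the variance-component ratio on the null model.

    ``delta`` is profiled by evaluating the restricted likelihood on a
    log-spaced grid over ``delta_bounds`` followed by bounded scalar
    refinement around the best grid point; each evaluation is linear in n
    thanks to the spectral decomposition of K. Deterministic.

    Parameters
    ----------
    y
        Genetic values, one per line.
    s
        Structure covariates (n x q) or None. An intercept is always added.
    k
        Kinship matrix, symmetric PSD up to a -1e-10 eigenvalue tolerance.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    k = np.asarray(k, dtype=float)
    if k.shape != (n, n):
        raise PanelError("kinship dimensions do not match y")
    if not np.allclose(k, k.T, atol=1e-8):
        raise PanelError("kinship matrix is not symmetric")
    x = np.ones((n, 1)) if s is None else np.column_stack([np.ones(n), s])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise PanelError("intercept and structure covariates are collinear")

    lam, u = np.linalg.eigh((k + k.T) / 2.0)
    if lam.min() < -1e-10 * max(1.0, lam.max()):
        raise PanelError(f"kinship not PSD (min eigenvalue {lam.min():.3g})")
    lam = np.clip(lam, 0.0, None)

    yt = u.T @ y
    xt = u.T @ x
    _, logdet_xtx = np.linalg.slogdet(x.T @ x)

    grid = np.logspace(np.log10(delta_bounds[0]), np.log10(delta_bounds[1]),
                       grid_size)
    lls = np.array([_reml_loglik(d, lam, yt, xt, logdet_xtx)[0] for d in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(10.0 ** t, lam, yt, xt, logdet_xtx)[0],
        bounds=(np.log10(lo), np.log10(hi)), method="bounded",
        options={"xatol": 1e-8})
    delta = float(10.0 ** res.x)
    ll, sigma_u2 = _reml_loglik(delta, lam, yt, xt, logdet_xtx)
    if ll < lls[best]:  # keep the grid optimum if refinement slipped
        delta = float(grid[best])
        ll, sigma_u2 = _reml_loglik(delta, lam, yt, xt, logdet_xtx)
    return MLMNullFit(delta=delta, sigma_u2=sigma_u2,
                      sigma_e2=delta * sigma_u2, loglik=float(ll),
                      eigvals=lam, eigvecs=u, x=x, y=y, k=k,
                      line_ids=list(line_ids) if line_ids is not None else None)


# ---------------------------------------------------------------------------
# Marker scans

def _attach_significance(df: pd.DataFrame, p_threshold: float,
                         fdr_q: float) -> pd.DataFrame:
    df["significant_p"] = df["p_value"] <= p_threshold
    if len(df):
        df["significant_fdr"] = bh_fdr(df["p_value"].to_numpy(), fdr_q)
    else:
        df["significant_fdr"] = pd.Series(dtype=bool)
    return df


def _t_pvalue(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def scan_snps_mlm(null_fit: MLMNullFit, genotypes: GenotypeMatrix,
                  maf_min: float = 0.05, p_threshold: float = 0.001,
                  fdr_q: float = 0.20) -> pd.DataFrame:
    """Per-SNP generalized least-squares tests with variance components
    fixed at the null REML fit.

    SNPs below the minor-allele-frequency cutoff, monomorphic SNPs, and
    SNPs collinear with the covariates are skipped. Missing genotypes drop
    the affected lines for that SNP only (the subset model is solved via
    the Cholesky factor of the subset covariance). Two-sided p-values come
    from the t distribution with the exact residual degrees of freedom.
    """
    if null_fit.line_ids is not None and null_fit.line_ids != genotypes.line_ids:
        raise PanelError("null fit and genotype matrix line sets differ")
    n, p = null_fit.x.shape
    if n != genotypes.n_lines:
        raise PanelError("null fit dimension does not match genotypes")

    g_raw = genotypes.calls
    obs = g_raw != MISSING
    freq = genotypes.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    testable = np.isfinite(maf) & (maf >= maf_min)

    beta = np.full(genotypes.n_snps, np.nan)
    se = np.full(genotypes.n_snps, np.nan)
    pval = np.full(genotypes.n_snps, np.nan)
    n_used = obs.sum(axis=0)

    w = null_fit.eigvals + null_fit.delta
    sw = np.sqrt(w)
    ut = null_fit.eigvecs.T
    ys = (ut @ null_fit.y) / sw
    xs = (ut @ null_fit.x) / sw[:, None]
    q, _ = np.linalg.qr(xs)
    yr = ys - q @ (q.T @ ys)
    yrss = float(yr @ yr)

    complete = testable & obs.all(axis=0)
    idx_c = np.flatnonzero(complete)
    if idx_c.size:
        gs = (ut @ g_raw[:, idx_c].astype(float)) / sw[:, None]
        gr = gs - q @ (q.T @ gs)
        gg = np.einsum("ij,ij->j", gr, gr)
        tot = np.einsum("ij,ij->j", gs, gs)
        ok = gg > 1e-10 * np.maximum(tot, 1.0)
        if (~ok).any():
            log.info("skipped %d SNP(s) collinear with covariates",
                     int((~ok).sum()))
        gy = gr.T @ yr
        b = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
        rss = yrss - b ** 2 * gg
        dof = n - p - 1
        sigma2 = rss / dof
        s_err = np.sqrt(sigma2 / np.where(ok, gg, np.nan))
        tstat = b / s_err
        beta[idx_c] = np.where(ok, b, np.nan)
        se[idx_c] = s_err
        pval[idx_c] = np.where(ok, _t_pvalue(tstat, dof), np.nan)

    for j in np.flatnonzero(testable & ~obs.all(axis=0)):
        keep = obs[:, j]
        g = g_raw[keep, j].astype(float)
        fj = g.sum() / (2 * g.size)
        if min(fj, 1 - fj) < maf_min:
            continue
        vstar = null_fit.k[np.ix_(keep, keep)].copy()
        vstar[np.diag_indices_from(vstar)] += null_fit.delta
        try:
            chol = np.linalg.cholesky(vstar)
        except np.linalg.LinAlgError:
            lam_s, u_s = np.linalg.eigh(vstar)
            chol = u_s * np.sqrt(np.clip(lam_s, 1e-12, None))
        from scipy.linalg import solve_triangular
        design = np.column_stack([null_fit.x[keep], g])
        if chol.shape[0] == chol.shape[1] and np.allclose(
                chol, np.tril(chol)):
            aw = solve_triangular(chol, design, lower=True)
            yw = solve_triangular(chol, null_fit.y[keep], lower=True)
        else:  # eigen fallback factor
            aw = np.linalg.solve(chol, design)
            yw = np.linalg.solve(chol, null_fit.y[keep])
        qj, _ = np.linalg.qr(aw[:, :-1])
        grj = aw[:, -1] - qj @ (qj.T @ aw[:, -1])
        yrj = yw - qj @ (qj.T @ yw)
        ggj = float(grj @ grj)
        if ggj <= 1e-10 * max(float(aw[:, -1] @ aw[:, -1]), 1.0):
            continue
        bj = float(grj @ yrj) / ggj
        dofj = g.size - p - 1
        if dofj <= 0:
            continue
        sigma2j = (float(yrj @ yrj) - bj ** 2 * ggj) / dofj
        sej = np.sqrt(sigma2j / ggj)
        beta[j] = bj
        se[j] = sej
        pval[j] = float(_t_pvalue(np.array([bj / sej]), np.array([dofj]))[0])

    keep = np.isfinite(pval)
    out = pd.DataFrame({
        "snp_id": np.asarray(genotypes.snp_ids, dtype=object)[keep],
        "beta": beta[keep], "se": se[keep], "p_value": pval[keep],
        "maf": maf[keep], "n_used": n_used[keep]})
    return _attach_significance(out, p_threshold, fdr_q)


def hybrid_heterozygosity(matrix: GenotypeMatrix, line_ids: Sequence[str],
                          tester_id: str) -> tuple[np.ndarray, list[str]]:
    """Per-SNP heterozygosity of line x tester hybrids.

    ``H = 1`` where line and tester carry different homozygous genotypes,
    ``0`` where they share one, and missing where either parental call is
    missing or heterozygous (inbred parents are nominally homozygous).

    Returns the (n_hybrids x n_snps) int8 matrix and the hybrid ids.
    """
    t_idx = matrix.line_index(tester_id)
    tester = matrix.calls[t_idx]
    rows = []
    hybrid_ids = []
    for lid in line_ids:
        g = matrix.calls[matrix.line_index(lid)]
        valid = np.isin(g, (0, 2)) & np.isin(tester, (0, 2))
        h = np.where(valid, (g != tester).astype(np.int8), MISSING)
        rows.append(h.astype(np.int8))
        hybrid_ids.append(f"{lid}x{tester_id}")
    return np.vstack(rows), hybrid_ids


def cross_heterozygosity(matrix: GenotypeMatrix,
                         crosses: Sequence[tuple[str, str]]
                         ) -> tuple[np.ndarray, list[str]]:
    """Per-SNP hybrid heterozygosity for arbitrary parent pairs.

    Generalizes :func:`hybrid_heterozygosity` to a factorial mating
    design: one row per cross, same missing/heterozygous-parent rules.
    """
    idx = {l: matrix.line_index(l) for pair in crosses for l in pair}
    calls = matrix.calls
    rows = np.full((len(crosses), matrix.n_snps), MISSING, dtype=np.int8)
    hybrid_ids = []
    for r, (p1, p2) in enumerate(crosses):
        g1, g2 = calls[idx[p1]], calls[idx[p2]]
        valid = np.isin(g1, (0, 2)) & np.isin(g2, (0, 2))
        rows[r] = np.where(valid, (g1 != g2).astype(np.int8), MISSING)
        hybrid_ids.append(f"{p1}x{p2}")
    return rows, hybrid_ids


def cross_distance(matrix: GenotypeMatrix,
                   crosses: Sequence[tuple[str, str]]) -> pd.Series:
    """``1 - IBS`` between the two parents of each cross."""
    idx = {l: matrix.line_index(l) for pair in crosses for l in pair}
    calls = matrix.calls
    vals = []
    ids = []
    for p1, p2 in crosses:
        g1, g2 = calls[idx[p1]], calls[idx[p2]]
        joint = (g1 != MISSING) & (g2 != MISSING)
        vals.append(np.abs(g1[joint] - g2[joint]).mean() / 2.0
                    if joint.any() else np.nan)
        ids.append(f"{p1}x{p2}")
    return pd.Series(vals, index=ids, name="parental_distance")


def genetic_distance(matrix: GenotypeMatrix, tester_id: str,
                     line_ids: Sequence[str] | None = None) -> pd.Series:
    """``D = 1 - IBS(line, tester)`` per line, in [0, 1]."""
    t_idx = matrix.line_index(tester_id)
    ids = list(line_ids) if line_ids is not None else matrix.line_ids
    tester = matrix.calls[t_idx]
    t_obs = tester != MISSING
    vals = []
    for lid in ids:
        g = matrix.calls[matrix.line_index(lid)]
        joint = (g != MISSING) & t_obs
        if not joint.any():
            vals.append(np.nan)
            continue
        vals.append(np.abs(g[joint] - tester[joint]).mean() / 2.0)
    return pd.Series(vals, index=ids, name="distance_to_tester")


def heterozygosity_scan(ph: Sequence[float], d: Sequence[float],
                        h: np.ndarray, snp_ids: Sequence[str],
                        maf_min: float = 0.05, p_threshold: float = 0.001,
                        fdr_q: float = 0.20) -> pd.DataFrame:
    """Per-SNP OLS of a heterosis measure on hybrid heterozygosity.

    The model is ``PH = mu + D*beta + H*theta + e`` fitted independently
    per SNP; the reported test is the two-sided t-test on ``theta``.
    Hybrids with a missing H are dropped per SNP; SNPs whose heterozygote
    fraction falls outside ``[maf_min, 1 - maf_min]`` are skipped. A
    constant D is dropped from the design with a warning.

    All per-SNP normal equations are assembled in one vectorized pass, so
    the scan costs a few matrix products regardless of missingness
    pattern.
    """
    y = np.asarray(ph, dtype=float)
    d = np.asarray(d, dtype=float)
    h = np.asarray(h)
    if h.shape[0] != y.size or d.size != y.size:
        raise PanelError("PH, D and H dimensions do not match")
    use_d = np.std(d) > 0
    if not use_d:
        log.warning("genetic distance D is constant; dropped from the design")

    m = (h != MISSING)
    hm = np.where(m, h, 0).astype(float)
    mf = m.astype(float)
    s1 = mf.sum(axis=0)
    sh = hm.sum(axis=0)
    sy = y @ mf
    shy = y @ hm
    syy = (y * y) @ mf
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(s1 > 0, sh / s1, np.nan)

    n_param = 3 if use_d else 2
    eligible = (np.isfinite(het_frac) & (het_frac >= maf_min)
                & (het_frac <= 1 - maf_min) & (s1 > n_param))
    idx = np.flatnonzero(eligible)

    if use_d:
        sd = d @ mf
        sdd = (d * d) @ mf
        sdy = (d * y) @ mf
        sdh = d @ hm
        xtx = np.empty((idx.size, 3, 3))
        xtx[:, 0, 0] = s1[idx]
        xtx[:, 0, 1] = xtx[:, 1, 0] = sd[idx]
        xtx[:, 0, 2] = xtx[:, 2, 0] = sh[idx]
        xtx[:, 1, 1] = sdd[idx]
        xtx[:, 1, 2] = xtx[:, 2, 1] = sdh[idx]
        xtx[:, 2, 2] = sh[idx]
        xty = np.stack([sy[idx], sdy[idx], shy[idx]], axis=1)
    else:
        xtx = np.empty((idx.size, 2, 2))
        xtx[:, 0, 0] = s1[idx]
        xtx[:, 0, 1] = xtx[:, 1, 0] = sh[idx]
        xtx[:, 1, 1] = sh[idx]
        xty = np.stack([sy[idx], shy[idx]], axis=1)

    scale = np.maximum(s1[idx], 1.0) ** n_param
    dets = np.linalg.det(xtx)
    solvable = dets > 1e-10 * scale
    sol_idx = idx[solvable]
    if sol_idx.size:
        b = np.linalg.solve(xtx[solvable], xty[solvable][..., None])[..., 0]
        rss = syy[sol_idx] - np.einsum("ij,ij->i", b, xty[solvable])
        dof = s1[sol_idx] - n_param
        sigma2 = np.maximum(rss, 0.0) / dof
        inv = np.linalg.inv(xtx[solvable])
        se = np.sqrt(sigma2 * inv[:, -1, -1])
        theta = b[:, -1]
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = theta / se
        pv = _t_pvalue(tstat, dof)
    else:
        theta = se = pv = np.array([])
        dof = np.array([])

    out = pd.DataFrame({
        "snp_id": np.asarray(snp_ids, dtype=object)[sol_idx],
        "beta": theta, "se": se, "p_value": pv,
        "maf": np.minimum(het_frac[sol_idx], 1 - het_frac[sol_idx]),
        "n_used": s1[sol_idx].astype(int)})
    out = out[np.isfinite(out["p_value"])].reset_index(drop=True)
    return _attach_significance(out, p_threshold, fdr_q)


def variance_explained(y: Sequence[float], predictors: np.ndarray,
                       covariates: np.ndarray | None = None) -> dict:
    """R-squared of the joint OLS fit of significant loci (plus the
    discovery-model covariates) to a phenotype.

    Returns ``{"r2": float | nan, "saturated": bool, "n": int, "k": int}``;
    designs with ``n <= k + 2`` are flagged saturated with no value.
    """
    y = np.asarray(y, dtype=float)
    parts = [np.ones((y.size, 1))]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != y.size:
            cov = cov.T
        parts.append(cov)
    pred = np.atleast_2d(np.asarray(predictors, dtype=float))
    if pred.shape[0] != y.size:
        pred = pred.T
    if pred.shape[1] == 0:
        return {"r2": np.nan, "saturated": False, "n": int(y.size), "k": 0}
    parts.append(pred)
    x = np.column_stack(parts)
    k = x.shape[1] - 1
    if y.size <= k + 2:
        return {"r2": np.nan, "saturated": True, "n": int(y.size), "k": k}
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else np.nan
    return {"r2": r2, "saturated": False, "n": int(y.size), "k": k}
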