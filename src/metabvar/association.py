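"""Pairwise association scans with Benjamini–Hochberg control.

Diet–metabolite and microbiome–metabolite links are Spearman correlations
between transformed features and covariate-adjusted metabolite residuals.
mQTLs are Spearman correlations between SNP dosage and metabolite
residuals, declared study-wide significant below the genome-wide alpha
divided by the number of metabolites tested, then reduced to independent
lead SNPs by greedy LD clumping (r^2 < 0.05 within a 500-kb window).
Metabolites linked to two or more factor types enter a pairwise
interaction scan, y ~ a + b + a*b, testing the product term.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsLayer
from .preprocess import ResidualMatrix

log = logging.getLogger("metabvar")

__all__ = [
    "spearman_scan",
    "benjamini_hochberg",
    "study_wide_threshold",
    "map_mqtls",
    "ld_clump",
    "interaction_scan",
]


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def study_wide_threshold(genomewide_alpha: float = 5.0e-8, n_metabolites: int = 1) -> float:
    """Study-wide mQTL significance: genome-wide alpha split over the
    number of metabolites tested (Bonferroni across the metabolite axis)."""
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    return genomewide_alpha / n_metabolites


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, ResidualMatrix):
        return x.data
    if isinstance(x, OmicsLayer):
        return x.data
    return x


def _spearman_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """All-pairs Spearman rho and two-sided t-approximation p between
    columns of X and columns of Y (complete data, shared samples)."""
    n = X.shape[0]
    rx = np.apply_along_axis(stats.rankdata, 0, X)
    ry = np.apply_along_axis(stats.rankdata, 0, Y)
    rx = (rx - rx.mean(axis=0)) / np.where(rx.std(axis=0) == 0, np.inf, rx.std(axis=0))
    ry = (ry - ry.mean(axis=0)) / np.where(ry.std(axis=0) == 0, np.inf, ry.std(axis=0))
    rho = rx.T @ ry / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p, n


def spearman_scan(X, Y, min_n: int = 10) -> pd.DataFrame:
    """Spearman correlation of every X feature against every Y metabolite.

    Pairwise-complete handling: rows with a missing value in either member
    of a pair are dropped for that pair.  Returns a long table with
    ``feature_id, metabolite_id, rho, p, q, n_used``; q is BH over the
    whole scan.
    """
    Xf, Yf = _as_frame(X), _as_frame(Y)
    common = Xf.index.intersection(Yf.index)
    if len(common) == 0:
        raise ValueError("spearman_scan: no overlapping samples")
    Xf, Yf = Xf.loc[common], Yf.loc[common]

    if not Xf.isna().any().any() and not Yf.isna().any().any():
        if len(common) < min_n:
            raise ValueError(f"spearman_scan: only {len(common)} shared samples (< {min_n})")
        rho, p, n = _spearman_matrix(Xf.to_numpy(float), Yf.to_numpy(float))
        recs = pd.DataFrame({
            "feature_id": np.repeat(Xf.columns, Yf.shape[1]),
            "metabolite_id": np.tile(Yf.columns, Xf.shape[1]),
            "rho": rho.ravel(),
            "p": p.ravel(),
            "n_used": n,
        })
    else:
        rows = []
        for fx in Xf.columns:
            xv = Xf[fx]
            for fy in Yf.columns:
                yv = Yf[fy]
                ok = xv.notna() & yv.notna()
                if int(ok.sum()) < min_n:
                    continue
                rho_i, p_i = stats.spearmanr(xv[ok], yv[ok])
                rows.append({"feature_id": fx, "metabolite_id": fy,
                             "rho": rho_i, "p": p_i, "n_used": int(ok.sum())})
        recs = pd.DataFrame(rows)
    recs["q"] = benjamini_hochberg(recs["p"].to_numpy())
    return recs


def ld_clump(
    records: pd.DataFrame,
    dosages: OmicsLayer,
    clump_r2: float = 0.05,
    window_bp: int = 500_000,
) -> list[str]:
    """Greedy LD clumping of one metabolite's SNP association records.

    Sort by ascending p (ties by chromosome, position, id); accept a SNP
    iff no previously accepted SNP on the same chromosome within
    ``window_bp`` has dosage r^2 >= ``clump_r2`` with it.  Returns lead
    SNP ids.
    """
    if records.empty:
        return []
    meta = dosages.feature_meta
    recs = records.copy()
    recs["chrom"] = meta.loc[recs["snp_id"], "chrom"].to_numpy()
    recs["pos"] = meta.loc[recs["snp_id"], "pos"].to_numpy()
    recs = recs.sort_values(["p", "chrom", "pos", "snp_id"], kind="mergesort")
    G = dosages.data
    leads: list[str] = []
    for _, row in recs.iterrows():
        sid = row["snp_id"]
        ok = True
        for lead in leads:
            if meta.loc[lead, "chrom"] != row["chrom"]:
                continue
            if abs(int(meta.loc[lead, "pos"]) - int(row["pos"])) > window_bp:
                continue
            r = np.corrcoef(G[sid], G[lead])[0, 1]
            if r * r >= clump_r2:
                ok = False
                break
        if ok:
            leads.append(sid)
    return leads


def map_mqtls(
    dosages: OmicsLayer,
    metabolite_residuals: ResidualMatrix | pd.DataFrame,
    threshold: float,
    clump_r2: float = 0.05,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Spearman mQTL scan of every SNP against every metabolite residual.

    Monomorphic SNPs are skipped with a log entry.  Records are flagged by
    the study-wide threshold; for each metabolite the study-wide-significant
    SNPs are clumped and leads flagged.
    """
    Y = _as_frame(metabolite_residuals)
    common = dosages.data.index.intersection(Y.index)
    G = dosages.data.loc[common]
    Y = Y.loc[common]
    poly = G.std(axis=0) > 0
    skipped = G.columns[~poly].tolist()
    if skipped:
        log.info("map_mqtls: skipped %d monomorphic SNP(s)", len(skipped))
    G = G.loc[:, poly]
    rho, p, n = _spearman_matrix(G.to_numpy(float), Y.to_numpy(float))
    recs = pd.DataFrame({
        "snp_id": np.repeat(G.columns, Y.shape[1]),
        "metabolite_id": np.tile(Y.columns, G.shape[1]),
        "rho": rho.ravel(),
        "p": p.ravel(),
        "n_used": n,
    })
    recs["q"] = benjamini_hochberg(recs["p"].to_numpy())
    recs["passes_study_wide"] = recs["p"] < threshold
    recs["clump_lead"] = False
    for mid, grp in recs[recs["passes_study_wide"]].groupby("metabolite_id", sort=False):
        leads = ld_clump(grp, dosages, clump_r2=clump_r2, window_bp=window_bp)
        sel = (recs["metabolite_id"] == mid) & recs["snp_id"].isin(leads)
        recs.loc[sel, "clump_lead"] = True
    return recs


def interaction_scan(
    metabolite_residuals: ResidualMatrix | pd.DataFrame,
    factor_pairs: list[tuple[str, pd.Series, str, pd.Series]] | pd.DataFrame,
    factors: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Pairwise interaction test per metabolite: y ~ a + b + a*b.

    ``factor_pairs`` is a list of (metabolite_id, factor_a_id, factor_b_id)
    triples when ``factors`` maps factor ids to sample-indexed series, or a
    list of (metabolite_id, series_a, name_a, series_b, name_b).  Reports
    the OLS two-sided t-test p for the product coefficient, BH-adjusted
    across all tested pairs; degenerate (zero-variance) product columns are
    skipped with a log entry.
    """
    Y = _as_frame(metabolite_residuals)
    rows = []
    for item in factor_pairs:
        mid, fa_id, fb_id = item
        a, b = factors[fa_id], factors[fb_id]
        y = Y[mid]
        common = y.index.intersection(a.index).intersection(b.index)
        yv = y.loc[common].to_numpy(float)
        av = a.loc[common].to_numpy(float)
        bv = b.loc[common].to_numpy(float)
        ab = av * bv
        if av.std() == 0 or bv.std() == 0 or ab.std() == 0:
            log.info("interaction_scan: degenerate pair (%s, %s, %s) skipped", mid, fa_id, fb_id)
            continue
        X = np.column_stack([np.ones_like(av), av, bv, ab])
        beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
        if rank < X.shape[1]:
            log.info("interaction_scan: rank-deficient pair (%s, %s, %s) skipped", mid, fa_id, fb_id)
            continue
        resid = yv - X @ beta
        dof = len(yv) - X.shape[1]
        sigma2 = resid @ resid / dof
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * XtX_inv[3, 3])
        tstat = beta[3] / se
        p = 2 * stats.t.sf(abs(tstat), df=dof)
        rows.append({
            "metabolite_id": mid, "factor_a": fa_id, "factor_b": fb_id,
            "interaction_beta": beta[3], "interaction_p": p, "n_used": len(yv),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = benjamini_hochberg(out["interaction_p"].to_numpy())
    return out
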