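"""Temporal stability across two time points and metabolome-based
diet-quality prediction.

Stability is the per-metabolite Spearman correlation between baseline and
follow-up levels in paired samples; it is related to explained variance
(the more a metabolite's variance is explained by diet, genetics and the
microbiome, the more stable it tends to be) and compared between
dominance groups by rank-sum tests.  A joint classical-MDS (PCoA)
projection of the pooled Euclidean distance matrix visualizes the
metabolome shift between time points, tested per component by paired
signed-rank tests.

The diet-quality model screens metabolites by univariate Spearman
association with the quality score (p < 0.05), runs lasso with
cross-validated lambda, refits survivors by OLS and reports validation
adjusted r^2 and F-test p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .io import OmicsLayer

log = logging.getLogger("metabvar")

__all__ = [
    "metabolite_stability",
    "stability_vs_variance",
    "compare_stability_groups",
    "classical_mds",
    "metabolome_pca_shift",
    "DietScoreModel",
    "train_diet_score_model",
    "evaluate_diet_score",
]


def _frame(x) -> pd.DataFrame:
    return x.data if isinstance(x, OmicsLayer) else x


def metabolite_stability(baseline, followup, min_pairs: int = 30) -> pd.DataFrame:
    """Per-metabolite Spearman rho between paired baseline and follow-up
    samples, with two-sided p."""
    b, f = _frame(baseline), _frame(followup)
    orphans = f.index.difference(b.index).tolist()
    if orphans:
        raise ValueError(f"unpaired follow-up sample(s): {orphans[:5]}")
    common = f.index
    if len(common) < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired samples, got {len(common)}")
    bv, fv = b.loc[common], f.loc[common]
    rows = []
    for mid in b.columns:
        rho, p = stats.spearmanr(bv[mid], fv[mid])
        rows.append({"metabolite_id": mid, "rho_temporal": rho, "p": p, "n_pairs": len(common)})
    return pd.DataFrame(rows)


def stability_vs_variance(stability: pd.DataFrame, variance_records: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of temporal stability against per-layer and
    total explained variance, joined on metabolite id."""
    joined = stability.merge(variance_records, on="metabolite_id")
    if len(joined) < 10:
        log.warning("stability_vs_variance: only %d joined metabolites", len(joined))
    rows = []
    cols = [c for c in joined.columns if c.startswith("r2_adj_")]
    for col in cols:
        rho, p = stats.spearmanr(joined["rho_temporal"], joined[col])
        rows.append({"variance_term": col.replace("r2_adj_", ""), "rho": rho, "p": p,
                     "n": len(joined)})
    return pd.DataFrame(rows)


def compare_stability_groups(
    stability: pd.DataFrame,
    dominance: pd.Series | pd.DataFrame,
    min_group: int = 5,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of temporal stability
    between dominance groups (normal approximation with continuity
    correction); groups smaller than ``min_group`` are skipped."""
    if isinstance(dominance, pd.DataFrame):
        dominance = dominance.set_index("metabolite_id")["dominant"]
    joined = stability.set_index("metabolite_id").join(dominance.rename("dominant"), how="inner")
    groups = {g: sub["rho_temporal"].to_numpy()
              for g, sub in joined.groupby("dominant") if g != "none"}
    names = sorted(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            if len(groups[ga]) < min_group or len(groups[gb]) < min_group:
                log.info("compare_stability_groups: pair (%s, %s) skipped (too small)", ga, gb)
                continue
            stat, p = stats.mannwhitneyu(groups[ga], groups[gb], alternative="two-sided",
                                         method="asymptotic")
            rows.append({"group_a": ga, "group_b": gb,
                         "n_a": len(groups[ga]), "n_b": len(groups[gb]),
                         "statistic": stat, "p": p})
    return pd.DataFrame(rows)


def classical_mds(distance: np.ndarray, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Classical metric MDS (principal coordinates) of a distance matrix.

    Eigendecomposition of the Gower-centered matrix; coordinates are
    eigenvectors scaled by sqrt of the positive eigenvalues.  For a
    Euclidean input the coordinates reproduce the distances exactly.
    """
    from .variance import gower_center

    G = gower_center(np.asarray(distance, float))
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-9 * max(1.0, vals.max())
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if n_components is not None:
        coords = coords[:, :n_components]
        vals = vals[:n_components]
    return coords, vals[vals > 0] if n_components is None else vals


def metabolome_pca_shift(baseline, followup, n_components: int = 2) -> dict:
    """Joint PCoA of both time points with per-component paired tests.

    Baseline and follow-up samples (paired) are pooled into one Euclidean
    distance matrix and projected together; each of the first components
    gets a paired two-sided Wilcoxon signed-rank p between time points.
    A degenerate test (all differences zero) reports p = 1 with a flag.
    """
    b, f = _frame(baseline), _frame(followup)
    common = b.index.intersection(f.index)
    bv, fv = b.loc[common].to_numpy(float), f.loc[common].to_numpy(float)
    pooled = np.vstack([bv, fv])
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(pooled, metric="euclidean"))
    coords, eigvals = classical_mds(D)
    n = len(common)
    rows = []
    for k in range(min(n_components, coords.shape[1])):
        diff = coords[n:, k] - coords[:n, k]
        if np.allclose(diff, 0):
            rows.append({"component": k + 1, "p": 1.0, "degenerate": True})
            continue
        _, p = stats.wilcoxon(coords[:n, k], coords[n:, k])
        rows.append({"component": k + 1, "p": float(p), "degenerate": False})
    return {
        "coords_baseline": pd.DataFrame(coords[:n, :n_components], index=common),
        "coords_followup": pd.DataFrame(coords[n:, :n_components], index=common),
        "eigenvalues": eigvals,
        "shift_tests": pd.DataFrame(rows),
        "distance": D,
        "coords_full": coords,
    }


@dataclass
class DietScoreModel:
    """Sparse linear predictor of a diet-quality score from metabolites."""

    selected: list[str]
    intercept: float
    coefficients: pd.Series
    train_r2_adj: float
    train_f_p: float
    intercept_only: bool = False

    def predict(self, metabolome: pd.DataFrame | OmicsLayer) -> pd.Series:
        df = _frame(metabolome)
        missing = [m for m in self.selected if m not in df.columns]
        if missing:
            raise ValueError(f"metabolite(s) missing from validation data: {missing[:5]}")
        if self.intercept_only:
            return pd.Series(self.intercept, index=df.index, name="predicted_score")
        pred = self.intercept + df[self.selected].to_numpy(float) @ self.coefficients.to_numpy()
        return pd.Series(pred, index=df.index, name="predicted_score")


def _adj_r2_f(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    if r2 >= 1 - 1e-14:
        return adj, 0.0
    f = (r2 / p) / ((1 - r2) / (n - p - 1))
    return adj, float(stats.f.sf(f, p, n - p - 1))


def train_diet_score_model(
    train_metabolome,
    train_score: pd.Series,
    screen_p: float = 0.05,
    cv_folds: int = 10,
    seed: int = 0,
) -> DietScoreModel:
    """Spearman screen (p < 0.05) -> lasso with CV lambda -> OLS refit."""
    X = _frame(train_metabolome)
    common = X.index.intersection(train_score.index)
    X, y = X.loc[common], train_score.loc[common].to_numpy(float)
    keep = []
    for mid in X.columns:
        _, p = stats.spearmanr(X[mid], y)
        if p < screen_p:
            keep.append(mid)
    if not keep:
        log.warning("train_diet_score_model: no metabolites pass the screen; intercept-only")
        return DietScoreModel([], float(np.mean(y)), pd.Series(dtype=float), 0.0, 1.0, True)
    Xs = X[keep].to_numpy(float)
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
    sd = np.where(sd == 0, 1, sd)
    Xz = (Xs - mu) / sd
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
    lasso = LassoCV(alphas=100, cv=cv, max_iter=5000).fit(Xz, y)
    sel = np.where(lasso.coef_ != 0)[0]
    if len(sel) == 0:
        log.warning("train_diet_score_model: lasso selected nothing; intercept-only")
        return DietScoreModel([], float(np.mean(y)), pd.Series(dtype=float), 0.0, 1.0, True)
    names = [keep[j] for j in sel]
    Xsel = X[names].to_numpy(float)
    Xc = np.column_stack([np.ones(len(y)), Xsel])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    adj, fp = _adj_r2_f(y, Xsel)
    return DietScoreModel(
        selected=names,
        intercept=float(beta[0]),
        coefficients=pd.Series(beta[1:], index=names),
        train_r2_adj=float(adj),
        train_f_p=float(fp),
    )


def evaluate_diet_score(
    model: DietScoreModel,
    validation_metabolome,
    validation_score: pd.Series,
) -> dict:
    """Validation performance: adjusted r^2 and F-test p of the observed
    score regressed on the model's predictions."""
    pred = model.predict(validation_metabolome)
    common = pred.index.intersection(validation_score.index)
    yv = validation_score.loc[common].to_numpy(float)
    pv = pred.loc[common].to_numpy(float)
    if model.intercept_only or pv.std() == 0:
        return {"r2_adj": 0.0, "f_p": 1.0, "n": len(common)}
    adj, fp = _adj_r2_f(yv, pv[:, None])
    return {"r2_adj": float(adj), "f_p": float(fp), "n": len(common)}
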