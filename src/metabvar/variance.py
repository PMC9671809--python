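"""Variance attribution: whole-metabolome PERMANOVA and per-metabolite
penalized partitioning.

The whole-metabolome share of each factor is estimated by PERMANOVA on a
sample dissimilarity matrix: the Gower-centered inner-product matrix is
projected on the factor's design, R^2 = SS_model / SS_total, and
significance comes from label permutation.  Collinear candidate features
are reduced to representatives by average-linkage clustering of the
1 - r^2 inter-correlation distance cut at 70% dissimilarity (medoid per
cluster), and the representatives enter a combined PERMANOVA whose
sequential sums of squares are attributed back to their layers.

Per metabolite, candidates significant in the association scans are
screened by lasso (10-fold cross-validated lambda at minimum mean error),
survivors are refit by OLS, and the adjusted r^2 per layer with its F-test
p-value is recorded; the layer with the strictly greatest significant
adjusted r^2 is the metabolite's dominant factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.linear_model import ElasticNetCV, LassoCV
from sklearn.model_selection import KFold

from .association import benjamini_hochberg

log = logging.getLogger("metabvar")

__all__ = [
    "PermanovaResult",
    "permanova_r2",
    "select_representative_features",
    "combined_permanova",
    "partition_metabolite_variance",
    "partition_all_metabolites",
    "assign_dominant_factor",
]

LAYERS = ("diet", "genotype", "microbiome")


@dataclass
class PermanovaResult:
    factor_id: str
    r2: float
    pseudo_f: float
    p_perm: float
    n_perm: int


def gower_center(distance: np.ndarray) -> np.ndarray:
    """Double-centered inner-product matrix G = -0.5 * J D^2 J."""
    a = -0.5 * distance**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _design(factor: np.ndarray) -> np.ndarray:
    """Centered design columns for a numeric vector/matrix or categorical
    label vector (dummy indicators, first level dropped)."""
    factor = np.asarray(factor)
    if factor.dtype.kind in "OUS":
        levels = pd.unique(factor)
        X = np.column_stack([(factor == lv).astype(float) for lv in levels[1:]])
    else:
        X = factor.astype(float)
        if X.ndim == 1:
            X = X[:, None]
    return X - X.mean(axis=0)


def _basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of centered X."""
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    return Q[:, keep]


def _hat(X: np.ndarray) -> np.ndarray:
    """Projection matrix onto the column space of centered X."""
    Q = _basis(X)
    return Q @ Q.T


def permanova_r2(
    distance: np.ndarray | pd.DataFrame,
    factor,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    R^2 = tr(H G)/tr(G) with G the Gower-centered matrix and H the hat
    matrix of the centered factor design; pseudo-F uses the model and
    residual degrees of freedom; p = (#{F_perm >= F_obs} + 1)/(n_perm + 1)
    under random relabeling of samples.  On a univariate Euclidean
    distance this reduces exactly to the one-way ANOVA R^2.
    """
    D = distance.to_numpy(dtype=float) if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    name = getattr(factor, "name", None) or "factor"
    fac = factor.to_numpy() if isinstance(factor, (pd.Series, pd.DataFrame)) else np.asarray(factor)
    n = D.shape[0]
    G = gower_center(D)
    X = _design(fac)
    Q = _basis(X)
    df_model = Q.shape[1]
    df_resid = n - df_model - 1
    ss_total = np.trace(G)
    ss_model = float(np.einsum("ik,ij,jk->", Q, G, Q))  # tr(Q^T G Q)
    r2 = ss_model / ss_total
    f_obs = (ss_model / df_model) / ((ss_total - ss_model) / df_resid)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # permuting G's rows/cols equals permuting the basis rows:
    # tr(Q^T P G P^T Q) = sum_k (P^T q_k)^T G (P^T q_k)
    ss_m = np.zeros(n_perm)
    for k in range(df_model):
        U = Q[:, k][perms]  # (n_perm, n)
        ss_m += ((U @ G) * U).sum(axis=1)
    f_perm = (ss_m / df_model) / ((ss_total - ss_m) / df_resid)
    p = (np.sum(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermanovaResult(str(name), float(r2), float(f_obs), float(p), n_perm)


def select_representative_features(
    features: pd.DataFrame,
    dissimilarity_cut: float = 0.70,
) -> tuple[list[str], pd.Series]:
    """Reduce collinear features to cluster representatives.

    Average-linkage tree on D = 1 - r^2 (pairwise Pearson), cut at the
    dissimilarity threshold; per cluster the medoid — the feature with the
    greatest mean r^2 to its cluster mates, ties broken by feature id —
    represents the cluster.  Constant features get r = 0 with everything.
    Returns (representative ids, cluster label per feature).
    """
    cols = features.columns.tolist()
    if len(cols) == 0:
        raise ValueError("no features to cluster")
    if len(cols) == 1:
        return cols, pd.Series([1], index=cols)
    vals = features.to_numpy(float)
    sd = vals.std(axis=0)
    const = sd == 0
    if const.any():
        log.info("select_representative_features: %d constant feature(s), r set to 0",
                 int(const.sum()))
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r2 = r**2
    D = np.clip(1.0 - r2, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=dissimilarity_cut, criterion="distance")
    reps = []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if len(members) == 1:
            reps.append(cols[members[0]])
            continue
        sub = r2[np.ix_(members, members)]
        mean_r2 = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        best = mean_r2.max()
        cand = sorted(cols[members[i]] for i in range(len(members))
                      if mean_r2[i] >= best - 1e-12)
        reps.append(cand[0])
    return sorted(reps, key=cols.index), pd.Series(labels, index=cols)


def combined_permanova(
    distance: np.ndarray | pd.DataFrame,
    representatives: pd.DataFrame,
    layer_of: dict[str, str] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    order: str = "sequential",
) -> dict:
    """Joint PERMANOVA over representative features with attribution.

    Representatives enter in descending order of marginal R^2; each one's
    design column is orthogonalized against those already entered, and its
    sequential sum of squares tr(h_k G) is attributed to its layer (via
    ``layer_of``).  Total R^2 = model SS / total SS.  With
    ``order='marginal'`` each feature's marginal R^2 is reported instead
    (shares then need not sum to the total).
    """
    D = distance.to_numpy(dtype=float) if isinstance(distance, pd.DataFrame) else np.asarray(distance, float)
    n = D.shape[0]
    if representatives.shape[1] > n - 2:
        raise ValueError("more representatives than samples - 2")
    G = gower_center(D)
    ss_total = np.trace(G)
    X = representatives.to_numpy(float)
    X = X - X.mean(axis=0)

    marg = np.array([np.sum(_hat(X[:, [j]]) * G) for j in range(X.shape[1])]) / ss_total
    feat_order = np.argsort(-marg, kind="mergesort")

    shares: dict[str, float] = {}
    per_feature = {}
    if order == "marginal":
        for j in feat_order:
            fid = representatives.columns[j]
            per_feature[fid] = float(marg[j])
    else:
        basis: list[np.ndarray] = []
        for j in feat_order:
            fid = representatives.columns[j]
            v = X[:, j].copy()
            for b in basis:
                v -= (v @ b) * b
            nv = np.linalg.norm(v)
            if nv < 1e-10:
                per_feature[fid] = 0.0
                continue
            v /= nv
            basis.append(v)
            per_feature[fid] = float(v @ G @ v) / ss_total
    for fid, share in per_feature.items():
        layer = (layer_of or {}).get(fid, "all")
        shares[layer] = shares.get(layer, 0.0) + share
    total = float(np.sum(_hat(X) * G)) / ss_total
    return {
        "total_r2": total,
        "layer_shares": shares,
        "per_feature": per_feature,
        "entry_order": [representatives.columns[j] for j in feat_order],
        "order_mode": order,
    }


# ---------------------------------------------------------------------------
# per-metabolite partitioning


def _ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """(r2, adjusted r2, F-test p) of y on X plus intercept."""
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    ss_res = resid @ resid
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    df_resid = n - p - 1
    if df_resid <= 0:
        return float(r2), float("nan"), 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    if r2 >= 1.0 - 1e-14:
        return float(r2), float(adj), 0.0
    f = (r2 / p) / ((1.0 - r2) / df_resid)
    pval = stats.f.sf(f, p, df_resid)
    return float(r2), float(adj), float(pval)


def partition_metabolite_variance(
    y: pd.Series,
    candidates: dict[str, pd.DataFrame],
    cv_folds: int = 10,
    regularization_mode: str = "lasso",
    seed: int = 0,
) -> dict:
    """Penalized variance partition of one metabolite across layers.

    Per layer: predictors standardized, lasso path over 100 log-spaced
    lambdas with seeded ``cv_folds``-fold CV, lambda at minimum mean CV
    error; nonzero-coefficient features refit by OLS; adjusted r^2 and
    F-test p recorded.  No surviving features means r2_adj = 0, p = 1.
    If more survivors than n/2, the top n/2 by |penalized coefficient|
    are kept (logged).  ``regularization_mode='elastic_net'`` switches to
    the mixing-0.5 elastic net.
    """
    out: dict = {"metabolite_id": y.name}
    selected_all: list[np.ndarray] = []
    yv = y.to_numpy(float)
    n = len(yv)
    for layer in LAYERS:
        X = candidates.get(layer)
        if X is None or X.shape[1] == 0:
            out[f"r2_adj_{layer}"] = 0.0
            out[f"p_{layer}"] = 1.0
            out[f"selected_{layer}"] = ""
            continue
        Xv = X.loc[y.index].to_numpy(float)
        sd = Xv.std(axis=0)
        keep = sd > 0
        Xv, names = Xv[:, keep], X.columns[keep]
        if Xv.shape[1] == 0:
            out[f"r2_adj_{layer}"] = 0.0
            out[f"p_{layer}"] = 1.0
            out[f"selected_{layer}"] = ""
            continue
        Xz = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed % (2**31))
        if regularization_mode == "elastic_net":
            model = ElasticNetCV(l1_ratio=0.5, alphas=100, cv=cv, max_iter=5000)
        else:
            model = LassoCV(alphas=100, cv=cv, max_iter=5000)
        model.fit(Xz, yv)
        coef = model.coef_
        sel = np.where(coef != 0)[0]
        if len(sel) > n // 2:
            top = np.argsort(-np.abs(coef[sel]), kind="mergesort")[: n // 2]
            log.info("partition: %s/%s truncated to top %d features", y.name, layer, n // 2)
            sel = sel[top]
        if len(sel) == 0:
            out[f"r2_adj_{layer}"] = 0.0
            out[f"p_{layer}"] = 1.0
            out[f"selected_{layer}"] = ""
            continue
        _, adj, pval = _ols_fit(yv, Xz[:, sel])
        out[f"r2_adj_{layer}"] = adj
        out[f"p_{layer}"] = pval
        out[f"selected_{layer}"] = ",".join(names[sel])
        selected_all.append(Xz[:, sel])
    if selected_all:
        Xall = np.column_stack(selected_all)
        _, adj_all, p_all = _ols_fit(yv, Xall)
        out["r2_adj_model"], out["model_p"] = adj_all, p_all
    else:
        out["r2_adj_model"], out["model_p"] = 0.0, 1.0
    return out


def partition_all_metabolites(
    metabolite_residuals: pd.DataFrame,
    candidate_map: dict[str, dict[str, pd.DataFrame]],
    cv_folds: int = 10,
    regularization_mode: str = "lasso",
    fdr_level: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Partition every metabolite and assign dominant factors.

    ``candidate_map[mid][layer]`` holds that metabolite's FDR-significant
    candidate features per layer.  BH q-values are computed across
    metabolites separately per layer and for the combined model; dominance
    follows :func:`assign_dominant_factor`.
    """
    rows = []
    for mid in metabolite_residuals.columns:
        rows.append(
            partition_metabolite_variance(
                metabolite_residuals[mid],
                candidate_map.get(mid, {}),
                cv_folds=cv_folds,
                regularization_mode=regularization_mode,
                seed=seed,
            )
        )
    recs = pd.DataFrame(rows).set_index("metabolite_id")
    for layer in LAYERS:
        recs[f"q_{layer}"] = benjamini_hochberg(recs[f"p_{layer}"].to_numpy())
    recs["q_model"] = benjamini_hochberg(recs["model_p"].to_numpy())
    recs["dominant"] = [
        assign_dominant_factor(row, fdr_level=fdr_level) for _, row in recs.iterrows()
    ]
    return recs.reset_index()


def assign_dominant_factor(record: pd.Series | dict, fdr_level: float = 0.05) -> str:
    """Dominant layer: strictly greatest adjusted r^2 among layers
    significant at q < fdr_level; 'none' when no layer is significant or
    the top is tied.  Negative adjusted r^2 is floored at 0 for the
    comparison (fraction semantics)."""
    rec = record if isinstance(record, dict) else record.to_dict()
    sig = {
        layer: max(0.0, float(rec[f"r2_adj_{layer}"]))
        for layer in LAYERS
        if rec.get(f"q_{layer}", 1.0) < fdr_level
    }
    if not sig:
        return "none"
    best = max(sig.values())
    winners = [l for l, v in sig.items() if v == best]
    if len(winners) > 1:
        return "none"
    return {"genotype": "genetics"}.get(winners[0], winners[0])
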