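"""Transformations applied before every analysis stage.

The metabolome is natural-log transformed and residualized on the
confounder set.  Microbiome relative abundances follow the chain
prevalence filter -> closure renormalization -> centered log-ratio ->
rank-based inverse normal.  Continuous dietary habits are inverse-rank
transformed.  All residualization is ordinary least squares with an
intercept, so residuals are exactly orthogonal to the covariates used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LayerKind, OmicsLayer

log = logging.getLogger("metabvar")

__all__ = [
    "ResidualMatrix",
    "log_transform",
    "residualize",
    "clr_transform",
    "inverse_rank_transform",
    "prevalence_filter",
    "transform_microbiome",
]


@dataclass
class ResidualMatrix:
    """Residuals of a layer after OLS removal of a covariate set."""

    data: pd.DataFrame
    covariate_names: list[str]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def log_transform(metabolome: OmicsLayer) -> OmicsLayer:
    """Elementwise natural log.

    Zeros are shifted by half the smallest positive value in the matrix
    before taking logs (and the shift is logged); negative values are
    rejected.  Zero-variance columns survive as constant columns.
    """
    vals = metabolome.values.copy()
    if np.nanmin(vals) < 0:
        raise ValueError("log_transform: negative values present")
    if np.any(vals == 0):
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError("log_transform: all values are zero")
        shift = pos.min() * 0.5
        n0 = int((vals == 0).sum())
        log.info("log_transform: %d zeros shifted by %g", n0, shift)
        vals = np.where(vals == 0, shift, vals)
    out = pd.DataFrame(np.log(vals), index=metabolome.data.index, columns=metabolome.data.columns)
    const = out.columns[out.std(axis=0, ddof=0) == 0].tolist()
    if const:
        log.info("log_transform: zero-variance column(s) preserved: %s", const[:10])
    return metabolome.with_data(out)


def residualize(
    target: OmicsLayer | pd.DataFrame,
    covariates: OmicsLayer | pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> ResidualMatrix:
    """OLS residuals of every target column on the covariate set (+intercept).

    Samples with any missing covariate are dropped (count logged).  A
    rank-deficient covariate design is rejected, naming the columns that
    make it collinear.
    """
    tgt = target.data if isinstance(target, OmicsLayer) else target
    cov = covariates.data if isinstance(covariates, OmicsLayer) else covariates
    if covariate_names is None:
        covariate_names = cov.columns.tolist()
    missing = [c for c in covariate_names if c not in cov.columns]
    if missing:
        raise ValueError(f"residualize: covariate(s) not found: {missing}")
    cov = cov[covariate_names]
    common = tgt.index.intersection(cov.index)
    tgt, cov = tgt.loc[common], cov.loc[common]
    keep = ~cov.isna().any(axis=1)
    if (~keep).sum():
        log.info("residualize: dropped %d samples with missing covariates", int((~keep).sum()))
    tgt, cov = tgt.loc[keep], cov.loc[keep]
    n, p = cov.shape
    if n <= p + 1:
        raise ValueError(f"residualize: n={n} too small for {p} covariates")

    X = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j, name in enumerate(covariate_names):
            Xj = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                collinear.append(name)
        raise ValueError(f"residualize: collinear covariate column(s): {collinear}")

    Y = tgt.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return ResidualMatrix(
        pd.DataFrame(resid, index=tgt.index, columns=tgt.columns),
        list(covariate_names),
    )


def clr_transform(abundances: OmicsLayer, pseudocount: float | None = None) -> OmicsLayer:
    """Centered log-ratio transform of compositional rows.

    Zeros are replaced by half the global smallest nonzero relative
    abundance (or ``pseudocount`` if given), rows are renormalized to sum
    to one, then clr(x)_i = ln x_i - mean_j ln x_j.  Output rows sum to
    zero by construction.
    """
    vals = abundances.values.copy()
    sums = vals.sum(axis=1)
    if np.any(np.abs(sums - 1) > 1e-6):
        bad = np.where(np.abs(sums - 1) > 1e-6)[0]
        if np.any(sums[bad] == 0):
            raise ValueError("clr_transform: all-zero row(s) present")
        raise ValueError("clr_transform: rows must sum to 1 (closure violated)")
    if np.any(vals == 0):
        nz = vals[vals > 0]
        pc = pseudocount if pseudocount is not None else nz.min() / 2.0
        vals = np.where(vals == 0, pc, vals)
        vals = vals / vals.sum(axis=1, keepdims=True)
    logv = np.log(vals)
    clr = logv - logv.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=abundances.data.index, columns=abundances.data.columns)
    return abundances.with_data(out, transformed=True)


def inverse_rank_transform(matrix: OmicsLayer | pd.DataFrame) -> pd.DataFrame:
    """Column-wise rank-based inverse normal transform (Blom offset).

    value = Phi^-1((r - 3/8) / (n + 1/4)) with average ranks for ties.
    Constant columns map to all zeros with a warning; missing values stay
    missing and ranks are computed over the non-missing entries.
    """
    df = matrix.data if isinstance(matrix, OmicsLayer) else matrix
    out = np.full(df.shape, np.nan)
    vals = df.to_numpy(dtype=float)
    for j in range(df.shape[1]):
        col = vals[:, j]
        ok = ~np.isnan(col)
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"inverse_rank_transform: column {df.columns[j]!r} has <3 non-missing values")
        if np.nanstd(col[ok]) == 0:
            log.warning("inverse_rank_transform: constant column %r -> zeros", df.columns[j])
            out[ok, j] = 0.0
            continue
        r = stats.rankdata(col[ok], method="average")
        out[ok, j] = stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def prevalence_filter(abundances: OmicsLayer, min_presence: float = 0.10) -> OmicsLayer:
    """Drop features with nonzero values in fewer than ``min_presence`` of
    samples (inclusive at the threshold: present in exactly 10% is kept)."""
    present = (abundances.values > 0).mean(axis=0)
    keep = present >= min_presence
    dropped = [f for f, k in zip(abundances.feature_ids, keep) if not k]
    if dropped:
        log.info("prevalence_filter: removed %d/%d features", len(dropped), len(keep))
    return abundances.with_data(abundances.data.loc[:, keep])


def transform_microbiome(abundances: OmicsLayer, min_presence: float = 0.10) -> pd.DataFrame:
    """Full microbiome chain: prevalence filter -> closure renormalization
    -> CLR -> inverse-rank.  Returns an unbounded numeric frame ready for
    association scans."""
    filt = prevalence_filter(abundances, min_presence)
    vals = filt.data.to_numpy(dtype=float)
    sums = vals.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("transform_microbiome: sample(s) with all-zero retained taxa")
    renorm = filt.with_data(pd.DataFrame(vals / sums, index=filt.data.index, columns=filt.data.columns))
    clr = clr_transform(renorm)
    return inverse_rank_transform(clr.data)
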