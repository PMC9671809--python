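"""One-sample bi-directional Mendelian randomization from summary stats.

Instruments are SNPs associated with the exposure at p < 1e-5, LD-clumped
to independence, with at least three surviving (optionally also required
to replicate with the same direction in follow-up samples).  Per-SNP Wald
ratios (beta_out / beta_exp, first-order delta SE) are meta-analyzed by
fixed-effect inverse-variance weighting; the weighted median gives a
pleiotropy-robust second estimate; MR-Egger's intercept tests directional
pleiotropy; Cochran's Q tests heterogeneity; leave-one-out flags
single-SNP-driven estimates.  The verdict cascade mirrors the filter
order: not_significant -> filtered_pleiotropy -> filtered_heterogeneity ->
filtered_loo -> filtered_reverse -> causal_candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import benjamini_hochberg, ld_clump
from .io import OmicsLayer

log = logging.getLogger("metabvar")

__all__ = [
    "InstrumentSet",
    "summary_associations",
    "select_instruments",
    "wald_ratio",
    "ivw_estimate",
    "weighted_median_estimate",
    "egger_regression",
    "cochran_q",
    "leave_one_out",
    "mr_single_pair",
    "apply_verdict_cascade",
    "run_bidirectional_mr",
]


@dataclass
class InstrumentSet:
    """Per-SNP summary statistics for one exposure's instruments."""

    exposure_id: str
    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray = field(default_factory=lambda: np.array([]))
    se_outcome: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if len(self.se_exposure) and np.any(np.asarray(self.se_exposure) <= 0):
            raise ValueError("exposure SEs must be positive")
        if len(self.se_outcome) and np.any(np.asarray(self.se_outcome) <= 0):
            raise ValueError("outcome SEs must be positive")


def summary_associations(feature: pd.Series, dosages: OmicsLayer) -> pd.DataFrame:
    """Per-SNP simple linear regression of a (residualized) feature on
    dosage: beta, SE and two-sided p per SNP.  Monomorphic SNPs skipped."""
    common = feature.index.intersection(dosages.data.index)
    y = feature.loc[common].to_numpy(float)
    G = dosages.data.loc[common].to_numpy(float)
    n = len(y)
    sd = G.std(axis=0)
    poly = sd > 0
    if (~poly).any():
        log.info("summary_associations: %d monomorphic SNP(s) skipped", int((~poly).sum()))
    Gc = G[:, poly] - G[:, poly].mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc**2).sum(axis=0)
    beta = Gc.T @ yc / sxx
    resid_ss = (yc**2).sum() - beta**2 * sxx  # per-SNP residual SS
    dof = n - 2
    se = np.sqrt(np.maximum(resid_ss, 0.0) / dof / sxx)
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2 * stats.t.sf(np.abs(t), df=dof)
    return pd.DataFrame(
        {"snp_id": dosages.data.columns[poly], "beta": beta, "se": se, "p": p, "n": n}
    )


def select_instruments(
    gwas: pd.DataFrame,
    dosages: OmicsLayer,
    exposure_id: str = "exposure",
    followup_gwas: pd.DataFrame | None = None,
    p_cut: float = 1e-5,
    followup_p: float = 0.05,
    min_snps: int = 3,
    clump_r2: float = 0.05,
    clump_window_bp: int = 500_000,
) -> InstrumentSet | str:
    """Instrument selection with the study's rules.

    SNPs below ``p_cut`` are LD-clumped to leads; if follow-up summary
    stats are supplied, leads must replicate there with the same effect
    direction at p < ``followup_p``.  Fewer than ``min_snps`` survivors is
    a typed rejection (a reason string), not an error.
    """
    hits = gwas[gwas["p"] < p_cut]
    if hits.empty:
        return "no SNPs below the instrument p threshold"
    leads = ld_clump(hits.rename(columns={"snp_id": "snp_id"}), dosages,
                     clump_r2=clump_r2, window_bp=clump_window_bp)
    sel = hits[hits["snp_id"].isin(leads)].set_index("snp_id")
    if followup_gwas is not None:
        fu = followup_gwas.set_index("snp_id")
        keep = []
        for sid in sel.index:
            if sid not in fu.index:
                continue
            same_dir = np.sign(fu.loc[sid, "beta"]) == np.sign(sel.loc[sid, "beta"])
            if same_dir and fu.loc[sid, "p"] < followup_p:
                keep.append(sid)
        sel = sel.loc[keep]
    if len(sel) < min_snps:
        return f"fewer than {min_snps} instruments ({len(sel)} survived)"
    return InstrumentSet(
        exposure_id=exposure_id,
        snp_ids=sel.index.tolist(),
        beta_exposure=sel["beta"].to_numpy(),
        se_exposure=sel["se"].to_numpy(),
    )


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Per-SNP causal estimate beta_out/beta_exp with first-order delta SE
    se_out/|beta_exp|."""
    if beta_exp == 0:
        raise ValueError("wald_ratio: exposure beta is zero")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def ivw_estimate(ratios: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted meta-analysis of Wald
    ratios: beta = sum(w b)/sum(w), se = sum(w)^-1/2 with w = se^-2;
    two-sided normal p.  With one ratio this is the Wald ratio itself."""
    ratios = np.asarray(ratios, float)
    w = np.asarray(ses, float) ** -2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def weighted_median_estimate(
    ratios: np.ndarray,
    ses: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Weighted median of Wald ratios (inverse-variance weights).

    The estimate interpolates the cumulative-weight function at 50%;
    the SE comes from a parametric bootstrap of the ratios (normal draws
    at their SEs); p is the normal approximation.  Consistent as long as
    >= 50% of the weight comes from valid instruments.
    """
    ratios = np.asarray(ratios, float)
    ses = np.asarray(ses, float)
    if len(ratios) < 3:
        raise ValueError("weighted median needs >= 3 ratios")
    beta = _weighted_median(ratios, ses**-2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.normal(ratios, ses)
        boots[b] = _weighted_median(draw, ses**-2)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else 0.0
    return float(beta), se, p


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x, kind="mergesort")
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum = cum / ws.sum()
    if cum[0] >= 0.5:
        return float(xs[0])
    if cum[-1] <= 0.5:
        return float(xs[-1])
    return float(np.interp(0.5, cum, xs))


def egger_regression(
    beta_exp: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
) -> tuple[float, float, float]:
    """MR-Egger: weighted least squares of outcome betas on exposure betas
    with an intercept (weights se_out^-2), exposure betas oriented
    positive first.  Returns (slope, intercept, intercept p).  The
    intercept tests directional pleiotropy; the slope is reported but is
    never used for filtering."""
    beta_exp = np.asarray(beta_exp, float)
    beta_out = np.asarray(beta_out, float)
    se_out = np.asarray(se_out, float)
    if len(beta_exp) < 3:
        raise ValueError("MR-Egger needs >= 3 SNPs")
    flip = np.sign(beta_exp)
    flip[flip == 0] = 1.0
    bx, by = beta_exp * flip, beta_out * flip
    w = se_out**-2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    coef = np.linalg.solve(X.T @ WX, WX.T @ by)
    resid = by - X @ coef
    dof = len(bx) - 2
    sigma2 = float(resid @ (w * resid)) / dof
    cov = sigma2 * np.linalg.inv(X.T @ WX)
    se_int = np.sqrt(cov[0, 0])
    t = coef[0] / se_int
    p_int = float(2 * stats.t.sf(abs(t), df=dof))
    return float(coef[1]), float(coef[0]), p_int


def cochran_q(ratios: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    """Heterogeneity across instruments: Q = sum w (b - b_IVW)^2,
    chi-square with J-1 df."""
    ratios = np.asarray(ratios, float)
    w = np.asarray(ses, float) ** -2
    if len(ratios) < 2:
        raise ValueError("Cochran's Q needs >= 2 ratios")
    b_ivw = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - b_ivw) ** 2))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def leave_one_out(ratios: np.ndarray, ses: np.ndarray, alpha: float = 0.05) -> tuple[pd.DataFrame, bool]:
    """Re-estimate IVW dropping each SNP in turn.

    ``loo_pass`` is False exactly when the single-driver signature shows:
    one and only one leave-one-out configuration loses significance while
    every other configuration keeps p < alpha.
    """
    ratios = np.asarray(ratios, float)
    ses = np.asarray(ses, float)
    j = len(ratios)
    if j < 3:
        raise ValueError("leave-one-out needs >= 3 ratios")
    rows = []
    for k in range(j):
        mask = np.ones(j, bool)
        mask[k] = False
        b, s, p = ivw_estimate(ratios[mask], ses[mask])
        rows.append({"dropped": k, "beta": b, "se": s, "p": p})
    loo = pd.DataFrame(rows)
    nonsig = int((loo["p"] >= alpha).sum())
    loo_pass = not (nonsig == 1 and (loo["p"] < alpha).sum() == j - 1)
    return loo, loo_pass


def mr_single_pair(
    instruments: InstrumentSet,
    outcome_gwas: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """All estimators and sensitivity statistics for one exposure-outcome
    pair given selected instruments and the outcome's per-SNP stats."""
    out = outcome_gwas.set_index("snp_id").loc[instruments.snp_ids]
    bx, sx = instruments.beta_exposure, instruments.se_exposure
    by, sy = out["beta"].to_numpy(), out["se"].to_numpy()
    ratios, rses = zip(*[wald_ratio(*args) for args in zip(bx, sx, by, sy)])
    ratios, rses = np.array(ratios), np.array(rses)
    beta_ivw, se_ivw, p_ivw = ivw_estimate(ratios, rses)
    beta_wm, se_wm, p_wm = weighted_median_estimate(ratios, rses, n_boot=n_boot, seed=seed)
    _, intercept, p_int = egger_regression(bx, by, sy)
    q, dfq, p_q = cochran_q(ratios, rses)
    loo, loo_pass = leave_one_out(ratios, rses)
    return {
        "n_snps": len(ratios),
        "beta_ivw": beta_ivw, "se_ivw": se_ivw, "p_ivw": p_ivw,
        "beta_wm": beta_wm, "se_wm": se_wm, "p_wm": p_wm,
        "egger_intercept": intercept, "egger_intercept_p": p_int,
        "cochran_q": q, "cochran_q_df": dfq, "cochran_q_p": p_q,
        "loo_pass": loo_pass,
        "wald_ratios": ratios, "wald_ses": rses,
    }


def apply_verdict_cascade(
    q_ivw: float,
    egger_intercept_p: float,
    cochran_q_p: float,
    loo_pass: bool,
    reverse_p: float | None,
    fdr_level: float = 0.05,
    alpha: float = 0.05,
) -> str:
    """Ordered filter cascade producing the MR verdict."""
    if q_ivw >= fdr_level:
        return "not_significant"
    if egger_intercept_p < alpha:
        return "filtered_pleiotropy"
    if cochran_q_p < alpha:
        return "filtered_heterogeneity"
    if not loo_pass:
        return "filtered_loo"
    if reverse_p is not None and reverse_p < alpha:
        return "filtered_reverse"
    return "causal_candidate"


def run_bidirectional_mr(
    pairs: list[tuple[str, str]],
    exposures: pd.DataFrame,
    outcomes: pd.DataFrame,
    dosages: OmicsLayer,
    followup_exposures: pd.DataFrame | None = None,
    followup_outcomes: pd.DataFrame | None = None,
    instrument_p: float = 1e-5,
    reverse_followup_p: float = 0.1,
    min_instruments: int = 3,
    clump_r2: float = 0.05,
    clump_window_bp: int = 500_000,
    fdr_level: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bi-directional MR over pre-filtered exposure-outcome pairs.

    Forward: exposure instruments (p < 1e-5, clumped, optional follow-up
    replication at p < 0.05) against the outcome.  Reverse: outcome
    instruments (same baseline cut, follow-up replication at the looser
    p < 0.1) against the exposure.  BH correction over forward IVW
    p-values; the verdict cascade closes with the reverse-direction check.
    Pairs lacking valid instruments in a direction are recorded as
    untestable for that direction.
    """
    rng = np.random.default_rng(seed % (2**31))
    cache: dict[tuple[str, str], pd.DataFrame] = {}

    def gwas_of(name: str, frame: pd.DataFrame, tag: str) -> pd.DataFrame:
        key = (tag, name)
        if key not in cache:
            cache[key] = summary_associations(frame[name], dosages)
        return cache[key]

    rows = []
    for exp_id, out_id in pairs:
        rec: dict = {"exposure_id": exp_id, "outcome_id": out_id}
        fwd_gwas = gwas_of(exp_id, exposures, "exp")
        fu = None
        if followup_exposures is not None and exp_id in followup_exposures.columns:
            fu = gwas_of(exp_id, followup_exposures, "exp_fu")
        inst = select_instruments(
            fwd_gwas, dosages, exposure_id=exp_id, followup_gwas=fu,
            p_cut=instrument_p, followup_p=0.05, min_snps=min_instruments,
            clump_r2=clump_r2, clump_window_bp=clump_window_bp,
        )
        if isinstance(inst, str):
            rec.update({"forward_testable": False, "forward_reason": inst})
            rows.append(rec)
            continue
        out_gwas = gwas_of(out_id, outcomes, "out")
        fwd = mr_single_pair(inst, out_gwas, n_boot=n_boot, seed=rng)
        rec.update({"forward_testable": True, "forward_reason": ""})
        rec.update({k: v for k, v in fwd.items() if k not in ("wald_ratios", "wald_ses")})

        # reverse direction: outcome's instruments against the exposure
        rev_gwas = gwas_of(out_id, outcomes, "out")
        rev_fu = None
        if followup_outcomes is not None and out_id in followup_outcomes.columns:
            rev_fu = gwas_of(out_id, followup_outcomes, "out_fu")
        rev_inst = select_instruments(
            rev_gwas, dosages, exposure_id=out_id, followup_gwas=rev_fu,
            p_cut=instrument_p, followup_p=reverse_followup_p, min_snps=min_instruments,
            clump_r2=clump_r2, clump_window_bp=clump_window_bp,
        )
        if isinstance(rev_inst, str):
            rec.update({"reverse_testable": False, "reverse_reason": rev_inst, "reverse_p": np.nan})
        else:
            exp_as_out = gwas_of(exp_id, exposures, "exp")
            rev = mr_single_pair(rev_inst, exp_as_out, n_boot=n_boot, seed=rng)
            rec.update({
                "reverse_testable": True, "reverse_reason": "",
                "reverse_beta": rev["beta_ivw"], "reverse_p": rev["p_ivw"],
            })
        rows.append(rec)

    recs = pd.DataFrame(rows)
    testable = recs.get("forward_testable", pd.Series(dtype=bool)) == True  # noqa: E712
    recs["q_ivw"] = np.nan
    if testable.any():
        recs.loc[testable, "q_ivw"] = benjamini_hochberg(recs.loc[testable, "p_ivw"].to_numpy())
    verdicts = []
    for _, r in recs.iterrows():
        if not r.get("forward_testable", False):
            verdicts.append("untestable")
            continue
        rev_p = r["reverse_p"] if r.get("reverse_testable", False) else None
        verdicts.append(
            apply_verdict_cascade(
                r["q_ivw"], r["egger_intercept_p"], r["cochran_q_p"],
                bool(r["loo_pass"]), rev_p, fdr_level=fdr_level,
            )
        )
    recs["verdict"] = verdicts
    return recs
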