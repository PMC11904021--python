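"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

All diagnostics operate on a harmonized exposure–outcome set. Internally the
classical fixed-effect IVW is used for Cochran's Q and the MR-PRESSO
residuals (their textbook definitions), regardless of which IVW model the
reporting layer uses.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MRResult, MREgger, _ivw_fixed, ivw
from .instruments import HarmonizedSet

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityReport", "PressoResult", "cochran_q", "egger_intercept_test",
    "mr_presso", "leave_one_out", "funnel_scatter_data", "sensitivity_report",
]

_TINY_P = np.finfo(float).tiny


def cochran_q(data: HarmonizedSet | pd.DataFrame) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic across the per-SNP Wald ratios.

    Q = Σ w_j (β̂_j − β_IVW)² with β̂_j = β_Y,j/β_X,j, first-order weights
    w_j = β_X,j²/se_Y,j², and β_IVW the fixed-effect estimate; the p-value is
    the χ²(n−1) upper tail. Returns ``(q_stat, q_df, q_pval)``.
    """
    bx, sx, by, sy = _arrays(data)
    n = len(bx)
    if n < 2:
        raise ValueError("cochran_q needs at least 2 SNPs")
    beta, _ = _ivw_fixed(bx, by, sy)
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = n - 1
    p = float(np.clip(stats.chi2.sf(q, df), _TINY_P, 1.0))
    return q, df, p


def _arrays(data):
    if isinstance(data, HarmonizedSet):
        return data.arrays()
    t = pd.DataFrame(data)
    return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))


@dataclasses.dataclass
class EggerInterceptTest:
    intercept: float
    se: float
    pval: float
    alpha: float
    pleiotropy_detected: bool


def egger_intercept_test(data, alpha: float = 0.05) -> EggerInterceptTest:
    """Directional-pleiotropy test from the MR-Egger intercept.

    The intercept estimates the average direct (pleiotropic) variant→outcome
    effect; a value significantly different from zero at ``alpha`` flags
    directional pleiotropy.
    """
    est = MREgger().fit(data)
    return EggerInterceptTest(
        intercept=est.intercept_, se=est.intercept_se_, pval=est.intercept_pval_,
        alpha=alpha, pleiotropy_detected=est.intercept_pval_ < alpha,
    )


@dataclasses.dataclass
class PressoResult:
    global_pval: float
    global_rss: float
    outliers: list[str]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    corrected: MRResult | None
    n_sim: int
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope excluding each SNP in turn (vectorized)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    data,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    snp_ids: Sequence[str] | None = None,
) -> PressoResult:
    """MR-PRESSO global pleiotropy, per-SNP outlier and distortion tests.

    The observed residual sum of squares
    RSS = Σ_j (β_Y,j − β̂_IVW(−j)·β_X,j)², with β̂_IVW(−j) the fixed-effect
    IVW slope excluding SNP j, is compared with its distribution under the
    no-pleiotropy null: ``n_sim`` parametric replicates redraw
    β*_X,j ~ N(β_X,j, se_X,j) and β*_Y,j ~ N(β̂_IVW(−j)·β_X,j, se_Y,j) and
    recompute the RSS. P-values use the add-one estimator
    (1 + #{RSS* ≥ RSS})/(n_sim + 1), so they are never exactly zero and have
    resolution 1/(n_sim+1).

    Per-SNP outliers: each observed squared residual against its simulated
    distribution, Bonferroni-adjusted by n_snp, flagged below
    ``outlier_alpha``. When outliers exist, ``corrected`` is the IVW without
    them and ``distortion_pval`` compares the observed shift in the estimate
    against removals of random same-size subsets.
    """
    bx, sx, by, sy = _arrays(data)
    n = len(bx)
    if n < 4:
        raise ValueError("mr_presso needs at least 4 SNPs")
    if snp_ids is None:
        if isinstance(data, HarmonizedSet):
            snp_ids = data.table["snp_id"].tolist()
        else:
            snp_ids = [str(i) for i in range(n)]
    snp_ids = list(snp_ids)

    w = 1.0 / sy**2
    slopes = _loo_slopes(bx, by, w)
    resid_obs = by - slopes * bx
    rss_obs = float(np.sum(resid_obs**2))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(slopes * bx, sy, size=(n_sim, n))
    w_row = np.broadcast_to(w, (n_sim, n))
    sxy = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w_row * bx_sim * bx_sim, axis=1, keepdims=True)
    slopes_sim = (sxy - w_row * bx_sim * by_sim) / (sxx - w_row * bx_sim * bx_sim)
    resid_sim = by_sim - slopes_sim * bx_sim
    rss_sim = np.sum(resid_sim**2, axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp = (1 + np.sum(resid_sim**2 >= resid_obs[None, :] ** 2, axis=0)) / (n_sim + 1)
    adj = np.minimum(per_snp * n, 1.0)
    outlier_mask = adj < outlier_alpha
    outliers = [snp_ids[i] for i in np.nonzero(outlier_mask)[0]]
    outlier_pvals = {snp_ids[i]: float(adj[i]) for i in range(n)}

    corrected = None
    distortion_pval = None
    if outliers:
        keep = ~outlier_mask
        if keep.sum() >= 2:
            table = pd.DataFrame({"beta_exp": bx[keep], "se_exp": sx[keep],
                                  "beta_out": by[keep], "se_out": sy[keep]})
            corrected = ivw(table)
            beta_all, _ = _ivw_fixed(bx, by, sy)
            beta_corr, _ = _ivw_fixed(bx[keep], by[keep], sy[keep])
            d_obs = (beta_corr - beta_all) / abs(beta_all) if beta_all != 0 else np.inf
            k = int(outlier_mask.sum())
            d_null = np.empty(n_sim)
            for i in range(n_sim):
                drop = rng.choice(n, size=k, replace=False)
                m = np.ones(n, dtype=bool)
                m[drop] = False
                b_i, _ = _ivw_fixed(bx[m], by[m], sy[m])
                d_null[i] = (b_i - beta_all) / abs(beta_all) if beta_all != 0 else np.inf
            distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))
    return PressoResult(global_pval, rss_obs, outliers, outlier_pvals,
                        distortion_pval, corrected, n_sim, seed)


def leave_one_out(data, model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated with each SNP removed in turn, in input order.

    Columns: snp_id, beta_without, se_without, pval_without. Large swings at
    a single row indicate that variant drives the pooled estimate.
    """
    bx, sx, by, sy = _arrays(data)
    n = len(bx)
    if n < 2:
        raise ValueError("leave_one_out needs at least 2 SNPs")
    snp_ids = (data.table["snp_id"].tolist() if isinstance(data, HarmonizedSet)
               else [str(i) for i in range(n)])
    rows = []
    for j in range(n):
        m = np.ones(n, dtype=bool)
        m[j] = False
        sub = pd.DataFrame({"beta_exp": bx[m], "se_exp": sx[m],
                            "beta_out": by[m], "se_out": sy[m]})
        r = ivw(sub, model=model)
        rows.append((snp_ids[j], r.beta, r.se, r.pval))
    return pd.DataFrame(rows, columns=["snp_id", "beta_without", "se_without", "pval_without"])


def funnel_scatter_data(data, results: Sequence[MRResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables behind the scatter and funnel diagnostics.

    Scatter: per-SNP (β_X, β_Y) with SE bars plus one fitted line per method.
    Funnel: per-SNP Wald ratio against its precision 1/se; asymmetry about
    the pooled estimate suggests directional pleiotropy.
    """
    bx, sx, by, sy = _arrays(data)
    snp_ids = (data.table["snp_id"].tolist() if isinstance(data, HarmonizedSet)
               else [str(i) for i in range(len(bx))])
    scatter = pd.DataFrame({
        "snp_id": snp_ids, "beta_exp": bx, "se_exp": sx,
        "beta_out": by, "se_out": sy,
    })
    for r in results:
        scatter[f"fit_{r.method}"] = r.beta * bx
    ratio = by / bx
    ratio_se = sy / np.abs(bx)
    funnel = pd.DataFrame({
        "snp_id": snp_ids, "ratio": ratio, "precision": 1.0 / ratio_se,
    })
    return scatter, funnel


@dataclasses.dataclass
class SensitivityReport:
    """Bundle of diagnostics for one exposure–outcome pair."""

    q_stat: float | None
    q_df: int | None
    q_pval: float | None
    egger_intercept: float | None
    intercept_se: float | None
    intercept_pval: float | None
    presso_global_pval: float | None
    presso_outliers: list[str]
    presso_distortion_pval: float | None
    loo: pd.DataFrame | None
    funnel: pd.DataFrame | None
    n_sim: int
    seed: int
    skipped: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loo"] = None if self.loo is None else self.loo.to_dict("records")
        d["funnel"] = None if self.funnel is None else self.funnel.to_dict("records")
        return d


def sensitivity_report(
    data,
    results: Sequence[MRResult] | None = None,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run every diagnostic whose precondition the data meet.

    Q needs ≥ 2 SNPs, the Egger intercept ≥ 3, MR-PRESSO ≥ 4; diagnostics
    that cannot run are recorded under ``skipped`` rather than failing, as a
    sparse instrument set is an expected state of a panel screen.
    """
    bx, *_ = _arrays(data)
    n = len(bx)
    skipped: list[str] = []
    q = dfq = qp = None
    if n >= 2:
        q, dfq, qp = cochran_q(data)
    else:
        skipped.append("cochran_q")
    ei = ei_se = ei_p = None
    if n >= 3:
        t = egger_intercept_test(data, alpha=alpha)
        ei, ei_se, ei_p = t.intercept, t.se, t.pval
    else:
        skipped.append("egger_intercept")
    gp = dp = None
    outliers: list[str] = []
    if n >= 4:
        pr = mr_presso(data, n_sim=n_sim, seed=seed, outlier_alpha=alpha)
        gp, outliers, dp = pr.global_pval, pr.outliers, pr.distortion_pval
    else:
        skipped.append("mr_presso")
        logger.info("sensitivity: MR-PRESSO skipped (n_snp=%d < 4)", n)
    loo = leave_one_out(data) if n >= 2 else None
    if loo is None:
        skipped.append("leave_one_out")
    funnel = None
    if results is not None and n >= 1:
        _, funnel = funnel_scatter_data(data, results)
    return SensitivityReport(
        q_stat=q, q_df=dfq, q_pval=qp,
        egger_intercept=ei, intercept_se=ei_se, intercept_pval=ei_p,
        presso_global_pval=gp, presso_outliers=outliers,
        presso_distortion_pval=dp, loo=loo, funnel=funnel,
        n_sim=n_sim, seed=seed, skipped=skipped,
    )
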