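"""Causal-effect estimators for two-sample Mendelian randomization.

Each estimator is a scikit-learn-style class: construct with hyperparameters,
``fit`` on a :class:`~mrmediate.instruments.HarmonizedSet` (or an equivalent
DataFrame with columns ``beta_exp, se_exp, beta_out, se_out``), then read the
fitted attributes ``beta_``, ``se_``, ``pval_``, ``or_``, ``ci_low_``,
``ci_high_`` or the bundled ``result_``. ``predict`` maps exposure effects to
fitted outcome effects. Module-level functions (``ivw``, ``mr_egger``, ...)
are thin wrappers returning :class:`MRResult` records.

Methods
-------
Wald ratio
    Single-instrument estimate β_Y/β_X with first-order SE se_Y/|β_X|.
IVW
    Inverse-variance weighted pooling of Wald ratios, equivalently weighted
    least squares of β_Y on β_X through the origin with weights se_Y⁻²; the
    default multiplicative random-effects model scales the SE by
    max(1, sqrt(Q/(n−1))).
MR-Egger
    The same regression with an unconstrained intercept after orienting all
    rows to β_X ≥ 0; the intercept estimates the average directional
    pleiotropic effect and the slope remains consistent under the InSIDE
    assumption. Slope and intercept p-values use t(n−2).
Weighted median
    Consistent when ≥ 50% of the weight comes from valid instruments;
    interpolated weighted median of the ratio estimates, SE from a seeded
    parametric bootstrap.
Simple / weighted mode
    Mode of the kernel-smoothed ratio density (ZEMPA: the largest group of
    instruments with equal ratios identifies the causal effect); bandwidth
    φ·0.9·min(SD, MAD/0.6745)·n^{−1/5}, SE from a seeded parametric bootstrap.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .instruments import HarmonizedSet

logger = logging.getLogger(__name__)

__all__ = [
    "MRResult", "EstimationError", "WaldRatio", "IVW", "MREgger",
    "WeightedMedian", "ModeEstimator", "wald_ratio", "ivw", "mr_egger",
    "weighted_median", "mode_estimate", "run_all",
]

_TINY_P = np.finfo(float).tiny
_Z95 = stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclasses.dataclass(frozen=True)
class MRResult:
    """One estimator's causal estimate on the log-odds (or outcome) scale."""

    method: str
    n_snp: int
    beta: float
    se: float
    pval: float

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - _Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + _Z95 * self.se)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "n_snp": self.n_snp, "beta": self.beta,
            "se": self.se, "or": self.or_, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pval": self.pval,
        }


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, HarmonizedSet):
        return data.arrays()
    t = pd.DataFrame(data)
    return (t["beta_exp"].to_numpy(float), t["se_exp"].to_numpy(float),
            t["beta_out"].to_numpy(float), t["se_out"].to_numpy(float))


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return _TINY_P if beta != 0 else 1.0
    return float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), _TINY_P, 1.0))


def _ivw_fixed(bx, by, sy) -> tuple[float, float]:
    """Closed-form origin WLS slope and fixed-effect SE."""
    w = 1.0 / sy**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    return float(beta), float(1.0 / np.sqrt(sxx))


def _cochran_q(bx, by, sy, beta: float) -> float:
    w = 1.0 / sy**2
    return float(np.sum(w * (by - beta * bx) ** 2))


class _BaseMR(BaseEstimator):
    """Shared fit plumbing for the MR estimators."""

    method: str = "base"
    _min_snp: int = 1

    def fit(self, data, y=None):
        bx, sx, by, sy = _as_arrays(data)
        n = len(bx)
        if n < self._min_snp:
            raise EstimationError(
                f"{self.method} needs at least {self._min_snp} SNPs, got {n}")
        self.n_snp_ = n
        self._fit(bx, sx, by, sy)
        self.or_ = math.exp(self.beta_)
        self.ci_low_ = math.exp(self.beta_ - _Z95 * self.se_)
        self.ci_high_ = math.exp(self.beta_ + _Z95 * self.se_)
        self.result_ = MRResult(self.method, self.n_snp_, self.beta_, self.se_, self.pval_)
        return self

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, beta_exp) -> np.ndarray:
        """Fitted outcome effect for given exposure effects."""
        if not hasattr(self, "beta_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        x = np.asarray(beta_exp, dtype=float)
        return getattr(self, "intercept_", 0.0) + self.beta_ * x


class WaldRatio(_BaseMR):
    """Single-instrument causal estimate β_Y/β_X with first-order SE."""

    method = "wald_ratio"
    _min_snp = 1

    def _fit(self, bx, sx, by, sy):
        if len(bx) != 1:
            raise EstimationError("wald_ratio takes exactly one SNP")
        if bx[0] == 0:
            raise EstimationError("wald_ratio undefined for beta_exp = 0")
        self.beta_ = float(by[0] / bx[0])
        self.se_ = float(sy[0] / abs(bx[0]))
        self.pval_ = _norm_p(self.beta_, self.se_)


class IVW(_BaseMR):
    """Inverse-variance weighted estimator (the study's primary method).

    Parameters
    ----------
    model:
        ``"multiplicative_random"`` (default) scales the fixed-effect SE by
        max(1, sqrt(Q/(n−1))); ``"fixed"`` uses the fixed-effect SE. A single
        SNP reduces to the Wald ratio.
    """

    method = "ivw"
    _min_snp = 1

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def _fit(self, bx, sx, by, sy):
        if self.model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown IVW model {self.model!r}")
        if len(bx) == 1:
            w = WaldRatio().fit(pd.DataFrame(
                {"beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy}))
            self.beta_, self.se_, self.pval_ = w.beta_, w.se_, w.pval_
            self.q_stat_, self.sigma_ = 0.0, 1.0
            return
        beta, se_fixed = _ivw_fixed(bx, by, sy)
        q = _cochran_q(bx, by, sy, beta)
        sigma = math.sqrt(q / (len(bx) - 1))
        self.q_stat_ = q
        self.sigma_ = sigma
        se = se_fixed * max(1.0, sigma) if self.model == "multiplicative_random" else se_fixed
        self.beta_, self.se_ = beta, se
        self.pval_ = _norm_p(beta, se)


class MREgger(_BaseMR):
    """MR-Egger regression: weighted fit of β_Y on β_X with a free intercept.

    Rows are oriented so every β_X ≥ 0 (flipping both betas), which the
    estimator needs for identifiability. Fitted attributes add
    ``intercept_``, ``intercept_se_``, ``intercept_pval_``. Standard errors
    follow the multiplicative random-effects convention with the residual
    dispersion floored at 1; p-values use t(n−2).
    """

    method = "egger"
    _min_snp = 3

    def _fit(self, bx, sx, by, sy):
        flip = np.sign(bx)
        flip[flip == 0] = 1.0
        x, yv = bx * flip, by * flip
        wls = sm.WLS(yv, sm.add_constant(x), weights=1.0 / sy**2).fit()
        sigma = math.sqrt(wls.scale)
        infl = 1.0 / min(1.0, sigma)  # floor dispersion at 1
        df = len(x) - 2
        a, b = wls.params
        a_se, b_se = wls.bse * infl
        self.beta_, self.se_ = float(b), float(b_se)
        self.pval_ = float(np.clip(2.0 * stats.t.sf(abs(b / b_se), df), _TINY_P, 1.0))
        self.intercept_ = float(a)
        self.intercept_se_ = float(a_se)
        self.intercept_pval_ = float(np.clip(2.0 * stats.t.sf(abs(a / a_se), df), _TINY_P, 1.0))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the value where the centred cumulative
    weight crosses one half."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    if cum[0] >= 0.5:
        return float(v[0])
    below = np.max(np.nonzero(cum < 0.5)[0])
    if below == len(v) - 1:
        return float(v[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(v[below] + (v[below + 1] - v[below]) * frac)


class WeightedMedian(_BaseMR):
    """Weighted median of the per-SNP Wald ratios.

    Consistent if instruments carrying at least half the weight are valid.
    Weights are normalized inverse variances of the first-order ratio
    estimates; the SE comes from a seeded parametric bootstrap that redraws
    both exposure and outcome effects from their standard errors.
    """

    method = "weighted_median"
    _min_snp = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, bx, sx, by, sy):
        ratios = by / bx
        w = bx**2 / sy**2          # 1 / first-order ratio variance
        w = w / np.sum(w)
        self.beta_ = _weighted_median(ratios, w)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            bx_s = rng.normal(bx, sx)
            by_s = rng.normal(by, sy)
            r = by_s / bx_s
            ws = bx_s**2 / sy**2
            boots[i] = _weighted_median(r, ws / np.sum(ws))
        self.se_ = float(np.std(boots, ddof=1))
        self.boot_estimates_ = boots
        self.pval_ = _norm_p(self.beta_, self.se_)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of a Gaussian-kernel density over the ratio range.

    Bandwidth φ·0.9·min(SD, MAD/0.6745)·n^{−1/5}; evaluated on a 512-point
    grid extended three bandwidths past the range. Zero spread returns the
    common ratio.
    """
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    s = 0.9 * min(sd, mad if mad > 0 else np.inf) * n ** (-1 / 5)
    h = phi * s
    if not h > 0:
        # degenerate spread: fall back to the weight-heaviest ratio
        return float(ratios[np.argmax(weights)]) if sd == 0 else float(np.median(ratios))
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


class ModeEstimator(_BaseMR):
    """Simple or weighted mode-based estimator over the Wald ratios.

    The causal effect is taken as the mode of the smoothed ratio density:
    valid instruments cluster at the true value while invalid ones scatter.
    ``weighted=True`` weights each ratio by its inverse first-order variance;
    ``bandwidth_phi`` scales the default bandwidth rule.
    """

    method = "simple_mode"
    _min_snp = 3

    def __init__(self, weighted: bool = False, bandwidth_phi: float = 1.0,
                 n_boot: int = 1000, seed: int = 0):
        self.weighted = weighted
        self.bandwidth_phi = bandwidth_phi
        self.n_boot = n_boot
        self.seed = seed

    def _weights(self, bx, sy):
        if self.weighted:
            w = bx**2 / sy**2
        else:
            w = np.ones_like(bx)
        return w / np.sum(w)

    def _fit(self, bx, sx, by, sy):
        self.method = "weighted_mode" if self.weighted else "simple_mode"
        ratios = by / bx
        if np.ptp(ratios) == 0.0:
            self.beta_ = float(ratios[0])
        else:
            self.beta_ = _kde_mode(ratios, self._weights(bx, sy), self.bandwidth_phi)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            bx_s = rng.normal(bx, sx)
            by_s = rng.normal(by, sy)
            r = by_s / bx_s
            boots[i] = _kde_mode(r, self._weights(bx_s, sy), self.bandwidth_phi)
        self.se_ = float(np.std(boots, ddof=1))
        self.boot_estimates_ = boots
        self.pval_ = _norm_p(self.beta_, self.se_)


# ---------------------------------------------------------------------------
# functional wrappers

def wald_ratio(row) -> MRResult:
    """Wald-ratio estimate from a single harmonized record (mapping or row)."""
    df = pd.DataFrame([{k: row[k] for k in ("beta_exp", "se_exp", "beta_out", "se_out")}])
    return WaldRatio().fit(df).result_


def ivw(data, model: str = "multiplicative_random") -> MRResult:
    return IVW(model=model).fit(data).result_


def mr_egger(data) -> tuple[MRResult, dict]:
    """MR-Egger slope plus an intercept record
    ``{estimate, se, pval}`` (the average pleiotropic effect)."""
    est = MREgger().fit(data)
    intercept = {"estimate": est.intercept_, "se": est.intercept_se_,
                 "pval": est.intercept_pval_}
    return est.result_, intercept


def weighted_median(data, n_boot: int = 1000, seed: int = 0) -> MRResult:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(data).result_


def mode_estimate(data, weighted: bool = False, bandwidth_phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult:
    return ModeEstimator(weighted=weighted, bandwidth_phi=bandwidth_phi,
                         n_boot=n_boot, seed=seed).fit(data).result_


def run_all(data, ivw_model: str = "multiplicative_random",
            n_boot: int = 1000, seed: int = 0) -> list[MRResult]:
    """Run every estimator whose preconditions the data meet.

    IVW always runs (delegating to the Wald ratio for one SNP); Egger,
    weighted median and the two modes need ≥ 3 SNPs — omissions are logged,
    mirroring how sparse instrument sets are reported rather than failing.
    """
    results = [ivw(data, model=ivw_model)]
    n = results[0].n_snp
    others = [
        ("egger", lambda: mr_egger(data)[0]),
        ("weighted_median", lambda: weighted_median(data, n_boot=n_boot, seed=seed)),
        ("simple_mode", lambda: mode_estimate(data, weighted=False, n_boot=n_boot, seed=seed)),
        ("weighted_mode", lambda: mode_estimate(data, weighted=True, n_boot=n_boot, seed=seed)),
    ]
    for name, fn in others:
        if n < 3:
            logger.info("run_all: %s omitted (n_snp=%d < 3)", name, n)
            continue
        results.append(fn())
    return results


def results_table(results: Sequence[MRResult]) -> pd.DataFrame:
    """Results as a TSV-ready table (method, nsnp, b, se, or, ci, p)."""
    return pd.DataFrame([r.to_dict() for r in results])
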