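"""Causal-effect estimators on harmonized summary statistics.

Per-SNP Wald ratios are combined by inverse-variance weighting (fixed or
multiplicative random effects), MR-Egger weighted regression with a free
pleiotropy intercept, and the weighted median with a parametric-bootstrap
standard error.  Estimates carry both the beta (log-odds) scale and the
exponentiated odds-ratio scale, always labelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm, t as t_dist

from .harmonize import HarmonizedPair, HarmonizedSet

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "to_odds_ratio",
]

Z95 = 1.96

METHODS = ("ivw_fixed", "ivw_random", "egger_slope", "weighted_median")


@dataclass(frozen=True)
class RatioEstimate:
    """Single-SNP Wald ratio with its first-order delta-method SE."""

    snp_id: str
    ratio: float
    se_ratio: float

    @property
    def weight(self) -> float:
        return 1.0 / (self.se_ratio * self.se_ratio)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the beta (log-odds) scale plus the
    exponentiated odds-ratio scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    nsnp: int
    extra: dict = field(default_factory=dict)

    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.nsnp,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or_point": self.or_point,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "scale_note": "beta/ci on log-odds scale; or_* exponentiated",
            "extra": dict(self.extra),
        }


def _pairs(obj) -> tuple[HarmonizedPair, ...]:
    if isinstance(obj, HarmonizedSet):
        return obj.pairs
    return tuple(obj)


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_x for p in pairs], dtype=float)
    sx = np.array([p.se_x for p in pairs], dtype=float)
    by = np.array([p.beta_y for p in pairs], dtype=float)
    sy = np.array([p.se_y for p in pairs], dtype=float)
    return bx, sx, by, sy


def wald_ratio(pair: HarmonizedPair) -> RatioEstimate:
    """Outcome effect over exposure effect; SE by the first-order delta
    method (``se_y / |beta_x|``, exposure uncertainty ignored)."""
    if pair.beta_x == 0.0:
        raise ZeroDivisionError(f"{pair.snp_id}: beta_x is zero, Wald ratio undefined")
    return RatioEstimate(
        snp_id=pair.snp_id,
        ratio=pair.beta_y / pair.beta_x,
        se_ratio=pair.se_y / abs(pair.beta_x),
    )


def _normal_estimate(method: str, beta: float, se: float, nsnp: int,
                     extra: dict | None = None) -> MREstimate:
    z = beta / se if se > 0 else math.inf
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=p,
        nsnp=nsnp,
        extra=extra or {},
    )


def cochran_q_components(pairs: Sequence[HarmonizedPair]) -> tuple[float, float]:
    """(fixed-effects IVW beta, Cochran's Q) for a set of pairs."""
    ratios = [wald_ratio(p) for p in pairs]
    w = np.array([r.weight for r in ratios])
    x = np.array([r.ratio for r in ratios])
    beta = float(np.sum(w * x) / np.sum(w))
    q = float(np.sum(w * (x - beta) ** 2))
    return beta, q


def ivw(set_or_pairs, model: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    ``model="random"`` applies multiplicative random effects: the fixed
    SE is inflated by ``sqrt(max(1, Q/(k-1)))``.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    pairs = _pairs(set_or_pairs)
    k = len(pairs)
    if k == 0:
        raise ValueError("ivw needs at least one instrument")
    ratios = [wald_ratio(p) for p in pairs]
    w = np.array([r.weight for r in ratios])
    x = np.array([r.ratio for r in ratios])
    beta = float(np.sum(w * x) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (x - beta) ** 2))
    scale = 1.0
    if model == "random" and k > 1:
        scale = math.sqrt(max(1.0, q / (k - 1)))
    se = se_fixed * scale
    return _normal_estimate(
        f"ivw_{model}", beta, se, k,
        extra={"q": q, "se_fixed": se_fixed, "re_scale": scale},
    )


def egger(set_or_pairs, ci: str = "normal") -> MREstimate:
    """MR-Egger: weighted least squares of the outcome effect on the
    exposure effect with a free intercept (the directional-pleiotropy
    term), weights ``1/se_y**2``.

    Pairs are first oriented so every ``beta_x >= 0``.  Standard errors
    are inflated by the residual scale factor ``max(1, sqrt(RSS/(k-2)))``
    (multiplicative random effects).  ``ci="t"`` switches the CI and
    p-values to the t distribution with k-2 degrees of freedom.
    """
    pairs = _pairs(set_or_pairs)
    k = len(pairs)
    if k < 3:
        raise ValueError(f"egger needs >= 3 instruments, got {k}")
    bx, sx, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    try:
        coef = np.linalg.solve(xtwx, WX.T @ by)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "egger regression is unidentified: exposure effects are "
            "constant after orientation"
        ) from exc
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss / (k - 2))
    cov = np.linalg.inv(xtwx) * sigma2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))

    if ci == "t":
        df = k - 2
        crit = float(t_dist.ppf(0.975, df))
        p_slope = float(2.0 * t_dist.sf(abs(slope / se_slope), df))
        p_int = float(2.0 * t_dist.sf(abs(intercept / se_int), df))
        return MREstimate(
            method="egger_slope",
            beta=slope, se=se_slope,
            ci_low=slope - crit * se_slope, ci_high=slope + crit * se_slope,
            pvalue=p_slope, nsnp=k,
            extra={"intercept": intercept, "intercept_se": se_int,
                   "intercept_pvalue": p_int, "rss": rss, "ci": "t"},
        )
    p_int = float(min(1.0, 2.0 * norm.sf(abs(intercept / se_int))))
    return _normal_estimate(
        "egger_slope", slope, se_slope, k,
        extra={"intercept": intercept, "intercept_se": se_int,
               "intercept_pvalue": p_int, "rss": rss, "ci": "normal"},
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by cumulative-weight interpolation.

    Sort ratios ascending; with weights normalized to sum 1, define the
    midpoint positions ``S_j = cumsum(w)_j - w_j/2`` and linearly
    interpolate the ratio at S = 0.5.  With equal weights and odd n this
    is the simple median.
    """
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    # tie-break equal ratios by weight so the result is order-invariant
    order = np.lexsort((weights, ratios))
    x = ratios[order]
    w = weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, x))


def weighted_median(set_or_pairs, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    Each bootstrap replicate redraws every SNP's exposure and outcome
    betas from their sampling distributions and recomputes the weighted
    median; the SE is the standard deviation across replicates.
    """
    pairs = _pairs(set_or_pairs)
    k = len(pairs)
    if k < 3:
        raise ValueError(f"weighted_median needs >= 3 instruments, got {k}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    bx, sx, by, sy = _arrays(pairs)
    ratios = by / bx
    weights = (bx / sy) ** 2
    point = weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx_b[i]
        bxi = np.where(bxi == 0.0, np.finfo(float).tiny, bxi)
        boots[i] = weighted_median_point(by_b[i] / bxi, (bxi / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate(
        "weighted_median", point, se, k,
        extra={"n_boot": n_boot, "seed": seed},
    )


def to_odds_ratio(estimate: MREstimate) -> dict:
    """Render an estimate on both scales, explicitly labelled."""
    d = estimate.as_dict()
    return {
        "method": d["method"],
        "log_odds": {"beta": d["beta"], "ci_low": d["ci_low"], "ci_high": d["ci_high"]},
        "odds_ratio": {
            "point": d["or_point"],
            "ci_low": d["or_ci_low"],
            "ci_high": d["or_ci_high"],
        },
        "pvalue": d["pvalue"],
        "nsnp": d["nsnp"],
    }
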