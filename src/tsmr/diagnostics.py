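"""Heterogeneity and pleiotropy sensitivity suite.

Cochran's Q over the per-SNP ratio estimates, the MR-Egger intercept test,
a simulation-based residual-sum-of-squares outlier framework with global /
outlier / distortion procedures, leave-one-out re-estimation, and the data
tables behind forest, funnel and scatter plots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .estimators import MREstimate, Z95, egger, ivw, wald_ratio
from .harmonize import HarmonizedPair, HarmonizedSet

__all__ = [
    "QTest",
    "PressoResult",
    "LooTable",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "funnel_and_forest_data",
]


def _pairs(obj) -> tuple[HarmonizedPair, ...]:
    if isinstance(obj, HarmonizedSet):
        return obj.pairs
    return tuple(obj)


@dataclass(frozen=True)
class QTest:
    q: float
    df: int
    pvalue: float


def cochran_q(set_or_pairs) -> QTest:
    """Cochran's Q of the Wald ratios about the fixed-effects IVW center."""
    pairs = _pairs(set_or_pairs)
    k = len(pairs)
    if k < 2:
        raise ValueError(f"cochran_q needs >= 2 instruments, got {k}")
    ratios = [wald_ratio(p) for p in pairs]
    w = np.array([r.weight for r in ratios])
    x = np.array([r.ratio for r in ratios])
    center = float(np.sum(w * x) / np.sum(w))
    q = float(np.sum(w * (x - center) ** 2))
    p = float(chi2.sf(q, k - 1))
    return QTest(q=q, df=k - 1, pvalue=max(p, np.finfo(float).tiny))


def egger_intercept_test(set_or_pairs) -> tuple[float, float, float]:
    """(intercept, se, two-sided p) from the MR-Egger regression."""
    est = egger(set_or_pairs)
    return (
        est.extra["intercept"],
        est.extra["intercept_se"],
        est.extra["intercept_pvalue"],
    )


@dataclass(frozen=True)
class PressoResult:
    """Global / outlier / distortion test output of the RSS framework."""

    rss_obs: float
    global_pvalue: float
    n_sim: int
    outlier_pvalues: dict[str, float]
    outlier_adjustment: str
    outliers: tuple[str, ...]
    distortion_pvalue: float | None
    beta_raw: float
    beta_corrected: float | None
    seed: int


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Origin-WLS slope of by on bx (weights w) excluding each index in turn."""
    num = np.sum(w * bx * by)
    den = np.sum(w * bx * bx)
    return (num - w * bx * by) / (den - w * bx * bx)


def mr_presso(
    set_or_pairs,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with three procedures.

    (a) *Global*: for each SNP j, predict its outcome effect from the
    leave-one-out inverse-variance fit; the observed weighted RSS is
    compared against ``n_sim`` parametric simulations that redraw all
    effects from their sampling distributions under the no-pleiotropy
    leave-one-out fits.  ``global_pvalue = (1 + #{RSS_sim >= RSS_obs}) /
    (n_sim + 1)``.

    (b) *Outlier*: a per-SNP simulation p-value for each weighted squared
    residual, Bonferroni-adjusted across instruments; SNPs with adjusted
    p < ``outlier_alpha`` are flagged.

    (c) *Distortion*: when outliers exist, the difference between the raw
    and outlier-corrected estimates is compared against the distribution
    obtained by removing equally many randomly chosen instruments.
    """
    pairs = _pairs(set_or_pairs)
    k = len(pairs)
    if k < 4:
        raise ValueError(f"mr_presso needs >= 4 instruments, got {k}")
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} is small; global p resolution is 1/{n_sim + 1}")

    bx = np.array([p.beta_x for p in pairs])
    sx = np.array([p.se_x for p in pairs])
    by = np.array([p.beta_y for p in pairs])
    sy = np.array([p.se_y for p in pairs])
    ids = [p.snp_id for p in pairs]
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, w)
    resid_obs = (by - slopes_loo * bx) ** 2 * w
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, k))

    num = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    den = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    slopes_sim = (num - w * bx_sim * by_sim) / (den - w * bx_sim**2)
    resid_sim = (by_sim - slopes_sim * bx_sim) ** 2 * w
    rss_sim = np.sum(resid_sim, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    per_snp_p = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, per_snp_p * k)  # Bonferroni
    flagged = [ids[j] for j in range(k) if adj[j] < outlier_alpha]

    beta_raw = float(np.sum(w * bx * by) / np.sum(w * bx**2))

    beta_corrected = None
    distortion_p = None
    if flagged:
        keep = np.array([s not in flagged for s in ids])
        if keep.sum() >= 2:
            beta_corrected = float(
                np.sum((w * bx * by)[keep]) / np.sum((w * bx**2)[keep])
            )
            d_obs = beta_raw - beta_corrected
            n_out = int((~keep).sum())
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(k, size=n_out, replace=False)
                mask = np.ones(k, dtype=bool)
                mask[drop] = False
                b_s = np.sum((w * bx * by)[mask]) / np.sum((w * bx**2)[mask])
                d_null[s] = beta_raw - b_s
            distortion_p = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
            )

    return PressoResult(
        rss_obs=rss_obs,
        global_pvalue=global_p,
        n_sim=n_sim,
        outlier_pvalues=dict(zip(ids, adj.tolist())),
        outlier_adjustment="bonferroni",
        outliers=tuple(flagged),
        distortion_pvalue=distortion_p,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        seed=seed,
    )


@dataclass(frozen=True)
class LooTable:
    """Leave-one-out IVW estimates; last row is the full set."""

    rows: tuple[dict, ...]
    sign_consistency: float

    def __len__(self) -> int:
        return len(self.rows)


def leave_one_out(set_or_pairs, model: str = "fixed") -> LooTable:
    """Re-run IVW excluding each SNP in turn; appends the full-set row and
    summarises how many rows agree with the full-set CI-excludes-zero
    conclusion."""
    pairs = _pairs(set_or_pairs)
    k = len(pairs)
    if k < 2:
        raise ValueError(f"leave_one_out needs >= 2 instruments, got {k}")
    full = ivw(pairs, model=model)
    full_sig = full.ci_low > 0 or full.ci_high < 0

    rows: list[dict] = []
    agree = 0
    for i in range(k):
        est = ivw(pairs[:i] + pairs[i + 1:], model=model)
        sig = est.ci_low > 0 or est.ci_high < 0
        if sig == full_sig:
            agree += 1
        rows.append({
            "excluded": pairs[i].snp_id,
            "beta": est.beta,
            "se": est.se,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
        })
    rows.append({
        "excluded": None,
        "beta": full.beta,
        "se": full.se,
        "ci_low": full.ci_low,
        "ci_high": full.ci_high,
    })
    return LooTable(rows=tuple(rows), sign_consistency=agree / k)


def funnel_and_forest_data(
    set_or_pairs,
    methods: Sequence[MREstimate] = (),
) -> dict[str, list[dict]]:
    """Tables behind the forest, funnel and scatter plots.

    ``forest``: per-SNP ratio with 95% CI, then one summary row per
    supplied method estimate.  ``funnel``: ratio vs precision (1/se).
    ``scatter``: per-SNP (beta_x, beta_y) points plus one fitted-line row
    per method (slope; intercept nonzero only for Egger).
    """
    pairs = _pairs(set_or_pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    ratios = [wald_ratio(p) for p in pairs]

    forest = [
        {
            "label": r.snp_id,
            "kind": "snp",
            "beta": r.ratio,
            "ci_low": r.ratio - Z95 * r.se_ratio,
            "ci_high": r.ratio + Z95 * r.se_ratio,
        }
        for r in ratios
    ]
    for m in methods:
        forest.append({
            "label": m.method,
            "kind": "summary",
            "beta": m.beta,
            "ci_low": m.ci_low,
            "ci_high": m.ci_high,
        })

    funnel = [
        {"snp_id": r.snp_id, "ratio": r.ratio, "precision": 1.0 / r.se_ratio}
        for r in ratios
    ]

    scatter: list[dict] = [
        {
            "kind": "point",
            "snp_id": p.snp_id,
            "beta_x": p.beta_x,
            "se_x": p.se_x,
            "beta_y": p.beta_y,
            "se_y": p.se_y,
        }
        for p in pairs
    ]
    for m in methods:
        scatter.append({
            "kind": "line",
            "method": m.method,
            "slope": m.beta,
            "intercept": m.extra.get("intercept", 0.0),
        })
    return {"forest": forest, "funnel": funnel, "scatter": scatter}
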