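"""Causal-effect estimators and heterogeneity diagnostics for two-sample MR.

Implements the standard summary-data estimators:

* per-SNP Wald ratios  θ̂_j = β_Yj / β_Xj with first-order SE β_SEYj/|β_Xj|;
* inverse-variance-weighted (IVW) pooling, fixed-effect or multiplicative
  random-effect (MRE, SE scaled by √φ with φ = Q/(J−1));
* MR-Egger weighted regression with intercept (directional-pleiotropy test);
* the weighted-median estimator with a parametric-bootstrap SE;
* Cochran's Q and I² heterogeneity, leave-one-out and funnel diagnostics.

All estimates are on the outcome's β scale (log odds for a binary outcome);
`to_odds_scale` exponentiates onto the OR scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedDataset

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "Z_975",
    "wald_ratios",
    "ivw",
    "cochran_q",
    "heterogeneity_from_q",
    "egger",
    "weighted_median",
    "weighted_median_point",
    "leave_one_out",
    "funnel_data",
    "to_odds_scale",
    "pval_from_or_ci",
]

#: Full-precision 97.5% normal quantile used for all 95% CIs.
Z_975 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one MR method."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_value: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    phi: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity across per-SNP Wald ratios."""

    q: float
    df: int
    pval: float
    i2: float  # percentage in [0, 100]


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _zp(beta: float, se: float) -> float:
    if se == 0.0:
        return 0.0 if beta != 0.0 else 1.0
    return _two_sided_normal_p(beta / se)


def wald_ratios(
    data: HarmonizedDataset,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Per-SNP ratio estimates θ̂_j = β_Yj/β_Xj with SE_j = SE_Yj/|β_Xj|.

    Returns (theta, se, snp_ids, excluded_snp_ids); rows with β_Xj = 0 are
    excluded (the ratio is undefined) and reported in the final list.
    """
    bx, sx, by, sy, ids = data.arrays()
    ok = bx != 0.0
    theta = by[ok] / bx[ok]
    se = sy[ok] / np.abs(bx[ok])
    kept = [s for s, o in zip(ids, ok) if o]
    excluded = [s for s, o in zip(ids, ok) if not o]
    return theta, se, kept, excluded


def heterogeneity_from_q(q: float, df: int) -> HeterogeneityResult:
    """Upper-tail χ²(df) p and I² = max(0, (Q−df)/Q)·100 for a given Q."""
    pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q=float(q), df=int(df), pval=pval, i2=i2)


def cochran_q(
    theta_j: Sequence[float],
    se_j: Sequence[float],
    pooled: float,
) -> HeterogeneityResult:
    """Cochran's Q = Σ (θ̂_j − θ̂)²/se_j² with df = J−1 and I² transform."""
    theta_j = np.asarray(theta_j, dtype=float)
    se_j = np.asarray(se_j, dtype=float)
    if theta_j.size < 2:
        raise ValueError("Cochran's Q needs at least 2 ratio estimates")
    q = float(np.sum(((theta_j - pooled) / se_j) ** 2))
    return heterogeneity_from_q(q, theta_j.size - 1)


def ivw(
    data: HarmonizedDataset,
    mode: str = "mre",
    floor_phi: bool = False,
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate (through-origin WLS of β_Y on β_X).

    θ̂ = Σ w_j β_Xj β_Yj / Σ w_j β_Xj² with w_j = 1/SE_Yj².  ``mode="fixed"``
    uses the analytic SE₀ = (Σ w_j β_Xj²)^{−1/2}; ``mode="mre"``
    (multiplicative random effects) scales it by √φ with φ = Q/(J−1),
    unfloored unless ``floor_phi`` (then √max(1, φ)).  p-values are
    two-sided normal.
    """
    if mode not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW mode: {mode!r}")
    bx, sx, by, sy, ids = data.arrays()
    j = bx.size
    if j < 2:
        raise ValueError(
            "IVW needs at least 2 instruments; use wald_ratios for a single SNP"
        )
    w = 1.0 / sy**2
    theta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se0 = float(np.sum(w * bx**2) ** -0.5)
    ratios, ratio_se, _, _ = wald_ratios(data)
    het = cochran_q(ratios, ratio_se, theta)
    phi = het.q / het.df
    if mode == "mre":
        scale = max(1.0, phi) if floor_phi else phi
        se = se0 * math.sqrt(scale)
    else:
        se = se0
    est = MREstimate(
        method=f"ivw_{mode}",
        n_snp=j,
        beta=theta,
        se=se,
        ci_low=theta - Z_975 * se,
        ci_high=theta + Z_975 * se,
        pval=_zp(theta, se),
        phi=phi,
    )
    return est, het


def egger(data: HarmonizedDataset) -> MREstimate:
    """MR-Egger: weighted regression of β_Y on β_X with an intercept.

    Instruments are first oriented so every β_Xj ≥ 0 (the model is defined
    up to allele orientation).  Weights 1/SE_Yj²; the slope is the causal
    estimate and the intercept α̂ the average directional pleiotropy.  Both
    SEs carry the overdispersion factor √max(1, φ) with φ = weighted
    RSS/(J−2); p-values use t with J−2 df.
    """
    bx, sx, by, sy, ids = data.arrays()
    j = bx.size
    if j < 3:
        raise ValueError("MR-Egger needs at least 3 instruments (J−2 residual df)")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = rss_w / (j - 2)
    cov0 = np.linalg.inv(xtwx)
    scale = math.sqrt(max(1.0, phi))
    se_int, se_slope = scale * np.sqrt(np.diag(cov0))
    alpha, slope = coef
    tdist = stats.t(df=j - 2)
    p_slope = float(2 * tdist.sf(abs(slope / se_slope)))
    p_int = float(2 * tdist.sf(abs(alpha / se_int)))
    return MREstimate(
        method="egger",
        n_snp=j,
        beta=float(slope),
        se=float(se_slope),
        ci_low=float(slope - Z_975 * se_slope),
        ci_high=float(slope + Z_975 * se_slope),
        pval=p_slope,
        phi=phi,
        intercept=float(alpha),
        intercept_se=float(se_int),
        intercept_pval=p_int,
    )


def weighted_median_point(theta_j: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median of ratio estimates.

    Ratios are sorted ascending; with normalized weights w_j the cumulative
    rank S_j = Σ_{i≤j} w_i − w_j/2 and the estimate interpolates linearly to
    S = 1/2 between bracketing order statistics.
    """
    order = np.argsort(theta_j)
    t = np.asarray(theta_j, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, t))


def weighted_median(
    data: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> MREstimate:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Consistent when ≥50% of the weight comes from valid instruments.  The SE
    is the standard deviation of the estimate over ``n_boot`` replicates in
    which both β̂_X and β̂_Y are resampled from normal(observed, SE).
    """
    bx, sx, by, sy, ids = data.arrays()
    j = bx.size
    if j < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    theta_j = by / bx
    se_j = sy / np.abs(bx)
    est = weighted_median_point(theta_j, 1.0 / se_j**2)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, j))
    by_b = rng.normal(by, sy, size=(n_boot, j))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx_b[b]
        bxb = np.where(bxb == 0.0, np.finfo(float).tiny, bxb)
        t_b = by_b[b] / bxb
        w_b = (np.abs(bxb) / sy) ** 2
        boots[b] = weighted_median_point(t_b, w_b)
    se = float(np.std(boots, ddof=1))
    return MREstimate(
        method="weighted_median",
        n_snp=j,
        beta=est,
        se=se,
        ci_low=est - Z_975 * se,
        ci_high=est + Z_975 * se,
        pval=_zp(est, se),
    )


def leave_one_out(
    data: HarmonizedDataset,
    mode: str = "mre",
    floor_phi: bool = False,
) -> pd.DataFrame:
    """IVW estimate after deleting each SNP in turn, plus the full-set row.

    Returns a table with one row per omitted SNP (``snp`` column) and a final
    row labelled ``"all"``; columns beta/se/ci_low/ci_high/pval.
    """
    kept = data.retained
    if len(kept) < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    rows = []
    ids = [r.snp_id for r in kept]
    for omit in ids:
        sub = HarmonizedDataset([r for r in kept if r.snp_id != omit])
        est, _ = ivw(sub, mode=mode, floor_phi=floor_phi)
        rows.append((omit, est.beta, est.se, est.ci_low, est.ci_high, est.pval))
    full, _ = ivw(HarmonizedDataset(kept), mode=mode, floor_phi=floor_phi)
    rows.append(("all", full.beta, full.se, full.ci_low, full.ci_high, full.pval))
    return pd.DataFrame(rows, columns=["snp", "beta", "se", "ci_low", "ci_high", "pval"])


def funnel_data(data: HarmonizedDataset) -> pd.DataFrame:
    """Plot-ready funnel table: per-SNP Wald ratio vs precision 1/SE_j."""
    theta, se, ids, _ = wald_ratios(data)
    return pd.DataFrame({"snp": ids, "theta": theta, "precision": 1.0 / se})


def to_odds_scale(est: MREstimate) -> MREstimate:
    """Exponentiate a log-odds-scale estimate onto the odds-ratio scale."""
    return replace(
        est,
        or_value=math.exp(est.beta),
        or_ci_low=math.exp(est.ci_low),
        or_ci_high=math.exp(est.ci_high),
    )


def pval_from_or_ci(or_value: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p recomputed from an OR and its 95% CI.

    The SE is recovered as (ln CI_high − ln CI_low)/(2·z₀.₉₇₅); useful for
    checking reported results where only OR and CI are printed.
    """
    beta = math.log(or_value)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z_975)
    return _zp(beta, se)
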