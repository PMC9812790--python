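"""MR-PRESSO: residual-sum-and-outlier detection for pleiotropic instruments.

Compares the observed weighted residual sum of squares (RSS) of the IVW fit
— computed with a leave-one-out slope for each SNP so an outlier cannot mask
itself — against a parametric simulated null in which every outcome effect
is drawn from its no-pleiotropy expectation.  Three tests:

* global: empirical p for the total RSS;
* outlier: per-SNP empirical p for each residual contribution,
  Bonferroni-adjusted;
* distortion: percent change of the IVW estimate after removing flagged
  outliers, with an empirical p from random outlier-label re-assignments.

All draws are keyed to rows sorted by rsID, so shuffling the input rows
cannot change any result for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instruments import HarmonizedDataset
from .estimators import ivw

__all__ = [
    "PressoResult",
    "rss_observed",
    "global_test",
    "outlier_test",
    "distortion_test",
]

_MIN_J = 4


@dataclass
class PressoResult:
    """Output of the MR-PRESSO global (and optionally outlier) tests."""

    rss_obs: float
    global_pval: float
    n_sim: int
    seed: int
    snp_ids: list[str]
    contributions: np.ndarray  # observed per-SNP residual contributions
    sim_contributions: np.ndarray  # (n_sim, J), aligned to snp_ids
    per_snp_pvals: dict[str, float] = field(default_factory=dict)
    per_snp_pvals_adj: dict[str, float] = field(default_factory=dict)
    outliers: list[str] = field(default_factory=list)
    distortion_pct: float | None = None
    distortion_pval: float | None = None


def _sorted_arrays(data: HarmonizedDataset):
    bx, sx, by, sy, ids = data.arrays()
    order = np.argsort(np.asarray(ids, dtype=object))
    return (
        bx[order],
        sx[order],
        by[order],
        sy[order],
        [ids[i] for i in order],
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes θ̂_{−j}, vectorized over j via sum updates."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def _loo_slopes_sim(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """As `_loo_slopes` but batched: bx, by of shape (n_sim, J)."""
    sxy = np.sum(w * bx * by, axis=1, keepdims=True)
    sxx = np.sum(w * bx**2, axis=1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def rss_observed(data: HarmonizedDataset) -> tuple[float, np.ndarray, list[str]]:
    """Observed weighted RSS and per-SNP contributions (sorted-rsID order).

    contribution_j = (β_Yj − θ̂_{−j} β_Xj)² / SE_Yj² with θ̂_{−j} the IVW
    slope fitted without SNP j.
    """
    bx, sx, by, sy, ids = _sorted_arrays(data)
    if bx.size < _MIN_J:
        raise ValueError(
            f"MR-PRESSO needs at least {_MIN_J} instruments, got {bx.size}"
        )
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(bx, by, w)
    contributions = w * (by - theta_loo * bx) ** 2
    return float(contributions.sum()), contributions, ids


def global_test(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> PressoResult:
    """MR-PRESSO global test: empirical p of the observed RSS under the null.

    For each replicate, β*_Xj ~ N(β_Xj, SE_Xj) and β*_Yj ~ N(θ̂_{−j} β_Xj,
    SE_Yj); the RSS of the replicate is computed with the same leave-one-out
    scheme.  The empirical p uses the plus-one correction, so it is bounded
    below by 1/(n_sim+1) and never zero.
    """
    rss_obs, contributions, ids = rss_observed(data)
    bx, sx, by, sy, _ = _sorted_arrays(data)
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(bx, by, w)

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, bx.size))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, bx.size))
    theta_loo_sim = _loo_slopes_sim(bx_sim, by_sim, w)
    contrib_sim = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = contrib_sim.sum(axis=1)
    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=float(global_pval),
        n_sim=n_sim,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
        snp_ids=ids,
        contributions=contributions,
        sim_contributions=contrib_sim,
    )


def outlier_test(result: PressoResult, alpha: float = 0.05) -> PressoResult:
    """Per-SNP outlier test on a completed global test.

    Raw empirical p_j = (1 + #{contribution*_j ≥ contribution_j})/(n_sim+1);
    Bonferroni adjustment multiplies by J and caps at 1.  SNPs with adjusted
    p < ``alpha`` are flagged.  Mutates and returns ``result``.
    """
    j = len(result.snp_ids)
    exceed = (result.sim_contributions >= result.contributions).sum(axis=0)
    raw = (1.0 + exceed) / (result.n_sim + 1.0)
    adj = np.minimum(1.0, raw * j)
    result.per_snp_pvals = dict(zip(result.snp_ids, raw.astype(float)))
    result.per_snp_pvals_adj = dict(zip(result.snp_ids, adj.astype(float)))
    result.outliers = [s for s, p in result.per_snp_pvals_adj.items() if p < alpha]
    return result


def distortion_test(
    data: HarmonizedDataset,
    outliers: list[str],
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Distortion of the IVW estimate caused by the flagged outliers.

    distortion_pct = 100·(θ̂_without_outliers − θ̂_all)/|θ̂_all|.  The
    empirical p compares |distortion| against re-computations in which the
    same number of outlier labels is re-assigned to random SNPs.
    """
    if not outliers:
        raise ValueError("no outliers flagged; skip the distortion test")
    bx, sx, by, sy, ids = _sorted_arrays(data)
    outlier_set = set(outliers)
    theta_all, _ = ivw(data, mode="mre")
    keep = [i for i in ids if i not in outlier_set]
    theta_no, _ = ivw(data.subset(keep), mode="mre")
    distortion = 100.0 * (theta_no.beta - theta_all.beta) / abs(theta_all.beta)

    rng = np.random.default_rng(seed)
    j = len(ids)
    k = len(outlier_set & set(ids))
    w = 1.0 / sy**2
    sxy, sxx = np.sum(w * bx * by), np.sum(w * bx**2)
    sims = np.empty(n_boot)
    for b in range(n_boot):
        drop = rng.choice(j, size=k, replace=False)
        mask = np.ones(j, dtype=bool)
        mask[drop] = False
        theta_b = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
        sims[b] = 100.0 * (theta_b - sxy / sxx) / abs(sxy / sxx)
    pval = (1.0 + np.sum(np.abs(sims) >= abs(distortion))) / (n_boot + 1.0)
    return float(distortion), float(pval)
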