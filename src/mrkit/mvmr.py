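"""Multivariable Mendelian randomization (MVMR).

Jointly regresses outcome effects on several exposures' effects to estimate
each exposure's direct effect, conditioning on the others.  Instruments are
the union of the per-exposure selections, restricted to SNPs with complete
effect information in all exposure datasets and the outcome, harmonized to
the first exposure's effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np

from .summary_io import SummaryAssociation
from .instruments import PALINDROME_MAF, RETAINED_ACTIONS, _align_outcome
from .estimators import MREstimate, Z_975
from scipy import stats

__all__ = ["MVMRDataset", "assemble_mvmr", "mvmr_ivw"]


@dataclass
class MVMRDataset:
    """Complete-case instrument matrix for K exposures and one outcome.

    ``beta_x`` is (J, K): row j holds SNP j's effect on each exposure, all
    aligned to the first exposure's effect allele.
    """

    snp_ids: list[str]
    exposure_names: list[str]
    beta_x: np.ndarray  # (J, K)
    se_x: np.ndarray  # (J, K)
    beta_y: np.ndarray  # (J,)
    se_y: np.ndarray  # (J,)

    def __post_init__(self):
        if self.beta_x.ndim != 2 or self.beta_x.shape[1] < 1:
            raise ValueError("beta_x must be a (J, K) matrix")
        if self.beta_x.shape[0] != len(self.snp_ids):
            raise ValueError("beta_x row count does not match snp_ids")

    @property
    def j(self) -> int:
        return len(self.snp_ids)

    @property
    def k(self) -> int:
        return self.beta_x.shape[1]


def assemble_mvmr(
    instrument_sets: Sequence[Sequence[SummaryAssociation]],
    outcome: Sequence[SummaryAssociation],
    exposure_names: Sequence[str] | None = None,
    palindrome_maf: float = PALINDROME_MAF,
) -> MVMRDataset:
    """Build the MVMR design from per-exposure association tables.

    Each element of ``instrument_sets`` is one exposure dataset's
    associations covering that exposure's candidate instruments (the rows of
    its GWAS for the union of selected SNPs).  The union of SNPs is
    restricted to those present in every exposure table and the outcome
    (complete cases); effects are aligned pairwise to the first exposure's
    effect allele with the same rules as two-sample harmonization, and SNPs
    that fail alignment anywhere (including ambiguous palindromes) are
    dropped.
    """
    k = len(instrument_sets)
    if k < 2:
        raise ValueError("MVMR needs at least 2 exposures")
    names = list(exposure_names) if exposure_names else [f"exposure_{i+1}" for i in range(k)]
    by_id = [{r.snp_id: r for r in s} for s in instrument_sets]
    out_by_id = {r.snp_id: r for r in outcome}

    union: list[str] = []
    seen: set[str] = set()
    for s in instrument_sets:
        for r in s:
            if r.snp_id not in seen:
                union.append(r.snp_id)
                seen.add(r.snp_id)

    complete = [s for s in union if all(s in d for d in by_id) and s in out_by_id]
    if not complete:
        missing = {
            names[i]: sum(1 for s in union if s not in by_id[i]) for i in range(k)
        }
        missing["outcome"] = sum(1 for s in union if s not in out_by_id)
        raise ValueError(
            f"no SNP present in all datasets; per-dataset missing counts: {missing}"
        )

    ids: list[str] = []
    bx_rows, sx_rows, by_vals, sy_vals = [], [], [], []
    for snp in complete:
        ref = by_id[0][snp]
        row_b = [ref.beta]
        row_s = [ref.se]
        ok = True
        for d in by_id[1:]:
            other = d[snp]
            action, beta, _ = _align_outcome(
                ref,
                other.effect_allele,
                other.other_allele,
                other.beta,
                other.eaf,
                ref.eaf,
                palindrome_maf,
            )
            if action not in RETAINED_ACTIONS:
                ok = False
                break
            row_b.append(beta)
            row_s.append(other.se)
        if not ok:
            continue
        out = out_by_id[snp]
        action, beta_y, _ = _align_outcome(
            ref,
            out.effect_allele,
            out.other_allele,
            out.beta,
            out.eaf,
            ref.eaf,
            palindrome_maf,
        )
        if action not in RETAINED_ACTIONS:
            continue
        ids.append(snp)
        bx_rows.append(row_b)
        sx_rows.append(row_s)
        by_vals.append(beta_y)
        sy_vals.append(out.se)

    return MVMRDataset(
        snp_ids=ids,
        exposure_names=names,
        beta_x=np.array(bx_rows, dtype=float),
        se_x=np.array(sx_rows, dtype=float),
        beta_y=np.array(by_vals, dtype=float),
        se_y=np.array(sy_vals, dtype=float),
    )


def mvmr_ivw(data: MVMRDataset, floor_phi: bool = True) -> list[MREstimate]:
    """Multivariable IVW: WLS of β_Y on the K exposure-effect columns.

    No intercept; weights 1/SE_Yj².  Coefficient k is exposure k's direct
    effect.  SEs carry √max(1, φ) with φ = weighted RSS/(J−K) by default
    (``floor_phi=False`` uses √φ, pure multiplicative random effects);
    p-values are two-sided normal.
    """
    j, k = data.j, data.k
    if j <= k:
        raise ValueError(f"underdetermined MVMR: J={j} instruments for K={k} exposures")
    w = 1.0 / data.se_y**2
    X = data.beta_x
    xtwx = X.T @ (w[:, None] * X)
    # pinv tolerates degenerate designs (e.g. an all-zero exposure column,
    # which then gets coefficient and variance 0)
    xtwx_inv = np.linalg.pinv(xtwx)
    coef = xtwx_inv @ (X.T @ (w * data.beta_y))
    resid = data.beta_y - X @ coef
    phi = float(np.sum(w * resid**2)) / (j - k)
    scale = math.sqrt(max(1.0, phi)) if floor_phi else math.sqrt(phi)
    se = scale * np.sqrt(np.diag(xtwx_inv))
    out: list[MREstimate] = []
    for name, b, s in zip(data.exposure_names, coef, se):
        p = float(2 * stats.norm.sf(abs(b / s))) if s > 0 else (0.0 if b else 1.0)
        out.append(
            MREstimate(
                method=f"mvmr_ivw[{name}]",
                n_snp=j,
                beta=float(b),
                se=float(s),
                ci_low=float(b - Z_975 * s),
                ci_high=float(b + Z_975 * s),
                pval=p,
                phi=phi,
            )
        )
    return out
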