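"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly at the summary level (no
individual genotypes): for SNP j with minor-allele frequency MAF_j and a
standardized trait, the standard error of a per-allele effect estimated in
N samples is approximately (2·N·MAF_j(1−MAF_j))^{−1/2}; for a binary trait
with case fraction k the variance is inflated by 1/(k(1−k)).  Observed
effects are then

    β̂_Xj ~ N(γ_j,              SE_Xj)
    β̂_Yj ~ N(θ·γ_j + α_j,      SE_Yj)

with γ_j the instrument strength, θ the causal effect and α_j a direct
(pleiotropic) effect on the outcome.  Pleiotropy can be balanced (mean 0)
or directional (mean μ_α), restricted to a fraction of SNPs, and correlated
with γ_j to violate the InSIDE assumption.  The generator also injects the
data artifacts every pipeline stage must survive: LD blocks (emitted as an
explicit r² table), allele swaps, strand flips, palindromic allele pairs,
and planted outlier instruments.  Every latent value is recorded in the
truth table so recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import LDTable, SummaryAssociation

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "MVMRSimulation",
    "simulate_two_sample",
    "simulate_mvmr",
    "scenario",
    "SCENARIOS",
]

_NON_PALINDROMIC_PAIRS = (
    ("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
    ("A", "C"), ("G", "T"), ("C", "A"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one two-sample summary-statistics dataset.

    Defaults emulate a moderately sized binary-exposure / binary-outcome
    design: ~23k exposure samples, ~173k outcome samples with a 0.35 case
    fraction, and per-allele instrument strengths around 0.1 (per-SNP F
    well above 10).
    """

    j: int = 50
    theta_true: float = 0.0
    gamma_mean: float = 0.1
    gamma_sd: float = 0.02
    pleiotropy: str = "none"  # none | balanced | directional
    sigma_alpha: float = 0.0
    mu_alpha: float = 0.0
    #: fraction of SNPs carrying a pleiotropic direct effect
    pleiotropy_fraction: float = 1.0
    #: correlation between γ_j and α_j (InSIDE violated when non-zero)
    inside_violation: float = 0.0
    n_exposure: int = 23_210
    n_outcome: int = 173_005
    case_fraction: float | None = 59_851 / 173_005
    maf_range: tuple[float, float] = (0.1, 0.4)
    #: list of (block_size, within_block_r2); remaining SNPs are singletons
    ld_blocks: tuple[tuple[int, float], ...] = ()
    allele_swap_rate: float = 0.0
    strand_flip_rate: float = 0.0
    palindrome_rate: float = 0.0
    #: list of (snp index, multiplier applied to the β_Y mean)
    outliers: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.j < 3:
            raise ValueError(f"j must be ≥ 3, got {self.j}")
        for name in ("allele_swap_rate", "strand_flip_rate", "palindrome_rate",
                     "pleiotropy_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode: {self.pleiotropy!r}")
        if not (-1.0 <= self.inside_violation <= 1.0):
            raise ValueError(f"inside_violation outside [-1, 1]: {self.inside_violation}")


@dataclass
class SyntheticDataset:
    exposure: list[SummaryAssociation]
    outcome: list[SummaryAssociation]
    ld: LDTable
    #: per-SNP latent values and corruption log
    truth: pd.DataFrame
    config: SyntheticConfig


def _se(n: float, maf: np.ndarray, case_fraction: float | None) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
    if case_fraction is not None:
        se = se / np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta / se))


def simulate_two_sample(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one exposure table, one outcome table, an LD table and truth.

    All randomness flows from ``config.seed``; the same config yields an
    identical dataset.  The truth table records γ_j, α_j, the realized
    (correctly aligned) effect estimates, and every corruption applied to
    the outcome table's allele presentation, so harmonization and outlier
    detection can be validated against known answers.
    """
    rng = np.random.default_rng(config.seed)
    j = config.j

    maf = rng.uniform(*config.maf_range, size=j)
    # effect allele is the minor allele half the time
    ea_is_minor = rng.random(j) < 0.5
    eaf = np.where(ea_is_minor, maf, 1.0 - maf)

    gamma = rng.normal(config.gamma_mean, config.gamma_sd, size=j)

    alpha = np.zeros(j)
    has_pleio = np.zeros(j, dtype=bool)
    if config.pleiotropy != "none" and config.sigma_alpha >= 0:
        has_pleio = rng.random(j) < config.pleiotropy_fraction
        mean = config.mu_alpha if config.pleiotropy == "directional" else 0.0
        z = rng.standard_normal(j)
        if config.inside_violation != 0.0 and np.std(gamma) > 0:
            g_std = (gamma - gamma.mean()) / gamma.std()
            rho = config.inside_violation
            z = rho * g_std + np.sqrt(1.0 - rho**2) * z
        alpha = np.where(has_pleio, mean + config.sigma_alpha * z, 0.0)

    se_x = _se(config.n_exposure, maf, None)
    se_y = _se(config.n_outcome, maf, config.case_fraction)

    beta_x = rng.normal(gamma, se_x)
    mean_y = config.theta_true * gamma + alpha
    outlier_mult = np.ones(j)
    for idx, mult in config.outliers:
        outlier_mult[idx] = mult
    beta_y = rng.normal(mean_y * outlier_mult, se_y)

    # allele presentation and corruption of the outcome table
    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=j)
    is_palindromic = rng.random(j) < config.palindrome_rate
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    swapped = rng.random(j) < config.allele_swap_rate
    strand_flipped = rng.random(j) < config.strand_flip_rate

    # genomic layout: LD blocks first, then singleton SNPs, blocks far apart
    block_of = np.full(j, -1)
    pos = np.zeros(j, dtype=int)
    ld = LDTable()
    cursor = 0
    block_id = 0
    base = 1_000_000
    for size, r2 in config.ld_blocks:
        members = list(range(cursor, min(cursor + size, j)))
        for m, snp_i in enumerate(members):
            block_of[snp_i] = block_id
            pos[snp_i] = base + m * 10_000
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ld.add(f"rs{members[a]+1:06d}", f"rs{members[b]+1:06d}", r2)
        cursor += len(members)
        block_id += 1
        base += 50_000_000  # blocks far outside any clumping window
    for snp_i in range(cursor, j):
        pos[snp_i] = base
        base += 50_000_000

    exposure: list[SummaryAssociation] = []
    outcome: list[SummaryAssociation] = []
    rows = []
    for i in range(j):
        snp = f"rs{i+1:06d}"
        if is_palindromic[i]:
            ea, oa = _PALINDROMIC_PAIRS[pal_idx[i]]
        else:
            ea, oa = _NON_PALINDROMIC_PAIRS[pair_idx[i]]
        px = _pvals(np.array([beta_x[i]]), np.array([se_x[i]]))[0]
        py = _pvals(np.array([beta_y[i]]), np.array([se_y[i]]))[0]
        exposure.append(
            SummaryAssociation(
                snp_id=snp, chrom="1", pos=int(pos[i]),
                effect_allele=ea, other_allele=oa,
                beta=float(beta_x[i]), se=float(se_x[i]), pval=float(px),
                eaf=float(eaf[i]), n=config.n_exposure, trait="exposure",
            )
        )
        o_ea, o_oa = ea, oa
        o_beta, o_eaf = float(beta_y[i]), float(eaf[i])
        if swapped[i]:
            o_ea, o_oa = o_oa, o_ea
            o_beta = -o_beta
            o_eaf = 1.0 - o_eaf
        if strand_flipped[i]:
            o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
        outcome.append(
            SummaryAssociation(
                snp_id=snp, chrom="1", pos=int(pos[i]),
                effect_allele=o_ea, other_allele=o_oa,
                beta=o_beta, se=float(se_y[i]), pval=float(py),
                eaf=o_eaf, n=config.n_outcome, trait="outcome",
            )
        )
        rows.append(
            (
                snp, gamma[i], alpha[i], float(beta_x[i]), float(beta_y[i]),
                float(se_x[i]), float(se_y[i]), float(maf[i]), float(eaf[i]),
                bool(is_palindromic[i]), bool(swapped[i]),
                bool(strand_flipped[i]), float(outlier_mult[i]),
                int(block_of[i]),
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "snp", "gamma", "alpha", "beta_x_hat", "beta_y_hat_aligned",
            "se_x", "se_y", "maf", "eaf", "palindromic", "allele_swapped",
            "strand_flipped", "outlier_multiplier", "ld_block",
        ],
    )
    return SyntheticDataset(exposure=exposure, outcome=outcome, ld=ld,
                            truth=truth, config=config)


@dataclass
class MVMRSimulation:
    exposures: list[list[SummaryAssociation]]
    outcome: list[SummaryAssociation]
    theta_true: np.ndarray  # direct effect of each exposure on the outcome
    truth: pd.DataFrame


def simulate_mvmr(
    configs: Sequence[SyntheticConfig],
    cross_effects: np.ndarray,
) -> MVMRSimulation:
    """K-exposure simulation on a shared SNP panel.

    ``cross_effects`` is a K×K matrix C: exposure k's true per-SNP effect is
    b⁽ᵏ⁾ = Σ_l C[k,l]·γ⁽ˡ⁾, so the identity matrix reduces to independent
    two-sample simulations on a shared panel.  The outcome mean combines
    the direct effects: Σ_k θ_k·b⁽ᵏ⁾, with θ_k taken from each config's
    ``theta_true``.
    """
    k = len(configs)
    if k < 2:
        raise ValueError("MVMR simulation needs at least 2 exposures")
    cross = np.asarray(cross_effects, dtype=float)
    if cross.shape != (k, k):
        raise ValueError(f"cross_effects must be {k}×{k}, got {cross.shape}")
    j = configs[0].j
    rng = np.random.default_rng(configs[0].seed)
    maf = rng.uniform(*configs[0].maf_range, size=j)
    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=j)
    eaf = np.where(rng.random(j) < 0.5, maf, 1.0 - maf)

    raw = np.stack([rng.normal(c.gamma_mean, c.gamma_sd, size=j) for c in configs])
    true_bx = cross @ raw  # (K, J)
    theta = np.array([c.theta_true for c in configs])
    mean_y = theta @ true_bx

    exposures: list[list[SummaryAssociation]] = []
    truth_cols = {"snp": [f"rs{i+1:06d}" for i in range(j)], "maf": maf}
    for idx, cfg in enumerate(configs):
        se_x = _se(cfg.n_exposure, maf, None)
        bx = rng.normal(true_bx[idx], se_x)
        px = _pvals(bx, se_x)
        exposures.append(
            [
                SummaryAssociation(
                    snp_id=f"rs{i+1:06d}", chrom="1", pos=1_000_000 + i * 50_000_000,
                    effect_allele=_NON_PALINDROMIC_PAIRS[pair_idx[i]][0],
                    other_allele=_NON_PALINDROMIC_PAIRS[pair_idx[i]][1],
                    beta=float(bx[i]), se=float(se_x[i]), pval=float(px[i]),
                    eaf=float(eaf[i]), n=cfg.n_exposure, trait=f"exposure_{idx+1}",
                )
                for i in range(j)
            ]
        )
        truth_cols[f"true_beta_x_{idx+1}"] = true_bx[idx]
    se_y = _se(configs[0].n_outcome, maf, configs[0].case_fraction)
    by = rng.normal(mean_y, se_y)
    py = _pvals(by, se_y)
    outcome = [
        SummaryAssociation(
            snp_id=f"rs{i+1:06d}", chrom="1", pos=1_000_000 + i * 50_000_000,
            effect_allele=_NON_PALINDROMIC_PAIRS[pair_idx[i]][0],
            other_allele=_NON_PALINDROMIC_PAIRS[pair_idx[i]][1],
            beta=float(by[i]), se=float(se_y[i]), pval=float(py[i]),
            eaf=float(eaf[i]), n=configs[0].n_outcome, trait="outcome",
        )
        for i in range(j)
    ]
    truth_cols["mean_y"] = mean_y
    return MVMRSimulation(
        exposures=exposures,
        outcome=outcome,
        theta_true=theta,
        truth=pd.DataFrame(truth_cols),
    )


#: Documented presets exercised by the test- and acceptance suites.
SCENARIOS: dict[str, SyntheticConfig] = {
    "null": SyntheticConfig(j=50, theta_true=0.0, pleiotropy="none", seed=0),
    "valid_strong": SyntheticConfig(j=50, theta_true=0.2, pleiotropy="none", seed=0),
    "directional_pleiotropy": SyntheticConfig(
        j=100, theta_true=0.2, pleiotropy="directional",
        mu_alpha=0.01, sigma_alpha=0.005, seed=0,
    ),
    "thirty_pct_invalid": SyntheticConfig(
        j=100, theta_true=0.2, pleiotropy="directional",
        mu_alpha=0.02, sigma_alpha=0.005, pleiotropy_fraction=0.3, seed=0,
    ),
    "planted_outlier": SyntheticConfig(
        j=30, theta_true=0.2, pleiotropy="none", outliers=((7, 10.0),), seed=0,
    ),
    "palindrome_mix": SyntheticConfig(
        j=60, theta_true=0.2, pleiotropy="none", maf_range=(0.1, 0.5),
        palindrome_rate=0.2, allele_swap_rate=0.3, strand_flip_rate=0.3, seed=0,
    ),
}


def scenario(name: str, **overrides) -> SyntheticConfig:
    """Return a documented preset config, optionally with field overrides."""
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    cfg = SCENARIOS[name]
    return replace(cfg, **overrides) if overrides else cfg
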