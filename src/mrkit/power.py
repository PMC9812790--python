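"""Analytic power for two-sample MR with a binary outcome.

Non-centrality-parameter calculation in the style of the mRnd calculator.
The hypothesized odds ratio per exposure SD is first attenuated onto the
probability scale,

    b_MR = K · ( OR / (1 + K·(OR − 1)) − 1 ),

where K is the outcome case fraction; the sampling variance of the MR
estimate on that scale is v_MR = (K(1−K) − b_MR²)/(N·R²_XZ) with N the
outcome sample size and R²_XZ the variance of the exposure explained by the
instruments.  Power is the upper-tail mass of a non-central χ²(1, NCP =
b_MR²/v_MR) beyond the central χ²(1) critical value at level α.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerParams", "PowerResult", "power_binary"]


@dataclass(frozen=True)
class PowerParams:
    """Inputs of the binary-outcome power calculation.

    n: outcome sample size (cases + controls);
    r2_xz: instrument R² on the exposure, in [0, 1);
    k: case fraction in (0, 1);
    or_alt: hypothesized odds ratio per exposure SD;
    alpha: significance level.
    """

    n: float
    r2_xz: float
    k: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not (0.0 <= self.r2_xz < 1.0):
            raise ValueError(f"r2_xz outside [0, 1): {self.r2_xz}")
        if not (0.0 < self.k < 1.0):
            raise ValueError(f"case fraction outside (0, 1): {self.k}")
        if self.or_alt <= 0:
            raise ValueError(f"or_alt must be positive, got {self.or_alt}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha outside (0, 1): {self.alpha}")


@dataclass(frozen=True)
class PowerResult:
    b_mr: float  # attenuated effect on the probability scale
    ncp: float  # non-centrality parameter
    power: float


def power_binary(params: PowerParams) -> PowerResult:
    """Analytic power of the MR Wald test for a binary outcome.

    Under the null (or_alt = 1) the NCP is 0 and power equals alpha exactly.
    Raises when the implied variance is non-positive (infeasible inputs).
    """
    k, or_alt = params.k, params.or_alt
    b_mr = k * (or_alt / (1.0 + k * (or_alt - 1.0)) - 1.0)
    if params.r2_xz == 0.0:
        if b_mr == 0.0:
            return PowerResult(b_mr=0.0, ncp=0.0, power=params.alpha)
        raise ValueError("r2_xz = 0 with a non-null effect: variance undefined")
    v_mr = (k * (1.0 - k) - b_mr**2) / (params.n * params.r2_xz)
    if v_mr <= 0:
        raise ValueError(
            f"infeasible parameters: implied variance {v_mr} is non-positive"
        )
    ncp = b_mr**2 / v_mr
    crit = stats.chi2.isf(params.alpha, df=1)
    power = float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else params.alpha
    return PowerResult(b_mr=float(b_mr), ncp=float(ncp), power=power)
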