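#!/usr/bin/env python
"""Analytic power surface for a binary-outcome two-sample MR design.

Tabulates power over a grid of instrument R-squared and hypothesized odds
ratios at a study-sized outcome GWAS (173,005 samples, case fraction
0.346), and verifies the analytic value against a Monte-Carlo Wald test on
a scaled-down design.
"""

import argparse
from pathlib import Path

import pandas as pd

from mrkit.calibration import empirical_power_binary
from mrkit.power import PowerParams, power_binary


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/power"))
    args = ap.parse_args()

    n, k = 173_005, 59_851 / 173_005
    rows = []
    for r2 in (0.01, 0.02, 0.05, 0.10):
        for or_alt in (0.983, 0.95, 0.90, 1.10, 1.20):
            res = power_binary(PowerParams(n=n, r2_xz=r2, k=k, or_alt=or_alt))
            rows.append({"n": n, "k": round(k, 4), "r2_xz": r2,
                         "or_alt": or_alt, "ncp": res.ncp, "power": res.power})
    df = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "power_grid.tsv", sep="\t", index=False)
    weakest = df.loc[df["or_alt"] == 0.983]
    print("power to detect OR 0.983 by instrument R2:")
    for _, r in weakest.iterrows():
        print(f"  R2={r['r2_xz']:.2f}: power={r['power']:.3f}")

    params = PowerParams(n=4000, r2_xz=0.05, k=0.35, or_alt=1.15, alpha=0.05)
    analytic = power_binary(params).power
    empirical = empirical_power_binary(params, n_rep=2000, seed=args.seed)
    print(
        f"scaled-down check (n=4000, OR=1.15): analytic {analytic:.3f} vs "
        f"empirical Wald rejection {empirical.value:.3f} over {empirical.n_rep} reps"
    )


if __name__ == "__main__":
    main()
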