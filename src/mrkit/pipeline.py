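"""End-to-end orchestration of the two-sample MR workflow.

Stage order: genome-wide p filter → LD clumping → proxy substitution →
weak-instrument (F) filter → harmonization (palindrome exclusion) →
MR-PRESSO outlier removal → final estimation with every requested method →
heterogeneity, leave-one-out and funnel diagnostics → report tables.
Reverse-direction MR is the same pipeline with the exposure and outcome
roles swapped.  Every dropped SNP is logged with the rule that removed it,
and the stage counts satisfy

    final = clumped − proxy_dropped − weak_dropped − palindromic_dropped
            − unresolvable_dropped − presso_dropped.

All randomness (weighted-median bootstrap, MR-PRESSO simulations) derives
from a single top-level seed via spawned child streams, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import summary_io
from .summary_io import LDTable, ProxyTable, SummaryAssociation
from .instruments import (
    CLUMP_R2,
    CLUMP_WINDOW_BP,
    F_MIN,
    GENOME_WIDE_P,
    PALINDROME_MAF,
    PROXY_R2,
    HarmonizedDataset,
    InstrumentRecord,
    apply_proxies,
    f_statistic,
    filter_genome_wide,
    filter_weak,
    harmonize,
    ld_clump,
)
from .estimators import (
    MREstimate,
    HeterogeneityResult,
    egger,
    funnel_data,
    ivw,
    leave_one_out,
    to_odds_scale,
    weighted_median,
)
from . import presso as presso_mod

__all__ = [
    "PipelineParams",
    "PipelineConfig",
    "StageCounts",
    "ReportBundle",
    "run_analysis",
    "run_pipeline",
    "render_report",
    "heterogeneity_verdict",
]

DEFAULT_METHODS = ("ivw_mre", "egger", "weighted_median")


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds and tuning knobs of the selection + estimation chain."""

    pval_threshold: float = GENOME_WIDE_P
    clump_r2: float = CLUMP_R2
    clump_window_bp: int = CLUMP_WINDOW_BP
    proxy_r2: float = PROXY_R2
    f_min: float = F_MIN
    palindrome_maf: float = PALINDROME_MAF
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    methods: tuple[str, ...] = DEFAULT_METHODS
    floor_phi: bool = False
    binary_outcome: bool = True
    run_presso: bool = True


@dataclass
class PipelineConfig:
    """File-level configuration for a pipeline run."""

    exposure_path: str
    outcome_path: str
    out_dir: str
    direction: str = "forward"  # forward | reverse
    ld_path: str | None = None
    proxy_path: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = PipelineParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


@dataclass
class StageCounts:
    """Instrument bookkeeping through the selection pipeline.

    ``final`` is derived, never stored, so the conservation identity holds
    by construction; the pipeline additionally asserts it against the
    actual retained row count.
    """

    candidates: int = 0
    selected: int = 0
    clumped: int = 0
    proxied: int = 0
    proxy_dropped: int = 0
    weak_dropped: int = 0
    palindromic_dropped: int = 0
    unresolvable_dropped: int = 0
    presso_dropped: int = 0

    @property
    def final(self) -> int:
        return (
            self.clumped
            - self.proxy_dropped
            - self.weak_dropped
            - self.palindromic_dropped
            - self.unresolvable_dropped
            - self.presso_dropped
        )

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d["final"] = self.final
        return pd.DataFrame({"stage": list(d), "count": list(d.values())})


@dataclass
class ReportBundle:
    counts: StageCounts
    harmonized: HarmonizedDataset
    estimates: list[MREstimate]
    heterogeneity: HeterogeneityResult | None
    loo: pd.DataFrame | None
    funnel: pd.DataFrame
    presso: "presso_mod.PressoResult | None"
    drop_log: list[tuple[str, str]]
    direction: str = "forward"


def heterogeneity_verdict(het: HeterogeneityResult) -> str:
    """Standard reading of the Q test: no heterogeneity iff p > 0.05 and I² < 25%."""
    if het.pval > 0.05 and het.i2 < 25.0:
        return "no heterogeneity"
    return "heterogeneity detected"


def run_analysis(
    exposure: Sequence[SummaryAssociation],
    outcome: Sequence[SummaryAssociation],
    ld: LDTable | None = None,
    proxies: ProxyTable | None = None,
    params: PipelineParams = PipelineParams(),
    direction: str = "forward",
) -> ReportBundle:
    """Run the full selection + estimation chain on in-memory records."""
    if direction == "reverse":
        exposure, outcome = outcome, exposure
    elif direction != "forward":
        raise ValueError(f"unknown direction: {direction!r}")
    counts = StageCounts(candidates=len(exposure))
    log: list[tuple[str, str]] = []
    seeds = np.random.SeedSequence(params.seed).spawn(3)

    try:
        selected = filter_genome_wide(exposure, params.pval_threshold)
        counts.selected = len(selected)
        for r in exposure:
            if r.pval >= params.pval_threshold:
                log.append((r.snp_id, "not_genome_wide_significant"))

        clumped = ld_clump(
            selected, ld or LDTable(), params.clump_r2, params.clump_window_bp
        )
        counts.clumped = len(clumped)
        clumped_ids = {r.snp_id for r in clumped}
        for r in selected:
            if r.snp_id not in clumped_ids:
                log.append((r.snp_id, "clumped_out"))

        outcome_ids = {r.snp_id for r in outcome}
        proxied = apply_proxies(
            clumped, outcome_ids, proxies or ProxyTable(), params.proxy_r2
        )
        counts.proxied = sum(1 for _, a in proxied.log if a.startswith("proxied_by"))
        counts.proxy_dropped = sum(1 for _, a in proxied.log if a == "dropped_no_proxy")
        log.extend((s, a) for s, a in proxied.log if a != "kept")

        instruments = [InstrumentRecord(r.snp_id, r) for r in proxied.records]
        strong = filter_weak(instruments, params.f_min)
        counts.weak_dropped = len(instruments) - len(strong)
        strong_ids = {r.snp_id for r in strong}
        for r in instruments:
            if r.snp_id not in strong_ids:
                log.append((r.snp_id, "weak_instrument_dropped"))

        data = harmonize(
            [r.exposure for r in strong], outcome, params.palindrome_maf
        )
        counts.palindromic_dropped = sum(
            1 for r in data.rows if r.action == "dropped_palindromic"
        )
        counts.unresolvable_dropped = sum(
            1 for r in data.rows if r.action == "dropped_unresolvable"
        )
        for r in data.rows:
            if not r.retained:
                log.append((r.snp_id, r.action))

        presso_result = None
        if params.run_presso and data.n_snp >= 4:
            presso_result = presso_mod.global_test(
                data, n_sim=params.presso_n_sim, seed=seeds[0]
            )
            presso_mod.outlier_test(presso_result, alpha=params.outlier_alpha)
            if presso_result.outliers:
                data = data.drop_snps(presso_result.outliers)
                counts.presso_dropped = len(presso_result.outliers)
                log.extend((s, "presso_outlier_dropped") for s in presso_result.outliers)

        assert data.n_snp == counts.final, (
            f"instrument conservation violated: {data.n_snp} retained rows "
            f"vs derived final count {counts.final}"
        )

        estimates: list[MREstimate] = []
        het = None
        if data.n_snp >= 2:
            for method in params.methods:
                if method in ("ivw_mre", "ivw_fixed"):
                    est, het = ivw(
                        data,
                        mode=method.removeprefix("ivw_"),
                        floor_phi=params.floor_phi,
                    )
                elif method == "egger":
                    est = egger(data)
                elif method == "weighted_median":
                    est = weighted_median(data, n_boot=params.n_boot, seed=seeds[1])
                else:
                    raise ValueError(f"unknown method: {method!r}")
                if params.binary_outcome:
                    est = to_odds_scale(est)
                estimates.append(est)
            if het is None:
                _, het = ivw(data, mode="mre", floor_phi=params.floor_phi)

        loo = (
            leave_one_out(data, floor_phi=params.floor_phi)
            if data.n_snp >= 3
            else None
        )
        funnel = funnel_data(data) if data.n_snp else pd.DataFrame()
    except Exception as exc:
        raise RuntimeError(f"pipeline failed ({direction} direction): {exc}") from exc

    return ReportBundle(
        counts=counts,
        harmonized=data,
        estimates=estimates,
        heterogeneity=het,
        loo=loo,
        funnel=funnel,
        presso=presso_result,
        drop_log=log,
        direction=direction,
    )


def _estimates_frame(estimates: Sequence[MREstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": e.method,
                "n_snp": e.n_snp,
                "beta": e.beta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "or": e.or_value,
                "or_ci_low": e.or_ci_low,
                "or_ci_high": e.or_ci_high,
                "phi": e.phi,
                "egger_intercept": e.intercept,
                "egger_intercept_se": e.intercept_se,
                "egger_intercept_pval": e.intercept_pval,
            }
            for e in estimates
        ]
    )


def render_report(bundle: ReportBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write plot-ready TSVs and a one-page text summary; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep="NA")
        paths[name] = p

    save("counts", bundle.counts.to_frame())
    save("harmonized", bundle.harmonized.to_frame())
    save("forest", _estimates_frame(bundle.estimates))
    if bundle.heterogeneity is not None:
        h = bundle.heterogeneity
        save(
            "heterogeneity",
            pd.DataFrame(
                {"q": [h.q], "df": [h.df], "pval": [h.pval], "i2_pct": [h.i2]}
            ),
        )
    if bundle.loo is not None:
        save("leave_one_out", bundle.loo)
    save("funnel", bundle.funnel)

    kept = bundle.harmonized.retained
    scatter = pd.DataFrame(
        {
            "snp": [r.snp_id for r in kept],
            "beta_x": [r.beta_x for r in kept],
            "se_x": [r.se_x for r in kept],
            "beta_y": [r.beta_y for r in kept],
            "se_y": [r.se_y for r in kept],
        }
    )
    save("scatter", scatter)
    lines = pd.DataFrame(
        {
            "method": [e.method for e in bundle.estimates],
            "slope": [e.beta for e in bundle.estimates],
            "intercept": [e.intercept if e.intercept is not None else 0.0
                          for e in bundle.estimates],
        }
    )
    save("scatter_lines", lines)

    if bundle.presso is not None:
        pr = bundle.presso
        save(
            "presso_global",
            pd.DataFrame(
                {
                    "rss_obs": [pr.rss_obs],
                    "global_pval": [pr.global_pval],
                    "n_sim": [pr.n_sim],
                    "n_outliers": [len(pr.outliers)],
                }
            ),
        )
        save(
            "presso_per_snp",
            pd.DataFrame(
                {
                    "snp": pr.snp_ids,
                    "contribution": pr.contributions,
                    "pval_raw": [pr.per_snp_pvals.get(s) for s in pr.snp_ids],
                    "pval_bonferroni": [pr.per_snp_pvals_adj.get(s) for s in pr.snp_ids],
                    "outlier": [s in pr.outliers for s in pr.snp_ids],
                }
            ),
        )

    log_path = out / "drop_log.tsv"
    with open(log_path, "w") as fh:
        fh.write("snp\trule\n")
        for snp, rule in bundle.drop_log:
            fh.write(f"{snp}\t{rule}\n")
    paths["drop_log"] = log_path

    summary_path = out / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write(f"Two-sample MR report ({bundle.direction} direction)\n")
        fh.write("=" * 50 + "\n\n")
        c = bundle.counts
        fh.write("Instrument selection\n")
        fh.write(f"  candidate SNPs:            {c.candidates}\n")
        fh.write(f"  genome-wide significant:   {c.selected}\n")
        fh.write(f"  LD-independent (clumped):  {c.clumped}\n")
        fh.write(f"  proxied:                   {c.proxied}\n")
        fh.write(f"  dropped (no proxy):        {c.proxy_dropped}\n")
        fh.write(f"  dropped (weak, F):         {c.weak_dropped}\n")
        fh.write(f"  dropped (palindromic):     {c.palindromic_dropped}\n")
        fh.write(f"  dropped (unresolvable):    {c.unresolvable_dropped}\n")
        fh.write(f"  dropped (MR-PRESSO):       {c.presso_dropped}\n")
        fh.write(f"  final instruments:         {c.final}\n\n")
        fh.write("Causal estimates\n")
        for e in bundle.estimates:
            if e.or_value is not None:
                fh.write(
                    f"  {e.method}: OR = {e.or_value:.3f} "
                    f"(95% CI {e.or_ci_low:.3f}-{e.or_ci_high:.3f}), "
                    f"p = {e.pval:.3g}, nSNP = {e.n_snp}\n"
                )
            else:
                fh.write(
                    f"  {e.method}: beta = {e.beta:.4f} (SE {e.se:.4f}), "
                    f"p = {e.pval:.3g}, nSNP = {e.n_snp}\n"
                )
            if e.intercept is not None:
                fh.write(
                    f"    intercept = {e.intercept:.4f}, p = {e.intercept_pval:.3g}\n"
                )
        if bundle.heterogeneity is not None:
            h = bundle.heterogeneity
            fh.write(
                f"\nHeterogeneity: Q = {h.q:.3f} (df {h.df}), p = {h.pval:.3f}, "
                f"I2 = {h.i2:.1f}% -> {heterogeneity_verdict(h)}\n"
            )
        if bundle.presso is not None:
            fh.write(
                f"MR-PRESSO: global p = {bundle.presso.global_pval:.4g}, "
                f"outliers removed = {len(bundle.presso.outliers)}\n"
            )
    paths["summary"] = summary_path
    return paths


def run_pipeline(config: PipelineConfig) -> tuple[ReportBundle, dict[str, Path]]:
    """File-driven pipeline: read inputs, run the analysis, write the report."""
    exposure = summary_io.read_summary_stats(config.exposure_path)
    outcome = summary_io.read_summary_stats(config.outcome_path)
    ld = summary_io.read_ld_table(config.ld_path) if config.ld_path else None
    proxies = (
        summary_io.read_proxy_table(config.proxy_path) if config.proxy_path else None
    )
    bundle = run_analysis(
        exposure, outcome, ld=ld, proxies=proxies,
        params=config.params, direction=config.direction,
    )
    paths = render_report(bundle, config.out_dir)
    return bundle, paths
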