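"""Instrument selection, LD clumping, proxy substitution and harmonization.

The selection pipeline mirrors standard two-sample MR practice: keep
genome-wide-significant exposure associations (p < 5×10⁻⁸), greedily clump
to LD-independent index SNPs (r² > 0.01 within a 10 Mb window), substitute
proxies (r² > 0.8) for instruments missing from the outcome GWAS, discard
weak instruments (F < 10, with F = (β/SE)² per SNP), and harmonize exposure
and outcome effects onto a shared effect allele — dropping palindromic
variants whose intermediate allele frequency (MAF > 0.42) makes strand
orientation unresolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .summary_io import (
    AnnotationTable,
    LDTable,
    ProxyTable,
    SummaryAssociation,
)

__all__ = [
    "InstrumentRecord",
    "HarmonizedRow",
    "HarmonizedDataset",
    "ProxyOutcome",
    "filter_genome_wide",
    "ld_clump",
    "apply_proxies",
    "f_statistic",
    "filter_weak",
    "harmonize",
    "annotate_confounders",
    "GENOME_WIDE_P",
    "CLUMP_R2",
    "CLUMP_WINDOW_BP",
    "PROXY_R2",
    "F_MIN",
    "PALINDROME_MAF",
]

GENOME_WIDE_P = 5e-8
CLUMP_R2 = 0.01
CLUMP_WINDOW_BP = 10_000_000
PROXY_R2 = 0.8
F_MIN = 10.0
PALINDROME_MAF = 0.42

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Harmonization actions that keep the row in the analysis.
RETAINED_ACTIONS = frozenset(
    {"unchanged", "sign_flipped", "strand_flipped", "strand_flipped_and_sign_flipped"}
)


@dataclass
class InstrumentRecord:
    """A selected instrument with its per-SNP strength and audit trail."""

    snp_id: str
    exposure: SummaryAssociation
    selection_flags: list[str] = field(default_factory=list)

    @property
    def f_stat(self) -> float:
        return f_statistic(self.exposure)


def f_statistic(assoc: SummaryAssociation) -> float:
    """Per-SNP instrument-strength F statistic, (β/SE)²."""
    return (assoc.beta / assoc.se) ** 2


@dataclass(frozen=True)
class HarmonizedRow:
    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None
    eaf_y: float | None
    action: str

    @property
    def retained(self) -> bool:
        return self.action in RETAINED_ACTIONS


class HarmonizedDataset:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    Retained rows (``action`` not a ``dropped_*`` label) form the instrument
    set consumed by every estimator; dropped rows are kept for the audit log.
    """

    def __init__(self, rows: Sequence[HarmonizedRow]):
        self.rows = list(rows)

    @property
    def retained(self) -> list[HarmonizedRow]:
        return [r for r in self.rows if r.retained]

    @property
    def n_snp(self) -> int:
        return len(self.retained)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
        """(beta_x, se_x, beta_y, se_y, snp_ids) over retained rows."""
        kept = self.retained
        return (
            np.array([r.beta_x for r in kept], dtype=float),
            np.array([r.se_x for r in kept], dtype=float),
            np.array([r.beta_y for r in kept], dtype=float),
            np.array([r.se_y for r in kept], dtype=float),
            [r.snp_id for r in kept],
        )

    def drop_snps(self, snp_ids: Iterable[str], reason: str = "presso_outlier_dropped") -> "HarmonizedDataset":
        """A copy with the named retained SNPs re-labelled as dropped."""
        targets = set(snp_ids)
        rows = [
            replace(r, action=reason) if r.snp_id in targets and r.retained else r
            for r in self.rows
        ]
        return HarmonizedDataset(rows)

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedDataset":
        keep = set(snp_ids)
        return HarmonizedDataset([r for r in self.rows if r.snp_id in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": [r.snp_id for r in self.rows],
                "beta_x": [r.beta_x for r in self.rows],
                "se_x": [r.se_x for r in self.rows],
                "beta_y": [r.beta_y for r in self.rows],
                "se_y": [r.se_y for r in self.rows],
                "eaf_x": [r.eaf_x for r in self.rows],
                "eaf_y": [r.eaf_y for r in self.rows],
                "action": [r.action for r in self.rows],
            }
        )


def filter_genome_wide(
    records: Sequence[SummaryAssociation],
    threshold: float = GENOME_WIDE_P,
) -> list[SummaryAssociation]:
    """Keep associations with p strictly below ``threshold`` (order preserved)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold outside (0, 1]: {threshold}")
    return [r for r in records if r.pval < threshold]


def ld_clump(
    records: Sequence[SummaryAssociation],
    ld: LDTable,
    r2_max: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> list[SummaryAssociation]:
    """Greedy LD clumping to p-value-ranked index SNPs.

    Repeatedly takes the most significant unclaimed SNP (ties broken by
    rsID) as an index and discards every unclaimed SNP on the same
    chromosome within ±``window_bp`` whose r² with the index exceeds
    ``r2_max``.  Returns the index SNPs in the input order.
    """
    if window_bp is not None:
        for r in records:
            if r.chrom is None or r.pos is None:
                raise ValueError(
                    f"{r.snp_id}: chrom/pos required for window-based clumping"
                )
    order = sorted(range(len(records)), key=lambda i: (records[i].pval, records[i].snp_id))
    claimed: set[int] = set()
    index_ids: set[int] = set()
    for i in order:
        if i in claimed:
            continue
        index_ids.add(i)
        claimed.add(i)
        idx = records[i]
        for j in order:
            if j in claimed:
                continue
            other = records[j]
            if window_bp is not None:
                if other.chrom != idx.chrom or abs(other.pos - idx.pos) > window_bp:
                    continue
            if ld.r2(idx.snp_id, other.snp_id) > r2_max:
                claimed.add(j)
    return [records[i] for i in range(len(records)) if i in index_ids]


class ProxyOutcome(NamedTuple):
    records: list[SummaryAssociation]
    #: per-SNP log lines: (snp_id, action) with action in
    #: {"kept", "proxied_by:<rsID>", "dropped_no_proxy"}
    log: list[tuple[str, str]]


def apply_proxies(
    selected: Sequence[SummaryAssociation],
    outcome_snps: set[str],
    proxies: ProxyTable,
    r2_min: float = PROXY_R2,
) -> ProxyOutcome:
    """Replace instruments missing from the outcome GWAS by LD proxies.

    A missing SNP is replaced by its highest-r² proxy with r² strictly
    above ``r2_min`` that is present in ``outcome_snps`` (ties broken by
    rsID); the proxy's orientation flag maps the exposure effect onto the
    proxy's effect allele.  With no suitable proxy the SNP is dropped.
    """
    kept: list[SummaryAssociation] = []
    log: list[tuple[str, str]] = []
    for rec in selected:
        if rec.snp_id in outcome_snps:
            kept.append(rec)
            log.append((rec.snp_id, "kept"))
            continue
        candidates = [
            c
            for c in proxies.candidates(rec.snp_id)
            if c.r2 > r2_min and c.proxy_snp in outcome_snps
        ]
        if not candidates:
            log.append((rec.snp_id, "dropped_no_proxy"))
            continue
        best = candidates[0]
        proxied = replace(
            rec,
            snp_id=best.proxy_snp,
            # The proxy table carries orientation explicitly: when the proxy's
            # effect allele tags the target's OTHER allele, the exposure effect
            # changes sign on the proxy scale.
            beta=rec.beta if best.same_effect_allele else -rec.beta,
            eaf=rec.eaf if best.same_effect_allele or rec.eaf is None else 1.0 - rec.eaf,
            # allele labels belong to the target SNP; keep them but note the swap
            effect_allele=rec.effect_allele if best.same_effect_allele else rec.other_allele,
            other_allele=rec.other_allele if best.same_effect_allele else rec.effect_allele,
        )
        kept.append(proxied)
        log.append((rec.snp_id, f"proxied_by:{best.proxy_snp}"))
    return ProxyOutcome(kept, log)


def filter_weak(
    records: Sequence[InstrumentRecord],
    f_min: float = F_MIN,
) -> list[InstrumentRecord]:
    """Retain instruments with F ≥ ``f_min`` (weak instruments discarded)."""
    return [r for r in records if r.f_stat >= f_min]


def _align_outcome(
    ref: SummaryAssociation,
    other_ea: str,
    other_oa: str,
    beta: float,
    eaf: float | None,
    ref_eaf: float | None,
    palindrome_maf: float,
) -> tuple[str, float, float | None]:
    """Align one association (``other``) to ``ref``'s effect allele.

    Returns (action, aligned beta, aligned eaf).  Dropped rows keep their
    original numbers.
    """
    ea_x, oa_x = ref.effect_allele, ref.other_allele
    palindromic = {ea_x, oa_x} in ({"A", "T"}, {"C", "G"})

    if palindromic:
        if {other_ea, other_oa} != {ea_x, oa_x}:
            return "dropped_unresolvable", beta, eaf
        # Strand orientation is ambiguous for A/T and C/G pairs; resolve by
        # allele-frequency agreement, and refuse when the frequency is too
        # close to 0.5 on either side (or unknown) to call.
        if ref_eaf is None or eaf is None:
            return "dropped_palindromic", beta, eaf
        if min(ref_eaf, 1 - ref_eaf) > palindrome_maf or min(eaf, 1 - eaf) > palindrome_maf:
            return "dropped_palindromic", beta, eaf
        if (ref_eaf - 0.5) * (eaf - 0.5) < 0:
            return "sign_flipped", -beta, 1.0 - eaf
        return "unchanged", beta, eaf

    if (other_ea, other_oa) == (ea_x, oa_x):
        return "unchanged", beta, eaf
    if (other_ea, other_oa) == (oa_x, ea_x):
        return "sign_flipped", -beta, None if eaf is None else 1.0 - eaf
    comp_ea = _COMPLEMENT[other_ea]
    comp_oa = _COMPLEMENT[other_oa]
    if (comp_ea, comp_oa) == (ea_x, oa_x):
        return "strand_flipped", beta, eaf
    if (comp_ea, comp_oa) == (oa_x, ea_x):
        return (
            "strand_flipped_and_sign_flipped",
            -beta,
            None if eaf is None else 1.0 - eaf,
        )
    return "dropped_unresolvable", beta, eaf


def harmonize(
    exposure: Sequence[SummaryAssociation],
    outcome: Sequence[SummaryAssociation],
    palindrome_maf: float = PALINDROME_MAF,
) -> HarmonizedDataset:
    """Align outcome effects to the exposure's effect allele per shared SNP.

    Handles identical, allele-swapped and strand-flipped records; palindromic
    SNPs are oriented by allele-frequency agreement and dropped when the MAF
    exceeds ``palindrome_maf`` on either side (or when a frequency is
    missing).  SNPs absent from either dataset are ignored (intersection).
    """
    outcome_by_id = {r.snp_id: r for r in outcome}
    rows: list[HarmonizedRow] = []
    for exp in exposure:
        out = outcome_by_id.get(exp.snp_id)
        if out is None:
            continue
        action, beta_y, eaf_y = _align_outcome(
            exp,
            out.effect_allele,
            out.other_allele,
            out.beta,
            out.eaf,
            exp.eaf,
            palindrome_maf,
        )
        rows.append(
            HarmonizedRow(
                snp_id=exp.snp_id,
                beta_x=exp.beta,
                se_x=exp.se,
                beta_y=beta_y,
                se_y=out.se,
                eaf_x=exp.eaf,
                eaf_y=eaf_y,
                action=action,
            )
        )
    return HarmonizedDataset(rows)


def annotate_confounders(
    instruments: Sequence[str],
    annotations: AnnotationTable,
    confounder_traits: Sequence[str],
) -> dict[str, list[str]]:
    """Flag instruments annotated to any listed confounder trait.

    Returns every instrument mapped to the sorted subset of
    ``confounder_traits`` it is annotated to; an empty list means clean.
    """
    confounders = set(confounder_traits)
    return {
        snp: sorted(annotations.traits(snp) & confounders) for snp in instruments
    }
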