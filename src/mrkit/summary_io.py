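"""Core data model and tabular I/O for GWAS summary statistics.

Everything downstream (instrument selection, harmonization, the MR
estimators) consumes :class:`SummaryAssociation` records, pairwise LD
(:class:`LDTable`), proxy lookups (:class:`ProxyTable`) and trait
annotations (:class:`AnnotationTable`).  All on-disk formats are plain
tab-separated text with a header row and ``NA`` for missing values — the
dominant convention for distributed GWAS summary statistics.

SNPs are keyed by rsID throughout; positions are 1-based (VCF-style).
Only biallelic single-nucleotide variants are accepted: indels and
multi-allelic records are rejected at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

__all__ = [
    "SummaryAssociation",
    "LDTable",
    "ProxyTable",
    "ProxyEntry",
    "AnnotationTable",
    "SummaryFormatError",
    "SummaryRowError",
    "CANONICAL_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_table",
    "write_ld_table",
    "read_proxy_table",
    "read_annotations",
]

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order for summary-statistics TSVs.
CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

_MANDATORY = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")


class SummaryFormatError(ValueError):
    """A file-level format problem (e.g. a missing mandatory column)."""


class SummaryRowError(ValueError):
    """A row-level problem; carries the 1-based file line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (log odds for a binary trait); ``se`` its standard error; ``eaf`` the
    effect-allele frequency.  ``chrom``/``pos``/``eaf``/``n`` are optional.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    trait: str = ""

    def __post_init__(self):
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single-base A/C/G/T, got {ea}/{oa}"
            )
        if ea == oa:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0.0 <= self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval outside [0, 1]: {self.pval}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside (0, 1): {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True when the allele pair is its own reverse complement (A/T or C/G)."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, if ``eaf`` is known."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def flipped(self) -> "SummaryAssociation":
        """The same association expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


class LDTable:
    """Sparse symmetric pairwise r² lookup.

    Unlisted pairs are treated as r² = 0; a SNP with itself is r² = 1.
    """

    def __init__(self, entries: Iterable[tuple[str, str, float]] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in entries:
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise SummaryFormatError(f"r2 outside [0, 1] for pair ({a}, {b}): {r2}")
        if a != b:
            self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), r2 in sorted(self._r2.items()):
            yield a, b, r2


@dataclass(frozen=True)
class ProxyEntry:
    target_snp: str
    proxy_snp: str
    r2: float
    #: True when the proxy's effect allele tags the target's effect allele
    #: (same orientation); False when it tags the other allele.
    same_effect_allele: bool = True

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise SummaryFormatError(
                f"proxy r2 outside [0, 1] for ({self.target_snp}, {self.proxy_snp}): {self.r2}"
            )


class ProxyTable:
    """Candidate proxies per target SNP, with explicit allele orientation."""

    def __init__(self, entries: Iterable[ProxyEntry] = ()):
        self._by_target: dict[str, list[ProxyEntry]] = {}
        for e in entries:
            self._by_target.setdefault(e.target_snp, []).append(e)

    def candidates(self, target: str) -> list[ProxyEntry]:
        """Proxies for ``target``, best first (descending r², then rsID)."""
        return sorted(
            self._by_target.get(target, []),
            key=lambda e: (-e.r2, e.proxy_snp),
        )


class AnnotationTable:
    """SNP → trait annotations from a catalogue snapshot (PhenoScanner-style)."""

    def __init__(self, entries: Iterable[tuple[str, str]] = ()):
        self._traits: dict[str, set[str]] = {}
        for snp, trait in entries:
            self._traits.setdefault(snp, set()).add(trait)

    def traits(self, snp: str) -> set[str]:
        return set(self._traits.get(snp, ()))


# ---------------------------------------------------------------------------
# TSV readers / writers


def _parse_float(value, line: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SummaryRowError(line, f"non-numeric {column}: {value!r}") from None


def _is_na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip().upper() in ("", "NA", "NAN", ".")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryAssociation]:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps canonical field names (``snp``, ``beta``, ...) to the
    file's column names for non-canonical dialects.  Rows violating the data
    model (se ≤ 0, indel alleles, p outside [0, 1], ...) raise
    :class:`SummaryRowError` carrying the file line number.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colname = {canon: column_map.get(canon, canon) for canon in CANONICAL_COLUMNS}
    for canon in _MANDATORY:
        if colname[canon] not in df.columns:
            raise SummaryFormatError(
                f"missing mandatory column {colname[canon]!r} in {path}"
            )

    records: list[SummaryAssociation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header line
        get = lambda canon: getattr(row, colname[canon], None) if colname[canon] in df.columns else None
        beta = _parse_float(get("beta"), line, "beta")
        se = _parse_float(get("se"), line, "se")
        pval = _parse_float(get("pval"), line, "pval")
        eaf_raw = get("eaf")
        n_raw = get("n")
        pos_raw = get("pos")
        chrom_raw = get("chr")
        try:
            rec = SummaryAssociation(
                snp_id=str(get("snp")).strip(),
                effect_allele=str(get("effect_allele")).strip(),
                other_allele=str(get("other_allele")).strip(),
                beta=beta,
                se=se,
                pval=pval,
                chrom=None if _is_na(chrom_raw) else str(chrom_raw).strip(),
                pos=None if _is_na(pos_raw) else int(float(pos_raw)),
                eaf=None if _is_na(eaf_raw) else _parse_float(eaf_raw, line, "eaf"),
                n=None if _is_na(n_raw) else _parse_float(n_raw, line, "n"),
            )
        except ValueError as exc:
            if isinstance(exc, SummaryRowError):
                raise
            raise SummaryRowError(line, str(exc)) from None
        records.append(rec)
    return records


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def write_summary_stats(records: Sequence[SummaryAssociation], path: str | Path) -> None:
    """Write records as canonical TSV; ``NA`` for missing optional fields.

    ``read_summary_stats(write_summary_stats(x))`` is the identity on field
    values (floats use shortest round-trip formatting).
    """
    if not records:
        raise ValueError("refusing to write an empty summary-statistics file")
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.snp_id,
                        _fmt(r.chrom),
                        _fmt(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        _fmt(r.n),
                    )
                )
                + "\n"
            )


def read_ld_table(path: str | Path) -> LDTable:
    """Read a long-format LD table (snp_a, snp_b, r2); symmetric closure applied."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise SummaryFormatError(f"missing column {col!r} in LD table {path}")
    table = LDTable()
    for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
        table.add(str(a), str(b), float(r2))
    return table


def write_ld_table(table: LDTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for a, b, r2 in table.pairs():
            fh.write(f"{a}\t{b}\t{_fmt(r2)}\n")


def read_proxy_table(path: str | Path) -> ProxyTable:
    """Read (target_snp, proxy_snp, r2, same_effect_allele) rows."""
    df = pd.read_csv(path, sep="\t")
    for col in ("target_snp", "proxy_snp", "r2", "same_effect_allele"):
        if col not in df.columns:
            raise SummaryFormatError(f"missing column {col!r} in proxy table {path}")
    entries = [
        ProxyEntry(
            target_snp=str(t),
            proxy_snp=str(p),
            r2=float(r2),
            same_effect_allele=str(flag).strip().lower() in ("true", "1", "yes"),
        )
        for t, p, r2, flag in zip(
            df["target_snp"], df["proxy_snp"], df["r2"], df["same_effect_allele"]
        )
    ]
    return ProxyTable(entries)


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read (snp, trait) annotation rows."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp", "trait"):
        if col not in df.columns:
            raise SummaryFormatError(f"missing column {col!r} in annotation table {path}")
    return AnnotationTable((str(s), str(t)) for s, t in zip(df["snp"], df["trait"]))
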