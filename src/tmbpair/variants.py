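"""Somatic variant parsing and the two standard filter regimes.

Two filtering regimes are implemented:

* WGS ("Ratio method") quality filtering — drop poor-quality calls
  (depth < 15 reads or VAF < 0.05) and known germline polymorphisms
  (dbSNP-style membership, optionally a population-AF cut-off).
* Targeted-panel (Oncomine-style) filtering — SNVs only (indels and
  MNVs excluded), exonic/splice-site/intronic consequences, minimum
  coverage 60x, 5% limit of detection, and germline exclusion at a
  maximum population allele frequency of 1e-4 against dbSNP/ExAC/1000G
  style resources.

Threshold edge semantics follow the filter inequalities literally:
calls exactly at a minimum-depth/VAF threshold are kept ("depth < 15"
is removed, so depth == 15 survives); population AF strictly greater
than the cut-off is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "VariantCall",
    "FilterConfig",
    "FilterReport",
    "VcfParseReport",
    "read_vcf",
    "write_vcf",
    "annotate_known",
    "wgs_quality_filter",
    "germline_filter",
    "panel_filter",
]

SNV = "SNV"
INDEL = "indel"
MNV = "MNV"

CONSEQUENCES = ("exonic", "splice_site", "intronic", "other")
CONSEQUENCE_INFO_KEY = "CONSEQUENCE"


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(ref) == len(alt):
        return MNV
    return INDEL


@dataclass
class VariantCall:
    """One normalised somatic call (one record x one alternate allele)."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    depth: int
    alt_depth: int
    var_class: str = SNV
    consequence: str = "exonic"
    known_snp: bool = False
    pop_af: float | None = None

    def __post_init__(self) -> None:
        if self.depth < 0 or not (0 <= self.alt_depth <= max(self.depth, 0)):
            raise ValueError(
                f"inconsistent depths at {self.chrom}:{self.pos}: "
                f"depth={self.depth} alt_depth={self.alt_depth}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction: alt-supporting reads over total depth."""
        return self.alt_depth / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FilterConfig:
    """Thresholds for both filter regimes; defaults are the standard clinical values."""

    # WGS quality filter
    min_depth: int = 15
    min_vaf: float = 0.05
    include_indels: bool = False
    # germline filter
    max_pop_af: float = 0.0001
    filter_known_snp: bool = True
    # panel filter
    panel_min_coverage: int = 60
    panel_min_af: float = 0.05
    exclude_indels: bool = True
    allowed_consequences: frozenset[str] = frozenset(
        {"exonic", "splice_site", "intronic"}
    )

    def __post_init__(self) -> None:
        for name in ("min_vaf", "max_pop_af", "panel_min_af"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("min_depth", "panel_min_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.allowed_consequences = frozenset(self.allowed_consequences)


@dataclass
class FilterReport:
    """Removal tallies with first-failing-predicate attribution."""

    n_input: int = 0
    n_kept: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    removed_calls: list = field(default_factory=list)

    def remove(self, reason: str, call: "VariantCall | None" = None) -> None:
        self.removed[reason] = self.removed.get(reason, 0) + 1
        if call is not None:
            self.removed_calls.append((call, reason))

    @property
    def conserved(self) -> bool:
        return self.n_kept + sum(self.removed.values()) == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed": dict(sorted(self.removed.items())),
        }


@dataclass
class VcfParseReport:
    path: str = ""
    n_records: int = 0
    n_calls: int = 0
    n_multiallelic: int = 0
    n_missing_depth: int = 0
    n_nonpass_dropped: int = 0
    depth_source: str = ""


def _record_depths(rec, sample: str | None):
    """Recover (depth, per-alt alt depths) with FORMAT AD/DP precedence.

    Falls back to INFO DP + AD-like keys when no usable sample field
    exists.  Returns (depth, alt_depths, source) or None when no depth
    information is recoverable.
    """
    smp = None
    if rec.samples:
        names = list(rec.samples)
        smp = rec.samples[sample if sample is not None else names[0]]
    n_alt = len(rec.alts or ())
    if smp is not None:
        ad = smp.get("AD")
        dp = smp.get("DP")
        if ad is not None and ad[0] is not None:
            ad = list(ad)
            depth = int(dp) if dp is not None else int(sum(a or 0 for a in ad))
            return depth, [int(ad[1 + i] or 0) for i in range(n_alt)], "format"
        if dp is not None:
            return int(dp), None, "format_dp_only"
    def _info(key):
        # pysam raises on keys absent from the header, not just the record
        try:
            return rec.info.get(key)
        except (KeyError, ValueError):
            return None

    dp = _info("DP")
    ad = _info("AD")
    if ad is not None:
        ad = list(ad)
        depth = int(dp) if dp is not None else int(sum(ad))
        return depth, [int(ad[1 + i]) for i in range(n_alt)], "info"
    if dp is not None:
        af = _info("AF")
        if af is not None:
            afs = list(af) if isinstance(af, tuple) else [af]
            return int(dp), [round(float(a) * int(dp)) for a in afs], "info_dp_af"
        return int(dp), None, "info_dp_only"
    return None


def read_vcf(
    path: str | Path,
    sample: str | None = None,
    keep_nonpass: bool = False,
) -> tuple[list[VariantCall], VcfParseReport]:
    """Parse a VCF into normalised calls, splitting multi-allelic records.

    Per-allele VAF is that allele's AD over DP.  Records with no usable
    depth field anywhere are emitted with depth 0 (they fail every
    quality filter) and tallied in the parse report.  Non-PASS records
    are dropped by default: somatic quality filtering presupposes a
    caller-PASS baseline.
    """
    report = VcfParseReport(path=str(path))
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            if not keep_nonpass and filters and filters != ["PASS"]:
                report.n_nonpass_dropped += 1
                continue
            report.n_records += 1
            alts = rec.alts or ()
            if len(alts) > 1:
                report.n_multiallelic += 1
            got = _record_depths(rec, sample)
            try:
                consequence = rec.info.get(CONSEQUENCE_INFO_KEY, "exonic")
            except (KeyError, ValueError):
                consequence = "exonic"
            if isinstance(consequence, tuple):
                consequence = consequence[0]
            for i, alt in enumerate(alts):
                if got is None:
                    depth, alt_depth = 0, 0
                    report.n_missing_depth += 1
                else:
                    depth, alt_depths, source = got
                    report.depth_source = report.depth_source or source
                    if alt_depths is None:
                        alt_depth = 0
                        report.n_missing_depth += 1
                    else:
                        alt_depth = min(alt_depths[i], depth)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        depth=depth,
                        alt_depth=alt_depth,
                        var_class=classify_alleles(rec.ref, str(alt)),
                        consequence=str(consequence),
                    )
                )
                report.n_calls += 1
    return calls, report


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contigs: dict[str, int] | None = None,
    sample_name: str = "SAMPLE",
) -> None:
    """Re-emit calls as a minimal single-sample VCF 4.2 with DP/AD."""
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for c in calls:
            contigs[c.chrom] = max(contigs.get(c.chrom, 0), c.pos + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add(CONSEQUENCE_INFO_KEY, 1, "String", "Functional consequence class")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample_name)
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in ordered:
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
                filter="PASS",
            )
            rec.info[CONSEQUENCE_INFO_KEY] = c.consequence
            rec.samples[sample_name]["GT"] = (0, 1)
            rec.samples[sample_name]["DP"] = c.depth
            rec.samples[sample_name]["AD"] = (c.depth - c.alt_depth, c.alt_depth)
            out.write(rec)


def annotate_known(
    calls: Iterable[VariantCall], resource: str | Path
) -> list[VariantCall]:
    """Annotate known-SNP membership and population AF from a resource VCF.

    Matching requires full (chrom, pos, ref, alt) allele identity —
    positional matching alone would over-filter true somatic changes at
    polymorphic sites.  pop_af takes the maximum AF across matching
    resource records; resources without AF annotate membership only.
    """
    table: dict[tuple[str, int, str, str], float | None] = {}
    with pysam.VariantFile(str(resource)) as vf:
        for rec in vf:
            af = rec.info.get("AF")
            afs = list(af) if isinstance(af, tuple) else [af] * len(rec.alts or ())
            for i, alt in enumerate(rec.alts or ()):
                key = (rec.chrom, rec.pos, rec.ref, str(alt))
                new = float(afs[i]) if afs[i] is not None else None
                old = table.get(key)
                if key not in table or (new is not None and (old is None or new > old)):
                    table[key] = new
    out = []
    for c in calls:
        if c.key in table:
            out.append(replace(c, known_snp=True, pop_af=table[c.key]))
        else:
            out.append(c)
    return out


def wgs_quality_filter(
    calls: Iterable[VariantCall],
    cfg: FilterConfig | None = None,
    collect_removed: bool = False,
) -> tuple[list[VariantCall], FilterReport]:
    """Drop poor-quality calls: depth below 15 reads or VAF below 0.05.

    SNVs only by default (``cfg.include_indels`` admits indels/MNVs).
    Values exactly at a threshold are kept.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    report = FilterReport()
    for c in calls:
        report.n_input += 1
        rm = c if collect_removed else None
        if not cfg.include_indels and c.var_class != SNV:
            report.remove("not_snv", rm)
        elif c.depth < cfg.min_depth:
            report.remove("low_depth", rm)
        elif c.vaf < cfg.min_vaf:
            report.remove("low_vaf", rm)
        else:
            kept.append(c)
    report.n_kept = len(kept)
    return kept, report


def germline_filter(
    calls: Iterable[VariantCall],
    cfg: FilterConfig | None = None,
    collect_removed: bool = False,
) -> tuple[list[VariantCall], FilterReport]:
    """Remove known SNPs and calls whose population AF exceeds the cut-off.

    Unannotated pop_af is treated as 0 (kept).  Membership filtering can
    be switched off to use the AF cut-off alone.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    report = FilterReport()
    for c in calls:
        report.n_input += 1
        rm = c if collect_removed else None
        if cfg.filter_known_snp and c.known_snp:
            report.remove("known_snp", rm)
        elif (c.pop_af or 0.0) > cfg.max_pop_af:
            report.remove("pop_af", rm)
        else:
            kept.append(c)
    report.n_kept = len(kept)
    return kept, report


def panel_filter(
    calls: Iterable[VariantCall],
    cfg: FilterConfig | None = None,
    collect_removed: bool = False,
) -> tuple[list[VariantCall], FilterReport]:
    """Oncomine-style panel filter.

    Retains somatic SNVs (indels/MNVs excluded) with an allowed
    consequence class, coverage >= 60x, VAF >= the 5% limit of
    detection, and passing the germline filter at max population AF
    1e-4.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    report = FilterReport()
    for c in calls:
        report.n_input += 1
        rm = c if collect_removed else None
        if cfg.exclude_indels and c.var_class != SNV:
            report.remove("not_snv", rm)
        elif c.consequence not in cfg.allowed_consequences:
            report.remove("consequence", rm)
        elif c.depth < cfg.panel_min_coverage:
            report.remove("low_coverage", rm)
        elif c.vaf < cfg.panel_min_af:
            report.remove("low_af", rm)
        elif cfg.filter_known_snp and c.known_snp:
            report.remove("known_snp", rm)
        elif (c.pop_af or 0.0) > cfg.max_pop_af:
            report.remove("pop_af", rm)
        else:
            kept.append(c)
    report.n_kept = len(kept)
    return kept, report
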