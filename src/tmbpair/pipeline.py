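"""End-to-end runs: generate -> filter -> TMB -> concordance.

A run is driven by one declarative YAML/JSON config whose thresholds
default to the standard clinical filter regimes, so a bare config
applies the full filtering with no further tuning.  Outputs (TSV results table, JSON report,
JSON-lines log) are deterministic given the config and seed; every
dropped variant, excluded pair and QC-flagged sample appears in the
log with a reason code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .concordance import (
    ConcordanceReport,
    PairedPatient,
    kras_concordance,
    paired_concordance,
    pdl1_concordance,
)
from .regions import RegionSet, load_bed
from .stats import ddpcr_maf
from .tmb import TmbResult, classify_tmb, compute_tmb, zscore_standardise
from .variants import (
    FilterConfig,
    annotate_known,
    germline_filter,
    panel_filter,
    read_vcf,
    wgs_quality_filter,
)

__all__ = [
    "RunConfig",
    "SampleSpec",
    "RunResult",
    "load_run_config",
    "validate_config",
    "run_wgs",
    "run_panel",
]

QC_MIN_CELLULARITY_PCT = 20.0


class SampleSpec(BaseModel):
    patient_id: str
    site: Literal["site1", "site2"]
    vcf: Path
    site_label: str = ""
    tumour_cellularity_pct: Optional[float] = None


class FilterSettings(BaseModel):
    min_depth: int = 15
    min_vaf: float = 0.05
    include_indels: bool = False
    max_pop_af: float = 0.0001
    filter_known_snp: bool = True
    panel_min_coverage: int = 60
    panel_min_af: float = 0.05
    exclude_indels: bool = True
    allowed_consequences: list[str] = Field(
        default_factory=lambda: ["exonic", "splice_site", "intronic"]
    )

    def to_filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_depth=self.min_depth,
            min_vaf=self.min_vaf,
            include_indels=self.include_indels,
            max_pop_af=self.max_pop_af,
            filter_known_snp=self.filter_known_snp,
            panel_min_coverage=self.panel_min_coverage,
            panel_min_af=self.panel_min_af,
            exclude_indels=self.exclude_indels,
            allowed_consequences=frozenset(self.allowed_consequences),
        )


class StatsSettings(BaseModel):
    spearman_method: Literal["auto", "exact", "approx", "mc"] = "auto"
    mc_draws: int = 100_000


class RunConfig(BaseModel):
    """Declarative run description; thresholds default to the standard clinical values."""

    model_config = ConfigDict(extra="forbid")

    mode: Literal["wgs_ratio", "panel"]
    samples: list[SampleSpec]
    regions: dict[str, Path] = Field(default_factory=dict)
    panel_bed: Optional[Path] = None
    gaps: Optional[Path] = None
    germline_resource: Optional[Path] = None
    filters: FilterSettings = Field(default_factory=FilterSettings)
    cutoff: float = 10.0
    strict_cutoff: bool = False
    comparison_definition: str = "canonical"
    chr_prefix: Literal["none", "strip", "add"] = "none"
    stats: StatsSettings = Field(default_factory=StatsSettings)
    seed: int = 0
    output_dir: Optional[Path] = None
    ddpcr_table: Optional[Path] = None
    pdl1_table: Optional[Path] = None


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    base = Path(path).parent
    cfg = RunConfig.model_validate(data)
    # paths are interpreted relative to the config file
    def _abs(p: Optional[Path]) -> Optional[Path]:
        return None if p is None else (p if p.is_absolute() else base / p)

    cfg.panel_bed = _abs(cfg.panel_bed)
    cfg.gaps = _abs(cfg.gaps)
    cfg.germline_resource = _abs(cfg.germline_resource)
    cfg.ddpcr_table = _abs(cfg.ddpcr_table)
    cfg.pdl1_table = _abs(cfg.pdl1_table)
    cfg.output_dir = _abs(cfg.output_dir)
    cfg.regions = {k: _abs(v) for k, v in cfg.regions.items()}
    for s in cfg.samples:
        s.vcf = _abs(s.vcf)
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Collect every validation error at once; empty list means valid."""
    errors: list[str] = []
    seen: set[tuple[str, str]] = set()
    for s in cfg.samples:
        key = (s.patient_id, s.site)
        if key in seen:
            errors.append(f"duplicate sample: patient {s.patient_id} site {s.site}")
        seen.add(key)
        if not Path(s.vcf).is_file():
            errors.append(f"missing VCF: {s.vcf}")
        if s.tumour_cellularity_pct is not None and not (
            0 <= s.tumour_cellularity_pct <= 100
        ):
            errors.append(
                f"cellularity out of range for {s.patient_id}/{s.site}: "
                f"{s.tumour_cellularity_pct}"
            )
    if cfg.mode == "wgs_ratio":
        if not cfg.regions:
            errors.append("wgs_ratio mode requires at least one region definition")
        if cfg.regions and cfg.comparison_definition not in cfg.regions:
            errors.append(
                f"comparison_definition {cfg.comparison_definition!r} not among "
                f"region labels {sorted(cfg.regions)}"
            )
    else:
        if cfg.panel_bed is None:
            errors.append("panel mode requires panel_bed")
    for label, path in cfg.regions.items():
        if not Path(path).is_file():
            errors.append(f"missing region BED [{label}]: {path}")
    for name in ("panel_bed", "gaps", "germline_resource", "ddpcr_table", "pdl1_table"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).is_file():
            errors.append(f"missing {name}: {p}")
    if cfg.cutoff < 0:
        errors.append("cutoff must be >= 0")
    return errors


@dataclass
class RunResult:
    results: pd.DataFrame
    tmb_report: Optional[ConcordanceReport]
    kras_report: Optional[ConcordanceReport] = None
    pdl1_report: Optional[ConcordanceReport] = None
    logs: list = field(default_factory=list)

    def to_report_dict(self) -> dict:
        return {
            "results": self.results.to_dict(orient="records"),
            "tmb_concordance": None
            if self.tmb_report is None
            else self.tmb_report.to_dict(),
            "kras_concordance": None
            if self.kras_report is None
            else self.kras_report.to_dict(),
            "pdl1_concordance": None
            if self.pdl1_report is None
            else self.pdl1_report.to_dict(),
        }


def _load_region_definition(
    path: Path, label: str, gaps: Optional[RegionSet], chr_prefix: str
) -> RegionSet:
    rs = load_bed(path, label=label).with_chrom_prefix(chr_prefix).merge()
    if gaps is not None:
        rs = rs.subtract(gaps)
        rs.label = label
    return rs


def _cellularity_flags(cfg: RunConfig, logs: list) -> None:
    for s in cfg.samples:
        pct = s.tumour_cellularity_pct
        if pct is not None and pct < QC_MIN_CELLULARITY_PCT:
            logs.append(
                {
                    "event": "qc_flag",
                    "reason": "low_tumour_cellularity",
                    "patient_id": s.patient_id,
                    "site": s.site,
                    "tumour_cellularity_pct": pct,
                }
            )


def _log_removed(logs: list, sample: SampleSpec, stage: str, report) -> None:
    for call, reason in report.removed_calls:
        logs.append(
            {
                "event": "variant_removed",
                "stage": stage,
                "patient_id": sample.patient_id,
                "site": sample.site,
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "reason": reason,
            }
        )


def _attach_zscores(results: list[TmbResult], logs: list) -> None:
    by_def: dict[str, list[TmbResult]] = {}
    for r in results:
        by_def.setdefault(r.definition, []).append(r)
    for label, rs in by_def.items():
        try:
            z = zscore_standardise([r.tmb for r in rs])
        except Exception as exc:
            logs.append(
                {"event": "zscore_skipped", "definition": label, "reason": str(exc)}
            )
            continue
        for r, zi in zip(rs, z):
            r.zscore = float(zi)


def _pair_up(
    cfg: RunConfig, results: list[TmbResult], definition: str, logs: list
) -> list[PairedPatient]:
    by_patient: dict[str, dict[str, TmbResult]] = {}
    labels: dict[tuple[str, str], str] = {}
    for s in cfg.samples:
        labels[(s.patient_id, s.site)] = s.site_label or s.site
    for r in results:
        if r.definition != definition:
            continue
        site = "site1" if r.site.startswith("site1") else "site2"
        by_patient.setdefault(r.sample_id, {})[site] = r
    pairs = []
    for pid in sorted(by_patient):
        got = by_patient[pid]
        if "site1" not in got or "site2" not in got:
            logs.append(
                {
                    "event": "pair_excluded",
                    "patient_id": pid,
                    "reason": "missing_site",
                    "sites_present": sorted(got),
                }
            )
        pairs.append(
            PairedPatient(
                patient_id=pid,
                site1=got.get("site1"),
                site2=got.get("site2"),
                site1_label=labels.get((pid, "site1"), "site1"),
                site2_label=labels.get((pid, "site2"), "site2"),
            )
        )
    return pairs


def _write_outputs(cfg: RunConfig, result: RunResult) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(out / "results.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(result.to_report_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "log.jsonl", "w") as fh:
        for event in result.logs:
            fh.write(json.dumps(event, sort_keys=True) + "\n")


def _results_frame(results: list[TmbResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results]).sort_values(
        ["definition", "sample_id", "site"], kind="mergesort"
    ).reset_index(drop=True)


def run_wgs(cfg: RunConfig) -> RunResult:
    """WGS Ratio-method run over one or more exome definitions.

    Per sample and definition: quality filter -> germline filter ->
    count in (merged definition minus gaps) -> TMB ratio; z-scores per
    definition across samples; paired concordance on the designated
    comparison definition.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    if cfg.mode != "wgs_ratio":
        raise ValueError("run_wgs requires mode wgs_ratio")
    logs: list[dict] = []
    fcfg = cfg.filters.to_filter_config()
    gaps = (
        None
        if cfg.gaps is None
        else load_bed(cfg.gaps, label="gaps").with_chrom_prefix(cfg.chr_prefix).merge()
    )
    definitions = {
        label: _load_region_definition(path, label, gaps, cfg.chr_prefix)
        for label, path in sorted(cfg.regions.items())
    }
    for label, rs in definitions.items():
        logs.append(
            {
                "event": "definition_loaded",
                "definition": label,
                "callable_mb": round(rs.total_length_mb(), 6),
            }
        )

    results: list[TmbResult] = []
    for s in cfg.samples:
        calls, parse_report = read_vcf(s.vcf)
        logs.append({"event": "vcf_parsed", **parse_report.__dict__})
        kept, qreport = wgs_quality_filter(calls, fcfg, collect_removed=True)
        _log_removed(logs, s, "wgs_quality", qreport)
        if cfg.germline_resource is not None:
            kept = annotate_known(kept, cfg.germline_resource)
        kept, greport = germline_filter(kept, fcfg, collect_removed=True)
        _log_removed(logs, s, "germline", greport)
        n_in_any = 0
        for label, rs in definitions.items():
            r = compute_tmb(
                kept, rs, sample_id=s.patient_id, site=s.site,
                definition=label, cutoff=cfg.cutoff,
            )
            n_in_any = max(n_in_any, r.mutation_count)
            results.append(r)
        logs.append(
            {
                "event": "sample_filtered",
                "patient_id": s.patient_id,
                "site": s.site,
                "quality": qreport.to_dict(),
                "germline": greport.to_dict(),
                "in_region_fraction": round(n_in_any / max(len(kept), 1), 4),
            }
        )
    _attach_zscores(results, logs)
    for r in results:
        r.tmb_class = classify_tmb(r.tmb, cfg.cutoff, cfg.strict_cutoff)
    _cellularity_flags(cfg, logs)
    pairs = _pair_up(cfg, results, cfg.comparison_definition, logs)
    report = paired_concordance(
        pairs,
        cutoff=cfg.cutoff,
        strict_cutoff=cfg.strict_cutoff,
        spearman_method=cfg.stats.spearman_method,
        seed=cfg.seed,
    )
    result = RunResult(_results_frame(results), report, logs=logs)
    _write_outputs(cfg, result)
    return result


def _read_assay_tables(cfg: RunConfig, pairs: list[PairedPatient], logs: list) -> None:
    if cfg.ddpcr_table is not None:
        dd = pd.read_csv(cfg.ddpcr_table, sep="\t")
        maf: dict[tuple[str, str], float] = {}
        for row in dd.itertuples():
            maf[(str(row.patient_id), row.site)] = ddpcr_maf(
                int(row.n_total), int(row.n_mut_positive), int(row.n_wt_positive)
            )
        for p in pairs:
            p.kras_maf_site1 = maf.get((p.patient_id, "site1"))
            p.kras_maf_site2 = maf.get((p.patient_id, "site2"))
        logs.append({"event": "ddpcr_loaded", "n_rows": len(dd)})
    if cfg.pdl1_table is not None:
        cn = pd.read_csv(cfg.pdl1_table, sep="\t")
        cns: dict[tuple[str, str], float] = {}
        for row in cn.itertuples():
            cns[(str(row.patient_id), row.site)] = float(row.copy_number)
        for p in pairs:
            p.pdl1_cn_site1 = cns.get((p.patient_id, "site1"))
            p.pdl1_cn_site2 = cns.get((p.patient_id, "site2"))
        logs.append({"event": "pdl1_loaded", "n_rows": len(cn)})


def run_panel(cfg: RunConfig) -> RunResult:
    """Targeted-panel run: Oncomine-style filter, TMB over the panel footprint.

    When assay tables are supplied, KRAS (ddPCR droplet counts with
    Poisson correction) and PD-L1 copy-number concordance are reported
    alongside TMB.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    if cfg.mode != "panel":
        raise ValueError("run_panel requires mode panel")
    logs: list[dict] = []
    fcfg = cfg.filters.to_filter_config()
    gaps = (
        None
        if cfg.gaps is None
        else load_bed(cfg.gaps, label="gaps").with_chrom_prefix(cfg.chr_prefix).merge()
    )
    panel = _load_region_definition(cfg.panel_bed, "panel", gaps, cfg.chr_prefix)
    logs.append(
        {
            "event": "definition_loaded",
            "definition": "panel",
            "callable_mb": round(panel.total_length_mb(), 6),
        }
    )
    results: list[TmbResult] = []
    for s in cfg.samples:
        calls, parse_report = read_vcf(s.vcf)
        logs.append({"event": "vcf_parsed", **parse_report.__dict__})
        if cfg.germline_resource is not None:
            calls = annotate_known(calls, cfg.germline_resource)
        kept, preport = panel_filter(calls, fcfg, collect_removed=True)
        _log_removed(logs, s, "panel", preport)
        results.append(
            compute_tmb(
                kept, panel, sample_id=s.patient_id, site=s.site,
                definition="panel", cutoff=cfg.cutoff,
            )
        )
        logs.append(
            {
                "event": "sample_filtered",
                "patient_id": s.patient_id,
                "site": s.site,
                "panel": preport.to_dict(),
            }
        )
    _attach_zscores(results, logs)
    for r in results:
        r.tmb_class = classify_tmb(r.tmb, cfg.cutoff, cfg.strict_cutoff)
    _cellularity_flags(cfg, logs)
    pairs = _pair_up(cfg, results, "panel", logs)
    tmb_report = paired_concordance(
        pairs,
        cutoff=cfg.cutoff,
        strict_cutoff=cfg.strict_cutoff,
        spearman_method=cfg.stats.spearman_method,
        seed=cfg.seed,
    )
    _read_assay_tables(cfg, pairs, logs)
    kras_report = (
        kras_concordance(pairs, spearman_method=cfg.stats.spearman_method,
                         seed=cfg.seed)
        if cfg.ddpcr_table is not None
        else None
    )
    pdl1_report = (
        pdl1_concordance(pairs, spearman_method=cfg.stats.spearman_method,
                         seed=cfg.seed)
        if cfg.pdl1_table is not None
        else None
    )
    result = RunResult(_results_frame(results), tmb_report, kras_report,
                       pdl1_report, logs)
    _write_outputs(cfg, result)
    return result
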