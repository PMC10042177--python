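"""Synthetic paired primary/metastatic cohorts with known ground truth.

The generator emulates the paired EBUS-TBNA design on a toy genome
(two 10 Mb contigs): each patient carries a shared set of *trunk*
somatic mutations, acquired before metastatic divergence and present
at both sampled sites, plus *private* mutations specific to each
site.  On top of the somatic truth it plants the nuisance signals the
filters exist to remove — germline polymorphisms with
population allele frequencies (matchable against the emitted
germline-resource VCF) and sub-threshold artefact calls violating the
depth or VAF thresholds — and adds read-sampling noise: per-site
depth ~ Poisson(mean_depth) and alt reads ~ Binomial(depth, VAF) with
clonal VAF ~ Beta(alpha, beta).

Nested callable-region definitions mimic the three exome definitions
(canonical > CREv2-like > TCGA-like) plus a small targeted-panel
footprint and assembly-gap regions, all as BED-writable RegionSets.

Everything is reproducible from (config, seed); per-patient random
substreams are derived by stable hashing so adding a patient never
changes earlier patients' data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .regions import GenomicInterval, RegionSet, write_bed
from .variants import CONSEQUENCE_INFO_KEY, VariantCall, classify_alleles

__all__ = [
    "CohortConfig",
    "RegionBundle",
    "SimulatedPatient",
    "Cohort",
    "generate_regions",
    "generate_patient",
    "generate_cohort",
    "sample_positions",
]

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class CohortConfig:
    """Study conditions for one simulated paired cohort.

    Rates are per callable megabase; the defaults emulate an
    advanced-NSCLC cohort whose site TMB sits near the 10 mut/Mb
    cut-off, with mostly-truncal mutation burden and a modest private
    component (slightly larger at the metastatic site).
    """

    n_patients: int = 10
    contigs: dict = field(
        default_factory=lambda: {"chrS1": 10_000_000, "chrS2": 10_000_000}
    )
    segment_bp: int = 2_000
    exome_fraction: float = 0.5     # of the toy genome, "canonical"
    crev2_fraction: float = 0.88    # of canonical (67.3/76.3 Mb)
    tcga_fraction: float = 0.565    # of CREv2-like (38/67.3 Mb)
    panel_mb: float = 1.7           # targeted-panel footprint
    gap_fraction: float = 0.02      # assembly-gap fraction of the genome
    # somatic burden
    trunk_rate: float = 8.0                  # mutations / callable Mb
    private_rate_site1: float = 0.5
    private_rate_site2: float = 1.0
    indel_fraction: float = 0.05
    consequence_probs: dict = field(
        default_factory=lambda: {
            "exonic": 0.85,
            "splice_site": 0.05,
            "intronic": 0.08,
            "other": 0.02,
        }
    )
    # read sampling
    mean_depth: float = 60.0
    vaf_alpha: float = 3.5          # clonal VAF ~ Beta(3.5, 6.5), mean 0.35
    vaf_beta: float = 6.5
    # nuisance signals
    germline_rate: float = 2.0      # contaminant SNPs / callable Mb
    germline_common_fraction: float = 0.8   # AF ~ U(0.01, 0.5); else 10^U(-5,-3)
    artefact_rate: float = 2.0      # sub-threshold artefacts / callable Mb
    artefact_low_depth: tuple = (1, 14)
    artefact_low_vaf: tuple = (0.005, 0.04)
    # orthogonal assays
    kras_positive_fraction: float = 0.3
    kras_maf_alpha: float = 2.0     # positive-patient MAF ~ Beta(2, 8), mean 0.2
    kras_maf_beta: float = 8.0
    kras_negative_maf_max: float = 0.0005
    kras_site_log_sd: float = 0.2
    n_droplets: int = 20_000
    wt_lambda: float = 0.8          # wild-type copies per droplet
    pdl1_log_mean: float = math.log(2.5)
    pdl1_log_sd: float = 0.4
    pdl1_site_log_sd: float = 0.15
    cellularity_range: tuple = (18.0, 80.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("exome_fraction", "crev2_fraction", "tcga_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")
        genome_mb = sum(self.contigs.values()) / 1e6
        if self.panel_mb <= 0 or self.panel_mb > genome_mb * self.exome_fraction:
            raise ValueError("panel_mb must fit inside the canonical definition")
        for name in (
            "trunk_rate",
            "private_rate_site1",
            "private_rate_site2",
            "germline_rate",
            "artefact_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.kras_positive_fraction <= 1.0:
            raise ValueError("kras_positive_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["artefact_low_depth"] = list(self.artefact_low_depth)
        d["artefact_low_vaf"] = list(self.artefact_low_vaf)
        d["cellularity_range"] = list(self.cellularity_range)
        return d


def _substream(seed: int, *names: str) -> np.random.Generator:
    """Named RNG substream: stable across machines and patient order."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


@dataclass
class RegionBundle:
    canonical: RegionSet
    crev2: RegionSet
    tcga: RegionSet
    panel: RegionSet
    gaps: RegionSet

    @property
    def callable(self) -> RegionSet:
        """Canonical definition with assembly gaps removed (merged)."""
        rs = self.canonical.merge().subtract(self.gaps)
        rs.label = "canonical_callable"
        return rs

    def sizes_mb(self) -> dict:
        return {
            rs.label: rs.merge().total_length_mb()
            for rs in (self.canonical, self.crev2, self.tcga, self.panel, self.gaps)
        }


def _segments_to_regions(
    seg_ids: np.ndarray, contig_names: list, contig_offsets: np.ndarray,
    contig_lengths: list, segment_bp: int, label: str
) -> RegionSet:
    intervals = []
    for s in np.sort(seg_ids):
        ci = int(np.searchsorted(contig_offsets, s, side="right") - 1)
        local = int(s - contig_offsets[ci])
        start = local * segment_bp
        end = min(start + segment_bp, contig_lengths[ci])
        intervals.append(GenomicInterval(contig_names[ci], start, end))
    return RegionSet(intervals, label=label).merge()


def generate_regions(cfg: CohortConfig) -> RegionBundle:
    """Draw nested callable definitions by sampling genome segments.

    tcga-like < crev2-like < canonical, panel < canonical; gaps are
    drawn over the whole genome and therefore overlap the definitions.
    Deterministic given cfg.seed.
    """
    cfg.validate()
    rng = _substream(cfg.seed, "regions")
    names = list(cfg.contigs)
    lengths = [cfg.contigs[c] for c in names]
    n_segs = np.array([length // cfg.segment_bp for length in lengths])
    offsets = np.concatenate([[0], np.cumsum(n_segs)[:-1]])
    total = int(n_segs.sum())

    k_canon = int(round(cfg.exome_fraction * total))
    canon = rng.choice(total, size=k_canon, replace=False)
    k_crev2 = int(round(cfg.crev2_fraction * k_canon))
    crev2 = rng.choice(canon, size=k_crev2, replace=False)
    k_tcga = int(round(cfg.tcga_fraction * k_crev2))
    tcga = rng.choice(crev2, size=k_tcga, replace=False)
    k_panel = int(round(cfg.panel_mb * 1e6 / cfg.segment_bp))
    panel = rng.choice(canon, size=k_panel, replace=False)
    k_gap = int(round(cfg.gap_fraction * total))
    gaps = rng.choice(total, size=k_gap, replace=False)

    def build(ids, label):
        return _segments_to_regions(
            np.asarray(ids), names, offsets, lengths, cfg.segment_bp, label
        )

    return RegionBundle(
        canonical=build(canon, "canonical"),
        crev2=build(crev2, "crev2"),
        tcga=build(tcga, "tcga"),
        panel=build(panel, "panel"),
        gaps=build(gaps, "gaps"),
    )


def sample_positions(
    regions: RegionSet, n: int, rng: np.random.Generator
) -> list:
    """Uniformly sample n distinct 0-based positions within a merged set."""
    ivs = regions.intervals
    if not ivs or n == 0:
        return []
    lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total = int(cum[-1])
    if n > total:
        raise ValueError("more positions requested than available base pairs")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(0, total, size=n - len(chosen))
        chosen.update(int(v) for v in draw)
    out = []
    for flat in sorted(chosen):
        i = int(np.searchsorted(cum, flat, side="right") - 1)
        out.append((ivs[i].chrom, ivs[i].start + (flat - int(cum[i]))))
    return out


@dataclass
class SimulatedPatient:
    patient_id: str
    calls: dict                      # site -> list[VariantCall] as emitted
    truth_variants: pd.DataFrame     # one row per (site, variant)
    kras_maf: dict                   # site -> true mutant-allele fraction
    kras_positive: bool
    droplets: dict                   # site -> (n_total, n_mut_pos, n_wt_pos)
    pdl1_cn: dict                    # site -> true copy number
    cellularity: dict                # site -> % tumour cells
    trunk_count: int = 0
    callable_mb: float = 0.0


SITES = ("site1", "site2")


def _draw_alleles(rng: np.random.Generator, n: int, indel_fraction: float):
    refs, alts = [], []
    kinds = rng.random(n) < indel_fraction
    base_idx = rng.integers(0, 4, size=(n, 3))
    for i in range(n):
        b0 = BASES[base_idx[i, 0]]
        b1 = BASES[(base_idx[i, 0] + 1 + base_idx[i, 1] % 3) % 4]
        if kinds[i]:
            if base_idx[i, 2] % 2 == 0:
                refs.append(b0)
                alts.append(b0 + b1)      # insertion
            else:
                refs.append(b0 + b1)
                alts.append(b0)           # deletion
        else:
            refs.append(b0)
            alts.append(b1)
    return refs, alts


def _draw_consequences(rng: np.random.Generator, n: int, probs: dict) -> np.ndarray:
    labels = list(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def generate_patient(
    cfg: CohortConfig,
    regions: RegionBundle,
    patient_id: str,
    kras_positive: bool = False,
    build_truth: bool = True,
) -> SimulatedPatient:
    """Simulate one patient's two sites from the patient's own RNG substream.

    ``build_truth=False`` skips the per-variant truth table (the emitted
    calls and scalar truth are still returned) — useful for large
    replicate experiments where only the calls are consumed.
    """
    rng = _substream(cfg.seed, "patient", patient_id)
    callable_rs = regions.callable
    mb = callable_rs.total_length_mb()

    n_trunk = int(rng.poisson(cfg.trunk_rate * mb))
    n_priv = {
        "site1": int(rng.poisson(cfg.private_rate_site1 * mb)),
        "site2": int(rng.poisson(cfg.private_rate_site2 * mb)),
    }
    n_germ = int(rng.poisson(cfg.germline_rate * mb))
    n_art = {s: int(rng.poisson(cfg.artefact_rate * mb)) for s in SITES}

    # one shared draw of distinct positions keeps all planted keys unique
    n_all = n_trunk + sum(n_priv.values()) + n_germ + sum(n_art.values())
    positions = sample_positions(callable_rs, n_all, rng)
    rng.shuffle(positions)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = positions[cursor : cursor + k]
        cursor += k
        return out

    rows: list[dict] = []
    calls: dict[str, list[VariantCall]] = {s: [] for s in SITES}

    def emit(site, origin, chrom, pos0, ref, alt, consequence, true_vaf,
             depth, alt_depth, pop_af=None):
        emitted = depth >= 1 and alt_depth >= 1
        if not build_truth:
            if emitted:
                calls[site].append(
                    VariantCall(
                        chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                        depth=int(depth), alt_depth=int(alt_depth),
                        var_class=classify_alleles(ref, alt),
                        consequence=consequence,
                    )
                )
            return
        rows.append(
            {
                "patient_id": patient_id,
                "site": site,
                "origin": origin,
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alt": alt,
                "var_class": classify_alleles(ref, alt),
                "consequence": consequence,
                "true_vaf": true_vaf,
                "depth": depth,
                "alt_depth": alt_depth,
                "pop_af": pop_af,
                "emitted": emitted,
            }
        )
        if emitted:
            calls[site].append(
                VariantCall(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    depth=int(depth),
                    alt_depth=int(alt_depth),
                    var_class=classify_alleles(ref, alt),
                    consequence=consequence,
                )
            )

    # --- trunk: shared positions, shared clonal VAF, per-site read noise
    trunk_pos = take(n_trunk)
    refs, alts = _draw_alleles(rng, n_trunk, cfg.indel_fraction)
    csq = _draw_consequences(rng, n_trunk, cfg.consequence_probs)
    vafs = rng.beta(cfg.vaf_alpha, cfg.vaf_beta, size=n_trunk)
    for site in SITES:
        depths = rng.poisson(cfg.mean_depth, size=n_trunk)
        alt_d = rng.binomial(depths, vafs)
        for i, (chrom, p0) in enumerate(trunk_pos):
            emit(site, "trunk", chrom, p0, refs[i], alts[i], str(csq[i]),
                 float(vafs[i]), int(depths[i]), int(alt_d[i]))

    # --- site-private mutations
    for site in SITES:
        k = n_priv[site]
        ppos = take(k)
        refs, alts = _draw_alleles(rng, k, cfg.indel_fraction)
        csq = _draw_consequences(rng, k, cfg.consequence_probs)
        vafs = rng.beta(cfg.vaf_alpha, cfg.vaf_beta, size=k)
        depths = rng.poisson(cfg.mean_depth, size=k)
        alt_d = rng.binomial(depths, vafs)
        for i, (chrom, p0) in enumerate(ppos):
            emit(site, "private", chrom, p0, refs[i], alts[i], str(csq[i]),
                 float(vafs[i]), int(depths[i]), int(alt_d[i]))

    # --- germline contaminants: shared genotype, annotated AF mixture
    gpos = take(n_germ)
    refs, alts = _draw_alleles(rng, n_germ, 0.0)
    common = rng.random(n_germ) < cfg.germline_common_fraction
    af = np.where(
        common,
        rng.uniform(0.01, 0.5, size=n_germ),
        10.0 ** rng.uniform(-5, -3, size=n_germ),
    )
    hom = rng.random(n_germ) < 1.0 / 3.0
    gvaf = np.where(hom, 1.0, 0.5)
    for site in SITES:
        depths = rng.poisson(cfg.mean_depth, size=n_germ)
        alt_d = rng.binomial(depths, gvaf)
        for i, (chrom, p0) in enumerate(gpos):
            emit(site, "germline", chrom, p0, refs[i], alts[i], "exonic",
                 float(gvaf[i]), int(depths[i]), int(alt_d[i]),
                 pop_af=float(af[i]))

    # --- sub-threshold artefacts: half depth-violating, half VAF-violating
    for site in SITES:
        k = n_art[site]
        apos = take(k)
        refs, alts = _draw_alleles(rng, k, 0.0)
        low_depth = rng.random(k) < 0.5
        for i, (chrom, p0) in enumerate(apos):
            if low_depth[i]:
                depth = int(rng.integers(cfg.artefact_low_depth[0],
                                         cfg.artefact_low_depth[1] + 1))
                v = float(rng.beta(cfg.vaf_alpha, cfg.vaf_beta))
                alt_d = max(1, int(rng.binomial(depth, v)))
            else:
                depth = max(int(rng.poisson(cfg.mean_depth)), 25)
                v = float(rng.uniform(*cfg.artefact_low_vaf))
                cap = int(0.049 * depth)
                alt_d = min(max(1, int(rng.binomial(depth, v))), cap)
            emit(site, "artefact", chrom, p0, refs[i], alts[i], "exonic",
                 v, depth, alt_d)

    # --- orthogonal assays
    if kras_positive:
        maf1 = float(rng.beta(cfg.kras_maf_alpha, cfg.kras_maf_beta))
        maf1 = max(maf1, 0.01)
        maf2 = min(0.95, maf1 * float(rng.lognormal(0.0, cfg.kras_site_log_sd)))
    else:
        maf1 = float(rng.uniform(0.0, cfg.kras_negative_maf_max))
        maf2 = float(rng.uniform(0.0, cfg.kras_negative_maf_max))
    kras = {"site1": maf1, "site2": maf2}
    droplets = {}
    for site in SITES:
        maf = kras[site]
        lam_wt = cfg.wt_lambda
        lam_mut = maf / (1.0 - maf) * lam_wt
        n_mut = int(rng.binomial(cfg.n_droplets, 1.0 - math.exp(-lam_mut)))
        n_wt = int(rng.binomial(cfg.n_droplets, 1.0 - math.exp(-lam_wt)))
        droplets[site] = (cfg.n_droplets, n_mut, n_wt)

    cn1 = float(rng.lognormal(cfg.pdl1_log_mean, cfg.pdl1_log_sd))
    cn2 = cn1 * float(rng.lognormal(0.0, cfg.pdl1_site_log_sd))
    cellularity = {
        s: float(rng.uniform(*cfg.cellularity_range)) for s in SITES
    }

    for site in SITES:
        calls[site].sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    if build_truth:
        truth = pd.DataFrame(rows).sort_values(
            ["site", "chrom", "pos"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        truth = pd.DataFrame()
    return SimulatedPatient(
        patient_id=patient_id,
        calls=calls,
        truth_variants=truth,
        kras_maf=kras,
        kras_positive=kras_positive,
        droplets=droplets,
        pdl1_cn={"site1": cn1, "site2": cn2},
        cellularity=cellularity,
        trunk_count=n_trunk,
        callable_mb=mb,
    )


@dataclass
class Cohort:
    config: CohortConfig
    regions: RegionBundle
    patients: list

    @property
    def germline_records(self) -> list:
        """Union of planted germline variants (chrom, pos, ref, alt, max AF)."""
        table: dict[tuple, float] = {}
        for p in self.patients:
            g = p.truth_variants
            g = g[(g.origin == "germline") & (g.site == "site1")]
            for row in g.itertuples():
                key = (row.chrom, row.pos, row.ref, row.alt)
                # AF is a population property; planted per patient, dedupe by max
                af = getattr(row, "pop_af", None)
                table[key] = max(table.get(key, 0.0), af if af is not None else 0.0)
        return sorted((k + (v,)) for k, v in table.items())

    def truth_variant_table(self) -> pd.DataFrame:
        return pd.concat(
            [p.truth_variants for p in self.patients], ignore_index=True
        )

    def truth_patient_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "trunk_count": p.trunk_count,
                    "callable_mb": p.callable_mb,
                    "kras_positive": p.kras_positive,
                    "kras_maf_site1": p.kras_maf["site1"],
                    "kras_maf_site2": p.kras_maf["site2"],
                    "pdl1_cn_site1": p.pdl1_cn["site1"],
                    "pdl1_cn_site2": p.pdl1_cn["site2"],
                    "cellularity_site1": p.cellularity["site1"],
                    "cellularity_site2": p.cellularity["site2"],
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path, overwrite: bool = False) -> dict:
        """Write VCFs, BEDs, assay tables, truth tables and a manifest."""
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()) and not overwrite:
            raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
        outdir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        files: list[Path] = []

        for rs, name in (
            (self.regions.canonical, "canonical"),
            (self.regions.crev2, "crev2"),
            (self.regions.tcga, "tcga"),
            (self.regions.panel, "panel"),
            (self.regions.gaps, "gaps"),
        ):
            path = outdir / f"{name}.bed"
            write_bed(rs, path)
            files.append(path)

        for p in self.patients:
            for site in SITES:
                path = outdir / f"{p.patient_id}_{site}.vcf"
                _write_site_vcf(p.calls[site], path, cfg.contigs,
                                f"{p.patient_id}_{site}")
                files.append(path)

        files.append(self._write_germline_resource(outdir / "germline_resource.vcf"))

        ddpcr = []
        pdl1 = []
        cellularity = []
        for p in self.patients:
            for site in SITES:
                n_total, n_mut, n_wt = p.droplets[site]
                ddpcr.append(
                    {
                        "patient_id": p.patient_id,
                        "site": site,
                        "n_total": n_total,
                        "n_mut_positive": n_mut,
                        "n_wt_positive": n_wt,
                    }
                )
                pdl1.append(
                    {
                        "patient_id": p.patient_id,
                        "site": site,
                        "copy_number": round(p.pdl1_cn[site], 4),
                    }
                )
                cellularity.append(
                    {
                        "patient_id": p.patient_id,
                        "site": site,
                        "tumour_cellularity_pct": round(p.cellularity[site], 1),
                    }
                )
        for name, rows in (
            ("ddpcr_kras.tsv", ddpcr),
            ("pdl1_cn.tsv", pdl1),
            ("cellularity.tsv", cellularity),
        ):
            path = outdir / name
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            files.append(path)

        path = outdir / "truth_variants.tsv"
        self.truth_variant_table().to_csv(path, sep="\t", index=False)
        files.append(path)
        path = outdir / "truth_patients.tsv"
        self.truth_patient_table().to_csv(path, sep="\t", index=False)
        files.append(path)

        cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
        manifest = {
            "config": cfg.to_dict(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "region_sizes_mb": {
                k: round(v, 6) for k, v in self.regions.sizes_mb().items()
            },
            "callable_mb": round(self.regions.callable.total_length_mb(), 6),
            "files": {
                f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                for f in sorted(files)
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest

    def _write_germline_resource(self, path: Path) -> Path:
        header = pysam.VariantHeader()
        for chrom, length in self.config.contigs.items():
            header.contigs.add(chrom, length=length)
        header.info.add("AF", "A", "Float", "Population allele frequency")
        # pop AF lives on the germline truth rows
        table: dict[tuple, float] = {}
        for p in self.patients:
            g = p.truth_variants
            g = g[(g.origin == "germline") & (g.site == "site1")]
            for row in g.itertuples():
                key = (row.chrom, int(row.pos), row.ref, row.alt)
                table[key] = max(table.get(key, 0.0), float(row.pop_af))
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for (chrom, pos, ref, alt), af in sorted(table.items()):
                rec = out.new_record(
                    contig=chrom,
                    start=pos - 1,
                    stop=pos - 1 + len(ref),
                    alleles=(ref, alt),
                )
                rec.info["AF"] = (af,)
                out.write(rec)
        return path


def _write_site_vcf(
    calls: Sequence[VariantCall], path: Path, contigs: dict, sample_name: str
) -> None:
    from .variants import write_vcf

    write_vcf(calls, path, contigs=contigs, sample_name=sample_name)


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a full in-memory cohort; use Cohort.write() to persist it.

    The number of KRAS-positive patients is exact
    (round(fraction * n_patients)), echoing a detected-positives count
    rather than a Binomial draw, so the planted truth is stated, not
    stochastic.
    """
    cfg.validate()
    regions = generate_regions(cfg)
    rng = _substream(cfg.seed, "cohort")
    n_pos = int(round(cfg.kras_positive_fraction * cfg.n_patients))
    pos_ids = set(
        rng.choice(cfg.n_patients, size=n_pos, replace=False).tolist()
    )
    patients = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        patients.append(
            generate_patient(cfg, regions, pid, kras_positive=i in pos_ids)
        )
    return Cohort(config=cfg, regions=regions, patients=patients)
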