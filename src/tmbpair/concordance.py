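"""Paired primary/metastatic concordance analysis.

For each patient the same biomarker is measured at two EBUS-sampled
sites (site 1 = primary or first site, site 2 = metastatic/nodal
site).  Cohort-level agreement is summarised by Spearman correlation
and the paired Wilcoxon test, and per-patient agreement by comparing
dichotomised classes: TMB high/low at 10 mutations/Mb, KRAS mutation
presence at 0.2% mutant-allele fraction.  PD-L1 copy number has no
established cut-off and is compared on values only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stats import (
    SpearmanResult,
    WilcoxonResult,
    InsufficientDataError,
    UndefinedCorrelationError,
    spearman,
    wilcoxon_paired,
)
from .tmb import TMB_CUTOFF, TmbResult, classify_tmb

__all__ = [
    "PairedPatient",
    "PairClass",
    "ConcordanceReport",
    "paired_concordance",
    "kras_concordance",
    "pdl1_concordance",
    "KRAS_MAF_CUTOFF",
]

KRAS_MAF_CUTOFF = 0.002  # 0.2% mutant allele frequency


@dataclass
class PairedPatient:
    """One patient's two sampled sites and their per-site measurements."""

    patient_id: str
    site1: TmbResult | None = None
    site2: TmbResult | None = None
    kras_maf_site1: float | None = None
    kras_maf_site2: float | None = None
    pdl1_cn_site1: float | None = None
    pdl1_cn_site2: float | None = None
    site1_label: str = "site1"
    site2_label: str = "site2"

    def has_tmb_pair(self) -> bool:
        if self.site1 is None or self.site2 is None:
            return False
        return self.site1.definition == self.site2.definition


@dataclass
class PairClass:
    patient_id: str
    value1: float
    value2: float
    class1: str
    class2: str

    @property
    def concordant(self) -> bool:
        return self.class1 == self.class2

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "value_site1": round(self.value1, 6),
            "value_site2": round(self.value2, 6),
            "class_site1": self.class1,
            "class_site2": self.class2,
            "concordant": self.concordant,
        }


def _summary(values: Sequence[float]) -> dict:
    x = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    # The dispersion around the median is reported both ways (IQR and SD)
    # since either may be wanted alongside a median.
    return {
        "median": float(med),
        "iqr": (float(q1), float(q3)),
        "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
    }


@dataclass
class ConcordanceReport:
    """Cohort-level paired-site agreement for one analyte."""

    analyte: str
    n_pairs: int
    spearman: SpearmanResult | None
    wilcoxon: WilcoxonResult | None
    per_patient: list[PairClass] = field(default_factory=list)
    summary_site1: dict = field(default_factory=dict)
    summary_site2: dict = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def n_discordant(self) -> int:
        return sum(1 for p in self.per_patient if not p.concordant)

    def to_dict(self) -> dict:
        sp = self.spearman
        wx = self.wilcoxon
        return {
            "analyte": self.analyte,
            "n_pairs": self.n_pairs,
            "spearman_rho": None if sp is None else round(sp.rho, 6),
            "spearman_p": None if sp is None else round(sp.p, 6),
            "wilcoxon_stat": None if wx is None else wx.statistic,
            "wilcoxon_p": None if wx is None else round(wx.p, 6),
            "wilcoxon_degenerate": None if wx is None else wx.degenerate,
            "n_discordant": self.n_discordant,
            "per_patient": [p.to_dict() for p in self.per_patient],
            "median_site1": self.summary_site1,
            "median_site2": self.summary_site2,
            "excluded_patients": list(self.excluded),
            "notes": list(self.notes),
        }


def _paired_stats(
    analyte: str,
    ids: list[str],
    v1: list[float],
    v2: list[float],
    classes: list[tuple[str, str]] | None,
    excluded: list[str],
    spearman_method: str = "auto",
    seed: int | None = None,
) -> ConcordanceReport:
    report = ConcordanceReport(
        analyte=analyte,
        n_pairs=len(ids),
        spearman=None,
        wilcoxon=None,
        excluded=excluded,
    )
    if not ids:
        report.notes.append("no complete pairs")
        return report
    if classes is not None:
        report.per_patient = [
            PairClass(i, a, b, c1, c2)
            for i, a, b, (c1, c2) in zip(ids, v1, v2, classes)
        ]
    report.summary_site1 = _summary(v1)
    report.summary_site2 = _summary(v2)
    try:
        report.spearman = spearman(v1, v2, method=spearman_method, seed=seed)
    except (InsufficientDataError, UndefinedCorrelationError) as exc:
        report.notes.append(f"spearman: {exc}")
    report.wilcoxon = wilcoxon_paired(v1, v2)
    if report.wilcoxon.degenerate:
        report.notes.append("wilcoxon: all paired differences zero")
    return report


def paired_concordance(
    pairs: Iterable[PairedPatient],
    cutoff: float = TMB_CUTOFF,
    strict_cutoff: bool = False,
    spearman_method: str = "auto",
    seed: int | None = None,
) -> ConcordanceReport:
    """TMB concordance: discordant iff the two sites' high/low classes differ.

    Patients missing either site (or compared under different region
    definitions) are excluded pairwise and listed in the report.
    """
    ids: list[str] = []
    v1: list[float] = []
    v2: list[float] = []
    classes: list[tuple[str, str]] = []
    excluded: list[str] = []
    for p in pairs:
        if not p.has_tmb_pair():
            excluded.append(p.patient_id)
            continue
        ids.append(p.patient_id)
        v1.append(p.site1.tmb)
        v2.append(p.site2.tmb)
        classes.append(
            (
                classify_tmb(p.site1.tmb, cutoff, strict_cutoff),
                classify_tmb(p.site2.tmb, cutoff, strict_cutoff),
            )
        )
    return _paired_stats(
        "TMB", ids, v1, v2, classes, excluded, spearman_method, seed
    )


def kras_concordance(
    pairs: Iterable[PairedPatient],
    cutoff: float = KRAS_MAF_CUTOFF,
    spearman_method: str = "auto",
    seed: int | None = None,
) -> ConcordanceReport:
    """KRAS mutation presence at the 0.2% MAF assay cut-off, both sites."""
    ids, v1, v2, classes, excluded = [], [], [], [], []
    for p in pairs:
        if p.kras_maf_site1 is None or p.kras_maf_site2 is None:
            excluded.append(p.patient_id)
            continue
        ids.append(p.patient_id)
        v1.append(p.kras_maf_site1)
        v2.append(p.kras_maf_site2)
        classes.append(
            (
                "positive" if p.kras_maf_site1 >= cutoff else "negative",
                "positive" if p.kras_maf_site2 >= cutoff else "negative",
            )
        )
    return _paired_stats(
        "KRAS_MAF", ids, v1, v2, classes, excluded, spearman_method, seed
    )


def pdl1_concordance(
    pairs: Iterable[PairedPatient],
    spearman_method: str = "auto",
    seed: int | None = None,
) -> ConcordanceReport:
    """PD-L1 copy-number agreement on values only (no established cut-off)."""
    ids, v1, v2, excluded = [], [], [], []
    for p in pairs:
        if p.pdl1_cn_site1 is None or p.pdl1_cn_site2 is None:
            excluded.append(p.patient_id)
            continue
        ids.append(p.patient_id)
        v1.append(p.pdl1_cn_site1)
        v2.append(p.pdl1_cn_site2)
    return _paired_stats(
        "PDL1_CN", ids, v1, v2, None, excluded, spearman_method, seed
    )


def plot_paired_scatter(report: ConcordanceReport, ax=None, cutoff: float | None = None):
    """Site-1 vs site-2 scatter for a report (simple QC figure)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x = [p.value1 for p in report.per_patient]
    y = [p.value2 for p in report.per_patient]
    ax.scatter(x, y, c="k", s=20)
    if cutoff is not None:
        ax.axhline(cutoff, ls="--", c="grey", lw=0.8)
        ax.axvline(cutoff, ls="--", c="grey", lw=0.8)
    lim = max(x + y) * 1.1 if x else 1.0
    ax.plot([0, lim], [0, lim], c="grey", lw=0.8)
    ax.set_xlabel(f"{report.analyte} site 1")
    ax.set_ylabel(f"{report.analyte} site 2")
    return ax
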