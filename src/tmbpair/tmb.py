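"""TMB scoring: the Ratio method, panel-mode TMB, z-scores and the clinical cut-off.

TMB ("Ratio method") is the number of filtered somatic calls that fall
inside a merged, gap-subtracted callable region set, divided by the set's
size in megabases.  Scores computed against different exome definitions
are made comparable by per-definition z-score standardisation, and
dichotomised high/low at the immunotherapy cut-off of 10 mutations/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .regions import RegionSet
from .variants import FilterConfig, VariantCall, panel_filter

__all__ = [
    "TmbResult",
    "count_callable",
    "tmb_ratio",
    "zscore_standardise",
    "classify_tmb",
    "panel_tmb",
    "compute_tmb",
    "DegenerateDenominatorError",
    "ZeroSpreadError",
    "TMB_CUTOFF",
]

TMB_CUTOFF = 10.0  # mutations per Mb

SITE1 = "site1_primary"
SITE2 = "site2_metastatic"


class DegenerateDenominatorError(ZeroDivisionError):
    """Raised when the callable-region denominator is zero or negative."""


class ZeroSpreadError(ValueError):
    """Raised when z-scores are requested for scores with no spread."""


@dataclass
class TmbResult:
    """TMB for one sample against one callable-region definition."""

    sample_id: str
    site: str
    definition: str
    mutation_count: int
    callable_mb: float
    tmb: float
    zscore: float | None = None
    tmb_class: str | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "site": self.site,
            "definition": self.definition,
            "mutation_count": self.mutation_count,
            "callable_mb": round(self.callable_mb, 6),
            "tmb": round(self.tmb, 2),
            "zscore": None if self.zscore is None else round(self.zscore, 4),
            "tmb_class": self.tmb_class,
        }


def count_callable(calls: Iterable[VariantCall], regions: RegionSet) -> int:
    """Number of calls inside the region set (1-based pos -> 0-based membership)."""
    calls = list(calls)
    if not calls:
        return 0
    chroms = [c.chrom for c in calls]
    pos0 = [c.pos - 1 for c in calls]
    return int(regions.contains_many(chroms, pos0).sum())


def tmb_ratio(mutation_count: int, callable_mb: float) -> float:
    """Callable mutations per callable megabase."""
    if callable_mb <= 0:
        raise DegenerateDenominatorError(
            f"callable_mb must be positive, got {callable_mb}"
        )
    if mutation_count < 0:
        raise ValueError("mutation_count must be >= 0")
    return mutation_count / callable_mb


def zscore_standardise(scores: Sequence[float]) -> np.ndarray:
    """Standardise one definition's scores across samples to mean 0, sd 1.

    Uses the sample standard deviation (n-1).  Zero spread raises rather
    than silently returning zeros.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ZeroSpreadError("need >= 2 scores to standardise")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroSpreadError("z-scores undefined: zero spread")
    return (x - x.mean()) / sd


def classify_tmb(tmb: float, cutoff: float = TMB_CUTOFF, strict: bool = False) -> str:
    """Dichotomise at the clinical cut-off; 'high' at tmb >= cutoff by default."""
    if tmb < 0:
        raise ValueError("tmb must be >= 0")
    high = tmb > cutoff if strict else tmb >= cutoff
    return "high" if high else "low"


def compute_tmb(
    calls: Iterable[VariantCall],
    regions: RegionSet,
    sample_id: str = "sample",
    site: str = "other",
    definition: str | None = None,
    cutoff: float = TMB_CUTOFF,
) -> TmbResult:
    """Count already-filtered calls in a merged callable set and form the ratio."""
    n = count_callable(calls, regions)
    mb = regions.total_length_mb()
    tmb = tmb_ratio(n, mb)
    return TmbResult(
        sample_id=sample_id,
        site=site,
        definition=definition or regions.label,
        mutation_count=n,
        callable_mb=mb,
        tmb=tmb,
        tmb_class=classify_tmb(tmb, cutoff),
    )


def panel_tmb(
    calls: Iterable[VariantCall],
    panel_regions: RegionSet,
    cfg: FilterConfig | None = None,
    sample_id: str = "sample",
    site: str = "other",
    cutoff: float = TMB_CUTOFF,
) -> TmbResult:
    """Panel-mode TMB: panel filter, count in the panel footprint, divide by its Mb.

    The denominator is the measured span of the supplied panel regions,
    not a nominal kit size; the nominal 1.7 Mb figure is metadata.
    """
    cfg = cfg or FilterConfig()
    kept, _ = panel_filter(calls, cfg)
    merged = panel_regions.merge()
    return compute_tmb(kept, merged, sample_id, site, merged.label, cutoff)
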