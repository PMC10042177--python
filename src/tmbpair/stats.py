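"""Paired nonparametric statistics and assay quantification helpers.

Small paired cohorts (n ~ 10) need exact small-sample p-values:

* Wilcoxon signed-rank — zero differences dropped (Wilcoxon convention);
  exact null distribution when the effective n <= 25 with no tied
  absolute differences, otherwise a normal approximation with
  continuity correction.  Two-sided throughout.
* Spearman rank correlation — average-rank ties; exact permutation
  p-value for n <= 9 by full enumeration, a t-approximation above,
  and an optional seeded Monte-Carlo permutation mode.

Also here: ddPCR mutant-allele fraction from droplet counts with
Poisson correction, and TaqMan-style copy number from ddCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "WilcoxonResult",
    "spearman",
    "wilcoxon_paired",
    "ddpcr_maf",
    "copy_number_from_ddct",
    "ALPHA",
]

ALPHA = 0.05


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    p: float
    n_effective: int
    method: str
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p < ALPHA


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("zero variance: rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x,
    y,
    method: str = "auto",
    exact_max_n: int = 9,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> SpearmanResult:
    """Spearman rho with an exact permutation p-value at small n.

    method: "auto" (exact for n <= exact_max_n, else t-approximation),
    "exact", "approx", or "mc" (seeded Monte-Carlo permutations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 for Spearman, got {n}")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)

    if method == "auto":
        method = "exact" if n <= exact_max_n else "approx"

    if method == "exact":
        # Full enumeration of y-rank permutations against fixed x ranks.
        obs = abs(rho)
        hits = total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            total += 1
            if abs(r) >= obs - 1e-12:
                hits += 1
        return SpearmanResult(rho, hits / total, n, "exact")
    if method == "mc":
        rng = np.random.default_rng(seed)
        obs = abs(rho)
        hits = 0
        for _ in range(n_mc):
            r = np.corrcoef(rx, rng.permutation(ry))[0, 1]
            if abs(r) >= obs - 1e-12:
                hits += 1
        return SpearmanResult(rho, (hits + 1) / (n_mc + 1), n, "mc")
    if method == "approx":
        res = sps.spearmanr(x, y)
        return SpearmanResult(rho, float(res.pvalue), n, "approx")
    raise ValueError(f"unknown method {method!r}")


def wilcoxon_paired(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; if every difference is zero the
    result is degenerate (statistic 0, p = 1) and flagged rather than
    raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be 1-D, equal length, n >= 1")
    d = x - y
    d = d[d != 0]
    n_eff = d.size
    if n_eff == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    ties = np.unique(np.abs(d)).size < n_eff
    if n_eff <= 25 and not ties:
        method, corr = "exact", False
    else:
        method, corr = "approx", True
    res = sps.wilcoxon(d, zero_method="wilcox", correction=corr, method=method)
    return WilcoxonResult(
        float(res.statistic), float(res.pvalue), int(n_eff), method
    )


def ddpcr_maf(
    n_total: int,
    n_mut_positive: int,
    n_wt_positive: int,
    poisson_correction: bool = True,
) -> float:
    """Mutant-allele fraction from ddPCR droplet counts.

    With Poisson correction, per-channel target concentration is
    lambda = -ln(N_negative / N_total) copies per droplet, and the
    fractional abundance is lambda_mut / (lambda_mut + lambda_wt).
    Without correction, the raw positive-droplet fraction is used.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_mut_positive < n_total and 0 <= n_wt_positive < n_total):
        raise ValueError("positive-droplet counts must lie in [0, n_total)")
    if poisson_correction:
        lam_mut = -math.log(1.0 - n_mut_positive / n_total)
        lam_wt = -math.log(1.0 - n_wt_positive / n_total)
    else:
        lam_mut, lam_wt = float(n_mut_positive), float(n_wt_positive)
    if lam_mut + lam_wt == 0:
        return 0.0
    return lam_mut / (lam_mut + lam_wt)


def copy_number_from_ddct(
    ct_target_sample: float,
    ct_reference_sample: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
    calibrator_copies: float = 2.0,
) -> float:
    """Copy number from TaqMan-style Ct values: CN = copies_cal * 2^(-ddCt).

    dCt = Ct_target - Ct_reference per sample; ddCt is the sample dCt
    minus the two-copy calibrator's dCt.
    """
    dct_sample = ct_target_sample - ct_reference_sample
    dct_cal = ct_target_calibrator - ct_reference_calibrator
    return calibrator_copies * 2.0 ** (-(dct_sample - dct_cal))
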