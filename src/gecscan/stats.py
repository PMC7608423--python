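"""Collapsing (COLL) and single-marker association statistics.

The collapsing test dichotomizes individuals by carrier status of >= 1 minor
allele in a region and applies a Pearson 1-df chi-square test (no continuity
correction) to the resulting 2x2 carrier-by-phenotype table. The
single-marker test (SMA) is the allelic 2x2 Pearson chi-square on
minor-allele counts. Odds ratios use Woolf's log-OR normal interval; a zero
cell leaves OR and CI undefined rather than applying a correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .bitset import CarrierSet
from .io import MISSING, Phenotype

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054  # standard normal 97.5% quantile

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "pearson_chi2_1df",
    "odds_ratio_woolf",
    "coll_test",
    "sma_test",
    "chi2_from_counts",
    "chi2_pvalue",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier-by-phenotype table: a/c = case carriers/non-carriers,
    b/d = control carriers/non-carriers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    """A single association test: chi2 statistic, upper-tail 1-df p value,
    odds ratio and Woolf 95% CI (None when a cell is zero)."""

    statistic: float
    p: float
    or_est: Optional[float] = None
    ci95: Optional[Tuple[float, float]] = None


def chi2_from_counts(a, m, n_case, n_total):
    """Vectorized Pearson 1-df chi2 from carrier counts.

    Parameters
    ----------
    a : array-like
        Case carriers.
    m : array-like
        Total carriers (a + b).
    n_case, n_total : int
        Fixed margins.

    Every path in the package (scalar tests, fast permutation engine, naive
    rescan) evaluates the statistic through this one function, so results
    are bit-identical across code paths. Zero margins give statistic 0.
    """
    a = np.asarray(a, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    n_case = float(n_case)
    n_total = float(n_total)
    b = m - a
    c = n_case - a
    d = n_total - m - c
    num = n_total * (a * d - b * c) ** 2
    den = m * (n_total - m) * n_case * (n_total - n_case)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return stat


def chi2_pvalue(stat):
    """Upper-tail probability of chi2(1 df); floored at float tiny to keep
    p in (0, 1]."""
    p = _chi2_dist.sf(stat, 1)
    return np.maximum(p, np.finfo(np.float64).tiny)


def pearson_chi2_1df(table: ContingencyTable2x2) -> Tuple[float, float]:
    """Pearson 1-df chi-square on a 2x2 table, no continuity correction.

    Degenerate margins (no carriers at all, or everyone a carrier) give
    statistic 0 and p = 1.
    """
    stat = float(
        chi2_from_counts(table.a, table.a + table.b, table.a + table.c, table.n)
    )
    return stat, float(chi2_pvalue(stat))


def odds_ratio_woolf(
    table: ContingencyTable2x2,
) -> Tuple[Optional[float], Optional[Tuple[float, float]]]:
    """Odds ratio (ad)/(bc) with Woolf's 95% CI; undefined on any zero cell."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return None, None
    or_est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_est)
    return float(or_est), (
        float(np.exp(log_or - Z975 * se)),
        float(np.exp(log_or + Z975 * se)),
    )


def carrier_table(carriers: CarrierSet, phenotype: Phenotype) -> ContingencyTable2x2:
    """2x2 carrier-by-phenotype table via masked popcount."""
    if carriers.n != phenotype.n:
        raise ValueError(
            f"carrier set length {carriers.n} != phenotype length {phenotype.n}"
        )
    a = carriers.intersection_count(phenotype.case_mask)
    m = carriers.popcount
    return ContingencyTable2x2(
        a=a, b=m - a, c=phenotype.n_case - a, d=phenotype.n_control - (m - a)
    )


def coll_test(carriers: CarrierSet, phenotype: Phenotype) -> TestResult:
    """Collapsing test of one carrier set against case/control status.

    Counting case carriers for the fixed carrier set is the only
    phenotype-dependent step; the permutation engine relies on this.
    """
    table = carrier_table(carriers, phenotype)
    stat, p = pearson_chi2_1df(table)
    or_est, ci = odds_ratio_woolf(table)
    return TestResult(statistic=stat, p=p, or_est=or_est, ci95=ci)


def sma_test(dosages: np.ndarray, phenotype: Phenotype) -> TestResult:
    """Single-marker allelic test for one variant site.

    Builds the 2x2 minor-vs-major allele count table over cases and
    controls (missing genotypes excluded) and applies the Pearson 1-df
    chi-square; the statistic is invariant under allele orientation, so raw
    ALT dosages may be passed.
    """
    dos = np.asarray(dosages)
    if dos.size != phenotype.n:
        raise ValueError("dosage row length does not match phenotype")
    nonmiss = dos != MISSING
    if not nonmiss.any():
        logger.warning("all genotypes missing at a site; p = 1")
        return TestResult(statistic=0.0, p=1.0)
    cases = phenotype.labels == 1
    a = int(dos[nonmiss & cases].sum())  # minor alleles in cases
    b = int(dos[nonmiss & ~cases].sum())
    alleles_case = 2 * int((nonmiss & cases).sum())
    alleles_ctrl = 2 * int((nonmiss & ~cases).sum())
    table = ContingencyTable2x2(a=a, b=b, c=alleles_case - a, d=alleles_ctrl - b)
    stat, p = pearson_chi2_1df(table)
    or_est, ci = odds_ratio_woolf(table)
    return TestResult(statistic=stat, p=p, or_est=or_est, ci95=ci)
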