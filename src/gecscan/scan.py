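"""Exhaustive collapsing scan over all locally distinct contiguous bins.

For a chromosome with n rare-variant sites there are n(n+1)/2 contiguous
bins, but the collapsing statistic only depends on a bin's carrier set, and
carrier sets change only when extending or trimming a bin actually adds or
removes carriers. The scan walks every start index i, grows the union
U = B(i, j) to the right, and

* stops the inner loop when U equals the union without the leftmost variant
  (B(i+1, j)) -- every longer bin from this start repeats a carrier set seen
  from start i+1 -- or when U covers all individuals;
* skips evaluation when the next variant adds no carriers (U == B(i, j+1));
* otherwise evaluates the collapsing test on U: a locally distinct bin.

Since B(i+1, j) is a subset of U and U a subset of B(i, j+1), the equality
tests reduce to popcount comparisons; with integer bitmasks they are plain
``==``. The emitted carrier sets are exactly the distinct non-full carrier
sets over all n(n+1)/2 bins (checked against brute force in the tests), so
the minimum p over emitted bins equals the brute-force minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bitset import CarrierSet
from .io import Phenotype, VariantPanel
from .stats import (
    TestResult,
    chi2_from_counts,
    chi2_pvalue,
    coll_test,
    odds_ratio_woolf,
    ContingencyTable2x2,
)

__all__ = [
    "DistinctBin",
    "ScanResult",
    "scan_chromosome",
    "brute_force_scan",
    "scan_study",
    "enumerate_distinct_bins",
    "study_min_p",
]


@dataclass
class DistinctBin:
    """A locally distinct contiguous bin and its collapsing-test result.

    ``i``/``j`` are 0-based inclusive variant indices into the panel;
    ``pos_start``/``pos_end`` are the 1-based positions of those variants.
    """

    maf_t: float
    chrom: str
    i: int
    j: int
    pos_start: int
    pos_end: int
    n_variants: int
    carriers: CarrierSet
    case_carriers: int
    control_carriers: int
    result: TestResult


@dataclass
class ScanResult:
    """All locally distinct bins of a study, across chromosomes and MAF
    thresholds, with per-threshold and combined minimum p values."""

    bins: list[DistinctBin]
    min_p_combined: float
    min_p_by_threshold: dict[float, float]
    n_bins_total: int
    n_bins_naive: int

    def bins_by_threshold(self, maf_t: float) -> list[DistinctBin]:
        return [b for b in self.bins if b.maf_t == maf_t]


def enumerate_distinct_bins(masks: Sequence[int], n_individuals: int, case_mask: int):
    """Core pruning loop: emit (i, j, union mask, popcount, case carriers)
    for every locally distinct, non-full bin.

    Phenotype enters only through ``case_mask`` (for the case-carrier
    popcount); the emitted (i, j, mask) triples are phenotype-independent.
    """
    n = len(masks)
    full = (1 << n_individuals) - 1
    out_i: list[int] = []
    out_j: list[int] = []
    out_mask: list[int] = []
    out_m: list[int] = []
    out_a: list[int] = []
    for i in range(n):
        u = masks[i]
        v = 0
        j = i
        while True:
            if u == v or u == full:
                break
            if j + 1 < n:
                u_next = u | masks[j + 1]
                if u_next != u:
                    out_i.append(i)
                    out_j.append(j)
                    out_mask.append(u)
                    out_m.append(u.bit_count())
                    out_a.append((u & case_mask).bit_count())
                j += 1
                v |= masks[j]
                u = u_next
            else:
                out_i.append(i)
                out_j.append(j)
                out_mask.append(u)
                out_m.append(u.bit_count())
                out_a.append((u & case_mask).bit_count())
                break
    return out_i, out_j, out_mask, out_m, out_a


def _bins_from_counts(
    panel: VariantPanel,
    phenotype: Phenotype,
    idx_i: list[int],
    idx_j: list[int],
    masks: list[int],
    m: list[int],
    a: list[int],
) -> list[DistinctBin]:
    n = phenotype.n
    stats = chi2_from_counts(a, m, phenotype.n_case, n)
    pvals = chi2_pvalue(stats)
    positions = panel.positions
    bins = []
    for k in range(len(idx_i)):
        b = m[k] - a[k]
        table = ContingencyTable2x2(
            a=a[k], b=b, c=phenotype.n_case - a[k], d=phenotype.n_control - b
        )
        or_est, ci = odds_ratio_woolf(table)
        bins.append(
            DistinctBin(
                maf_t=panel.maf_t,
                chrom=panel.chrom,
                i=idx_i[k],
                j=idx_j[k],
                pos_start=int(positions[idx_i[k]]),
                pos_end=int(positions[idx_j[k]]),
                n_variants=idx_j[k] - idx_i[k] + 1,
                carriers=CarrierSet(masks[k], n),
                case_carriers=a[k],
                control_carriers=b,
                result=TestResult(
                    statistic=float(stats[k]), p=float(pvals[k]), or_est=or_est, ci95=ci
                ),
            )
        )
    return bins


def scan_chromosome(panel: VariantPanel, phenotype: Phenotype) -> list[DistinctBin]:
    """Scan one chromosome panel, returning every locally distinct bin with
    its collapsing-test result."""
    if len(panel) == 0:
        return []
    for cs in panel.carriers:
        if cs.is_empty:
            raise ValueError("panel contains an empty carrier set")
        if cs.n != phenotype.n:
            raise ValueError("carrier sets and phenotype differ in length")
    idx_i, idx_j, masks, m, a = enumerate_distinct_bins(
        panel.masks(), phenotype.n, phenotype.case_mask
    )
    return _bins_from_counts(panel, phenotype, idx_i, idx_j, masks, m, a)


def brute_force_scan(panel: VariantPanel, phenotype: Phenotype):
    """Evaluate every one of the n(n+1)/2 contiguous bins explicitly.

    Test oracle for :func:`scan_chromosome`; quadratic, intended for small
    panels. Returns (i, j, CarrierSet, TestResult) tuples.
    """
    masks = panel.masks()
    n = len(masks)
    out = []
    for i in range(n):
        u = 0
        for j in range(i, n):
            u |= masks[j]
            cs = CarrierSet(u, phenotype.n)
            out.append((i, j, cs, coll_test(cs, phenotype)))
    return out


def scan_study(
    panels: Iterable[VariantPanel], phenotype: Phenotype
) -> ScanResult:
    """Scan every (chromosome, MAF threshold) panel and aggregate.

    The same physical bin found under two thresholds counts as two tests.
    A threshold with no bins contributes min p = 1.
    """
    panels = list(panels)
    if not panels or all(len(p) == 0 for p in panels):
        raise ValueError("no variants pass thresholds")
    bins: list[DistinctBin] = []
    naive = 0
    for panel in panels:
        n = len(panel)
        naive += n * (n + 1) // 2
        bins.extend(scan_chromosome(panel, phenotype))
    thresholds = sorted({p.maf_t for p in panels})
    min_p_by_threshold = {}
    for t in thresholds:
        ps = [b.result.p for b in bins if b.maf_t == t]
        min_p_by_threshold[t] = min(ps) if ps else 1.0
    return ScanResult(
        bins=bins,
        min_p_combined=min(min_p_by_threshold.values()),
        min_p_by_threshold=min_p_by_threshold,
        n_bins_total=len(bins),
        n_bins_naive=naive,
    )


def study_min_p(panels: Iterable[VariantPanel], phenotype: Phenotype) -> float:
    """Genome-wide minimum collapsing p over all panels, without
    materializing bin objects (used for power and calibration replicates)."""
    best_stat = 0.0
    any_bins = False
    for panel in panels:
        if len(panel) == 0:
            continue
        _, _, _, m, a = enumerate_distinct_bins(
            panel.masks(), phenotype.n, phenotype.case_mask
        )
        if not m:
            continue
        any_bins = True
        stats = chi2_from_counts(a, m, phenotype.n_case, phenotype.n)
        best_stat = max(best_stat, float(stats.max()))
    if not any_bins:
        return 1.0
    return float(chi2_pvalue(best_stat))
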