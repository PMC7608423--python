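"""Permutation-based family-wise error rate control.

Genome-wide significance thresholds come from the distribution of the
minimum p value over all bins (and optionally all single markers) under
random permutation of case/control labels. Because MAF filtering and bin
enumeration never look at the phenotype, bins are enumerated once and only
the case-carrier counts are recomputed per permutation; this fast path is
bit-identical to naively re-running the whole scan per replicate (the tests
check this).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .bitset import bools_from_mask
from .io import MISSING, GenotypeTable, Phenotype, VariantPanel
from .scan import enumerate_distinct_bins, scan_study
from .stats import chi2_from_counts, chi2_pvalue, sma_test

logger = logging.getLogger(__name__)

__all__ = [
    "MinPDistribution",
    "ThresholdSet",
    "permuted_phenotype",
    "minp_distribution",
    "empirical_threshold",
    "adjusted_p",
    "sma_min_p",
]

_CHUNK = 128  # permutation replicates per matmul chunk


@dataclass
class MinPDistribution:
    """Per-replicate genome-wide minimum p values under label permutation."""

    r: int
    minp_combined: np.ndarray
    minp_by_threshold: dict[float, np.ndarray]
    minp_sma: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def vector(self, scope) -> np.ndarray:
        """Min-p vector for scope 'combined', 'sma' or a MAF threshold."""
        if scope == "combined":
            return self.minp_combined
        if scope == "sma":
            if self.minp_sma is None:
                raise ValueError("SMA min-p values were not recorded")
            return self.minp_sma
        return self.minp_by_threshold[float(scope)]


@dataclass
class ThresholdSet:
    """Empirical significance thresholds at a nominal FWER level;
    significance is declared for observed p strictly below alpha."""

    fwer: float
    alpha_combined: float
    alpha_by_threshold: dict[float, float]
    alpha_sma: Optional[float] = None


def permuted_phenotype(phenotype: Phenotype, rng: np.random.Generator) -> Phenotype:
    """Uniform random permutation of the case/control labels."""
    return Phenotype(rng.permutation(phenotype.labels))


def _bin_matrix(masks: list[int], n: int) -> np.ndarray:
    """Stack bin carrier masks into a (n_bins, n) float32 0/1 matrix."""
    nbytes = (n + 7) // 8
    raw = b"".join(m.to_bytes(nbytes, "little") for m in masks)
    packed = np.frombuffer(raw, dtype=np.uint8).reshape(len(masks), nbytes)
    bits = np.unpackbits(packed, axis=1, bitorder="little")[:, :n]
    return bits.astype(np.float32)


def _max_chi2_per_replicate(
    carrier: np.ndarray, m: np.ndarray, labels32: np.ndarray, n_case: int, n: int
) -> np.ndarray:
    """Max chi2 over bins for each permutation column of ``labels32``.

    ``carrier`` is (n_bins, n) float32 0/1; case-carrier counts come from one
    BLAS matmul per chunk. Sums of 0/1 are exact in float32 for n < 2^24, so
    the integer counts (and hence chi2 values) match the naive path exactly.
    """
    r = labels32.shape[1]
    out = np.empty(r, dtype=np.float64)
    for lo in range(0, r, _CHUNK):
        hi = min(lo + _CHUNK, r)
        a = carrier @ labels32[:, lo:hi]  # (n_bins, chunk), exact integers
        stats = chi2_from_counts(a, m[:, None], n_case, n)
        out[lo:hi] = stats.max(axis=0)
    return out


def sma_min_p(genotypes: GenotypeTable, phenotype: Phenotype) -> float:
    """Minimum single-marker allelic p over all sites of a study."""
    if genotypes.n_sites == 0:
        return 1.0
    return float(
        min(sma_test(genotypes.dosages[k], phenotype).p for k in range(genotypes.n_sites))
    )


def _sma_minp_matrix(
    genotypes: GenotypeTable, labels32: np.ndarray
) -> np.ndarray:
    """Per-replicate minimum SMA p, vectorized over sites and permutations."""
    dos = genotypes.dosages
    nonmiss = (dos != MISSING).astype(np.float32)
    dos0 = np.where(dos == MISSING, 0, dos).astype(np.float32)
    minor_total = dos0.sum(axis=1)  # per site
    alleles_total = 2 * nonmiss.sum(axis=1)
    r = labels32.shape[1]
    out = np.empty(r, dtype=np.float64)
    for lo in range(0, r, _CHUNK):
        hi = min(lo + _CHUNK, r)
        a = dos0 @ labels32[:, lo:hi]  # minor alleles in cases
        alleles_case = 2 * (nonmiss @ labels32[:, lo:hi])
        # allele margins vary per replicate when genotypes are missing, so
        # chi2 is computed from the four cells directly
        stats = _chi2_general(a, minor_total[:, None] - a, alleles_case - a,
                              alleles_total[:, None] - minor_total[:, None]
                              - (alleles_case - a))
        out[lo:hi] = stats.max(axis=0)
    return chi2_pvalue(out)


def _chi2_general(a, b, c, d):
    """Pearson 1-df chi2 from four cell arrays (float64, same arithmetic as
    :func:`gecscan.stats.chi2_from_counts`)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def minp_distribution(
    panels: Iterable[VariantPanel],
    phenotype: Phenotype,
    r: int,
    rng: np.random.Generator,
    include_sma: bool = False,
    genotypes: Optional[GenotypeTable] = None,
    method: str = "fast",
) -> MinPDistribution:
    """Distribution of genome-wide minimum p under label permutation.

    ``method='fast'`` enumerates bins once and re-counts case carriers per
    replicate; ``method='naive'`` re-runs the full scan per replicate. Both
    consume the identical permutation stream and give bit-identical results.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if include_sma and genotypes is None:
        raise ValueError("include_sma requires the genotype table")
    panels = list(panels)
    n = phenotype.n
    perms = np.empty((n, r), dtype=np.int8)
    for k in range(r):
        perms[:, k] = rng.permutation(phenotype.labels)

    thresholds = sorted({p.maf_t for p in panels})
    if method == "naive":
        minp_thr = {t: np.empty(r) for t in thresholds}
        for k in range(r):
            ph = Phenotype(perms[:, k])
            res = scan_study(panels, ph)
            for t in thresholds:
                minp_thr[t][k] = res.min_p_by_threshold[t]
        minp_sma = None
        if include_sma:
            minp_sma = np.array(
                [sma_min_p(genotypes, Phenotype(perms[:, k])) for k in range(r)]
            )
    elif method == "fast":
        labels32 = perms.astype(np.float32)
        minp_thr = {}
        for t in thresholds:
            max_stat = np.zeros(r, dtype=np.float64)
            any_bins = False
            for panel in (p for p in panels if p.maf_t == t):
                if len(panel) == 0:
                    continue
                _, _, masks, m, _ = enumerate_distinct_bins(
                    panel.masks(), n, phenotype.case_mask
                )
                if not masks:
                    continue
                any_bins = True
                carrier = _bin_matrix(masks, n)
                mm = np.asarray(m, dtype=np.float64)
                stat = _max_chi2_per_replicate(
                    carrier, mm, labels32, phenotype.n_case, n
                )
                max_stat = np.maximum(max_stat, stat)
            minp_thr[t] = (
                chi2_pvalue(max_stat) if any_bins else np.ones(r, dtype=np.float64)
            )
        minp_sma = _sma_minp_matrix(genotypes, labels32) if include_sma else None
    else:
        raise ValueError(f"unknown method: {method!r}")

    minp_combined = np.min(np.vstack([minp_thr[t] for t in thresholds]), axis=0)
    return MinPDistribution(
        r=r,
        minp_combined=minp_combined,
        minp_by_threshold=minp_thr,
        minp_sma=minp_sma,
    )


def _order_stat_alpha(values: np.ndarray, fwer: float, r: int) -> float:
    k = int(np.floor(fwer * (r + 1)))
    if k == 0:
        raise ValueError(
            f"r={r} replicates are too few for fwer={fwer}; "
            f"need r >= {int(np.ceil(1 / fwer)) - 1} (raise r)"
        )
    return float(np.sort(values)[k - 1])


def empirical_threshold(dist: MinPDistribution, fwer: float = 0.05) -> ThresholdSet:
    """Empirical alpha = k-th smallest min-p with k = floor(fwer * (r + 1));
    declare significance for observed p < alpha (strict)."""
    if not (0 < fwer < 1):
        raise ValueError("fwer must be in (0, 1)")
    if dist.r < 1 / fwer:
        warnings.warn(
            f"r={dist.r} < 1/fwer={1 / fwer:.0f}: threshold estimate is coarse",
            stacklevel=2,
        )
    alpha_combined = _order_stat_alpha(dist.minp_combined, fwer, dist.r)
    if alpha_combined >= 1.0:
        warnings.warn(
            "all permutation min-p values are 1; every p < 1 will be "
            "declared significant (degenerate panels?)",
            stacklevel=2,
        )
    alpha_by_threshold = {
        t: _order_stat_alpha(v, fwer, dist.r)
        for t, v in dist.minp_by_threshold.items()
    }
    alpha_sma = (
        _order_stat_alpha(dist.minp_sma, fwer, dist.r)
        if dist.minp_sma is not None
        else None
    )
    return ThresholdSet(
        fwer=fwer,
        alpha_combined=alpha_combined,
        alpha_by_threshold=alpha_by_threshold,
        alpha_sma=alpha_sma,
    )


def adjusted_p(p: float, dist: MinPDistribution, scope: str = "combined") -> float:
    """Min-p FWER-adjusted p value: (1 + #{min-p <= p}) / (r + 1)."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    v = dist.vector(scope)
    return float((1 + int((v <= p).sum())) / (dist.r + 1))
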