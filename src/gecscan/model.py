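"""Model/results interface to the exhaustive collapsing scan.

:class:`ExhaustiveCollapsingScan` is built from a genotype table and a
phenotype (or directly from a VCF + phenotype file, or from a simulation
config); its :meth:`~ExhaustiveCollapsingScan.fit` runs the scan at the
requested MAF thresholds, calibrates permutation significance thresholds
and returns a :class:`ScanResults` carrying the bins, thresholds, adjusted
p values, merged blocks and a text ``summary()``.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import (
    GenotypeTable,
    Phenotype,
    orient_and_filter,
    read_phenotype,
    read_vcf,
)
from .permutation import (
    MinPDistribution,
    ThresholdSet,
    adjusted_p,
    empirical_threshold,
    minp_distribution,
)
from .report import SignificantBlock, merge_significant_blocks, write_results
from .scan import ScanResult, scan_study
from .simulate import DiseaseSimConfig, NullSimConfig, simulate_disease_study, simulate_null_study

__all__ = ["ExhaustiveCollapsingScan", "ScanResults"]

DEFAULT_THRESHOLDS = (0.01, 0.03, 0.05)


class ExhaustiveCollapsingScan:
    """Exhaustive rare-variant collapsing scan of a case-control study.

    Parameters
    ----------
    genotypes : GenotypeTable
        Variant-major ALT dosages plus site metadata.
    phenotype : Phenotype
        Case/control labels aligned to the genotype sample order.
    maf_thresholds : sequence of float
        MAF thresholds; each defines a separate rare-variant panel and the
        combined analysis takes the minimum over all of them.
    """

    def __init__(
        self,
        genotypes: GenotypeTable,
        phenotype: Phenotype,
        maf_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    ):
        if genotypes.n_individuals != phenotype.n:
            raise ValueError("genotypes and phenotype differ in sample count")
        if not maf_thresholds:
            raise ValueError("need at least one MAF threshold")
        for t in maf_thresholds:
            if not (0 < t <= 0.5):
                raise ValueError(f"MAF threshold {t} outside (0, 0.5]")
        self.genotypes = genotypes
        self.phenotype = phenotype
        self.maf_thresholds = tuple(sorted(maf_thresholds))
        self.panels = [
            panel
            for t in self.maf_thresholds
            for panel in orient_and_filter(genotypes, t)
        ]

    @classmethod
    def from_vcf(
        cls,
        vcf_path,
        phenotype_path,
        maf_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
        samples: Optional[Sequence[str]] = None,
    ) -> "ExhaustiveCollapsingScan":
        gt = read_vcf(vcf_path, samples=samples)
        ph = read_phenotype(phenotype_path, gt.samples)
        return cls(gt, ph, maf_thresholds)

    @classmethod
    def from_simulation(
        cls,
        config: Union[NullSimConfig, DiseaseSimConfig],
        rng: Optional[np.random.Generator] = None,
        maf_thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    ) -> "ExhaustiveCollapsingScan":
        if isinstance(config, DiseaseSimConfig):
            gt, ph, _ = simulate_disease_study(config, rng)
        else:
            gt, ph = simulate_null_study(config, rng)
        return cls(gt, ph, maf_thresholds)

    def fit(
        self,
        permutations: int = 999,
        fwer: float = 0.05,
        seed: Optional[int] = None,
        include_sma: bool = False,
    ) -> "ScanResults":
        """Run the scan and calibrate permutation thresholds.

        Returns a :class:`ScanResults`. With ``include_sma`` the
        single-marker min-p distribution and threshold are computed on the
        same permutations.
        """
        scan = scan_study(self.panels, self.phenotype)
        rng = np.random.default_rng(seed)
        dist = minp_distribution(
            self.panels,
            self.phenotype,
            r=permutations,
            rng=rng,
            include_sma=include_sma,
            genotypes=self.genotypes if include_sma else None,
        )
        dist.seed = seed
        thresholds = empirical_threshold(dist, fwer)
        return ScanResults(self, scan, dist, thresholds)


class ScanResults:
    """Results of a fitted exhaustive collapsing scan."""

    def __init__(
        self,
        model: ExhaustiveCollapsingScan,
        scan: ScanResult,
        minp: MinPDistribution,
        thresholds: ThresholdSet,
    ):
        self.model = model
        self.scan = scan
        self.minp = minp
        self.thresholds = thresholds
        self.blocks: list[SignificantBlock] = merge_significant_blocks(
            scan.bins, thresholds.alpha_combined
        )

    @property
    def min_p_combined(self) -> float:
        return self.scan.min_p_combined

    @property
    def min_p_adjusted(self) -> float:
        return adjusted_p(self.scan.min_p_combined, self.minp, "combined")

    def significant_bins(self) -> list:
        return [
            b for b in self.scan.bins if b.result.p < self.thresholds.alpha_combined
        ]

    def bins_frame(self, significant_only: bool = False) -> pd.DataFrame:
        """Bins as a DataFrame (one row per locally distinct bin)."""
        bins = self.significant_bins() if significant_only else self.scan.bins
        rows = []
        for b in bins:
            ci = b.result.ci95
            rows.append(
                {
                    "chrom": b.chrom,
                    "pos_start": b.pos_start,
                    "pos_end": b.pos_end,
                    "maf_t": b.maf_t,
                    "n_variants": b.n_variants,
                    "case_carriers": b.case_carriers,
                    "control_carriers": b.control_carriers,
                    "chi2": b.result.statistic,
                    "p": b.result.p,
                    "p_adjusted": adjusted_p(b.result.p, self.minp, "combined"),
                    "OR": b.result.or_est if b.result.or_est is not None else np.nan,
                    "ci_low": ci[0] if ci else np.nan,
                    "ci_high": ci[1] if ci else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def save(self, out_prefix, manifest_extra: Optional[dict] = None):
        """Write bins/blocks/BED/manifest files (see report.write_results)."""
        return write_results(
            self.scan,
            self.thresholds,
            self.blocks,
            out_prefix,
            dist=self.minp,
            manifest_extra=manifest_extra,
        )

    def summary(self) -> str:
        """Human-readable summary of the fitted scan."""
        t = self.thresholds
        lines = [
            "Exhaustive collapsing scan",
            "=" * 58,
            f"individuals: {self.model.phenotype.n} "
            f"({self.model.phenotype.n_case} cases, "
            f"{self.model.phenotype.n_control} controls)",
            f"MAF thresholds: {', '.join(f'{x:g}' for x in self.model.maf_thresholds)}",
            f"bins evaluated: {self.scan.n_bins_total} "
            f"(of {self.scan.n_bins_naive} contiguous bins, "
            f"{self.scan.n_bins_naive / max(self.scan.n_bins_total, 1):.1f}x reduction)",
            f"permutations: {self.minp.r} (FWER {t.fwer:g})",
            f"alpha combined: {t.alpha_combined:.3e}",
        ]
        for thr, alpha in sorted(t.alpha_by_threshold.items()):
            lines.append(f"alpha MAF<={thr:g}: {alpha:.3e}")
        if t.alpha_sma is not None:
            lines.append(f"alpha SMA: {t.alpha_sma:.3e}")
        lines += [
            f"min p (combined): {self.scan.min_p_combined:.3e} "
            f"(adjusted {self.min_p_adjusted:.4f})",
            f"significant bins: {len(self.significant_bins())} "
            f"in {len(self.blocks)} block(s)",
        ]
        for blk in self.blocks:
            tb = blk.top_bin
            or_txt = f"{tb.result.or_est:.3g}" if tb.result.or_est is not None else "NA"
            lines.append(
                f"  {blk.chrom}:{blk.span_start}-{blk.span_end} "
                f"({blk.n_bins} bins) top p={tb.result.p:.3e} OR={or_txt}"
            )
        return "\n".join(lines)
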