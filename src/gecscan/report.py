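"""Aggregation of scan output: merging overlapping significant bins into
blocks and writing TSV/BED/manifest files."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .permutation import MinPDistribution, ThresholdSet, adjusted_p
from .scan import DistinctBin, ScanResult

__all__ = ["SignificantBlock", "merge_significant_blocks", "write_results"]


@dataclass
class SignificantBlock:
    """Maximal group of mutually overlapping significant bins on one
    chromosome, reported via its most significant member."""

    chrom: str
    span_start: int
    span_end: int
    n_bins: int
    top_bin: DistinctBin
    bins: list[DistinctBin]


def _top_bin(bins: list[DistinctBin]) -> DistinctBin:
    # smallest p, then smallest bp span, then leftmost
    return min(
        bins, key=lambda b: (b.result.p, b.pos_end - b.pos_start, b.pos_start)
    )


def merge_significant_blocks(
    bins: Iterable[DistinctBin], alpha: float
) -> list[SignificantBlock]:
    """Group bins with p < alpha into blocks by transitive bp-interval
    overlap (touching endpoints overlap); bins from different MAF thresholds
    merge together."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    sig = [b for b in bins if b.result.p < alpha]
    blocks: list[SignificantBlock] = []
    by_chrom: dict[str, list[DistinctBin]] = {}
    for b in sig:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom in by_chrom:
        members = sorted(by_chrom[chrom], key=lambda b: (b.pos_start, b.pos_end))
        group: list[DistinctBin] = []
        end = 0
        for b in members:
            if group and b.pos_start > end:
                blocks.append(_make_block(chrom, group))
                group = []
            group.append(b)
            end = b.pos_end if len(group) == 1 else max(end, b.pos_end)
        if group:
            blocks.append(_make_block(chrom, group))
    blocks.sort(key=lambda blk: (blk.chrom, blk.span_start))
    return blocks


def _make_block(chrom: str, group: list[DistinctBin]) -> SignificantBlock:
    return SignificantBlock(
        chrom=chrom,
        span_start=min(b.pos_start for b in group),
        span_end=max(b.pos_end for b in group),
        n_bins=len(group),
        top_bin=_top_bin(group),
        bins=list(group),
    )


_BIN_COLUMNS = [
    "chrom",
    "pos_start",
    "pos_end",
    "maf_t",
    "n_variants",
    "case_carriers",
    "control_carriers",
    "chi2",
    "p",
    "p_adjusted",
    "OR",
    "ci_low",
    "ci_high",
]


def _bin_row(b: DistinctBin, dist: Optional[MinPDistribution]) -> list[str]:
    p_adj = adjusted_p(b.result.p, dist, "combined") if dist is not None else None
    or_est, ci = b.result.or_est, b.result.ci95
    return [
        b.chrom,
        str(b.pos_start),
        str(b.pos_end),
        f"{b.maf_t:g}",
        str(b.n_variants),
        str(b.case_carriers),
        str(b.control_carriers),
        f"{b.result.statistic:.6g}",
        f"{b.result.p:.6g}",
        f"{p_adj:.6g}" if p_adj is not None else ".",
        f"{or_est:.6g}" if or_est is not None else ".",
        f"{ci[0]:.6g}" if ci is not None else ".",
        f"{ci[1]:.6g}" if ci is not None else ".",
    ]


def write_results(
    scan: ScanResult,
    thresholds: ThresholdSet,
    blocks: list[SignificantBlock],
    out_prefix,
    dist: Optional[MinPDistribution] = None,
    manifest_extra: Optional[dict] = None,
) -> dict[str, Path]:
    """Write the significant-bin TSV, block TSV, block BED and run manifest.

    BED uses the 0-based half-open convention (start = span_start - 1).
    Returns the paths written, keyed by kind.
    """
    from . import __version__

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "bins": Path(f"{prefix}.bins.tsv"),
        "blocks": Path(f"{prefix}.blocks.tsv"),
        "bed": Path(f"{prefix}.blocks.bed"),
        "manifest": Path(f"{prefix}.manifest.json"),
    }

    sig = [b for b in scan.bins if b.result.p < thresholds.alpha_combined]
    sig.sort(key=lambda b: (b.chrom, b.pos_start, b.pos_end, b.maf_t))
    with open(paths["bins"], "w") as fh:
        fh.write("\t".join(_BIN_COLUMNS) + "\n")
        for b in sig:
            fh.write("\t".join(_bin_row(b, dist)) + "\n")

    with open(paths["blocks"], "w") as fh:
        fh.write(
            "chrom\tspan_start\tspan_end\tn_bins\t"
            + "\t".join(_BIN_COLUMNS[1:])
            + "\n"
        )
        for blk in blocks:
            fh.write(
                f"{blk.chrom}\t{blk.span_start}\t{blk.span_end}\t{blk.n_bins}\t"
                + "\t".join(_bin_row(blk.top_bin, dist)[1:])
                + "\n"
            )

    with open(paths["bed"], "w") as fh:
        for k, blk in enumerate(blocks, start=1):
            fh.write(
                f"{blk.chrom}\t{blk.span_start - 1}\t{blk.span_end}\tblock_{k}\n"
            )

    manifest = {
        "software": "gecscan",
        "version": __version__,
        "fwer": thresholds.fwer,
        "alpha_combined": thresholds.alpha_combined,
        "alpha_by_threshold": {
            f"{t:g}": a for t, a in thresholds.alpha_by_threshold.items()
        },
        "alpha_sma": thresholds.alpha_sma,
        "n_bins_total": scan.n_bins_total,
        "n_bins_naive": scan.n_bins_naive,
        "min_p_combined": scan.min_p_combined,
        "n_significant_bins": len(sig),
        "n_blocks": len(blocks),
    }
    if dist is not None:
        manifest["permutations"] = dist.r
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
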