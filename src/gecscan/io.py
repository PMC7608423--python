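"""Genotype and phenotype input/output.

Reads multi-sample VCFs (biallelic, diploid GT) into a variant-major dosage
table, reads case/control phenotype tables, orients sites to the minor
allele, applies MAF thresholds and builds per-chromosome carrier-set panels.
Also writes simulated studies back to VCF + phenotype TSV so the full
pipeline can be exercised without external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bitset import CarrierSet, mask_from_bools

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing genotype

__all__ = [
    "GenotypeTable",
    "Phenotype",
    "VariantSite",
    "VariantPanel",
    "read_vcf",
    "read_phenotype",
    "orient_and_filter",
    "write_vcf",
    "write_phenotype",
]


@dataclass
class GenotypeTable:
    """Variant-major diploid dosage table plus site metadata.

    ``dosages[k, b]`` counts ALT alleles of individual ``b`` at site ``k``
    (0/1/2, or -1 for missing), before minor-allele orientation. ``sites``
    has one row per variant with columns chrom, pos, id, ref, alt, in file
    order per chromosome.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self):
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.sites):
            raise ValueError("dosage matrix does not match site table")
        if self.dosages.shape[1] != len(self.samples):
            raise ValueError("dosage matrix does not match sample list")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.sites["chrom"]))


class Phenotype:
    """Binary case/control labels aligned to the genotype sample order."""

    __slots__ = ("labels", "n_case", "n_control", "case_mask")

    def __init__(self, labels):
        labels = np.asarray(labels, dtype=np.int8)
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (case)")
        self.labels = labels
        self.n_case = int(labels.sum())
        self.n_control = int(labels.size - self.n_case)
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control")
        self.case_mask = mask_from_bools(labels == 1)

    @property
    def n(self) -> int:
        return self.labels.size

    def __repr__(self) -> str:
        return f"Phenotype(n_case={self.n_case}, n_control={self.n_control})"


@dataclass(frozen=True)
class VariantSite:
    """A retained variant site after minor-allele orientation."""

    chrom: str
    pos: int
    id: str
    maf: float
    carrier_count: int


@dataclass
class VariantPanel:
    """Ordered rare-variant sites of one chromosome at one MAF threshold."""

    maf_t: float
    chrom: str
    sites: list[VariantSite] = field(default_factory=list)
    carriers: list[CarrierSet] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sites) != len(self.carriers):
            raise ValueError("sites and carrier sets are not parallel")

    def __len__(self) -> int:
        return len(self.sites)

    def masks(self) -> list[int]:
        return [c.mask for c in self.carriers]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)


def read_vcf(path, samples: Optional[Sequence[str]] = None) -> GenotypeTable:
    """Read a VCF into a :class:`GenotypeTable`.

    Biallelic records only; multiallelic records are skipped with a warning.
    Dosages count ALT alleles (0/1/2, -1 missing).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path), gts012=True)
    if "GT" not in [f for f in _format_ids(vcf)]:
        raise ValueError(f"{path}: no GT FORMAT field declared")
    if samples is not None:
        missing = sorted(set(samples) - set(vcf.samples))
        if missing:
            raise ValueError(f"samples not found in VCF: {', '.join(missing)}")
        vcf.set_samples(list(samples))
    kept_samples = list(vcf.samples)

    rows = []
    dosage_rows = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        dos = v.gt_types.astype(np.int8)
        dos[dos == 3] = MISSING
        dosage_rows.append(dos)
        rows.append((v.CHROM, v.POS, v.ID or ".", v.REF, v.ALT[0]))
    if n_multi:
        logger.warning("skipped %d non-biallelic record(s) in %s", n_multi, path)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = (
        np.vstack(dosage_rows)
        if dosage_rows
        else np.empty((0, len(kept_samples)), dtype=np.int8)
    )
    return GenotypeTable(sites=sites, dosages=dosages, samples=kept_samples)


def _format_ids(vcf):
    for h in vcf.header_iter():
        info = h.info()
        if info.get("HeaderType") == "FORMAT":
            yield info.get("ID")


def read_phenotype(path, sample_order: Sequence[str]) -> Phenotype:
    """Read a two-column (sample id, 0/1 status) table, realigned to
    ``sample_order``."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample id, status)")
    # tolerate an optional header line (non-numeric status field)
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:]
    ids = df.iloc[:, 0].tolist()
    status = df.iloc[:, 1].tolist()
    bad = sorted({s for s in status if s not in ("0", "1")})
    if bad:
        raise ValueError(f"{path}: unknown status codes: {', '.join(bad)}")
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicated sample ids: {', '.join(dupes)}")
    table = dict(zip(ids, status))
    missing = [s for s in sample_order if s not in table]
    if missing:
        raise ValueError(
            f"{path}: phenotype missing for genotyped sample(s): "
            + ", ".join(missing)
        )
    labels = np.array([int(table[s]) for s in sample_order], dtype=np.int8)
    return Phenotype(labels)


def orient_and_filter(genotypes: GenotypeTable, maf_t: float) -> list[VariantPanel]:
    """Orient each site to its minor allele, apply the MAF threshold and
    build per-chromosome carrier-set panels.

    The minor allele is the one with combined-sample frequency <= 0.5 (ALT on
    an exact tie). MAF is computed over all non-missing alleles of cases and
    controls combined, so panels are invariant under phenotype permutation.
    Retention is inclusive (maf <= maf_t); monomorphic sites are dropped.
    Missing genotypes count as non-carriers.
    """
    if not (0 < maf_t <= 0.5):
        raise ValueError(f"maf_t must be in (0, 0.5], got {maf_t}")
    dos = genotypes.dosages
    n_sites, n_ind = dos.shape
    nonmiss = dos != MISSING
    alleles = 2 * nonmiss.sum(axis=1)
    alt_count = np.where(nonmiss, dos, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(alleles > 0, alt_count / np.maximum(alleles, 1), 0.0)
    minor_is_alt = alt_freq <= 0.5
    maf = np.where(minor_is_alt, alt_freq, 1.0 - alt_freq)
    keep = (maf > 0) & (maf <= maf_t) & (alleles > 0)

    panels: list[VariantPanel] = []
    chrom_col = genotypes.sites["chrom"].to_numpy()
    pos_col = genotypes.sites["pos"].to_numpy()
    id_col = genotypes.sites["id"].to_numpy()
    for chrom in genotypes.chromosomes():
        idx = np.nonzero((chrom_col == chrom) & keep)[0]
        sites: list[VariantSite] = []
        carriers: list[CarrierSet] = []
        for k in idx:
            if minor_is_alt[k]:
                carrier_bits = dos[k] >= 1  # MISSING is -1, excluded
            else:
                carrier_bits = (dos[k] <= 1) & nonmiss[k]
            cs = CarrierSet.from_bools(carrier_bits)
            sites.append(
                VariantSite(
                    chrom=str(chrom),
                    pos=int(pos_col[k]),
                    id=str(id_col[k]),
                    maf=float(maf[k]),
                    carrier_count=cs.popcount,
                )
            )
            carriers.append(cs)
        if not sites:
            logger.info("chromosome %s: no sites pass maf <= %g", chrom, maf_t)
        panels.append(
            VariantPanel(maf_t=maf_t, chrom=str(chrom), sites=sites, carriers=carriers)
        )
    return panels


def write_vcf(genotypes: GenotypeTable, path) -> None:
    """Write a plain-text VCFv4.2 with GT-only FORMAT."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in genotypes.chromosomes():
            sub = genotypes.sites[genotypes.sites["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for k in range(genotypes.n_sites):
            row = genotypes.sites.iloc[k]
            gts = "\t".join(gt_code[int(d)] for d in genotypes.dosages[k])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_phenotype(phenotype: Phenotype, samples: Sequence[str], path) -> None:
    """Write a two-column sample/status TSV."""
    with open(Path(path), "w") as fh:
        for s, y in zip(samples, phenotype.labels):
            fh.write(f"{s}\t{int(y)}\n")
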