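import numpy as np
import pytest

from gecscan.bitset import CarrierSet
from gecscan.io import Phenotype, VariantPanel, VariantSite


def panel_from_sets(carrier_sets, n_individuals, maf_t=0.05, chrom="1"):
    """Build a VariantPanel from explicit carrier index sets (test helper)."""
    sites = [
        VariantSite(
            chrom=chrom,
            pos=100 * (k + 1),
            id=f"v{k}",
            maf=maf_t,
            carrier_count=len(s),
        )
        for k, s in enumerate(carrier_sets)
    ]
    carriers = [CarrierSet.from_indices(s, n_individuals) for s in carrier_sets]
    return VariantPanel(maf_t=maf_t, chrom=chrom, sites=sites, carriers=carriers)


def random_panel(rng, n_variants, n_individuals, density_range=(0.02, 0.5), maf_t=0.05):
    """Random panel with non-empty carrier sets of varied density."""
    sets = []
    for _ in range(n_variants):
        d = rng.uniform(*density_range)
        bits = rng.random(n_individuals) < d
        if not bits.any():
            bits[rng.integers(n_individuals)] = True
        sets.append(set(np.nonzero(bits)[0].tolist()))
    return panel_from_sets(sets, n_individuals, maf_t=maf_t)


def random_phenotype(rng, n_individuals):
    n_case = int(rng.integers(1, n_individuals))
    labels = np.zeros(n_individuals, dtype=np.int8)
    labels[rng.permutation(n_individuals)[:n_case]] = 1
    return Phenotype(labels)


@pytest.fixture
def toy_panel():
    """The 4-variant worked example: carriers {0}, {0}, {1}, {2,3}; N = 4."""
    return panel_from_sets([{0}, {0}, {1}, {2, 3}], 4)


@pytest.fixture
def toy_phenotype():
    return Phenotype([1, 1, 0, 0])


VCF_5_RECORDS = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
1\t100\trs1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tG\t.\t.\t.\tGT\t./.\t0/0\t0/1
1\t300\trs3\tA\tC,G\t.\t.\t.\tGT\t0/1\t0/2\t0/0
1\t400\trs4\tT\tA\t.\t.\t.\tGT\t1/1\t1/1\t0/1
1\t500\trs5\tG\tA\t.\t.\t.\tGT\t0/0\t0/0\t0/1
"""


@pytest.fixture
def vcf_file(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_5_RECORDS)
    return path
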