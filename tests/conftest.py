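import numpy as np
import pytest

from admixkit import GenotypeDataset, HaplotypeDataset


def make_genotypes(dosages, chrom=None, gpos=None, ppos=None, pops=None,
                   sample_ids=None):
    """Small-fixture builder: dosage matrix plus defaulted map/labels."""
    dosages = np.asarray(dosages, dtype=np.int8)
    m, n = dosages.shape
    chrom = np.full(m, "1", dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    if gpos is None:
        gpos = np.zeros(m)
        for c in dict.fromkeys(chrom):
            sel = chrom == c
            gpos[sel] = np.linspace(0, 1, sel.sum(), endpoint=False)
    ppos = np.arange(1, m + 1) * 10_000 if ppos is None else ppos
    pops = ["pop0"] * n if pops is None else list(pops)
    sample_ids = [f"s{j}" for j in range(n)] if sample_ids is None else sample_ids
    alleles = np.tile(np.array(["A", "C"], dtype=object), (m, 1))
    return GenotypeDataset([f"snp{i}" for i in range(m)], chrom, gpos, ppos,
                           alleles, dosages, sample_ids, pops)


def make_haplotypes(hapmat, chrom=None, gpos=None, pops=None):
    hapmat = np.asarray(hapmat, dtype=np.int8)
    m, h = hapmat.shape
    n = h // 2
    chrom = np.full(m, "1", dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    if gpos is None:
        gpos = np.linspace(0, 1, m, endpoint=False)
    ppos = np.arange(1, m + 1) * 10_000
    alleles = np.tile(np.array(["A", "C"], dtype=object), (m, 1))
    return HaplotypeDataset([f"snp{i}" for i in range(m)], chrom, gpos, ppos,
                            alleles, hapmat, [f"s{j}" for j in range(n)],
                            ["pop0"] * n if pops is None else list(pops))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
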