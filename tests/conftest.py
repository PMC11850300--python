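import numpy as np
import pytest

from triads import Genome, GenomicInterval, LabeledTrack, Peak, PRPeak, RDContact


@pytest.fixture
def genome():
    return Genome({"chr1": 2_000_000, "chr2": 2_000_000})


@pytest.fixture
def ab_track():
    """A = [0, 1 Mb), B = [1 Mb, 2 Mb) on both chromosomes."""
    blocks = []
    for chrom in ("chr1", "chr2"):
        blocks.append((GenomicInterval(chrom, 0, 1_000_000), "A"))
        blocks.append((GenomicInterval(chrom, 1_000_000, 2_000_000), "B"))
    return LabeledTrack(blocks)


def make_contact(rna="RNA1", biotype="lncRNA", rna_chrom="chr1", rna_start=10_000,
                 rna_end=10_100, strand="+", dna_chrom="chr1", dna_start=500_000,
                 dna_end=500_300, q_bardic=1.0):
    return RDContact(
        rna_id=rna,
        biotype=biotype,
        rna_part=GenomicInterval(rna_chrom, rna_start, rna_end, strand),
        dna_part=GenomicInterval(dna_chrom, dna_start, dna_end),
        q_bardic=q_bardic,
    )


def make_pd_peak(protein="P1", chrom="chr1", start=499_000, end=501_000, q=0.01):
    return Peak(protein, GenomicInterval(chrom, start, end), q, "PD")


def make_pr_peak(protein="P1", rna="RNA1", chrom="chr1", start=9_990, end=10_200,
                 strand="+", q=0.02, biotype="lncRNA"):
    return PRPeak(
        owner=protein,
        interval=GenomicInterval(chrom, start, end, strand),
        q_value=q,
        biotype=biotype,
        rna_id=rna,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
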