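import pytest

from splicecat import synthetic
from splicecat.core_io import GenomicInterval, TranscriptRecord


def make_transcript(tid, exons, strand="+", chrom="chr1", sample="s1",
                    gene="G", fpkm=1.0):
    """Build a TranscriptRecord from (start, end) pairs in genomic order."""
    intervals = [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    if strand == "-":
        intervals = intervals[::-1]
    return TranscriptRecord(
        transcript_id=tid, gene_id=gene, sample_id=sample,
        exons=intervals, fpkm=fpkm, coverage=fpkm,
    )


@pytest.fixture(scope="session")
def locus():
    return synthetic.simulate_locus(synthetic.SyntheticLocusSpec(), seed=7)


@pytest.fixture(scope="session")
def adgrf_locus():
    spec = synthetic.SyntheticLocusSpec(archetype=synthetic.ARCHETYPE_ADGRF)
    return synthetic.simulate_locus(spec, seed=7)


@pytest.fixture(scope="session")
def planted_variants(locus):
    mix = {
        "FULL_RECEPTOR": 0.4,
        "SOLUBLE_NTF": 0.2,
        "ANCHORED_NTF": 0.2,
        "CTF": 0.2,
    }
    return synthetic.simulate_variants(
        locus, mix, 5, seed=7,
        include_icl3_insertion=True,
        include_alt_cterm=True,
        include_ig2_skip=True,
    )
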