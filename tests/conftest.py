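import pytest

from scubkit.genetic_code import build_genetic_code
from scubkit.genome_io import RawTranscript


@pytest.fixture(scope="session")
def code():
    return build_genetic_code()


@pytest.fixture()
def tiny_genome():
    """One contig with a plus-strand two-exon gene and its minus mirror.

    Plus gene: CDS ATG GCT TAA split 4|5 after the first nucleotide of the
    GCT codon (phase-1 intron).  The minus-strand gene carries the reverse
    complement of the same spliced CDS.
    """
    cds = "ATGGCTTAA"
    intron = "GT" + "A" * 16 + "AG"  # 20 nt
    plus_gene = cds[:4] + intron + cds[4:]
    from scubkit.codon_extraction import reverse_complement

    minus_gene = reverse_complement(plus_gene)
    pad = "C" * 10
    seq = pad + plus_gene + pad + minus_gene + pad
    genome = {"chr1": seq}
    plus = RawTranscript(
        gene_id="gplus",
        transcript_id="tplus",
        seq_id="chr1",
        strand="+",
        cds_segments=[(11, 14), (35, 39)],
    )
    # minus gene occupies 1-based 50..78 (29 nt): the reading-orientation
    # exons [0,4) and [24,29) mirror to genomic (75,78) and (50,54).
    minus = RawTranscript(
        gene_id="gminus",
        transcript_id="tminus",
        seq_id="chr1",
        strand="-",
        cds_segments=[(50, 54), (75, 78)],
    )
    return genome, plus, minus
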