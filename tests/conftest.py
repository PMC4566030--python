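import numpy as np
import pytest

from semap.events import Interval, SkippedExonEvent
from semap.regions import DictGenome, reverse_complement


def make_event(
    event_id="SE00000",
    gene_id="GENE0",
    chrom="chrT",
    strand="+",
    left=(0, 100),
    cassette=(400, 550),
    right=(850, 950),
    psi=None,
    p=0.001,
    fdr=0.01,
):
    """Event builder; left/cassette/right are genomic-order exon intervals."""
    up, dn = (left, right) if strand == "+" else (right, left)
    return SkippedExonEvent(
        event_id=event_id, gene_id=gene_id, chrom=chrom, strand=strand,
        upstream_exon=Interval(*up), cassette_exon=Interval(*cassette),
        downstream_exon=Interval(*dn),
        psi_by_group=psi or {"WT": [0.9, 0.85], "KO": [0.4, 0.45]},
        p_value=p, fdr=fdr,
    )


def make_locus(up_exon, up_intron, cassette, down_intron, down_exon,
               strand="+", chrom="chrT", pad=25, **event_kw):
    """Build a genome containing exactly one event from transcript-direction
    DNA pieces; returns (genome, event)."""
    transcript = up_exon + up_intron + cassette + down_intron + down_exon
    block = transcript if strand == "+" else reverse_complement(transcript)
    rng = np.random.default_rng(7)
    flank = "".join(rng.choice(list("ACGT"), size=pad))
    seq = flank + block + flank
    s = pad
    lu, li1, lc, li2, ld = map(len, (up_exon, up_intron, cassette, down_intron, down_exon))
    if strand == "+":
        left = (s, s + lu)
        cas = (left[1] + li1, left[1] + li1 + lc)
        right = (cas[1] + li2, cas[1] + li2 + ld)
    else:
        left = (s, s + ld)
        cas = (left[1] + li2, left[1] + li2 + lc)
        right = (cas[1] + li1, cas[1] + li1 + lu)
    genome = DictGenome({chrom: seq})
    return genome, make_event(strand=strand, chrom=chrom, left=left,
                              cassette=cas, right=right, **event_kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def random_rna(n, rng):
    return "".join(rng.choice(list("ACGU"), size=n))
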