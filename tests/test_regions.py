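import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semap.regions import (
    BoundsError,
    DictGenome,
    RegionConfig,
    extract_map_segments,
    extract_regions,
    regions_to_bed,
    reverse_complement,
    to_rna,
)

from conftest import make_locus, random_dna


def _pieces(rng, up=120, i1=600, cas=150, i2=600, dn=120):
    return dict(
        up_exon=random_dna(up, rng), up_intron=random_dna(i1, rng),
        cassette=random_dna(cas, rng), down_intron=random_dna(i2, rng),
        down_exon=random_dna(dn, rng),
    )


def test_long_intron_scanned_lengths(rng):
    # 250-nt window minus 20-nt 3'ss exclusion upstream, 6-nt 5'ss downstream
    p = _pieces(rng)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    regs = extract_regions(event, genome)
    assert len(regs.upstream_intron) == 230
    assert len(regs.downstream_intron) == 244
    assert regs.upstream_intron == to_rna(p["up_intron"][-250:-20])
    assert regs.downstream_intron == to_rna(p["down_intron"][6:250])
    assert regs.exon_body == to_rna(p["cassette"])
    assert not regs.provenance["upstream_intron"].truncated


def test_short_intron_truncates_with_both_exclusions(rng):
    p = _pieces(rng, i1=40, i2=40)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    regs = extract_regions(event, genome)
    assert len(regs.upstream_intron) == 14  # 40 - 20 - 6
    assert regs.upstream_intron == to_rna(p["up_intron"][6:20])
    assert len(regs.downstream_intron) == 14
    assert regs.provenance["upstream_intron"].truncated


def test_intron_shorter_than_exclusions_gives_empty_flagged_region(rng):
    p = _pieces(rng, i1=20, i2=25)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    regs = extract_regions(event, genome)
    assert regs.upstream_intron == ""
    assert regs.provenance["upstream_intron"].truncated


def test_minus_strand_exon_is_reverse_complement(rng):
    p = _pieces(rng)
    p["cassette"] = "GGTACC" * 25  # 150 nt
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"], strand="-")
    regs = extract_regions(event, genome)
    assert regs.exon_body == to_rna(p["cassette"])  # builder stores transcript pieces
    # the genomic slice itself is the reverse complement
    gslice = genome.fetch(event.chrom, event.cassette_exon.start, event.cassette_exon.end)
    assert to_rna(reverse_complement(gslice)) == regs.exon_body
    assert "GGUACC" in regs.exon_body


@pytest.mark.parametrize("extract", [extract_regions, extract_map_segments])
def test_strand_involution(rng, extract):
    """A mirrored genome (revcomp + flipped coordinates + flipped strand)
    yields identical region strings."""
    p = _pieces(rng, i1=300, i2=500)
    genome, event = make_locus(*[p[k] for k in
                                 ("up_exon", "up_intron", "cassette", "down_intron", "down_exon")])
    a = extract(event, genome)

    chrom_seq = genome.chromosomes()["chrT"]
    L = len(chrom_seq)
    mirrored = DictGenome({"chrT": reverse_complement(chrom_seq)})

    def flip(iv):
        from semap.events import Interval
        return Interval(L - iv.end, L - iv.start)

    from semap.events import SkippedExonEvent
    flipped = SkippedExonEvent(
        event_id=event.event_id, gene_id=event.gene_id, chrom="chrT", strand="-",
        upstream_exon=flip(event.upstream_exon), cassette_exon=flip(event.cassette_exon),
        downstream_exon=flip(event.downstream_exon),
        psi_by_group=event.psi_by_group, p_value=event.p_value, fdr=event.fdr,
    )
    b = extract(flipped, mirrored)
    names = ("upstream_intron", "downstream_intron", "upstream_exon", "downstream_exon")
    body = "exon_body" if extract is extract_regions else "cassette_exon"
    for name in names + (body,):
        assert getattr(a, name) == getattr(b, name), name


@settings(deadline=None, derandomize=True, max_examples=40)
@given(intron_len=st.integers(min_value=1, max_value=600))
def test_scanned_length_law(intron_len):
    """scanned length = min(250, L) - covered exclusions, never negative."""
    rng = np.random.default_rng(intron_len)
    p = _pieces(rng, i1=intron_len)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    regs = extract_regions(event, genome)
    w = min(250, intron_len)
    # set-based oracle: window positions minus both splice-site zones
    window = set(range(intron_len - w, intron_len))
    scanned = window - set(range(0, 6)) - set(range(intron_len - 20, intron_len))
    assert len(regs.upstream_intron) == len(scanned)
    assert len(regs.upstream_intron) <= w


def test_concatenated_subintervals_reproduce_genomic_substring(rng):
    p = _pieces(rng, i1=200, i2=240)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    segs = extract_map_segments(event, genome, RegionConfig(intron_window=10_000))
    joined = "".join(s for _, s in segs.ordered())
    start, end = event.upstream_exon.start, event.downstream_exon.end
    assert joined == to_rna(genome.fetch("chrT", start, end))


def test_map_segments_window_and_truncation(rng):
    p = _pieces(rng, i1=300, i2=100)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    segs = extract_map_segments(event, genome)
    assert len(segs.upstream_intron) == 250
    assert segs.upstream_intron == to_rna(p["up_intron"][-250:])  # exon-proximal
    assert len(segs.downstream_intron) == 100
    assert segs.truncated["downstream_intron"] and not segs.truncated["upstream_intron"]


def test_shift_mode_takes_window_outside_exclusions(rng):
    p = _pieces(rng, i1=600)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    regs = extract_regions(event, genome, RegionConfig(exclusion_mode="shift"))
    assert len(regs.upstream_intron) == 250
    assert regs.upstream_intron == to_rna(p["up_intron"][-270:-20])


def test_bounds_error_outside_chromosome():
    genome = DictGenome({"c": "ACGT" * 10})
    with pytest.raises(BoundsError):
        genome.fetch("c", 0, 100)
    with pytest.raises(BoundsError):
        genome.fetch("missing", 0, 1)


def test_bed_export_is_zero_based_half_open(rng):
    p = _pieces(rng)
    genome, event = make_locus(p["up_exon"], p["up_intron"], p["cassette"],
                               p["down_intron"], p["down_exon"])
    regs = extract_regions(event, genome)
    lines = regions_to_bed(regs)
    fields = [l.split("\t") for l in lines]
    by_name = {f[3].split("|")[1]: f for f in fields}
    f = by_name["exon_body"]
    assert (int(f[1]), int(f[2])) == (event.cassette_exon.start, event.cassette_exon.end)
    assert f[5] == "+"
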