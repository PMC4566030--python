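import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from semap.motifs import (
    EnrichConfig,
    Motif,
    bh_adjust,
    count_occurrences,
    enrich,
    enrichment_table,
    enumerate_kmers,
    fisher_right,
    read_motif_tsv,
)
from semap.regions import RegionSequences

from conftest import random_rna


def fisher_right_oracle(a, b, c, d):
    """Exact right-tail by integer enumeration of fixed-margin tables."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    num = sum(
        math.comb(col1, x) * math.comb(n - col1, row1 - x)
        for x in range(a, min(row1, col1) + 1)
        if row1 - x <= n - col1
    )
    return num / math.comb(n, row1) if n else 1.0


def bh_oracle(pvals):
    """Textbook step-up: sort, p*m/rank, cumulative min from the largest."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


def _regions(seqs, tag="R"):
    return [
        RegionSequences(event_id=f"{tag}{i}", upstream_intron=s, exon_body=s,
                        downstream_intron=s, upstream_exon="", downstream_exon="")
        for i, s in enumerate(seqs)
    ]


def test_overlapping_occurrences_counted_by_nt():
    m = Motif("x", "GUGGUG")
    assert count_occurrences("GUGGUGGUG", m, "by_nt") == 2  # starts 0 and 3
    assert count_occurrences("GUGGUGGUG", m, "by_seq") == 1
    assert count_occurrences("", m, "by_nt") == 0
    assert count_occurrences("", m, "by_seq") == 0
    assert count_occurrences("AAAAAAA", m, "by_nt") == 0
    assert count_occurrences("AAA", m, "by_nt") == 0  # motif longer than seq


def test_iupac_degenerate_matching_and_sequence_n():
    m = Motif("mbnl", "YGCY")
    assert count_occurrences("UGCU", m) == 1
    assert count_occurrences("CGCC", m) == 1
    assert count_occurrences("AGCU", m) == 0
    # N in the sequence matches nothing, even against N in a pattern
    assert count_occurrences("UGNU", m) == 0
    assert count_occurrences("ANGU", Motif("n", "ANGU".replace("N", "N")), "by_nt") == 0


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.text(alphabet="ACGUN", min_size=0, max_size=60),
       st.text(alphabet="ACGU", min_size=1, max_size=5))
def test_by_seq_is_capped_by_nt(seq, pattern):
    m = Motif("m", pattern)
    assert count_occurrences(seq, m, "by_seq") == min(1, count_occurrences(seq, m, "by_nt"))


def test_fisher_right_examples():
    assert fisher_right(2, 0, 0, 2) == pytest.approx(1 / 6, abs=1e-12)
    assert fisher_right(0, 5, 3, 7) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fisher_right(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        fisher_right(1.5, 2, 3, 4)


def test_fisher_right_matches_enumeration_on_random_tables(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        assert fisher_right(a, b, c, d) == pytest.approx(
            fisher_right_oracle(a, b, c, d), abs=1e-12)


def test_bh_examples_and_permutation_invariance(rng):
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.37]) == [0.37]
    assert bh_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])

    p = rng.uniform(size=25).tolist()
    adj = bh_adjust(p)
    assert adj == pytest.approx(bh_oracle(p), abs=1e-12)
    # monotone non-decreasing in sorted-p order
    order = np.argsort(p)
    assert np.all(np.diff(np.array(adj)[order]) >= -1e-15)
    # invariant to permutation up to the inverse permutation
    perm = rng.permutation(25)
    adj_perm = bh_adjust([p[i] for i in perm])
    assert [adj_perm[j] for j in np.argsort(perm)] == pytest.approx(adj)


def test_enumerate_kmers():
    assert [m.pattern for m in enumerate_kmers(1)] == ["A", "C", "G", "U"]
    two = enumerate_kmers(2)
    assert len(two) == 16 and [m.pattern for m in two] == sorted(m.pattern for m in two)
    assert len(enumerate_kmers(6)) == 4096
    with pytest.raises(ValueError):
        enumerate_kmers(0)


def test_motif_tsv_round_trip(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("name\tpattern\tsource\nESRP1\tUGGUGG\tesrp_selex\nX\tYGCY\t\n")
    motifs = read_motif_tsv(p)
    assert motifs[0] == Motif("ESRP1", "UGGUGG", "esrp_selex")
    assert motifs[1].source == "known_rbp_set"
    with pytest.raises(ValueError):
        Motif("bad", "UGGXGG")


def test_enrich_null_self_comparison_flags_nothing(rng):
    seqs = [random_rna(120, rng) for _ in range(40)]
    regs = _regions(seqs)
    results = enrich({"enhanced": regs}, regs, [Motif("E", "UGGUGG"), Motif("P", "UCUUC")])
    assert all(not r.enriched for r in results)
    # identical sets give the most extreme possible balanced table: p >= 0.5
    assert all(r.p_by_nt >= 0.5 for r in results)


def test_enrich_absent_motif_p_one(rng):
    regs = _regions(["A" * 100 for _ in range(10)])
    ctl = _regions(["A" * 100 for _ in range(10)], tag="C")
    (r,) = [x for x in enrich({"d": regs}, ctl, [Motif("E", "UGGUGG")])
            if x.region == "exon_body"]
    assert r.p_by_nt == 1.0 and r.p_by_seq == 1.0 and not r.enriched


def test_enrich_planted_motif_is_flagged(rng):
    motif = "UGGUGG"
    reg = []
    for _ in range(60):
        s = list(random_rna(200, rng))
        for start in (20, 90, 150):
            s[start:start + 6] = motif
        reg.append("".join(s))
    ctl = [random_rna(200, rng) for _ in range(200)]
    results = enrich({"silenced": _regions(reg)}, _regions(ctl, "C"),
                     [Motif("ESRP1", motif), Motif("QKI", "ACUAAY")])
    flagged = {(r.motif.name, r.region): r.enriched for r in results if r.direction == "silenced"}
    assert flagged[("ESRP1", "upstream_intron")]
    assert not flagged[("QKI", "upstream_intron")]
    df = enrichment_table(results)
    assert set(df.columns) >= {"motif", "region", "direction", "p_by_nt", "fdr_by_nt",
                               "p_by_seq", "enriched"}


def test_enrich_coverage_table_mode(rng):
    reg = _regions([random_rna(150, rng) for _ in range(20)])
    ctl = _regions([random_rna(150, rng) for _ in range(20)], "C")
    res = enrich({"d": reg}, ctl, [Motif("E", "UGGUGG")],
                 EnrichConfig(by_nt_table="coverage"))
    r = res[0]
    assert r.a + r.b == 20 * 150  # nucleotide totals, not positions


def test_enrich_rejects_empty_sets():
    regs = _regions(["ACGUACGU"])
    with pytest.raises(ValueError):
        enrich({}, regs, [Motif("E", "UGGUGG")])
    with pytest.raises(ValueError):
        enrich({"d": regs}, [], [Motif("E", "UGGUGG")])
    with pytest.raises(ValueError):
        enrich({"d": regs}, regs, [])
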