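import numpy as np
import pytest

from semap.motifs import Motif
from semap.regions import MapSegments
from semap.rnamap import MapConfig, build_map, coverage_track, map_table, window_scores

from conftest import random_rna

ESRP = [Motif("ESRP1", "UGGUGG")]


def brute_force_window_scores(seq, motifs, window=50):
    """Independent per-window counter: for each window, count positions lying
    inside any motif occurrence found by naive string scanning."""
    covered = set()
    for m in motifs:
        k = len(m.pattern)
        for s in range(len(seq) - k + 1):
            if seq[s:s + k] == m.pattern:  # literal motifs only
                covered.update(range(s, s + k))
    out = []
    for s in range(len(seq) - window + 1):
        out.append(sum(1 for i in range(s, s + window) if i in covered) / window)
    return np.array(out)


def test_coverage_track_single_match():
    track = coverage_track("AAUGGUGGAA", ESRP)
    assert track.tolist() == [0, 0, 1, 1, 1, 1, 1, 1, 0, 0]


def test_coverage_track_overlapping_union():
    track = coverage_track("GUGGUGGUG", [Motif("x", "GUGGUG")])
    assert track.tolist() == [1] * 9  # spans 0-5 and 3-8


def test_coverage_track_no_match():
    assert coverage_track("ACACACAC", ESRP).sum() == 0


def test_window_scores_examples():
    seq = "A" * 20 + "UGGUGG" + "A" * 24  # 50 nt, one occurrence
    scores = window_scores(seq, ESRP)
    assert scores.shape == (1,)
    assert scores[0] == pytest.approx(6 / 50)

    tiled = "UGGUGG" * 20
    assert np.all(window_scores(tiled, ESRP) == 1.0)

    assert np.all(window_scores("A" * 80, ESRP) == 0.0)
    assert window_scores("A" * 30, ESRP).size == 0  # shorter than one window


def test_window_scores_equal_brute_force(rng):
    motifs = [Motif("a", "UGGUGG"), Motif("b", "GUGGU"), Motif("c", "UCUU")]
    for _ in range(25):
        seq = random_rna(int(rng.integers(50, 200)), rng)
        got = window_scores(seq, motifs)
        expected = brute_force_window_scores(seq, motifs)
        assert got == pytest.approx(expected, abs=1e-12)


def _segments(event_id, rng, up_i=None, dn_i=None, lengths=(120, 250, 150, 250, 120)):
    lu, li1, lc, li2, ld = lengths
    return MapSegments(
        event_id=event_id,
        upstream_exon=random_rna(lu, rng),
        upstream_intron=up_i if up_i is not None else random_rna(li1, rng),
        cassette_exon=random_rna(lc, rng),
        downstream_intron=dn_i if dn_i is not None else random_rna(li2, rng),
        downstream_exon=random_rna(ld, rng),
    )


def test_single_event_profile_equals_its_window_scores(rng):
    segs = _segments("e0", rng)
    profiles = build_map({"control": ["e0"]}, {"e0": segs}, ESRP)
    table = profiles["control"].table
    scores = window_scores(segs.downstream_intron, ESRP)
    sub = table[(table.segment == "downstream_intron")].sort_values("position")
    assert sub["mean_score"].to_numpy() == pytest.approx(scores)
    assert (sub["n_events"] == 1).all()
    # upstream intron is anchored at the exon-proximal (right) boundary
    up_scores = window_scores(segs.upstream_intron, ESRP)
    up = table[table.segment == "upstream_intron"].sort_values("position")
    assert up["mean_score"].to_numpy() == pytest.approx(up_scores[::-1])


def test_set_vs_itself_identical_and_order_invariant(rng):
    segs = {f"e{i}": _segments(f"e{i}", rng) for i in range(6)}
    ids = list(segs)
    p1 = build_map({"control": ids}, segs, ESRP)
    p2 = build_map({"control": ids[::-1]}, segs, ESRP)
    assert p1["control"].table.equals(p2["control"].table)


def test_exon_anchoring_depth(rng):
    segs = _segments("e0", rng, lengths=(400, 250, 150, 250, 120))
    profiles = build_map({"c": ["e0"]}, {"e0": segs}, ESRP,
                         MapConfig(exon_anchor_windows=30))
    tab = profiles["c"].table
    up_exon = tab[tab.segment == "upstream_exon"]
    assert set(up_exon.anchor) == {"5p", "3p"}
    assert up_exon.groupby("anchor").size().max() == 30


def test_planting_monotonicity(rng):
    """Adding planted occurrences to upstream introns never lowers the
    upstream-intron profile at any position."""
    background = "A" * 250
    motif = "UGGUGG"

    def planted(positions):
        s = list(background)
        for p in positions:
            s[p:p + 6] = motif
        return "".join(s)

    base_positions = {"e0": [40], "e1": [], "e2": [200]}
    more_positions = {"e0": [40, 120], "e1": [90], "e2": [200, 10]}
    segs_base, segs_more = {}, {}
    for eid in base_positions:
        # identical non-intron content between the two maps
        segs_base[eid] = _segments(eid, np.random.default_rng(1), up_i=planted(base_positions[eid]))
        segs_more[eid] = _segments(eid, np.random.default_rng(1), up_i=planted(more_positions[eid]))
    ids = list(base_positions)
    t_base = build_map({"s": ids}, segs_base, ESRP)["s"].table
    t_more = build_map({"s": ids}, segs_more, ESRP)["s"].table
    b = t_base[t_base.segment == "upstream_intron"].sort_values("position")["mean_score"].to_numpy()
    m = t_more[t_more.segment == "upstream_intron"].sort_values("position")["mean_score"].to_numpy()
    assert np.all(m >= b - 1e-12)
    assert m.sum() > b.sum()


def test_directional_peaks_reproduce_regulator_map(rng):
    """Silenced-set peak in the upstream intron, enhanced-set peak in the
    downstream intron, both exceeding the control profile."""
    def with_plant(region, eid):
        s = list(random_rna(250, rng))
        for p in (30, 100, 180):
            s[p:p + 6] = "UGGUGG"
        planted = "".join(s)
        kw = {region: planted} if region else {}
        return _segments(eid, rng, **kw)

    segs = {}
    sets = {"silenced": [], "enhanced": [], "control": []}
    for i in range(8):
        eid = f"s{i}"; segs[eid] = with_plant("up_i", eid); sets["silenced"].append(eid)
        eid = f"h{i}"; segs[eid] = with_plant("dn_i", eid); sets["enhanced"].append(eid)
        eid = f"c{i}"; segs[eid] = _segments(eid, rng); sets["control"].append(eid)
    profiles = build_map(sets, segs, ESRP)
    assert profiles["silenced"].peak()[0] == "upstream_intron"
    assert profiles["enhanced"].peak()[0] == "downstream_intron"
    sil_means = profiles["silenced"].segment_means()
    ctl_means = profiles["control"].segment_means()
    assert sil_means["upstream_intron"] > ctl_means["upstream_intron"] + 0.02
    long_table = map_table(profiles)
    assert set(long_table.event_set) == {"silenced", "enhanced", "control"}


def test_build_map_validates_inputs(rng):
    segs = {"e0": _segments("e0", rng)}
    with pytest.raises(ValueError):
        build_map({"c": []}, segs, ESRP)
    with pytest.raises(ValueError):
        build_map({"c": ["e0"]}, segs, [])
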