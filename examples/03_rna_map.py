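"""Positional RNA binding map around regulated exons.

Computes the fraction of nucleotides covered by GU-rich 6-mers in a 50-nt
window slid 1 nt at a time over five segments, averaged per event set, and
reports where each set's profile peaks.
"""

from semap import SimConfig, classify_events, extract_map_segments, simulate_dataset
from semap.expression import expression_index
from semap.pipeline import packaged_motifs
from semap.rnamap import build_map, plot_map

res = simulate_dataset(SimConfig(seed=3))
cls = classify_events(res.events, expression_index(res.expression), reference_group="WT")
segs = {e.event_id: extract_map_segments(e, res.genome) for e in res.events}
sets = {lab: [i for i, c in cls.items() if c.label == lab]
        for lab in ("enhanced", "silenced", "control")}

profiles = build_map(sets, segs, packaged_motifs("esrp"))
for label, prof in profiles.items():
    seg, anchor, pos, score = prof.peak()
    print(f"{label:9s} peak: {seg} ({anchor}, window {pos}), mean coverage {score:.3f}")
    print(f"          segment means: "
          + ", ".join(f"{k}={v:.4f}" for k, v in sorted(prof.segment_means().items())))
plot_map(profiles, "rna_map_example.png")
print("wrote rna_map_example.png")
# Silenced exons peak in the upstream intron and enhanced exons in the
# downstream intron near the 5' splice site — the positional signature of a
# regulator that represses from upstream and activates from downstream.
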