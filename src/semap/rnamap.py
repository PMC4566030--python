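"""Positional RNA binding map: windowed motif-coverage profiles around exons.

For each event, every nucleotide of each of the five map segments is marked
covered if it falls inside at least one occurrence of any motif in the set
(by default the GU-rich Esrp 6-mers). A fixed-length window (default 50 nt)
slides in 1-nt steps; each window's score is the fraction of covered
nucleotides. Scores are averaged across the events of a set (enhanced,
silenced, control) at aligned positions:

* intron segments are anchored at the exon-proximal boundary — position 0 is
  the window flush against the exon, increasing away from it;
* exon segments are anchored at both edges (anchors '5p' and '3p'), up to a
  configurable number of windows per edge, since exon lengths vary;
* only windows fully inside a single segment are scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import Motif, match_starts
from .regions import MapSegments, SEGMENT_ORDER

logger = logging.getLogger(__name__)

INTRON_SEGMENTS = ("upstream_intron", "downstream_intron")
EXON_SEGMENTS = ("upstream_exon", "cassette_exon", "downstream_exon")


def coverage_track(seq: str, motifs: Sequence[Motif]) -> np.ndarray:
    """Binary per-nucleotide vector: 1 iff inside >= 1 motif occurrence."""
    track = np.zeros(len(seq), dtype=np.int8)
    for motif in motifs:
        k = len(motif.pattern)
        for s in match_starts(seq, motif):
            track[s : s + k] = 1
    return track


def window_scores(
    seq: str, motifs: Sequence[Motif], window: int = 50, step: int = 1
) -> np.ndarray:
    """Mean coverage per full window; empty array when the segment is shorter
    than one window."""
    if window < max((len(m.pattern) for m in motifs), default=1):
        warnings.warn("window is shorter than the longest motif", stacklevel=2)
    if len(seq) < window:
        return np.zeros(0, dtype=float)
    track = coverage_track(seq, motifs).astype(float)
    csum = np.concatenate(([0.0], np.cumsum(track)))
    starts = np.arange(0, len(seq) - window + 1, step)
    return (csum[starts + window] - csum[starts]) / window


@dataclass
class MapConfig:
    window: int = 50
    step: int = 1
    exon_anchor_windows: int = 100  # windows kept per exon edge

    def __post_init__(self) -> None:
        if self.window < 1 or self.step < 1 or self.exon_anchor_windows < 1:
            raise ValueError("window, step and exon_anchor_windows must be positive")


@dataclass
class RnaMapProfile:
    """Aligned mean-score profile for one event set.

    ``table`` columns: segment, anchor ('exon_proximal' for introns,
    '5p'/'3p' for exons), position (window index in the alignment frame),
    mean_score, n_events.
    """

    event_set: str
    table: pd.DataFrame

    def segment_means(self) -> dict[str, float]:
        """Mean of the positional profile per segment (event-count weighted)."""
        out = {}
        for seg, sub in self.table.groupby("segment"):
            out[seg] = float(np.average(sub["mean_score"], weights=sub["n_events"]))
        return out

    def peak(self) -> tuple[str, str, int, float]:
        """(segment, anchor, position, score) of the profile maximum."""
        row = self.table.loc[self.table["mean_score"].idxmax()]
        return str(row["segment"]), str(row["anchor"]), int(row["position"]), float(row["mean_score"])


def _aligned_positions(segment: str, n_scores: int, cfg: MapConfig):
    """Yield (anchor, aligned position, score index) for one segment's scores."""
    if segment == "upstream_intron":
        # position 0 = window flush against the cassette exon (rightmost)
        for i in range(n_scores):
            yield "exon_proximal", n_scores - 1 - i, i
    elif segment == "downstream_intron":
        for i in range(n_scores):
            yield "exon_proximal", i, i
    else:
        depth = min(n_scores, cfg.exon_anchor_windows)
        for i in range(depth):
            yield "5p", i, i
        for j in range(depth):
            yield "3p", j, n_scores - 1 - j


def build_map(
    event_sets: Mapping[str, Sequence[str]],
    segments: Mapping[str, MapSegments],
    motifs: Sequence[Motif],
    cfg: MapConfig | None = None,
) -> dict[str, RnaMapProfile]:
    """Average windowed coverage profiles per event set across the five
    segments, in each segment's alignment frame."""
    cfg = cfg or MapConfig()
    if not motifs:
        raise ValueError("empty motif set")
    if not event_sets or any(len(v) == 0 for v in event_sets.values()):
        raise ValueError("every event set must contain at least one event")

    profiles: dict[str, RnaMapProfile] = {}
    for label, event_ids in event_sets.items():
        sums: dict[tuple[str, str, int], float] = {}
        counts: dict[tuple[str, str, int], int] = {}
        for event_id in event_ids:
            segs = segments[event_id]
            for seg_name, seq in segs.ordered():
                scores = window_scores(seq, motifs, cfg.window, cfg.step)
                for anchor, pos, idx in _aligned_positions(seg_name, len(scores), cfg):
                    key = (seg_name, anchor, pos)
                    sums[key] = sums.get(key, 0.0) + float(scores[idx])
                    counts[key] = counts.get(key, 0) + 1
        rows = [
            {
                "segment": seg, "anchor": anchor, "position": pos,
                "mean_score": sums[(seg, anchor, pos)] / counts[(seg, anchor, pos)],
                "n_events": counts[(seg, anchor, pos)],
            }
            for (seg, anchor, pos) in sorted(
                sums, key=lambda k: (SEGMENT_ORDER.index(k[0]), k[1], k[2])
            )
        ]
        profiles[label] = RnaMapProfile(label, pd.DataFrame(rows))
    return profiles


def map_table(profiles: Mapping[str, RnaMapProfile]) -> pd.DataFrame:
    """Long-format table over all event sets (event_set, segment, anchor,
    position, mean_score, n_events)."""
    frames = []
    for label, prof in profiles.items():
        df = prof.table.copy()
        df.insert(0, "event_set", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plot_map(profiles: Mapping[str, RnaMapProfile], path, title: str = "RNA binding map") -> None:
    """Five-panel profile plot (one panel per segment, one line per set)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(SEGMENT_ORDER), figsize=(18, 3.2), sharey=True)
    colors = {"enhanced": "tab:blue", "silenced": "tab:red", "control": "tab:gray"}
    for ax, seg in zip(axes, SEGMENT_ORDER):
        for label, prof in profiles.items():
            sub = prof.table[prof.table["segment"] == seg]
            for anchor, a_sub in sub.groupby("anchor"):
                a_sub = a_sub.sort_values("position")
                x = a_sub["position"].to_numpy()
                if seg == "upstream_intron" or anchor == "3p":
                    x = -x  # distal positions to the left of the anchor
                ax.plot(x, a_sub["mean_score"], color=colors.get(label), lw=1,
                        label=label if (seg == SEGMENT_ORDER[0] and anchor in ("exon_proximal", "5p")) else None)
        ax.set_title(seg.replace("_", " "), fontsize=9)
        ax.set_xlabel("window position")
    axes[0].set_ylabel("mean motif coverage")
    axes[0].legend(fontsize=8)
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
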