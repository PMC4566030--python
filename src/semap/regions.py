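"""Strand-aware extraction of the sequences scanned around a cassette exon.

Two region layouts are produced:

* **enrichment regions** — exon body plus 250-nt intronic windows adjacent to
  the cassette exon, with splice-site nucleotides masked out of the scanned
  sequence (20 nt at each 3' splice site, 6 nt at each 5' splice site,
  whenever the window covers them);
* **map segments** — the five ordered segments of the positional binding map
  (upstream exon, upstream intron window, cassette exon, downstream intron
  window, downstream exon) with no splice-site exclusions.

All returned strings are RNA alphabet (T->U) in transcript direction: on the
minus strand the genomic slice is reverse-complemented, so "upstream" always
means 5' of the cassette exon in the transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .events import Interval, SkippedExonEvent

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BoundsError(ValueError):
    """Requested interval lies outside the chromosome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """Uppercase (soft-masked bases are scanned) and transcribe T->U."""
    return seq.upper().replace("T", "U")


class DictGenome:
    """In-memory genome: chrom -> DNA string. Bounds-checked fetch."""

    def __init__(self, chromosomes: Mapping[str, str]):
        self._chroms = dict(chromosomes)

    def length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._chroms:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.length(chrom) or start > end:
            raise BoundsError(
                f"[{start}, {end}) outside {chrom} (length {self.length(chrom)})"
            )
        return self._chroms[chrom][start:end]

    def chromosomes(self):
        return dict(self._chroms)


class FastaGenome:
    """FASTA-backed genome using pyfaidx indexed access."""

    def __init__(self, path):
        from pyfaidx import Fasta

        self._fasta = Fasta(str(path), as_raw=True, sequence_always_upper=False)

    def length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._fasta:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.length(chrom) or start > end:
            raise BoundsError(
                f"[{start}, {end}) outside {chrom} (length {self.length(chrom)})"
            )
        return str(self._fasta[chrom][start:end])


@dataclass
class RegionConfig:
    """Windowing and splice-site-exclusion parameters (nt).

    ``exclusion_mode='mask'`` removes splice-site nucleotides from the
    window in place; ``'shift'`` removes them from the intron first and then
    takes the exon-proximal window from what remains.
    """

    intron_window: int = 250
    three_ss_exclusion: int = 20
    five_ss_exclusion: int = 6
    apply_exclusions: bool = True
    exclusion_mode: str = "mask"  # or "shift"

    def __post_init__(self) -> None:
        if self.intron_window <= 0:
            raise ValueError("intron_window must be positive")
        if self.three_ss_exclusion < 0 or self.five_ss_exclusion < 0:
            raise ValueError("exclusions must be non-negative")
        if self.exclusion_mode not in ("mask", "shift"):
            raise ValueError("exclusion_mode must be 'mask' or 'shift'")


@dataclass(frozen=True)
class RegionProvenance:
    """Genomic span a region string came from, plus truncation bookkeeping."""

    chrom: str
    start: int
    end: int
    strand: str
    truncated: bool = False


@dataclass
class RegionSequences:
    """Scanned sequences for one event (enrichment layout)."""

    event_id: str
    upstream_intron: str
    exon_body: str
    downstream_intron: str
    upstream_exon: str
    downstream_exon: str
    provenance: dict[str, RegionProvenance] = field(default_factory=dict)

    def region(self, name: str) -> str:
        return getattr(self, name)


SEGMENT_ORDER = (
    "upstream_exon",
    "upstream_intron",
    "cassette_exon",
    "downstream_intron",
    "downstream_exon",
)


@dataclass
class MapSegments:
    """The five ordered map segments for one event, transcript direction."""

    event_id: str
    upstream_exon: str
    upstream_intron: str
    cassette_exon: str
    downstream_intron: str
    downstream_exon: str
    truncated: dict[str, bool] = field(default_factory=dict)

    def segment(self, name: str) -> str:
        return getattr(self, name)

    def ordered(self) -> list[tuple[str, str]]:
        return [(name, getattr(self, name)) for name in SEGMENT_ORDER]


def _introns(event: SkippedExonEvent) -> tuple[Interval, Interval]:
    """(upstream, downstream) introns in transcript direction, genomic coords."""
    left = Interval(event.left_exon.end, event.cassette_exon.start)
    right = Interval(event.cassette_exon.end, event.right_exon.start)
    return (left, right) if event.strand == "+" else (right, left)


def _fetch_transcript(genome, chrom: str, iv: Interval, strand: str) -> str:
    seq = genome.fetch(chrom, iv.start, iv.end)
    if strand == "-":
        seq = reverse_complement(seq)
    return to_rna(seq)


def _local_to_genomic(iv: Interval, strand: str, a: int, b: int) -> tuple[int, int]:
    """Map a transcript-local half-open slice [a, b) of an interval to genomic."""
    if strand == "+":
        return iv.start + a, iv.start + b
    return iv.end - b, iv.end - a


def _scan_slice(intron_len: int, side: str, cfg: RegionConfig) -> tuple[int, int]:
    """Transcript-local [a, b) of the scanned part of an intron.

    ``side='upstream'`` means the intron 5' of the cassette exon (its 3'
    splice site abuts the cassette); ``'downstream'`` the intron 3' of it.
    Exclusion zones sit at fixed intron ends: the first ``five_ss_exclusion``
    nt after any exon end (5'ss) and the last ``three_ss_exclusion`` nt before
    any exon start (3'ss).
    """
    L = intron_len
    w = min(cfg.intron_window, L)
    if not cfg.apply_exclusions:
        return (L - w, L) if side == "upstream" else (0, w)
    e5, e3 = cfg.five_ss_exclusion, cfg.three_ss_exclusion
    if cfg.exclusion_mode == "mask":
        # window first, then intersect with the non-excluded core [e5, L - e3)
        if side == "upstream":
            a, b = max(L - w, e5), L - e3
        else:
            a, b = e5, min(w, L - e3)
    else:  # shift: exclude, then take the exon-proximal window of the core
        core_a, core_b = e5, L - e3
        if core_a >= core_b:
            return (0, 0)
        w = min(cfg.intron_window, core_b - core_a)
        if side == "upstream":
            a, b = core_b - w, core_b
        else:
            a, b = core_a, core_a + w
    if a >= b:
        return (0, 0)
    return a, b


def extract_regions(
    event: SkippedExonEvent, genome, cfg: RegionConfig | None = None
) -> RegionSequences:
    """Extract the enrichment-scan regions for one event.

    Intronic windows are the ``intron_window`` nt adjacent to the cassette
    exon; splice-site nucleotides covered by the window are removed from the
    scanned string (an intron shorter than its exclusions yields an empty
    region flagged as truncated, never an error).
    """
    cfg = cfg or RegionConfig()
    up_intron, down_intron = _introns(event)
    if len(up_intron) <= 0 or len(down_intron) <= 0:
        raise ValueError(f"event {event.event_id}: introns must have positive length")

    prov: dict[str, RegionProvenance] = {}

    def intron_region(iv: Interval, side: str) -> str:
        a, b = _scan_slice(len(iv), side, cfg)
        full_window = min(cfg.intron_window, len(iv))
        expected = full_window - (
            (cfg.three_ss_exclusion + cfg.five_ss_exclusion) if cfg.apply_exclusions else 0
        )
        gs, ge = _local_to_genomic(iv, event.strand, a, b)
        truncated = (b - a) < max(expected, 0) or full_window < cfg.intron_window
        name = f"{side}_intron"
        prov[name] = RegionProvenance(event.chrom, gs, ge, event.strand, truncated)
        if b <= a:
            return ""
        return _fetch_transcript(genome, event.chrom, Interval(gs, ge), event.strand)

    def exon_region(iv: Interval, name: str) -> str:
        prov[name] = RegionProvenance(event.chrom, iv.start, iv.end, event.strand)
        return _fetch_transcript(genome, event.chrom, iv, event.strand)

    return RegionSequences(
        event_id=event.event_id,
        upstream_intron=intron_region(up_intron, "upstream"),
        exon_body=exon_region(event.cassette_exon, "exon_body"),
        downstream_intron=intron_region(down_intron, "downstream"),
        upstream_exon=exon_region(event.upstream_exon, "upstream_exon"),
        downstream_exon=exon_region(event.downstream_exon, "downstream_exon"),
        provenance=prov,
    )


def extract_map_segments(
    event: SkippedExonEvent, genome, cfg: RegionConfig | None = None
) -> MapSegments:
    """Extract the five ordered binding-map segments (no exclusions).

    Intron segments are the exon-proximal ``intron_window`` nt, truncated to
    the available intron length; flanking exons are used whole.
    """
    cfg = cfg or RegionConfig()
    up_intron, down_intron = _introns(event)
    if len(up_intron) <= 0 or len(down_intron) <= 0:
        raise ValueError(f"event {event.event_id}: introns must have positive length")

    truncated: dict[str, bool] = {}

    def intron_segment(iv: Interval, side: str) -> str:
        w = min(cfg.intron_window, len(iv))
        a, b = (len(iv) - w, len(iv)) if side == "upstream" else (0, w)
        gs, ge = _local_to_genomic(iv, event.strand, a, b)
        truncated[f"{side}_intron"] = w < cfg.intron_window
        return _fetch_transcript(genome, event.chrom, Interval(gs, ge), event.strand)

    return MapSegments(
        event_id=event.event_id,
        upstream_exon=_fetch_transcript(genome, event.chrom, event.upstream_exon, event.strand),
        upstream_intron=intron_segment(up_intron, "upstream"),
        cassette_exon=_fetch_transcript(genome, event.chrom, event.cassette_exon, event.strand),
        downstream_intron=intron_segment(down_intron, "downstream"),
        downstream_exon=_fetch_transcript(genome, event.chrom, event.downstream_exon, event.strand),
        truncated=truncated,
    )


def regions_to_bed(regions: RegionSequences) -> list[str]:
    """BED6 lines (0-based half-open, strand column) for the scanned regions."""
    lines = []
    for name, p in regions.provenance.items():
        lines.append(f"{p.chrom}\t{p.start}\t{p.end}\t{regions.event_id}|{name}\t0\t{p.strand}")
    return lines


def regions_to_fasta(regions_list, path) -> None:
    """FASTA of scanned region sequences with provenance headers."""
    with open(path, "w") as fh:
        for regions in regions_list:
            for name in ("upstream_intron", "exon_body", "downstream_intron",
                         "upstream_exon", "downstream_exon"):
                seq = regions.region(name)
                if not seq:
                    continue
                p = regions.provenance.get(name)
                loc = f" {p.chrom}:{p.start}-{p.end}({p.strand})" if p else ""
                fh.write(f">{regions.event_id}|{name}{loc}\n{seq}\n")
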