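"""Skipped-exon (cassette) event tables: parsing, PSI summaries, classification.

The unit of analysis is a cassette-exon trio — an alternative exon flanked by
two constitutive exons — with replicate-level percent-spliced-in (PSI) values
for two genotype groups and an event-level p-value/FDR from an upstream
differential-splicing caller (rMATS-style tab-delimited output).

Events are classified against a reference group (wild type by convention):

* ``enhanced``  — inclusion is higher in the reference group
  (delta PSI = mean PSI(reference) - mean PSI(comparison) >= +threshold,
  FDR below the significance cutoff);
* ``silenced``  — inclusion is lower in the reference group (delta PSI
  <= -threshold at the same FDR cutoff);
* ``control``   — no evidence of regulation (high FDR), intermediate
  inclusion in every group, and the host gene well expressed; these events
  form the background set for motif enrichment;
* ``unclassified`` — everything else.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

LABELS = ("enhanced", "silenced", "control", "unclassified")


class FormatError(ValueError):
    """A mandatory column is missing or a field cannot be parsed."""


class ValidationError(ValueError):
    """A parsed value violates the event contract (range, strand, ordering)."""


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValidationError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SkippedExonEvent:
    """One cassette-exon trio with replicate PSIs and test statistics.

    ``upstream_exon`` / ``downstream_exon`` are in *transcript* direction:
    on the minus strand the upstream exon is genomically to the right of the
    cassette. Missing replicates are stored as NaN.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    upstream_exon: Interval
    cassette_exon: Interval
    downstream_exon: Interval
    psi_by_group: dict[str, list[float]]
    p_value: float
    fdr: float
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"event {self.event_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        left, right = (
            (self.upstream_exon, self.downstream_exon)
            if self.strand == "+"
            else (self.downstream_exon, self.upstream_exon)
        )
        if not (left.end <= self.cassette_exon.start <= self.cassette_exon.end <= right.start):
            raise ValidationError(
                f"event {self.event_id}: exon trio not ordered on the genome"
            )
        for group, psis in self.psi_by_group.items():
            for v in psis:
                if not math.isnan(v) and not 0.0 <= v <= 1.0:
                    raise ValidationError(
                        f"event {self.event_id}: PSI {v} in group {group} outside [0, 1]"
                    )
        if not 0.0 <= self.p_value <= 1.0 or self.fdr < 0.0:
            raise ValidationError(f"event {self.event_id}: bad p/FDR")

    # genomic-order accessors used by region extraction
    @property
    def left_exon(self) -> Interval:
        return self.upstream_exon if self.strand == "+" else self.downstream_exon

    @property
    def right_exon(self) -> Interval:
        return self.downstream_exon if self.strand == "+" else self.upstream_exon


@dataclass(frozen=True)
class GroupPsiSummary:
    group: str
    mean_psi: float
    n_reps: int


@dataclass(frozen=True)
class EventClassification:
    event_id: str
    label: str
    delta_psi: float
    fdr: float


@dataclass
class TableDialect:
    """Column map and coordinate convention for rMATS-like SE tables.

    rMATS prints 0-based starts and end coordinates that already behave as
    half-open bounds, so the default conversion is the identity; set
    ``one_based_starts`` for GTF-style tables.
    """

    event_id: str = "ID"
    gene_id: str = "GeneID"
    gene_name: str = "geneSymbol"
    chrom: str = "chr"
    strand: str = "strand"
    exon_start: str = "exonStart_0base"
    exon_end: str = "exonEnd"
    upstream_start: str = "upstreamES"
    upstream_end: str = "upstreamEE"
    downstream_start: str = "downstreamES"
    downstream_end: str = "downstreamEE"
    inc_levels: tuple[str, str] = ("IncLevel1", "IncLevel2")
    p_value: str = "PValue"
    fdr: str = "FDR"
    group_labels: tuple[str, str] = ("WT", "KO")
    one_based_starts: bool = False

    def mandatory_columns(self) -> list[str]:
        return [
            self.event_id, self.gene_id, self.chrom, self.strand,
            self.exon_start, self.exon_end,
            self.upstream_start, self.upstream_end,
            self.downstream_start, self.downstream_end,
            *self.inc_levels, self.p_value, self.fdr,
        ]


DEFAULT_DIALECT = TableDialect()


def _parse_psi_list(raw: str, row_num: int) -> list[float]:
    out: list[float] = []
    for tok in str(raw).split(","):
        tok = tok.strip()
        if tok in ("NA", "nan", ""):
            out.append(math.nan)
            continue
        v = float(tok)
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"row {row_num}: PSI value {v} outside [0, 1]")
        out.append(v)
    return out


def read_se_table(path, dialect: TableDialect = DEFAULT_DIALECT) -> list[SkippedExonEvent]:
    """Parse a tab-delimited rMATS-style skipped-exon table.

    Replicate inclusion levels are comma-separated; ``NA`` entries are kept
    as NaN placeholders so replicate indices stay aligned across groups.
    """
    events: list[SkippedExonEvent] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header")
        missing = [c for c in dialect.mandatory_columns() if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        off = 1 if dialect.one_based_starts else 0
        for i, row in enumerate(reader, start=2):
            def iv(scol: str, ecol: str) -> Interval:
                return Interval(int(row[scol]) - off, int(row[ecol]))

            psi_by_group = {
                g: _parse_psi_list(row[col], i)
                for g, col in zip(dialect.group_labels, dialect.inc_levels)
            }
            events.append(
                SkippedExonEvent(
                    event_id=str(row[dialect.event_id]),
                    gene_id=str(row[dialect.gene_id]),
                    gene_name=str(row.get(dialect.gene_name, "")),
                    chrom=str(row[dialect.chrom]),
                    strand=str(row[dialect.strand]),
                    upstream_exon=iv(dialect.upstream_start, dialect.upstream_end),
                    cassette_exon=iv(dialect.exon_start, dialect.exon_end),
                    downstream_exon=iv(dialect.downstream_start, dialect.downstream_end),
                    psi_by_group=psi_by_group,
                    p_value=float(row[dialect.p_value]),
                    fdr=float(row[dialect.fdr]),
                )
            )
    return events


class DegenerateGroupError(ValueError):
    """Every replicate PSI in a group is missing."""


def summarize_groups(event: SkippedExonEvent) -> list[GroupPsiSummary]:
    """Mean PSI per group over non-missing replicates."""
    out = []
    for group, psis in event.psi_by_group.items():
        usable = [v for v in psis if not math.isnan(v)]
        if not usable:
            raise DegenerateGroupError(
                f"event {event.event_id}: group {group} has no usable replicates"
            )
        out.append(GroupPsiSummary(group, sum(usable) / len(usable), len(usable)))
    return out


@dataclass
class ClassifyThresholds:
    """Regulated/control cutoffs; defaults follow the study design.

    Regulated: FDR < 5% and |delta PSI| >= 5% (inclusive). Control: FDR > 50%,
    every group mean PSI strictly inside (0.15, 0.85), and the host gene with
    average FPKM > 5 in at least one group.
    """

    max_fdr: float = 0.05
    min_abs_delta_psi: float = 0.05
    control_min_fdr: float = 0.50
    control_psi_low: float = 0.15
    control_psi_high: float = 0.85
    control_min_fpkm: float = 5.0


def classify_events(
    events: Iterable[SkippedExonEvent],
    expression: Mapping[str, Mapping[str, float]] | None = None,
    thresholds: ClassifyThresholds | None = None,
    reference_group: str | None = None,
) -> dict[str, EventClassification]:
    """Partition events into enhanced / silenced / control / unclassified.

    ``expression`` maps gene_id -> group -> average FPKM and is consulted only
    by the control criterion; events whose gene is absent are excluded from
    the control set (warned, never raised). delta PSI is computed as
    mean PSI(reference) - mean PSI(comparison), so exons whose inclusion
    depends on the reference-group regulator have positive delta PSI.
    """
    th = thresholds or ClassifyThresholds()
    out: dict[str, EventClassification] = {}
    for event in events:
        summaries = summarize_groups(event)
        groups = [s.group for s in summaries]
        ref = reference_group if reference_group is not None else groups[0]
        if ref not in groups:
            raise ValidationError(f"reference group {ref!r} absent from event {event.event_id}")
        means = {s.group: s.mean_psi for s in summaries}
        comp = next(g for g in groups if g != ref)
        delta = means[ref] - means[comp]

        label = "unclassified"
        if event.fdr < th.max_fdr and delta >= th.min_abs_delta_psi:
            label = "enhanced"
        elif event.fdr < th.max_fdr and delta <= -th.min_abs_delta_psi:
            label = "silenced"
        elif event.fdr > th.control_min_fdr and all(
            th.control_psi_low < m < th.control_psi_high for m in means.values()
        ):
            if expression is None:
                label = "control"
            elif event.gene_id in expression:
                if any(v > th.control_min_fpkm for v in expression[event.gene_id].values()):
                    label = "control"
            else:
                logger.warning(
                    "event %s: gene %s absent from expression table; "
                    "excluded from control set",
                    event.event_id, event.gene_id,
                )
        out[event.event_id] = EventClassification(event.event_id, label, delta, event.fdr)
    return out


def label_counts(classifications: Mapping[str, EventClassification]) -> dict[str, int]:
    counts = {label: 0 for label in LABELS}
    for c in classifications.values():
        counts[c.label] += 1
    return counts


def compare_event_sets(sets: Mapping[str, set]) -> dict:
    """Venn-style overlap table for >= 2 event-id sets.

    Returns totals per set and the cardinality of every exclusive region
    (keyed by '&'-joined sorted member labels).
    """
    if len(sets) < 2:
        raise ValueError("need at least two event sets to compare")
    labels = sorted(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for members in combinations(labels, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(set(), *(sets[m] for m in labels if m not in members))
            regions["&".join(members)] = len(inside - outside)
    return {"totals": {m: len(sets[m]) for m in labels}, "exclusive_regions": regions}


def write_classifications(classifications: Mapping[str, EventClassification], path) -> None:
    """TSV of (event_id, label, delta_psi, fdr); round-trips with the reader."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["event_id", "label", "delta_psi", "fdr"])
        for c in classifications.values():
            w.writerow([c.event_id, c.label, repr(c.delta_psi), repr(c.fdr)])


def read_classifications(path) -> dict[str, EventClassification]:
    out: dict[str, EventClassification] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["event_id"]] = EventClassification(
                row["event_id"], row["label"], float(row["delta_psi"]), float(row["fdr"])
            )
    return out


def write_overlap_summary(
    classifications: Mapping[str, EventClassification],
    overlaps: dict | None,
    path,
) -> None:
    """JSON summary of label counts and (optionally) cross-comparison overlaps."""
    payload: dict = {"label_counts": label_counts(classifications)}
    if overlaps is not None:
        payload["overlaps"] = overlaps
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
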