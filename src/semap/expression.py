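"""Differential-gene-expression filters for Cuffdiff-style FPKM tables.

A gene is called differentially expressed (DEG) when q < 0.05, the group-mean
FPKM ratio exceeds twofold (strict), and the larger group mean exceeds the
0.1 FPKM floor. A separate filter extracts an RNA-binding-protein /
splicing-factor panel at a gentler fold cutoff (>= 1.5-fold, inclusive).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


@dataclass
class ExpressionRecord:
    gene_id: str
    gene_name: str
    fpkm_by_group: dict[str, float]
    q_value: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fpkm_by_group.values()):
            raise ValueError(f"gene {self.gene_id}: negative FPKM")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"gene {self.gene_id}: q-value outside [0, 1]")

    def means(self) -> tuple[float, float]:
        vals = list(self.fpkm_by_group.values())
        if len(vals) != 2:
            raise ValueError(f"gene {self.gene_id}: expected exactly two groups")
        return vals[0], vals[1]

    def fold_change(self, pseudocount: float = 0.0) -> float:
        """max/min ratio of group means; inf when one mean is zero (no
        pseudocount), NaN when both are zero."""
        m1, m2 = (v + pseudocount for v in self.means())
        if m1 == 0 and m2 == 0:
            return math.nan
        lo, hi = sorted((m1, m2))
        return math.inf if lo == 0 else hi / lo


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    is_deg: bool
    direction: str  # 'up' / 'down' in the comparison group, '' when not DEG


@dataclass
class DegThresholds:
    max_q: float = 0.05
    min_fold: float = 2.0       # strict: fold must EXCEED this
    min_fpkm: float = 0.1       # floor on the larger group mean (strict)
    fpkm_rule: str = "max"      # 'max': larger mean > floor; 'both': both means
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.fpkm_rule not in ("max", "both"):
            raise ValueError("fpkm_rule must be 'max' or 'both'")


def deg_filter(
    records: Iterable[ExpressionRecord],
    thresholds: DegThresholds | None = None,
    reference_group: str | None = None,
) -> list[DegCall]:
    """Apply the three DEG criteria; direction is relative to the comparison
    (non-reference) group."""
    th = thresholds or DegThresholds()
    calls = []
    for rec in records:
        groups = list(rec.fpkm_by_group)
        ref = reference_group if reference_group is not None else groups[0]
        if ref not in groups:
            raise ValueError(f"reference group {ref!r} absent for gene {rec.gene_id}")
        comp = next(g for g in groups if g != ref)
        ref_mean, comp_mean = rec.fpkm_by_group[ref], rec.fpkm_by_group[comp]
        if ref_mean == 0 and comp_mean == 0:
            logger.info("gene %s: zero FPKM in both groups, never a DEG", rec.gene_id)
            calls.append(DegCall(rec.gene_id, False, ""))
            continue
        fold = rec.fold_change(th.pseudocount)
        if th.fpkm_rule == "max":
            fpkm_ok = max(ref_mean, comp_mean) > th.min_fpkm
        else:
            fpkm_ok = min(ref_mean, comp_mean) > th.min_fpkm
        is_deg = rec.q_value < th.max_q and fold > th.min_fold and fpkm_ok
        direction = ("up" if comp_mean > ref_mean else "down") if is_deg else ""
        calls.append(DegCall(rec.gene_id, is_deg, direction))
    return calls


def deg_counts(calls: Sequence[DegCall]) -> dict[str, int]:
    return {
        "deg": sum(c.is_deg for c in calls),
        "up": sum(c.direction == "up" for c in calls),
        "down": sum(c.direction == "down" for c in calls),
    }


def rbp_panel(
    records: Iterable[ExpressionRecord],
    panel: Sequence[str],
    min_fold: float = 1.5,
) -> list[ExpressionRecord]:
    """Panel members with fold change >= ``min_fold`` (inclusive), sorted by
    descending |log2 fold|. ``panel`` matches gene_id or gene_name."""
    if not panel:
        raise ValueError("empty RBP panel")
    wanted = set(panel)
    hits = []
    for rec in records:
        if rec.gene_id not in wanted and rec.gene_name not in wanted:
            continue
        fold = rec.fold_change()
        if not math.isnan(fold) and fold >= min_fold:
            hits.append((abs(math.log2(fold)) if math.isfinite(fold) else math.inf, rec))
    hits.sort(key=lambda t: -t[0])
    return [rec for _, rec in hits]


@dataclass
class ExpressionDialect:
    """Column map for Cuffdiff gene_exp.diff-like tables."""

    gene_id: str = "gene_id"
    gene_name: str = "gene"
    value_1: str = "value_1"
    value_2: str = "value_2"
    q_value: str = "q_value"
    group_labels: tuple[str, str] = ("WT", "KO")


DEFAULT_EXPRESSION_DIALECT = ExpressionDialect()


def read_expression_table(
    path, dialect: ExpressionDialect = DEFAULT_EXPRESSION_DIALECT
) -> list[ExpressionRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        for col in (dialect.gene_id, dialect.value_1, dialect.value_2, dialect.q_value):
            if col not in reader.fieldnames:
                raise ValueError(f"{path}: missing mandatory column {col!r}")
        g1, g2 = dialect.group_labels
        for row in reader:
            records.append(
                ExpressionRecord(
                    gene_id=row[dialect.gene_id],
                    gene_name=row.get(dialect.gene_name, "") or "",
                    fpkm_by_group={g1: float(row[dialect.value_1]),
                                   g2: float(row[dialect.value_2])},
                    q_value=float(row[dialect.q_value]),
                )
            )
    return records


def expression_index(records: Iterable[ExpressionRecord]) -> dict[str, dict[str, float]]:
    """gene_id -> group -> mean FPKM map, as consumed by event classification."""
    return {rec.gene_id: dict(rec.fpkm_by_group) for rec in records}


def write_deg_tsv(records: Sequence[ExpressionRecord], calls: Sequence[DegCall], path) -> None:
    by_id = {r.gene_id: r for r in records}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "gene_name", "fold_change", "q_value", "is_deg", "direction"])
        for c in calls:
            rec = by_id[c.gene_id]
            w.writerow([c.gene_id, rec.gene_name, f"{rec.fold_change():.6g}",
                        repr(rec.q_value), int(c.is_deg), c.direction])
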