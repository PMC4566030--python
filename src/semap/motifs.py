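"""RBP motif counting and region-wise enrichment testing.

Occurrences of short RNA motifs (literal or IUPAC-degenerate) are counted in
regulated vs control region sequences in two modes:

* **by-NT** — every (possibly overlapping) matching start position counts;
* **by-Sequence** — a motif counts at most once per sequence.

Each motif x region x direction is tested with a right-sided Fisher exact
test on a 2x2 table, by-NT p-values are Benjamini-Hochberg adjusted within
each region family, and a motif is called enriched when FDR(by-NT) < 5% and
the raw by-Sequence p < 0.01.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .regions import RegionSequences

# IUPAC RNA codes -> matched base sets. N in a *sequence* matches nothing:
# character classes list concrete bases only, so sequence Ns never match.
IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

REGIONS = ("exon_body", "upstream_intron", "downstream_intron")


@dataclass(frozen=True)
class Motif:
    """A named RNA motif; the pattern may use IUPAC degeneracy codes."""

    name: str
    pattern: str
    source: str = "known_rbp_set"

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise ValueError(f"motif {self.name}: empty pattern")
        bad = [ch for ch in self.pattern if ch not in IUPAC_RNA]
        if bad:
            raise ValueError(
                f"motif {self.name}: non-IUPAC-RNA symbol(s) {bad} in {self.pattern!r}"
            )

    def compiled(self) -> re.Pattern:
        return _compile(self.pattern)


def _compile(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    body = "".join(
        ch if len(IUPAC_RNA[ch]) == 1 else f"[{IUPAC_RNA[ch]}]" for ch in pattern
    )
    return re.compile(f"(?=({body}))")


_PATTERN_CACHE: dict[str, re.Pattern] = {}


def _compiled(pattern: str) -> re.Pattern:
    pat = _PATTERN_CACHE.get(pattern)
    if pat is None:
        pat = _compile(pattern)
        _PATTERN_CACHE[pattern] = pat
    return pat


def match_starts(seq: str, motif: Motif) -> list[int]:
    """Start positions of all (overlapping) occurrences of the motif."""
    return [m.start() for m in _compiled(motif.pattern).finditer(seq)]


def count_occurrences(seq: str, motif: Motif, mode: str = "by_nt") -> int:
    """Count motif occurrences; by-NT counts every start, by-Sequence 0/1."""
    if mode == "by_nt":
        return len(match_starts(seq, motif))
    if mode == "by_seq":
        return 1 if _compiled(motif.pattern).search(seq) else 0
    raise ValueError(f"unknown counting mode {mode!r}")


def fisher_right(a, b, c, d):
    """Right-tail Fisher exact p for the 2x2 table [[a, b], [c, d]].

    P(X >= a) under the hypergeometric law with all margins fixed. Accepts
    scalars (returns float) or equal-shaped integer arrays (returns ndarray).
    """
    arrs = [np.asarray(v) for v in (a, b, c, d)]
    for v in arrs:
        if not np.issubdtype(v.dtype, np.integer) or np.any(v < 0):
            raise ValueError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    av, bv, cv, dv = arrs
    n_total = av + bv + cv + dv
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(av - 1, n_total, av + cv, av + bv)
    p = np.where(n_total == 0, 1.0, np.minimum(p, 1.0))
    return float(p) if p.ndim == 0 else p


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enumerate_kmers(k: int, source: str = "kmer_enumeration") -> list[Motif]:
    """All 4^k literal RNA k-mers in lexicographic (ACGU) order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [Motif("".join(t), "".join(t), source) for t in product("ACGU", repeat=k)]


def read_motif_tsv(path) -> list[Motif]:
    """Motif file: TSV with columns name, pattern[, source]."""
    motifs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            motifs.append(
                Motif(row["name"], row["pattern"].strip().upper(),
                      row.get("source", "known_rbp_set") or "known_rbp_set")
            )
    if not motifs:
        raise ValueError(f"{path}: no motifs")
    return motifs


@dataclass
class EnrichConfig:
    """Enrichment thresholds and the by-NT table construction.

    ``by_nt_table='positions'`` compares occurrence counts against remaining
    scannable start positions; ``'coverage'`` compares motif-covered
    nucleotides against uncovered ones.
    """

    fdr_by_nt: float = 0.05
    p_by_seq: float = 0.01
    by_nt_table: str = "positions"  # or "coverage"
    regions: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        if self.by_nt_table not in ("positions", "coverage"):
            raise ValueError("by_nt_table must be 'positions' or 'coverage'")


@dataclass
class EnrichmentResult:
    motif: Motif
    region: str
    direction: str
    a: int
    b: int
    c: int
    d: int
    p_by_nt: float
    p_by_seq: float
    fdr_by_nt: float = float("nan")
    enriched: bool = False


def _covered_nt(seq: str, motif: Motif) -> int:
    track = np.zeros(len(seq), dtype=bool)
    k = len(motif.pattern)
    for s in match_starts(seq, motif):
        track[s : s + k] = True
    return int(track.sum())


def _by_nt_counts(seqs: Sequence[str], motif: Motif, table: str) -> tuple[int, int]:
    k = len(motif.pattern)
    if table == "positions":
        hits = sum(len(match_starts(s, motif)) for s in seqs)
        positions = sum(max(0, len(s) - k + 1) for s in seqs)
        return hits, positions - hits
    covered = sum(_covered_nt(s, motif) for s in seqs)
    total = sum(len(s) for s in seqs)
    return covered, total - covered


def _by_seq_counts(seqs: Sequence[str], motif: Motif) -> tuple[int, int]:
    with_hit = sum(count_occurrences(s, motif, "by_seq") for s in seqs)
    return with_hit, len(seqs) - with_hit


def enrich(
    regulated_regions: Mapping[str, Sequence[RegionSequences]],
    control_regions: Sequence[RegionSequences],
    motifs: Sequence[Motif],
    cfg: EnrichConfig | None = None,
) -> list[EnrichmentResult]:
    """Test each motif for enrichment per region and regulation direction.

    ``regulated_regions`` maps direction label (e.g. 'enhanced', 'silenced')
    to that direction's extracted regions; ``control_regions`` is the shared
    background. BH correction is applied to by-NT p-values across motifs
    within each (region, direction) family; by-Sequence p-values are used raw.
    """
    cfg = cfg or EnrichConfig()
    if not motifs:
        raise ValueError("empty motif set")
    if not control_regions or not regulated_regions or any(
        len(v) == 0 for v in regulated_regions.values()
    ):
        raise ValueError("regulated and control region sets must be non-empty")

    results: list[EnrichmentResult] = []
    for direction, reg_set in regulated_regions.items():
        for region in cfg.regions:
            reg_seqs = [r.region(region) for r in reg_set]
            ctl_seqs = [r.region(region) for r in control_regions]
            family: list[EnrichmentResult] = []
            for motif in motifs:
                a, b = _by_nt_counts(reg_seqs, motif, cfg.by_nt_table)
                c, d = _by_nt_counts(ctl_seqs, motif, cfg.by_nt_table)
                sa, sb = _by_seq_counts(reg_seqs, motif)
                sc, sd = _by_seq_counts(ctl_seqs, motif)
                family.append(
                    EnrichmentResult(
                        motif=motif, region=region, direction=direction,
                        a=a, b=b, c=c, d=d,
                        p_by_nt=fisher_right(a, b, c, d),
                        p_by_seq=fisher_right(sa, sb, sc, sd),
                    )
                )
            fdrs = bh_adjust([r.p_by_nt for r in family])
            for r, fdr in zip(family, fdrs):
                r.fdr_by_nt = fdr
                r.enriched = fdr < cfg.fdr_by_nt and r.p_by_seq < cfg.p_by_seq
            results.extend(family)
    return results


def enrichment_table(results: Iterable[EnrichmentResult]):
    """Long-format DataFrame mirroring the result TSV layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "motif": r.motif.name, "pattern": r.motif.pattern,
                "region": r.region, "direction": r.direction,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "p_by_nt": r.p_by_nt, "fdr_by_nt": r.fdr_by_nt,
                "p_by_seq": r.p_by_seq, "enriched": r.enriched,
            }
            for r in results
        ]
    )


def write_enrichment_tsv(results: Iterable[EnrichmentResult], path, cfg: EnrichConfig | None = None) -> None:
    df = enrichment_table(results)
    with open(path, "w") as fh:
        if cfg is not None:
            fh.write(f"# by_nt_table={cfg.by_nt_table} fdr_by_nt<{cfg.fdr_by_nt} p_by_seq<{cfg.p_by_seq}\n")
        df.to_csv(fh, sep="\t", index=False)
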