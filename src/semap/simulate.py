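"""Synthetic cassette-exon datasets with planted regulatory architecture.

The generator emulates the data structure the analysis consumes: a genome
FASTA, an rMATS-style skipped-exon table with replicate PSIs and test
statistics, a Cuffdiff-style expression table, and a truth bundle.

Default study conditions: 119 enhanced / 95 silenced / 500 control events
(the sizes of the largest knockout-vs-wild-type comparison), 3 biological
replicates per genotype group, beta-distributed replicate PSIs with an
effect size of |delta PSI| = 0.4 and within-group SD ~ 0.05, uniform base
composition, and a GU-rich 6-mer (UGGUGG) planted at a mean rate of 1
occurrence per event in the upstream introns of silenced exons and the
downstream introns of enhanced exons — the directionality expected of an
epithelial splicing regulator that represses via upstream/exonic binding and
activates via downstream binding.

Event p-values/FDRs are, by default, *computed* (two-sample t-test on the
simulated replicate PSIs, then BH across events) so threshold-based
classification behaves as it does on real tables; a ``deterministic`` mode
places p/FDR strictly beyond the thresholds for exact-recovery checks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .events import Interval, SkippedExonEvent
from .expression import ExpressionRecord
from .motifs import Motif, bh_adjust
from .regions import DictGenome, RegionConfig, RegionSequences, _scan_slice, reverse_complement

logger = logging.getLogger(__name__)

RNA_TO_DNA = str.maketrans("U", "T")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic dataset."""

    n_enhanced: int = 119
    n_silenced: int = 95
    n_control: int = 500
    groups: tuple[str, str] = ("WT", "DKO")   # (reference, comparison)
    n_replicates: int = 3

    # PSI model: replicate ~ Beta(mu*nu, (1-mu)*nu); nu=99 gives SD ~ 0.05
    psi_high: float = 0.75
    psi_low: float = 0.35
    control_psi_range: tuple[float, float] = (0.35, 0.65)
    concentration: float = 99.0
    delta_psi_range: tuple[float, float] | None = None  # per-event |delta|, else fixed high/low

    fdr_mode: str = "test"  # 'test' (computed) or 'deterministic'

    # geometry (nt)
    flank_exon_len: tuple[int, int] = (80, 200)
    cassette_exon_len: tuple[int, int] = (120, 250)
    intron_len: tuple[int, int] = (400, 800)
    spacer: int = 100
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A C G T

    # motif planting: (event_set, region) -> mean occurrences per event
    planted_motif: str = "UGGUGG"
    planting_rates: dict = field(default_factory=lambda: {
        ("silenced", "upstream_intron"): 1.0,
        ("enhanced", "downstream_intron"): 1.0,
    })
    region_cfg: RegionConfig = field(default_factory=RegionConfig)

    # expression model
    n_deg_up: int = 178
    n_deg_down: int = 337
    n_null_genes: int = 1000
    n_low_genes: int = 50
    deg_fold: float = 4.0
    control_gene_fpkm: tuple[float, float] = (10.0, 30.0)

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_enhanced, self.n_silenced) < 0 or self.n_control < 0:
            raise ValueError("event counts must be non-negative")
        if self.fdr_mode not in ("test", "deterministic"):
            raise ValueError("fdr_mode must be 'test' or 'deterministic'")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        min_region = self.region_cfg.intron_window
        if self.intron_len[0] < min_region + self.region_cfg.three_ss_exclusion + self.region_cfg.five_ss_exclusion:
            logger.info("introns may be shorter than the scan window; regions will truncate")
        if self.cassette_exon_len[0] < len(self.planted_motif):
            raise ValueError("cassette exons shorter than the planted motif are infeasible")


def plant_motifs(seq: str, motif: str, rate: float, rng: np.random.Generator,
                 count: int | None = None) -> tuple[str, list[int]]:
    """Overwrite Poisson(rate)-many non-overlapping copies of ``motif`` into
    ``seq`` at uniform positions; returns the new sequence and start positions.

    The sequence length is preserved. When the requested count cannot be
    placed without overlap the count is truncated with a warning.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    k = len(motif)
    if k > len(seq):
        if rate > 0 or (count or 0) > 0:
            warnings.warn("motif longer than sequence; nothing planted", stacklevel=2)
        return seq, []
    n = int(rng.poisson(rate)) if count is None else count
    if n == 0:
        return seq, []
    available = np.ones(len(seq) - k + 1, dtype=bool)
    chars = list(seq)
    positions: list[int] = []
    for _ in range(n):
        idx = np.flatnonzero(available)
        if idx.size == 0:
            warnings.warn("sequence too short for requested non-overlapping placements; "
                          f"planted {len(positions)} of {n}", stacklevel=2)
            break
        s = int(rng.choice(idx))
        chars[s : s + k] = motif
        positions.append(s)
        lo, hi = max(0, s - k + 1), min(len(available), s + k)
        available[lo:hi] = False
    return "".join(chars), sorted(positions)


@dataclass
class TruthBundle:
    """Ground truth emitted alongside the tables."""

    events: dict  # event_id -> {label, true_delta_psi, planted: {region: [offsets]}}
    genes: dict   # gene_id -> {is_deg, direction}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"events": self.events, "genes": self.genes}, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimResult:
    genome: DictGenome
    events: list[SkippedExonEvent]
    se_table: pd.DataFrame
    expression: list[ExpressionRecord]
    expression_table: pd.DataFrame
    truth: TruthBundle
    config: SimConfig

    def write(self, out_dir) -> dict[str, str]:
        """Write genome.fa, se_events.tsv, gene_expression.tsv, truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": str(out / "genome.fa"),
            "se_table": str(out / "se_events.tsv"),
            "expression": str(out / "gene_expression.tsv"),
            "truth": str(out / "truth.json"),
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.chromosomes().items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.se_table.to_csv(paths["se_table"], sep="\t", index=False)
        self.expression_table.to_csv(paths["expression"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        return paths


def _random_dna(n: int, rng: np.random.Generator, freqs) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=list(freqs)))


def _beta_reps(mu: float, nu: float, n: int, rng: np.random.Generator) -> np.ndarray:
    mu = float(np.clip(mu, 1e-4, 1 - 1e-4))
    return rng.beta(mu * nu, (1 - mu) * nu, size=n)


def simulate_dataset(cfg: SimConfig | None = None, out_dir=None) -> SimResult:
    """Generate a complete synthetic dataset; deterministic for a given seed."""
    cfg = cfg or SimConfig()
    if cfg.n_control == 0:
        raise ValueError(
            "n_control must be positive: downstream enrichment requires a non-empty control set"
        )
    rng = np.random.default_rng(cfg.seed)
    ref, comp = cfg.groups

    labels = (["enhanced"] * cfg.n_enhanced + ["silenced"] * cfg.n_silenced
              + ["control"] * cfg.n_control)
    rng.shuffle(labels)

    chrom = "chrS1"
    parts: list[str] = []
    offset = 0
    events: list[SkippedExonEvent] = []
    truth_events: dict = {}
    rows: list[dict] = []
    reps_ref = np.zeros((len(labels), cfg.n_replicates))
    reps_comp = np.zeros((len(labels), cfg.n_replicates))
    true_deltas = np.zeros(len(labels))

    for i, label in enumerate(labels):
        event_id = f"SE{i:05d}"
        gene_id = f"GENE{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        lu = int(rng.integers(*cfg.flank_exon_len))
        ld = int(rng.integers(*cfg.flank_exon_len))
        lc = int(rng.integers(*cfg.cassette_exon_len))
        li1 = int(rng.integers(*cfg.intron_len))
        li2 = int(rng.integers(*cfg.intron_len))

        # transcript-orientation pieces (DNA alphabet)
        pieces = {
            "upstream_exon": _random_dna(lu, rng, cfg.base_freqs),
            "upstream_intron": _random_dna(li1, rng, cfg.base_freqs),
            "cassette_exon": _random_dna(lc, rng, cfg.base_freqs),
            "downstream_intron": _random_dna(li2, rng, cfg.base_freqs),
            "downstream_exon": _random_dna(ld, rng, cfg.base_freqs),
        }
        planted: dict[str, list[int]] = {}
        motif_dna = cfg.planted_motif.translate(RNA_TO_DNA)
        for region in ("upstream_intron", "exon_body", "downstream_intron"):
            rate = cfg.planting_rates.get((label, region), 0.0)
            if rate <= 0:
                continue
            if region == "exon_body":
                seq = pieces["cassette_exon"]
                a, b = 0, len(seq)
                key = "cassette_exon"
            else:
                key = region
                seq = pieces[key]
                side = "upstream" if region == "upstream_intron" else "downstream"
                a, b = _scan_slice(len(seq), side, cfg.region_cfg)
            if b - a < len(motif_dna):
                continue
            window, pos = plant_motifs(seq[a:b], motif_dna, rate, rng)
            pieces[key] = seq[:a] + window + seq[b:]
            if pos:
                planted[region] = pos  # offsets relative to the scanned window

        transcript_block = "".join(
            pieces[k] for k in ("upstream_exon", "upstream_intron", "cassette_exon",
                                "downstream_intron", "downstream_exon")
        )
        block = transcript_block if strand == "+" else reverse_complement(transcript_block)
        start = offset + cfg.spacer
        parts.append(_random_dna(cfg.spacer, rng, cfg.base_freqs))
        parts.append(block)
        offset = start + len(block)

        if strand == "+":
            up = Interval(start, start + lu)
            cas = Interval(up.end + li1, up.end + li1 + lc)
            dn = Interval(cas.end + li2, cas.end + li2 + ld)
        else:
            dn = Interval(start, start + ld)
            cas = Interval(dn.end + li2, dn.end + li2 + lc)
            up = Interval(cas.end + li1, cas.end + li1 + lu)

        # PSI model
        if label == "enhanced":
            delta = (rng.uniform(*cfg.delta_psi_range) if cfg.delta_psi_range
                     else cfg.psi_high - cfg.psi_low)
            mid = (cfg.psi_high + cfg.psi_low) / 2
            mu_ref, mu_comp = mid + delta / 2, mid - delta / 2
        elif label == "silenced":
            delta = -(rng.uniform(*cfg.delta_psi_range) if cfg.delta_psi_range
                      else cfg.psi_high - cfg.psi_low)
            mid = (cfg.psi_high + cfg.psi_low) / 2
            mu_ref, mu_comp = mid + delta / 2, mid - delta / 2
        else:
            mu_ref = mu_comp = rng.uniform(*cfg.control_psi_range)
            delta = 0.0
        reps_ref[i] = _beta_reps(mu_ref, cfg.concentration, cfg.n_replicates, rng)
        reps_comp[i] = _beta_reps(mu_comp, cfg.concentration, cfg.n_replicates, rng)
        true_deltas[i] = delta

        events.append(SkippedExonEvent(
            event_id=event_id, gene_id=gene_id, gene_name=gene_id, chrom=chrom,
            strand=strand, upstream_exon=up, cassette_exon=cas, downstream_exon=dn,
            psi_by_group={ref: reps_ref[i].tolist(), comp: reps_comp[i].tolist()},
            p_value=0.5, fdr=0.5,
        ))
        truth_events[event_id] = {
            "label": label, "gene_id": gene_id,
            "true_delta_psi": float(delta), "planted": planted,
        }

    genome = DictGenome({chrom: "".join(parts)})

    # event-level statistics
    if cfg.fdr_mode == "test":
        tt = stats.ttest_ind(reps_ref, reps_comp, axis=1, equal_var=True)
        pvals = np.asarray(tt.pvalue)
        fdrs = np.array(bh_adjust(pvals))
    else:
        regulated = np.array([labels[i] != "control" for i in range(len(labels))])
        pvals = np.where(regulated, 1e-6, 0.8)
        fdrs = np.where(regulated, 1e-4, 0.9)
    for i, ev in enumerate(events):
        ev.p_value = float(pvals[i])
        ev.fdr = float(fdrs[i])

    for ev in events:
        inc1 = ",".join(repr(round(v, 6)) for v in ev.psi_by_group[ref])
        inc2 = ",".join(repr(round(v, 6)) for v in ev.psi_by_group[comp])
        rows.append({
            "ID": ev.event_id, "GeneID": ev.gene_id, "geneSymbol": ev.gene_name,
            "chr": ev.chrom, "strand": ev.strand,
            "exonStart_0base": ev.cassette_exon.start, "exonEnd": ev.cassette_exon.end,
            "upstreamES": ev.upstream_exon.start, "upstreamEE": ev.upstream_exon.end,
            "downstreamES": ev.downstream_exon.start, "downstreamEE": ev.downstream_exon.end,
            "IncLevel1": inc1, "IncLevel2": inc2,
            "PValue": ev.p_value, "FDR": ev.fdr,
            "IncLevelDifference": round(float(np.nanmean(ev.psi_by_group[ref]))
                                        - float(np.nanmean(ev.psi_by_group[comp])), 6),
        })
    se_table = pd.DataFrame(rows)

    # expression table: event genes + planted DEGs + nulls + low-expression genes
    expr_records: list[ExpressionRecord] = []
    truth_genes: dict = {}

    for i, label in enumerate(labels):
        gene_id = f"GENE{i:05d}"
        if label == "control":
            v1 = float(rng.uniform(*cfg.control_gene_fpkm))
            v2 = float(rng.uniform(*cfg.control_gene_fpkm))
            q = 0.85
        else:
            v1 = float(rng.uniform(2, 20))
            v2 = v1 * float(rng.uniform(0.85, 1.18))
            q = 0.5
        expr_records.append(ExpressionRecord(gene_id, gene_id, {ref: v1, comp: v2}, q))
        truth_genes[gene_id] = {"is_deg": False, "direction": ""}

    def add_gene(prefix: str, j: int, v_ref: float, v_comp: float, q: float,
                 is_deg: bool, direction: str) -> None:
        gid = f"{prefix}{j:05d}"
        expr_records.append(ExpressionRecord(gid, gid, {ref: v_ref, comp: v_comp}, q))
        truth_genes[gid] = {"is_deg": is_deg, "direction": direction}

    for j in range(cfg.n_deg_up):
        base = float(rng.uniform(1, 10))
        add_gene("DEGU", j, base, base * cfg.deg_fold, 1e-4, True, "up")
    for j in range(cfg.n_deg_down):
        base = float(rng.uniform(1, 10))
        add_gene("DEGD", j, base * cfg.deg_fold, base, 1e-4, True, "down")
    for j in range(cfg.n_null_genes):
        base = float(rng.uniform(0.5, 20))
        add_gene("NULL", j, base, base * float(rng.uniform(0.8, 1.25)),
                 float(rng.uniform(0.2, 1.0)), False, "")
    for j in range(cfg.n_low_genes):
        base = float(rng.uniform(0.002, 0.015))
        add_gene("LOWX", j, base, base * 5.0, 1e-4, False, "")

    expression_table = pd.DataFrame([
        {"gene_id": r.gene_id, "gene": r.gene_name,
         "value_1": r.fpkm_by_group[ref], "value_2": r.fpkm_by_group[comp],
         "q_value": r.q_value}
        for r in expr_records
    ])

    truth = TruthBundle(truth_events, truth_genes)
    result = SimResult(genome, events, se_table, expr_records, expression_table, truth, cfg)
    if out_dir is not None:
        result.write(out_dir)
    return result


def simulate_null_regions(
    n_regulated: int, n_control: int, rng: np.random.Generator,
    intron_len: int = 230, exon_len: int = 150,
    base_freqs=(0.25, 0.25, 0.25, 0.25),
) -> tuple[dict[str, list[RegionSequences]], list[RegionSequences]]:
    """Region sequences drawn i.i.d. from one base composition for both the
    'regulated' and control sets — a null for enrichment calibration."""
    def rna(n: int) -> str:
        return _random_dna(n, rng, base_freqs).replace("T", "U")

    def one(i: int, tag: str) -> RegionSequences:
        return RegionSequences(
            event_id=f"{tag}{i:04d}",
            upstream_intron=rna(intron_len), exon_body=rna(exon_len),
            downstream_intron=rna(intron_len),
            upstream_exon=rna(exon_len), downstream_exon=rna(exon_len),
        )

    regulated = {"regulated": [one(i, "R") for i in range(n_regulated)]}
    control = [one(i, "C") for i in range(n_control)]
    return regulated, control


def simulate_rt_pcr_measurements(
    true_deltas, rng: np.random.Generator, noise_sd: float = 0.05
) -> np.ndarray:
    """Gel-quantified delta-PSI re-measurements: truth plus measurement noise,
    clipped to the attainable [-1, 1] range."""
    arr = np.asarray(list(true_deltas), dtype=float)
    return np.clip(arr + rng.normal(0.0, noise_sd, size=arr.shape), -1.0, 1.0)
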