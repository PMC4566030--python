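# semap

Analysis toolkit for splicing-regulator studies built on skipped-exon
(cassette) events: classify differentially spliced exons from rMATS-style
tables, test RNA-binding-protein motifs for region-wise enrichment, compute
positional "RNA binding maps" around regulated exons, filter
differentially expressed genes from Cuffdiff-style FPKM tables, and
reproduce the small quantitative statistics such analyses report. A
synthetic-data generator emits complete datasets (genome FASTA, event and
expression tables, truth labels) with planted motif architecture, so every
stage is testable end to end without sequencing data.

The package is written for transcriptomics researchers studying tissue- or
cell-type-specific splicing programs — the motivating case is an epithelial
splicing regulator (Esrp1/2) whose loss in mouse epidermis switches hundreds
of cassette exons — but all thresholds, motif sets and group labels are
configuration.

## The model

For each cassette exon, percent spliced in (PSI, ψ) is the fraction of the
gene's transcripts that include the exon; Δψ = mean ψ(reference group) −
mean ψ(comparison group). Events are partitioned as:

- **enhanced**: FDR < 5% and Δψ ≥ +5% (inclusion depends on the regulator),
- **silenced**: FDR < 5% and Δψ ≤ −5%,
- **control**: FDR > 50%, every group mean ψ ∈ (0.15, 0.85), host gene with
  average FPKM > 5 in at least one group — the enrichment background,
- **unclassified** otherwise.

Motifs are scanned in the exon body and in 250-nt intronic windows adjacent
to the exon, excluding 20 nt at each 3′ splice site and 6 nt at each 5′
splice site. Two counting modes feed a right-sided Fisher exact test of
regulated vs control regions: **by-NT** (every, possibly overlapping,
occurrence vs remaining scannable start positions) and **by-Sequence**
(sequences with ≥1 hit vs without). By-NT p-values are Benjamini–Hochberg
corrected per region family; a motif is *enriched* when FDR(by-NT) < 5% and
raw p(by-Sequence) < 0.01.

The RNA binding map scores each 50-nt window (slid 1 nt) by the fraction of
its nucleotides covered by any motif of a GU-rich 6-mer set, across five
segments (upstream exon, 250-nt upstream intron, exon body, 250-nt
downstream intron, downstream exon), averaged per event set at aligned
positions.

## Worked example

```python
from semap import SimConfig, simulate_dataset, classify_events, enrich, extract_regions
from semap.expression import expression_index
from semap.pipeline import packaged_motifs
from semap.motifs import enrichment_table

res = simulate_dataset(SimConfig(seed=2))   # 119 enhanced / 95 silenced / 500 control
cls = classify_events(res.events, expression_index(res.expression), reference_group="WT")
regs = {e.event_id: extract_regions(e, res.genome) for e in res.events}
results = enrich(
    {d: [regs[i] for i, c in cls.items() if c.label == d] for d in ("enhanced", "silenced")},
    [regs[i] for i, c in cls.items() if c.label == "control"],
    packaged_motifs("rbp"),
)
print(enrichment_table(results).query("enriched")[["motif", "region", "direction", "fdr_by_nt", "p_by_seq"]])
```

prints (seed 2):

```
motif            region direction    fdr_by_nt     p_by_seq
ESRP1   upstream_intron  silenced 5.379882e-55 2.072268e-34
ESRP1 downstream_intron  enhanced 1.247956e-42 2.910878e-30
```

i.e. the GU-rich motif planted by the generator is recovered exactly where
a skipping-from-upstream / inclusion-from-downstream regulator binds, and
no other motif of the example RBP set is called. The `examples/` directory
has one short script per capability (classification, enrichment, RNA map,
expression filters, quantitative statistics, simulation); each prints the
numbers it computes and what they mean. A thin CLI (`semap simulate`,
`semap run --config cfg.yaml`, ...) orchestrates the same stages from a
shell and writes a hash-stamped manifest.

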