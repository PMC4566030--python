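"""Classify cassette-exon events from an rMATS-style table.

Simulates a small dataset, writes the tables, reads them back through the
parsers, and partitions events into enhanced / silenced / control sets.
"""

import tempfile
from pathlib import Path

from semap import SimConfig, TableDialect, classify_events, read_se_table, simulate_dataset
from semap.events import label_counts
from semap.expression import ExpressionDialect, expression_index, read_expression_table

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(seed=1, n_enhanced=30, n_silenced=25, n_control=100)
    simulate_dataset(cfg, out_dir=tmp)

    events = read_se_table(Path(tmp) / "se_events.tsv",
                           TableDialect(group_labels=("WT", "DKO")))
    records = read_expression_table(Path(tmp) / "gene_expression.tsv",
                                    ExpressionDialect(group_labels=("WT", "DKO")))
    cls = classify_events(events, expression_index(records), reference_group="WT")

counts = label_counts(cls)
print(f"events parsed: {len(events)}")
print(f"label counts:  {counts}")
example = next(c for c in cls.values() if c.label == "enhanced")
print(f"one enhanced event: delta_psi={example.delta_psi:+.3f}, fdr={example.fdr:.2g}")
# 'enhanced' = higher inclusion in WT (positive delta PSI at FDR < 5%);
# 'control' = unregulated, intermediate-PSI exons in well-expressed genes,
# used as the background for motif enrichment.
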