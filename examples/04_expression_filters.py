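"""Differential-expression filter and the splicing-factor panel.

Applies the three DEG criteria (q < 5%, fold > 2, expression floor) to a
synthetic Cuffdiff-style table, then extracts an RBP panel at >= 1.5-fold.
"""

from semap import SimConfig, deg_filter, rbp_panel, simulate_dataset
from semap.expression import deg_counts

res = simulate_dataset(SimConfig(seed=4, n_enhanced=10, n_silenced=10, n_control=30))
calls = deg_filter(res.expression, reference_group="WT")
print(f"DEG calls: {deg_counts(calls)}  (truth planted 178 up, 337 down)")

panel_genes = [r.gene_id for r in res.expression[:40]]  # stand-in panel list
panel = rbp_panel(res.expression, panel_genes, min_fold=1.5)
print(f"panel members with >= 1.5-fold change: {len(panel)} of {len(panel_genes)}")
for rec in panel[:5]:
    print(f"  {rec.gene_id}: fold {rec.fold_change():.2f}, q={rec.q_value:.3g}")
# 'up'/'down' are relative to the comparison (knockout) group; the panel
# filter is intentionally gentler (|fold| >= 1.5, no q cutoff) because it
# screens candidate co-regulators rather than calling significance.
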