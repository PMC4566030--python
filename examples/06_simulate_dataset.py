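"""The synthetic-data generator and its truth bundle.

Writes a complete dataset (genome FASTA, SE table, expression table, truth
JSON) and shows that the planted architecture is recoverable.
"""

import json
import tempfile
from pathlib import Path

from semap import Motif, SimConfig, count_occurrences, extract_regions, simulate_dataset

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(seed=5, n_enhanced=20, n_silenced=20, n_control=60)
    res = simulate_dataset(cfg, out_dir=tmp)
    print("files:", sorted(p.name for p in Path(tmp).iterdir()))
    truth = json.loads((Path(tmp) / "truth.json").read_text())

silenced = [e for e in res.events if truth["events"][e.event_id]["label"] == "silenced"]
control = [e for e in res.events if truth["events"][e.event_id]["label"] == "control"]
esrp = Motif("ESRP1", "UGGUGG")

def mean_hits(events):
    return sum(count_occurrences(extract_regions(e, res.genome).upstream_intron, esrp)
               for e in events) / len(events)

print(f"mean UGGUGG occurrences per upstream intron: "
      f"silenced {mean_hits(silenced):.2f} vs control {mean_hits(control):.2f}")
print(f"planted positions recorded for {sum(bool(t['planted']) for t in truth['events'].values())} events")
# The generator plants ~1 occurrence per silenced upstream intron over a
# uniform background (~0.06 expected by chance in 230 nt), giving the
# >= 5-fold occurrence excess the enrichment test is designed to detect.
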