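"""Pipeline orchestration: declarative config, staged execution, manifest.

Stages run in order classify -> extract -> enrich -> rnamap -> deg. Every
output is recorded in a JSON manifest together with SHA-256 hashes of the
inputs and the fully resolved parameter set, so a rerun on unchanged inputs
is reproducible (and skippable under ``resume``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import events as ev
from . import expression as xp
from . import motifs as mo
from . import regions as rg
from . import rnamap as rm

logger = logging.getLogger(__name__)

STAGES = ("classify", "extract", "enrich", "rnamap", "deg")


def packaged_motifs(which: str = "rbp") -> list[mo.Motif]:
    """Bundled example motif sets: 'rbp' (known splicing-factor binding sites,
    a small documented example list) or 'esrp' (the GU-rich 6-mer set; nine of
    the twelve are documented stand-ins, see the file name)."""
    fname = {"rbp": "rbp_motifs.tsv", "esrp": "esrp_top12_standin.tsv"}[which]
    with resources.as_file(resources.files("semap.data") / fname) as p:
        return mo.read_motif_tsv(p)


@dataclass
class PipelineConfig:
    """Paths, thresholds and run metadata; all thresholds default to the
    study's values."""

    se_table: str = ""
    genome: str = ""
    expression_table: str = ""
    output_dir: str = "semap_out"
    motifs: str = ""       # enrichment motif TSV ('' -> packaged rbp set)
    map_motifs: str = ""   # RNA-map motif TSV ('' -> packaged esrp set)
    reference_group: str = "WT"
    group_labels: tuple[str, str] = ("WT", "KO")
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    classify: ev.ClassifyThresholds = field(default_factory=ev.ClassifyThresholds)
    region: rg.RegionConfig = field(default_factory=rg.RegionConfig)
    enrich: mo.EnrichConfig = field(default_factory=mo.EnrichConfig)
    rnamap: rm.MapConfig = field(default_factory=rm.MapConfig)
    deg: xp.DegThresholds = field(default_factory=xp.DegThresholds)
    rbp_panel: tuple[str, ...] = ()

    def validate(self) -> None:
        for name in ("max_fdr", "min_abs_delta_psi", "control_min_fdr"):
            v = getattr(self.classify, name)
            if not 0 < v <= 1:
                raise ValueError(f"classify.{name} must lie in (0, 1], got {v}")
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}")
        # nested dataclass __post_init__ already validates windows/exclusions

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        nested = {"classify": ev.ClassifyThresholds, "region": rg.RegionConfig,
                  "enrich": mo.EnrichConfig, "rnamap": rm.MapConfig,
                  "deg": xp.DegThresholds}
        for key, value in raw.items():
            if key in nested:
                sub = {k: (tuple(v) if isinstance(v, list) else v) for k, v in value.items()}
                kwargs[key] = nested[key](**sub)
            elif key in ("group_labels", "stages", "rbp_panel"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.resolved(), sort_keys=True, default=str).encode()
    ).hexdigest()


def run(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the configured stages; returns the artifact manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text())

    inputs = {}
    for name in ("se_table", "genome", "expression_table", "motifs", "map_motifs"):
        p = getattr(config, name)
        if p:
            inputs[name] = _sha256(p)
    manifest: dict = {
        "inputs": inputs,
        "params_hash": _params_hash(config),
        "thresholds": config.resolved(),
        "stages": {},
    }

    def unchanged(stage: str) -> bool:
        prev = previous.get("stages", {}).get(stage)
        return (
            prev is not None
            and previous.get("inputs") == inputs
            and previous.get("params_hash") == manifest["params_hash"]
            and all(Path(p).exists() for p in prev.get("outputs", {}).values())
        )

    dialect = ev.TableDialect(group_labels=config.group_labels)
    xdialect = xp.ExpressionDialect(group_labels=config.group_labels)

    se_events = classifications = None
    region_seqs = segments = None

    def load_events():
        nonlocal se_events
        if se_events is None:
            se_events = ev.read_se_table(config.se_table, dialect)
        return se_events

    def load_classifications():
        nonlocal classifications
        if classifications is None:
            cls_path = out / "classifications.tsv"
            if cls_path.exists():
                classifications = ev.read_classifications(cls_path)
            else:
                records = xp.read_expression_table(config.expression_table, xdialect)
                classifications = ev.classify_events(
                    load_events(), xp.expression_index(records),
                    config.classify, config.reference_group,
                )
        return classifications

    try:
        for stage in config.stages:
            if unchanged(stage):
                logger.info("stage %s: inputs unchanged, reusing previous outputs", stage)
                manifest["stages"][stage] = previous["stages"][stage]
                continue
            outputs: dict[str, str] = {}

            if stage == "classify":
                records = xp.read_expression_table(config.expression_table, xdialect)
                classifications_local = ev.classify_events(
                    load_events(), xp.expression_index(records),
                    config.classify, config.reference_group,
                )
                nonlocal_path = out / "classifications.tsv"
                ev.write_classifications(classifications_local, nonlocal_path)
                ev.write_overlap_summary(classifications_local, None, out / "classification_summary.json")
                outputs = {"classifications": str(nonlocal_path),
                           "summary": str(out / "classification_summary.json")}
                nonlocal_cls = classifications_local
                classifications = nonlocal_cls

            elif stage == "extract":
                genome = rg.FastaGenome(config.genome)
                cls = load_classifications()
                keep = {eid for eid, c in cls.items() if c.label != "unclassified"}
                regs = [rg.extract_regions(e, genome, config.region)
                        for e in load_events() if e.event_id in keep]
                fasta_path = out / "regions.fa"
                rg.regions_to_fasta(regs, fasta_path)
                bed_path = out / "regions.bed"
                with open(bed_path, "w") as fh:
                    for r in regs:
                        fh.write("\n".join(rg.regions_to_bed(r)) + "\n")
                outputs = {"regions_fasta": str(fasta_path), "regions_bed": str(bed_path)}
                region_seqs = {r.event_id: r for r in regs}

            elif stage == "enrich":
                genome = rg.FastaGenome(config.genome)
                cls = load_classifications()
                if region_seqs is None:
                    keep = {eid for eid, c in cls.items() if c.label != "unclassified"}
                    region_seqs = {e.event_id: rg.extract_regions(e, genome, config.region)
                                   for e in load_events() if e.event_id in keep}
                motifs = (mo.read_motif_tsv(config.motifs) if config.motifs
                          else packaged_motifs("rbp"))
                regulated = {
                    d: [region_seqs[eid] for eid, c in cls.items()
                        if c.label == d and eid in region_seqs]
                    for d in ("enhanced", "silenced")
                }
                control = [region_seqs[eid] for eid, c in cls.items()
                           if c.label == "control" and eid in region_seqs]
                results = mo.enrich(regulated, control, motifs, config.enrich)
                path = out / "motif_enrichment.tsv"
                mo.write_enrichment_tsv(results, path, config.enrich)
                outputs = {"enrichment": str(path)}

            elif stage == "rnamap":
                genome = rg.FastaGenome(config.genome)
                cls = load_classifications()
                segments = {e.event_id: rg.extract_map_segments(e, genome, config.region)
                            for e in load_events()
                            if cls[e.event_id].label != "unclassified"}
                motifs = (mo.read_motif_tsv(config.map_motifs) if config.map_motifs
                          else packaged_motifs("esrp"))
                sets = {lab: [eid for eid, c in cls.items() if c.label == lab and eid in segments]
                        for lab in ("enhanced", "silenced", "control")}
                sets = {k: v for k, v in sets.items() if v}
                profiles = rm.build_map(sets, segments, motifs, config.rnamap)
                tsv = out / "rna_map.tsv"
                rm.map_table(profiles).to_csv(tsv, sep="\t", index=False)
                png = out / "rna_map.png"
                rm.plot_map(profiles, png)
                outputs = {"map_table": str(tsv), "map_plot": str(png)}

            elif stage == "deg":
                records = xp.read_expression_table(config.expression_table, xdialect)
                calls = xp.deg_filter(records, config.deg, config.reference_group)
                path = out / "deg_calls.tsv"
                xp.write_deg_tsv(records, calls, path)
                outputs = {"deg": str(path)}
                if config.rbp_panel:
                    panel = xp.rbp_panel(records, config.rbp_panel)
                    ppath = out / "rbp_panel.tsv"
                    with open(ppath, "w") as fh:
                        fh.write("gene_id\tgene_name\tfold_change\tq_value\n")
                        for r in panel:
                            fh.write(f"{r.gene_id}\t{r.gene_name}\t{r.fold_change():.6g}\t{r.q_value}\n")
                    outputs["rbp_panel"] = str(ppath)

            manifest["stages"][stage] = {
                "outputs": outputs,
                "output_hashes": {k: _sha256(v) for k, v in outputs.items()
                                  if not v.endswith(".png")},
            }
    except Exception:
        # keep partial outputs identifiable
        partial = manifest_path.with_suffix(".json.partial")
        partial.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        raise

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
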