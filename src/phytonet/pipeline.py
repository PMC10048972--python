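"""End-to-end orchestration: overlap → enrichment → network → screening.

``run_pipeline`` executes the four stages in order, writes each stage's
artifact into the output directory, and records a manifest with the SHA-256
of every input and output plus the thresholds actually used, so a rerun on
identical inputs is verifiably identical. ``render_report`` turns a
completed manifest into a human-readable Markdown report with the hub-target
and key-component tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import core_io, enrichment, network, screening, target_space
from .errors import ConfigurationError, PhytonetError
from .models import ScreeningCriteria, TargetSpaceConfig

log = logging.getLogger(__name__)

STAGES = ("overlap", "enrich", "network", "screen")


@dataclass
class PipelineConfig:
    components: Path
    predictions: Path
    disease_genes: Path
    annotations: Path
    literature: Path
    out_dir: Path
    docking: Path | None = None
    selected_terms: Path | None = None  # allow-list of term ids, one per line
    module_map: Path | None = None  # optional TSV: term_id <tab> module label
    target_space: TargetSpaceConfig = field(default_factory=TargetSpaceConfig)
    enrichment: enrichment.EnrichmentConfig = field(
        default_factory=enrichment.EnrichmentConfig
    )
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    literature_cutoff: float | None = None
    docking_cutoff: float = -5.0
    seed: int = 0

    def __post_init__(self):
        for name in ("components", "predictions", "disease_genes", "annotations",
                     "literature", "out_dir", "docking", "selected_terms",
                     "module_map"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        ts = raw.pop("target_space", {})
        if "source_thresholds" in ts:
            ts["source_thresholds"] = {
                source: (None if rule is None else (rule[0], float(rule[1])))
                for source, rule in ts["source_thresholds"].items()
            }
        enr = raw.pop("enrichment", {})
        if "background" in enr and enr["background"] is not None:
            enr["background"] = set(enr["background"])
        crit = raw.pop("criteria", {})
        return cls(
            target_space=TargetSpaceConfig(**ts),
            enrichment=enrichment.EnrichmentConfig(**enr),
            criteria=ScreeningCriteria(**crit),
            **raw,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all four stages; return (and write) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": cfg.seed}

    def record(stage: str, inputs: list[Path], outputs: list[Path], info: dict):
        manifest["stages"].append(
            {
                "name": stage,
                "inputs": {str(p): _sha256(p) for p in inputs},
                "outputs": {str(p): _sha256(p) for p in outputs},
                "info": info,
            }
        )

    try:
        # stage 1: target-space overlap
        preds = core_io.read_predictions(cfg.predictions)
        disease = core_io.read_disease_genes(cfg.disease_genes)
        overlap = target_space.build_overlap(preds, disease, cfg.target_space)
        overlap_path = out / "overlap.json"
        target_space.overlap_to_json(overlap, overlap_path)
        record("overlap", [cfg.predictions, cfg.disease_genes], [overlap_path],
               {"tanimoto_min": cfg.target_space.tanimoto_min, **overlap.sizes()})

        # stage 2: enrichment of the overlap genes
        annotations = core_io.read_gmt(cfg.annotations, namespace="kegg")
        results = enrichment.enrich(set(overlap.overlap), annotations, cfg.enrichment)
        if cfg.module_map is not None:
            pairs = [
                line.split("\t")[:2]
                for line in Path(cfg.module_map).read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
            results = enrichment.assign_modules(results, pairs)
        enrich_path = out / "enrichment.tsv"
        enrichment.results_to_frame(results).to_csv(enrich_path, sep="\t", index=False)
        record("enrich", [cfg.annotations, overlap_path], [enrich_path],
               {"n_terms_tested": len(results),
                "n_significant": sum(r.significant for r in results),
                "alpha": cfg.enrichment.alpha,
                "statistic": cfg.enrichment.statistic})

        # stage 3: tripartite network and topology metrics
        by_id = {a.term_id: a for a in annotations}
        if cfg.selected_terms is not None:
            wanted = [
                line.strip()
                for line in Path(cfg.selected_terms).read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
            missing = [t for t in wanted if t not in by_id]
            if missing:
                raise ConfigurationError(f"allow-listed terms not annotated: {missing[:5]}")
            selected = [by_id[t] for t in wanted]
        else:
            significant = [r.term_id for r in results if r.significant]
            selected = [by_id[t] for t in (significant or [r.term_id for r in results])]
        covered = set().union(*(a.genes for a in selected)) if selected else set()
        effective = set(overlap.overlap) & covered
        net = network.build_network(
            dict(overlap.per_compound_targets), selected, effective
        )
        metrics = network.node_metrics(net)
        net_path = out / "net.graphml"
        core_io.write_network(net, net_path, "graphml")
        metrics_path = out / "metrics.tsv"
        _write_metrics(metrics, metrics_path)
        record("network", [overlap_path, cfg.annotations], [net_path, metrics_path],
               {"n_selected_terms": len(selected), **net.summary()})

        # stage 4: median-threshold screening
        components = core_io.read_components(cfg.components)
        literature = core_io.read_literature(cfg.literature)
        thresholds = screening.compute_medians(
            metrics, literature, components, cfg.criteria, cfg.literature_cutoff
        )
        hubs = screening.screen_hub_targets(metrics, thresholds, cfg.criteria)
        evidence = screening.assemble_component_evidence(metrics, literature, components)
        audited = screening.screen_key_components(evidence, thresholds, cfg.criteria)
        selection = {
            "thresholds": {
                "target_degree_median": thresholds.target_degree_median,
                "component_degree_median": thresholds.component_degree_median,
                "response_median": thresholds.response_median,
                "literature_median": thresholds.literature_median,
            },
            "hub_targets": [
                {"gene": m.node_id, "degree": m.degree,
                 "closeness": round(m.closeness, 6),
                 "betweenness": round(m.betweenness, 6)}
                for m in hubs
            ],
            "key_components": [
                {"compound_id": e.compound_id, "degree": e.degree,
                 "n_studies": e.n_studies, "response": e.response,
                 "criteria_passed": sorted(e.criteria_passed),
                 "selected": e.selected}
                for e in audited
            ],
        }
        screen_inputs = [metrics_path, cfg.literature, cfg.components]
        if cfg.docking is not None:
            docking = core_io.read_docking(cfg.docking)
            dock = screening.screen_docking(docking, cfg.docking_cutoff)
            selection["docking"] = {
                "cutoff": dock.cutoff,
                "n_pass": sum(dock.passes.values()),
                "n_pairs": len(dock.passes),
                "per_target_pass_counts": dict(sorted(dock.per_target_pass_counts.items())),
            }
            screen_inputs.append(cfg.docking)
        selection_path = out / "selection.json"
        with open(selection_path, "w", encoding="utf-8") as fh:
            json.dump(selection, fh, indent=1, sort_keys=True)
            fh.write("\n")
        record("screen", screen_inputs, [selection_path],
               {"n_hub_targets": len(hubs),
                "n_selected_components": sum(e.selected for e in audited)})
    except PhytonetError as exc:
        stage = STAGES[len(manifest["stages"])]
        raise PhytonetError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_metrics(metrics, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tpartition\tdegree\tcloseness\tbetweenness\n")
        for m in metrics:
            fh.write(
                f"{m.node_id}\t{m.partition}\t{m.degree}"
                f"\t{m.closeness:.6f}\t{m.betweenness:.6f}\n"
            )


def read_metrics(path):
    """Read a metrics.tsv back into NodeMetrics records."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        network.NodeMetrics(
            node_id=str(r.node_id), partition=r.partition, degree=int(r.degree),
            closeness=float(r.closeness), betweenness=float(r.betweenness),
        )
        for r in df.itertuples(index=False)
    ]


def render_report(out_dir) -> Path:
    """Render report.md plus flat TSV tables from a completed run directory.

    Regeneration from the same artifacts is byte-identical.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise PhytonetError(f"no manifest in {out}: run the pipeline first")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    done = [s["name"] for s in manifest["stages"]]
    missing = [s for s in STAGES if s not in done]
    if missing:
        raise PhytonetError(f"incomplete manifest; missing stages: {missing}")

    with open(out / "selection.json", encoding="utf-8") as fh:
        selection = json.load(fh)
    info = {s["name"]: s["info"] for s in manifest["stages"]}

    hub_tsv = out / "hub_targets.tsv"
    with open(hub_tsv, "w", encoding="utf-8") as fh:
        fh.write("gene\tdegree\tcloseness\tbetweenness\n")
        for row in selection["hub_targets"]:
            fh.write(f"{row['gene']}\t{row['degree']}\t{row['closeness']}\t{row['betweenness']}\n")
    comp_tsv = out / "key_components.tsv"
    with open(comp_tsv, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tdegree\tresponse\tn_studies\tcriteria_passed\tselected\n")
        for row in selection["key_components"]:
            fh.write(
                f"{row['compound_id']}\t{row['degree']}\t{row['response']}"
                f"\t{row['n_studies']}\t{','.join(row['criteria_passed'])}"
                f"\t{row['selected']}\n"
            )

    lines = ["# Screening report", ""]
    lines += [
        "## Network summary", "",
        f"- nodes: {info['network']['n_nodes']} "
        f"(components {info['network']['n_components']}, "
        f"targets {info['network']['n_targets']}, "
        f"pathways {info['network']['n_pathways']})",
        f"- edges: {info['network']['n_edges']}",
        f"- overlap genes: {info['overlap']['overlap']} "
        f"(drug targets {info['overlap']['drug_targets']}, "
        f"disease genes {info['overlap']['disease_genes']})",
        "",
        "## Thresholds (recomputed from inputs)", "",
    ]
    for name, value in sorted(selection["thresholds"].items()):
        lines.append(f"- {name}: {value:g}")
    hubs = selection["hub_targets"]
    lines += ["", f"## Hub targets ({len(hubs)} selected)", "",
              "gene | degree | closeness | betweenness", "--- | --- | --- | ---"]
    for row in hubs:
        lines.append(
            f"{row['gene']} | {row['degree']} | {row['closeness']} | {row['betweenness']}"
        )
    comps = [r for r in selection["key_components"] if r["selected"]]
    lines += ["", f"## Key components ({len(comps)} selected)", "",
              "compound | degree | response | studies | criteria", "--- | --- | --- | --- | ---"]
    if not comps:
        lines.append("(0 selected) | - | - | - | -")
    for row in comps:
        lines.append(
            f"{row['compound_id']} | {row['degree']} | {row['response']:g} | "
            f"{row['n_studies']} | {','.join(row['criteria_passed'])}"
        )
    if "docking" in selection:
        dock = selection["docking"]
        lines += ["", "## Docking screen", "",
                  f"- cutoff: {dock['cutoff']} kcal/mol",
                  f"- pairs passing: {dock['n_pass']} / {dock['n_pairs']}"]
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return report_path
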