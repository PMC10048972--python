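"""Drug-target and disease-gene set construction and their overlap.

The drug-target set keeps compound→target predictions whose Tanimoto
similarity is at or above the cutoff (inclusive, 0.7 by default). The
disease-gene set is the union over sources of records passing their
source-native score threshold (strict ``>`` as configured; GeneCards > 10,
DisGeNET > 0.1, TCMIP admitted without a threshold). The overlap of the two
sets defines the candidate therapeutic target space.
"""

from __future__ import annotations

import json
import logging

from .errors import ConfigurationError
from .models import (
    DiseaseGeneRecord,
    OverlapResult,
    TargetPrediction,
    TargetSpaceConfig,
    apply_comparator,
)

log = logging.getLogger(__name__)


def filter_predictions(
    preds: list[TargetPrediction], cfg: TargetSpaceConfig | None = None
) -> dict:
    """Similarity-filter predictions to a compound_id → gene-set map.

    A prediction is retained iff ``similarity >= cfg.tanimoto_min``
    (boundary inclusive); genes are de-duplicated per compound.
    """
    cfg = cfg or TargetSpaceConfig()
    out: dict[str, set] = {}
    dropped = 0
    for p in preds:
        if p.similarity >= cfg.tanimoto_min:
            out.setdefault(p.compound_id, set()).add(p.gene)
        else:
            dropped += 1
            log.debug(
                "dropped prediction %s->%s: tanimoto %.3f < %.3f",
                p.compound_id, p.gene, p.similarity, cfg.tanimoto_min,
            )
    if dropped:
        log.info("tanimoto filter dropped %d/%d predictions", dropped, len(preds))
    return out


def collect_disease_genes(
    records: list[DiseaseGeneRecord], cfg: TargetSpaceConfig | None = None
) -> set:
    """Union of genes passing their per-source score thresholds.

    The threshold is applied per record, then records are unioned, so a gene
    failing in one source may still enter via another.
    """
    cfg = cfg or TargetSpaceConfig()
    genes: set[str] = set()
    dropped = 0
    for rec in records:
        if rec.source not in cfg.source_thresholds:
            raise ConfigurationError(
                f"no threshold configured for source {rec.source!r}"
            )
        rule = cfg.source_thresholds[rec.source]
        if rule is None:
            genes.add(rec.gene)
            continue
        op, cutoff = rule
        if rec.score is None:
            raise ConfigurationError(
                f"{rec.gene}: source {rec.source!r} requires a score"
            )
        if apply_comparator(rec.score, op, cutoff):
            genes.add(rec.gene)
        else:
            dropped += 1
            log.debug(
                "dropped disease record %s (%s %.4g not %s %.4g)",
                rec.gene, rec.source, rec.score, op, cutoff,
            )
    if dropped:
        log.info("source-score filter dropped %d/%d records", dropped, len(records))
    return genes


def intersect_targets(drug_targets, disease_genes, per_compound_targets=None) -> OverlapResult:
    """Exact intersection of the two case-normalised gene sets."""
    drug_targets = frozenset(g.upper() for g in drug_targets)
    disease_genes = frozenset(g.upper() for g in disease_genes)
    return OverlapResult(
        drug_targets=drug_targets,
        disease_genes=disease_genes,
        overlap=drug_targets & disease_genes,
        per_compound_targets={
            k: frozenset(v) for k, v in (per_compound_targets or {}).items()
        },
    )


def build_overlap(
    preds: list[TargetPrediction],
    records: list[DiseaseGeneRecord],
    cfg: TargetSpaceConfig | None = None,
) -> OverlapResult:
    """End-to-end target-space stage: filter both evidence layers, intersect."""
    cfg = cfg or TargetSpaceConfig()
    per_compound = filter_predictions(preds, cfg)
    drug_targets = set().union(*per_compound.values()) if per_compound else set()
    disease_genes = collect_disease_genes(records, cfg)
    return intersect_targets(drug_targets, disease_genes, per_compound)


def overlap_to_json(result: OverlapResult, path) -> None:
    payload = {
        "sizes": result.sizes(),
        "drug_targets": sorted(result.drug_targets),
        "disease_genes": sorted(result.disease_genes),
        "overlap": sorted(result.overlap),
        "per_compound_targets": {
            k: sorted(v) for k, v in sorted(result.per_compound_targets.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def overlap_from_json(path) -> OverlapResult:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return OverlapResult(
        drug_targets=frozenset(payload["drug_targets"]),
        disease_genes=frozenset(payload["disease_genes"]),
        overlap=frozenset(payload["overlap"]),
        per_compound_targets={
            k: frozenset(v) for k, v in payload["per_compound_targets"].items()
        },
    )
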