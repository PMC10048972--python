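"""Median-threshold screens: hub targets, key components, docking.

Three selection rules operate downstream of the tripartite network:

* hub targets — target-partition nodes whose network degree strictly
  exceeds the median degree of the target partition;
* key components — compounds passing at least two of three evidence
  criteria: network degree above the component-degree median (topology),
  literature-study count at or above the literature median (literature),
  and MS response at or above the response median (quantitation);
* docking — compound–target pairs whose predicted binding free energy is
  strictly below a cutoff (−5.0 kcal/mol by default).

Every median is recomputed from its own population at run time; published
values are expectations to check against, never constants.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass

from .errors import EmptyPopulationError
from .models import (
    ChemicalComponent,
    ComponentEvidence,
    DockingRecord,
    LiteratureEvidence,
    MedianThresholds,
    ScreeningCriteria,
    apply_comparator,
)
from .network import NodeMetrics

log = logging.getLogger(__name__)


def _median(values, population_name: str) -> float:
    values = list(values)
    if not values:
        raise EmptyPopulationError(f"empty population: {population_name}")
    return float(statistics.median(values))


def _dedupe_metrics(metrics: list[NodeMetrics]) -> list[NodeMetrics]:
    seen, out = set(), []
    for m in metrics:
        if m.node_id not in seen:
            seen.add(m.node_id)
            out.append(m)
    return out


def compute_medians(
    metrics: list[NodeMetrics],
    literature: list[LiteratureEvidence],
    components: list[ChemicalComponent],
    criteria: ScreeningCriteria | None = None,
    literature_cutoff: float | None = None,
) -> MedianThresholds:
    """Compute the four screening medians from their populations.

    Degree medians are taken within a partition of the tripartite network;
    the response median over all ingested components; the literature median
    over the topology-passing candidate compounds (override it with
    ``literature_cutoff`` when an external bar is preferred).
    """
    criteria = criteria or ScreeningCriteria()
    metrics = _dedupe_metrics(metrics)
    target_degrees = [m.degree for m in metrics if m.partition == "target"]
    component_degrees = {
        m.node_id: m.degree for m in metrics if m.partition == "component"
    }
    target_median = _median(target_degrees, "target degrees")
    component_median = _median(component_degrees.values(), "component degrees")
    response_median = _median(
        (c.response for c in components), "component responses"
    )

    if literature_cutoff is not None:
        literature_median = float(literature_cutoff)
    else:
        counts = {ev.compound_id: ev.n_studies for ev in literature}
        candidates = [
            cid for cid, deg in component_degrees.items()
            if apply_comparator(deg, criteria.component_degree_rule, component_median)
        ]
        literature_median = _median(
            (counts.get(cid, 0) for cid in candidates),
            "literature counts of topology-passing candidates",
        )
    thresholds = MedianThresholds(
        target_degree_median=target_median,
        component_degree_median=component_median,
        response_median=response_median,
        literature_median=literature_median,
    )
    log.info("screening medians: %s", thresholds)
    return thresholds


def screen_hub_targets(
    metrics: list[NodeMetrics],
    thresholds: MedianThresholds,
    criteria: ScreeningCriteria | None = None,
) -> list[NodeMetrics]:
    """Target nodes whose degree beats the target-degree median.

    Returned sorted by degree descending, then node id.
    """
    criteria = criteria or ScreeningCriteria()
    hubs = [
        m
        for m in _dedupe_metrics(metrics)
        if m.partition == "target"
        and apply_comparator(m.degree, criteria.hub_rule, thresholds.target_degree_median)
    ]
    hubs.sort(key=lambda m: (-m.degree, m.node_id))
    log.info(
        "hub-target screen: %d targets with degree %s %g",
        len(hubs), criteria.hub_rule, thresholds.target_degree_median,
    )
    return hubs


CRITERION_TOPOLOGY = "topology"
CRITERION_LITERATURE = "literature"
CRITERION_QUANTITATION = "quantitation"


def assemble_component_evidence(
    metrics: list[NodeMetrics],
    literature: list[LiteratureEvidence],
    components: list[ChemicalComponent],
) -> list[ComponentEvidence]:
    """Join network degree, literature count and response per compound.

    Only compounds present in the component partition of the network are
    candidates. A compound with no literature row counts as 0 studies.
    """
    counts = {ev.compound_id: ev.n_studies for ev in literature}
    responses = {c.compound_id: c.response for c in components}
    out = []
    for m in _dedupe_metrics(metrics):
        if m.partition != "component":
            continue
        out.append(
            ComponentEvidence(
                compound_id=m.node_id,
                degree=m.degree,
                n_studies=counts.get(m.node_id, 0),
                response=responses.get(m.node_id, 0.0),
            )
        )
    return out


def screen_key_components(
    evidence: list[ComponentEvidence],
    thresholds: MedianThresholds,
    criteria: ScreeningCriteria | None = None,
) -> list[ComponentEvidence]:
    """Apply the 2-of-3 evidence screen, returning a full audit trail.

    Every input compound comes back with its fired-criteria set; a compound
    is ``selected`` when at least ``criteria.min_criteria_met`` fired.
    """
    criteria = criteria or ScreeningCriteria()
    out = []
    for ev in evidence:
        fired = set()
        if apply_comparator(
            ev.degree, criteria.component_degree_rule, thresholds.component_degree_median
        ):
            fired.add(CRITERION_TOPOLOGY)
        if apply_comparator(
            ev.n_studies, criteria.literature_rule, thresholds.literature_median
        ):
            fired.add(CRITERION_LITERATURE)
        if apply_comparator(
            ev.response, criteria.response_rule, thresholds.response_median
        ):
            fired.add(CRITERION_QUANTITATION)
        out.append(
            ComponentEvidence(
                compound_id=ev.compound_id,
                degree=ev.degree,
                n_studies=ev.n_studies,
                response=ev.response,
                criteria_passed=frozenset(fired),
                selected=len(fired) >= criteria.min_criteria_met,
            )
        )
    out.sort(key=lambda e: (-len(e.criteria_passed), -e.degree, e.compound_id))
    log.info(
        "key-component screen: %d/%d selected (>= %d of 3 criteria)",
        sum(e.selected for e in out), len(out), criteria.min_criteria_met,
    )
    return out


@dataclass(frozen=True)
class DockingScreenResult:
    """Pass/fail per compound–target pair plus per-target pass counts."""

    cutoff: float
    passes: dict  # (compound_id, target_gene) -> bool
    per_target_pass_counts: dict  # target_gene -> int


def screen_docking(
    records: list[DockingRecord], cutoff: float = -5.0
) -> DockingScreenResult:
    """Threshold screen on docking affinities: pass iff strictly below cutoff."""
    passes = {
        (r.compound_id, r.target_gene): r.affinity_kcal_mol < cutoff for r in records
    }
    counts: dict[str, int] = {}
    for (cid, gene), ok in passes.items():
        counts.setdefault(gene, 0)
        if ok:
            counts[gene] += 1
    log.info(
        "docking screen: %d/%d pairs below %g kcal/mol",
        sum(passes.values()), len(passes), cutoff,
    )
    return DockingScreenResult(cutoff=cutoff, passes=passes, per_target_pass_counts=counts)
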