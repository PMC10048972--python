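"""Domain records for the evidence tables feeding the screening pipeline.

The pipeline relates a multi-component herbal extract to a disease through
layered evidence: identified chemical components (with mass-spectrometric
response values as abundance proxies), compound→target predictions scored by
chemical-fingerprint (Tanimoto) similarity, disease–gene records from scored
databases, gene-set annotations, per-compound literature-study counts, and
docking affinities. Each record type below carries one row of that evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError

ION_MODES = frozenset({"positive", "negative"})
STRUCTURAL_CLASSES = frozenset({"flavonoid", "flavonoid_glycoside", "other"})
NAMESPACES = frozenset({"kegg", "go_bp", "go_cc", "go_mf", "custom"})
MODULE_LABELS = frozenset({"inflammation", "metabolism", "other"})


@dataclass(frozen=True)
class ChemicalComponent:
    """One identified compound, merged across ion-mode detections.

    ``response`` is the MS peak response (arbitrary units), used downstream
    as an abundance proxy; for compounds detected in both ion modes it is an
    aggregate (maximum by default) of the per-mode responses.
    """

    compound_id: str
    name: str
    ion_modes: frozenset
    retention_time_min: float = 0.0
    mz_measured: float = float("nan")
    formula: str = ""
    response: float = 1.0
    structural_class: str = "other"
    peak_numbers: tuple = ()  # (mode, peak number) pairs, e.g. ("positive", 40)

    def __post_init__(self):
        if not self.ion_modes:
            raise ValueError(f"{self.compound_id}: ion_modes must be nonempty")
        bad = set(self.ion_modes) - ION_MODES
        if bad:
            raise ValueError(f"{self.compound_id}: unknown ion modes {sorted(bad)}")
        if not self.response > 0:
            raise ValueError(f"{self.compound_id}: response must be > 0")
        if self.retention_time_min < 0:
            raise ValueError(f"{self.compound_id}: negative retention time")
        if self.structural_class not in STRUCTURAL_CLASSES:
            raise ValueError(
                f"{self.compound_id}: unknown structural class {self.structural_class!r}"
            )


@dataclass(frozen=True)
class TargetPrediction:
    """A predicted compound→target edge with its Tanimoto similarity score."""

    compound_id: str
    gene: str
    similarity: float

    def __post_init__(self):
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(
                f"{self.compound_id}->{self.gene}: similarity {self.similarity} not in [0,1]"
            )
        object.__setattr__(self, "gene", self.gene.upper())


@dataclass(frozen=True)
class DiseaseGeneRecord:
    """One disease–gene association from a scored source database."""

    gene: str
    source: str
    score: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "gene", self.gene.upper())
        object.__setattr__(self, "source", self.source.lower())


@dataclass(frozen=True)
class GeneSetAnnotation:
    """A named gene set (pathway or ontology term)."""

    term_id: str
    term_name: str
    genes: frozenset
    namespace: str = "custom"
    module_label: str | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"{self.term_id}: empty gene set")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"{self.term_id}: unknown namespace {self.namespace!r}")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))


@dataclass(frozen=True)
class LiteratureEvidence:
    """Number of published studies supporting a compound's disease activity."""

    compound_id: str
    n_studies: int

    def __post_init__(self):
        if self.n_studies < 0:
            raise ValueError(f"{self.compound_id}: negative study count")


@dataclass(frozen=True)
class DockingRecord:
    """Predicted binding free energy for a compound–target pair (kcal/mol).

    More negative is more favorable.
    """

    compound_id: str
    target_gene: str
    affinity_kcal_mol: float

    def __post_init__(self):
        if not math.isfinite(self.affinity_kcal_mol):
            raise ValueError(
                f"{self.compound_id}->{self.target_gene}: non-finite affinity"
            )
        object.__setattr__(self, "target_gene", self.target_gene.upper())


# --------------------------------------------------------------------------
# Configuration objects


#: default per-source disease-gene score thresholds: (comparator, cutoff),
#: or None for sources admitted without a threshold.
DEFAULT_SOURCE_THRESHOLDS = {
    "genecards": (">", 10.0),
    "disgenet": (">", 0.1),
    "tcmip": None,
}


def apply_comparator(value: float, op: str, cutoff: float) -> bool:
    if op == ">":
        return value > cutoff
    if op == ">=":
        return value >= cutoff
    if op == "<":
        return value < cutoff
    if op == "<=":
        return value <= cutoff
    raise ConfigurationError(f"unknown comparator {op!r}")


@dataclass
class TargetSpaceConfig:
    """Thresholds defining the drug-target and disease-gene sets."""

    tanimoto_min: float = 0.7
    source_thresholds: dict = field(
        default_factory=lambda: dict(DEFAULT_SOURCE_THRESHOLDS)
    )

    def __post_init__(self):
        if not 0.0 <= self.tanimoto_min <= 1.0:
            raise ConfigurationError("tanimoto_min must lie in [0,1]")
        for source, rule in self.source_thresholds.items():
            if rule is None:
                continue
            op, cutoff = rule
            if not math.isfinite(cutoff):
                raise ConfigurationError(f"{source}: non-finite cutoff")
            apply_comparator(0.0, op, cutoff)  # validates the comparator


@dataclass(frozen=True)
class OverlapResult:
    """Drug-target set, disease-gene set, and their intersection."""

    drug_targets: frozenset
    disease_genes: frozenset
    overlap: frozenset
    per_compound_targets: dict

    def sizes(self) -> dict:
        return {
            "drug_targets": len(self.drug_targets),
            "disease_genes": len(self.disease_genes),
            "overlap": len(self.overlap),
        }


@dataclass
class ScreeningCriteria:
    """Comparators and vote threshold for the multi-evidence screens.

    Degree comparators default to strict ``>`` (a node must exceed the
    median); literature and response comparators default to inclusive
    ``>=``. A compound is selected when at least ``min_criteria_met`` of the
    three evidence criteria (network topology, literature support, measured
    abundance) fire.
    """

    hub_rule: str = ">"
    component_degree_rule: str = ">"
    literature_rule: str = ">="
    response_rule: str = ">="
    min_criteria_met: int = 2

    def __post_init__(self):
        if not 1 <= self.min_criteria_met <= 3:
            raise ConfigurationError("min_criteria_met must be in 1..3")
        for op in (
            self.hub_rule,
            self.component_degree_rule,
            self.literature_rule,
            self.response_rule,
        ):
            apply_comparator(1.0, op, 0.0)


@dataclass(frozen=True)
class MedianThresholds:
    """Median cutoffs, each computed from its own population at run time."""

    target_degree_median: float
    component_degree_median: float
    response_median: float
    literature_median: float


@dataclass(frozen=True)
class ComponentEvidence:
    """Per-compound evidence triplet and the audit trail of fired criteria."""

    compound_id: str
    degree: int
    n_studies: int
    response: float
    criteria_passed: frozenset = frozenset()
    selected: bool = False
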