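"""Synthetic evidence-bundle generator with planted ground truth.

Emulates the statistical shape of a real herbal-medicine evidence bundle so
that every pipeline stage is testable without any database download:

* a bipartite compound–target prediction layer with a heavy-tailed
  per-compound target count and planted hub compounds/targets;
* log-normal MS response values (real surveys span two orders of
  magnitude);
* zero-inflated, overdispersed (negative-binomial) literature-study counts
  — most minor constituents have never been studied;
* disease-gene records with source-native score scales and thresholds;
* gene-set annotations with a handful of planted enriched terms
  concentrated on the drug–disease overlap.

The seed fully determines every output byte, so two runs with the same
configuration are file-for-file identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .models import GeneSetAnnotation

log = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_compounds: int = 80
    n_targets: int = 500
    n_disease_genes: int = 900
    n_terms: int = 150
    overlap_fraction: float = 0.2
    hub_compound_count: int = 10
    hub_target_count: int = 15
    hub_degree_multiplier: float = 4.0
    baseline_mean_targets: float = 6.0
    n_planted_terms: int = 5
    # MS responses: log-normal, two orders of magnitude of spread
    response_mu: float = 11.0
    response_sigma: float = 1.5
    # literature counts: NB(r=1) baseline with extra zeros; hubs studied more
    literature_mean: float = 3.0
    literature_r: float = 1.0
    literature_zero_mass: float = 0.3
    hub_literature_mean: float = 10.0
    tanimoto_min: float = 0.7

    def __post_init__(self):
        for name in (
            "n_compounds", "n_targets", "n_disease_genes", "n_terms",
            "hub_compound_count", "hub_target_count",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ConfigurationError("overlap_fraction must lie in (0,1]")
        if self.hub_compound_count > self.n_compounds:
            raise ConfigurationError("more hub compounds than compounds")
        if self.hub_target_count > self.n_targets:
            raise ConfigurationError("more hub targets than targets")


@dataclass(frozen=True)
class GroundTruth:
    planted_hub_compounds: frozenset
    planted_hub_targets: frozenset
    planted_enriched_terms: frozenset
    compound_universe: frozenset
    target_universe: frozenset
    term_universe: frozenset

    def to_json(self, path) -> None:
        payload = {
            f.name: sorted(getattr(self, f.name)) for f in dataclasses.fields(self)
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**{k: frozenset(v) for k, v in payload.items()})


@dataclass
class Bundle:
    """Paths of one generated input bundle."""

    components: Path
    predictions: Path
    disease_genes: Path
    annotations: Path
    literature: Path
    docking: Path
    truth: Path

    def paths(self) -> list[Path]:
        return [getattr(self, f.name) for f in dataclasses.fields(self)]


def _zinb_counts(rng, size, mean, r, zero_mass):
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p, size=size)
    if zero_mass > 0:
        counts[rng.random(size) < zero_mass] = 0
    return counts


def generate_bundle(cfg: SyntheticConfig, out_dir) -> tuple[Bundle, GroundTruth]:
    """Write the six input files plus truth.json into ``out_dir``."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    compounds = [f"CMP{i:04d}" for i in range(1, cfg.n_compounds + 1)]
    targets = [f"TGT{i:04d}" for i in range(1, cfg.n_targets + 1)]
    hub_compounds = sorted(
        rng.choice(compounds, size=cfg.hub_compound_count, replace=False)
    )
    hub_targets = sorted(rng.choice(targets, size=cfg.hub_target_count, replace=False))
    hub_compound_set, hub_target_set = set(hub_compounds), set(hub_targets)

    # --- compound-target prediction layer --------------------------------
    # heavy-tailed per-compound true-target counts; hubs scaled up
    sigma = 0.6
    mu = np.log(cfg.baseline_mean_targets) - sigma**2 / 2
    weights = np.ones(cfg.n_targets)
    weights[[targets.index(t) for t in hub_targets]] = 12.0
    weights /= weights.sum()

    per_compound_true: dict[str, list] = {}
    prediction_rows = []
    for cid in compounds:
        n_true = max(1, int(round(float(rng.lognormal(mu, sigma)))))
        if cid in hub_compound_set:
            # planting guarantees the hub property per compound: at least
            # multiplier x baseline-mean targets, heavy tail on top
            floor = int(round(cfg.hub_degree_multiplier * cfg.baseline_mean_targets))
            n_true = max(floor, int(round(n_true * cfg.hub_degree_multiplier)))
        n_true = min(n_true, cfg.n_targets)
        chosen = list(rng.choice(targets, size=n_true, replace=False, p=weights))
        per_compound_true[cid] = chosen
        for gene in chosen:
            score = rng.uniform(cfg.tanimoto_min, 1.0)
            prediction_rows.append((cid, gene, score))
        # decoy predictions below the similarity cutoff
        n_decoy = int(rng.integers(2, 9))
        for gene in rng.choice(targets, size=n_decoy, replace=False):
            prediction_rows.append((cid, gene, rng.uniform(0.2, cfg.tanimoto_min * 0.999)))

    drug_target_union = sorted({g for genes in per_compound_true.values() for g in genes})

    # --- components table -------------------------------------------------
    responses = rng.lognormal(cfg.response_mu, cfg.response_sigma, size=cfg.n_compounds)
    classes = rng.choice(
        ["flavonoid", "flavonoid_glycoside", "other"],
        size=cfg.n_compounds,
        p=[0.45, 0.35, 0.20],
    )
    mode_choice = rng.choice(["positive", "negative", "both"],
                             size=cfg.n_compounds, p=[0.35, 0.35, 0.30])
    component_rows = []
    for i, cid in enumerate(compounds):
        modes = ["positive", "negative"] if mode_choice[i] == "both" else [mode_choice[i]]
        rt = rng.uniform(0.5, 20.0)
        mz = rng.uniform(100.0, 1500.0)
        for mode in modes:
            # per-mode response jitter; the reader aggregates with max()
            resp = responses[i] * (1.0 if mode == modes[0] else float(rng.uniform(0.3, 1.0)))
            component_rows.append(
                (
                    cid,
                    f"compound_{cid[3:]}",
                    "+" if mode == "positive" else "-",
                    int(rng.integers(1, 99)),
                    rt, mz, "C15H10O5",
                    resp,
                    classes[i],
                )
            )

    # --- disease-gene records ---------------------------------------------
    # the planted hub targets are disease-relevant by construction: they
    # enter the overlap first (otherwise the planted truth could never be
    # recovered downstream of the overlap filter), the rest is uniform
    n_overlap = int(round(cfg.overlap_fraction * len(drug_target_union)))
    hub_in_union = [t for t in hub_targets if t in set(drug_target_union)]
    rest_pool = [g for g in drug_target_union if g not in set(hub_in_union)]
    n_rest = max(0, n_overlap - len(hub_in_union))
    overlap_genes = sorted(
        set(hub_in_union[:n_overlap])
        | set(rng.choice(rest_pool, size=min(n_rest, len(rest_pool)), replace=False))
    )
    n_only = max(0, cfg.n_disease_genes - n_overlap)
    disease_only = [f"DIS{i:04d}" for i in range(1, n_only + 1)]
    disease_genes = overlap_genes + disease_only

    disease_rows = []
    for gene in disease_genes:
        source = rng.choice(["genecards", "disgenet", "tcmip"], p=[0.45, 0.45, 0.10])
        if source == "genecards":
            score = rng.uniform(10.5, 30.0)  # passing region of uniform(0, 30)
        elif source == "disgenet":
            score = rng.uniform(0.12, 0.5)  # passing region of uniform(0, 0.5)
        else:
            score = ""
        disease_rows.append((gene, source, score))
    # chaff records that fail their source threshold
    n_chaff = cfg.n_disease_genes // 3
    chaff_pool = [g for g in drug_target_union if g not in set(overlap_genes)]
    for gene in rng.choice(chaff_pool, size=min(n_chaff, len(chaff_pool)), replace=False):
        source = rng.choice(["genecards", "disgenet"])
        score = rng.uniform(0.0, 10.0) if source == "genecards" else rng.uniform(0.0, 0.1)
        disease_rows.append((gene, source, score))

    # --- gene-set annotations ---------------------------------------------
    universe = drug_target_union + disease_only
    planted_terms = [f"PW{i:04d}" for i in range(1, cfg.n_planted_terms + 1)]
    annotations = []
    for i in range(1, cfg.n_terms + 1):
        term_id = f"PW{i:04d}"
        size = int(rng.integers(10, 60))
        if term_id in planted_terms and overlap_genes:
            # planted terms are dominated by drug-disease overlap genes
            n_from_overlap = min(len(overlap_genes), max(5, int(0.8 * size)))
            genes = list(rng.choice(overlap_genes, size=n_from_overlap, replace=False))
            genes += list(rng.choice(universe, size=size - n_from_overlap, replace=False))
        else:
            genes = list(rng.choice(universe, size=size, replace=False))
        annotations.append(
            GeneSetAnnotation(
                term_id=term_id,
                term_name=f"pathway {i}",
                genes=frozenset(genes),
                namespace="kegg",
            )
        )

    # --- literature counts --------------------------------------------------
    lit_rows = []
    base = _zinb_counts(
        rng, cfg.n_compounds, cfg.literature_mean, cfg.literature_r,
        cfg.literature_zero_mass,
    )
    hub_counts = rng.negative_binomial(
        cfg.literature_r,
        cfg.literature_r / (cfg.literature_r + cfg.hub_literature_mean),
        size=cfg.n_compounds,
    )
    for i, cid in enumerate(compounds):
        n = int(hub_counts[i]) if cid in hub_compound_set else int(base[i])
        lit_rows.append((cid, n))

    # --- docking affinities --------------------------------------------------
    docking_rows = []
    for cid in hub_compounds:
        for gene in rng.choice(hub_targets, size=min(3, len(hub_targets)), replace=False):
            docking_rows.append((cid, gene, rng.uniform(-10.0, -5.2)))
    for cid in rng.choice(compounds, size=min(10, cfg.n_compounds), replace=False):
        gene = rng.choice(targets)
        docking_rows.append((cid, gene, rng.uniform(-6.0, -2.0)))

    # --- write every file deterministically ---------------------------------
    bundle = Bundle(
        components=out_dir / "components.tsv",
        predictions=out_dir / "predictions.tsv",
        disease_genes=out_dir / "disease_genes.tsv",
        annotations=out_dir / "annotations.gmt",
        literature=out_dir / "literature.tsv",
        docking=out_dir / "docking.tsv",
        truth=out_dir / "truth.json",
    )
    _write_tsv(
        bundle.components,
        ("compound_id", "name", "ion_mode", "peak_no", "rt_min", "mz", "formula",
         "response", "class"),
        [
            (cid, name, mode, peak, f"{rt:.3f}", f"{mz:.4f}", formula,
             f"{resp:.2f}", cls)
            for cid, name, mode, peak, rt, mz, formula, resp, cls in component_rows
        ],
    )
    _write_tsv(
        bundle.predictions,
        ("compound_id", "gene", "tanimoto"),
        [(cid, gene, f"{s:.4f}") for cid, gene, s in prediction_rows],
    )
    _write_tsv(
        bundle.disease_genes,
        ("gene", "source", "score"),
        [
            (gene, source, f"{score:.4f}" if score != "" else "")
            for gene, source, score in disease_rows
        ],
    )
    with open(bundle.annotations, "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write("\t".join([ann.term_id, ann.term_name, *sorted(ann.genes)]) + "\n")
    _write_tsv(bundle.literature, ("compound_id", "n_studies"), lit_rows)
    _write_tsv(
        bundle.docking,
        ("compound_id", "target_gene", "affinity_kcal_mol"),
        [(cid, gene, f"{a:.3f}") for cid, gene, a in docking_rows],
    )
    truth = GroundTruth(
        planted_hub_compounds=frozenset(hub_compounds),
        planted_hub_targets=frozenset(hub_targets),
        planted_enriched_terms=frozenset(planted_terms),
        compound_universe=frozenset(compounds),
        target_universe=frozenset(universe),
        term_universe=frozenset(a.term_id for a in annotations),
    )
    truth.to_json(bundle.truth)
    log.info("synthetic bundle written to %s (seed=%d)", out_dir, cfg.seed)
    return bundle, truth


def _write_tsv(path, header, rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def recovery(selected: set, planted: set, universe: set) -> dict:
    """Precision/recall of a selected set against a planted set.

    Precision is ``None`` (JSON null) when nothing was selected.
    """
    selected, planted = set(selected), set(planted)
    stray = selected - set(universe)
    if stray:
        raise ValueError(f"selection ids outside the universe: {sorted(stray)[:5]}")
    tp = len(selected & planted)
    return {
        "n_selected": len(selected),
        "n_planted": len(planted),
        "precision": (tp / len(selected)) if selected else None,
        "recall": (tp / len(planted)) if planted else None,
    }


def evaluate_recovery(selection: dict, truth: GroundTruth) -> dict:
    """Score a pipeline selection against the planted ground truth.

    ``selection`` maps any of the keys ``key_components``, ``hub_targets``
    and ``enriched_terms`` to the selected id sets.
    """
    report = {}
    pairs = {
        "key_components": (truth.planted_hub_compounds, truth.compound_universe),
        "hub_targets": (truth.planted_hub_targets, truth.target_universe),
        "enriched_terms": (truth.planted_enriched_terms, truth.term_universe),
    }
    for key, (planted, universe) in pairs.items():
        if key in selection:
            report[key] = recovery(set(selection[key]), planted, universe)
    return report
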