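"""Readers and writers for the evidence tables and network exports.

All tabular inputs are tab-separated UTF-8 with a mandatory header row.
Numeric cells may carry thousands separators ("4,210,682"), which are
stripped on parse. Gene symbols are upper-cased before any set operation;
no alias mapping is attempted.

The module also ships two small curated reference tables for the safflower /
myocardial ischemia–reperfusion (MIR) case study that this pipeline
re-implements: the hub-target metrics table (31 targets with degree,
closeness and betweenness from the published tripartite network) and the
key-component evidence table (11 compounds with their network targets, MS
response values and literature-study counts).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, SchemaError, TableParseError
from .models import (
    ChemicalComponent,
    DiseaseGeneRecord,
    DockingRecord,
    GeneSetAnnotation,
    LiteratureEvidence,
    TargetPrediction,
)
from .network import TripartiteNetwork, build_network

_ION_MODE_ALIASES = {
    "+": "positive",
    "pos": "positive",
    "positive": "positive",
    "esi+": "positive",
    "-": "negative",
    "−": "negative",
    "neg": "negative",
    "negative": "negative",
    "esi-": "negative",
}

_RESPONSE_AGGREGATORS = {"max": max, "sum": sum, "mean": lambda v: sum(v) / len(v)}


def parse_number(text) -> float:
    """Parse a numeric cell, stripping thousands separators and whitespace."""
    if isinstance(text, (int, float)):
        return float(text)
    return float(str(text).replace(",", "").replace(" ", "").replace("−", "-"))


def _read_table(path, required: tuple) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _cell_number(value, path, row_index, column) -> float:
    try:
        return parse_number(value)
    except ValueError:
        # +2: one for the header line, one for 1-based numbering
        raise TableParseError(
            f"{path}: row {row_index + 2}: non-numeric {column} {value!r}"
        ) from None


def read_components(path, response_agg: str = "max") -> list[ChemicalComponent]:
    """Read the identified-component table.

    Rows that repeat a ``compound_id`` are per-ion-mode detections of the
    same compound; they are merged into one :class:`ChemicalComponent` whose
    ``ion_modes`` is the union and whose ``response`` aggregates the per-mode
    responses (``max`` by default; ``sum`` and ``mean`` are available).
    """
    if response_agg not in _RESPONSE_AGGREGATORS:
        raise ConfigurationError(f"unknown response aggregator {response_agg!r}")
    agg = _RESPONSE_AGGREGATORS[response_agg]
    df = _read_table(path, ("compound_id", "name", "ion_mode", "response"))

    groups: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        cid = row["compound_id"].strip()
        mode_raw = row["ion_mode"].strip().lower()
        if mode_raw not in _ION_MODE_ALIASES:
            raise TableParseError(
                f"{path}: row {i + 2}: unknown ion mode {row['ion_mode']!r}"
            )
        mode = _ION_MODE_ALIASES[mode_raw]
        response = _cell_number(row["response"], path, i, "response")
        rec = groups.setdefault(
            cid,
            {
                "name": row["name"].strip(),
                "modes": set(),
                "responses": [],
                "peaks": [],
                "rt": row.get("rt_min", ""),
                "mz": row.get("mz", ""),
                "formula": row.get("formula", ""),
                "class": row.get("class", "") or "other",
            },
        )
        rec["modes"].add(mode)
        rec["responses"].append(response)
        peak = str(row.get("peak_no", "")).strip()
        if peak:
            rec["peaks"].append(
                (mode, int(parse_number(peak)))
            )

    out = []
    for cid, rec in groups.items():
        out.append(
            ChemicalComponent(
                compound_id=cid,
                name=rec["name"],
                ion_modes=frozenset(rec["modes"]),
                retention_time_min=parse_number(rec["rt"]) if str(rec["rt"]).strip() else 0.0,
                mz_measured=parse_number(rec["mz"]) if str(rec["mz"]).strip() else float("nan"),
                formula=str(rec["formula"]),
                response=agg(rec["responses"]),
                structural_class=str(rec["class"]).strip() or "other",
                peak_numbers=tuple(sorted(rec["peaks"])),
            )
        )
    return out


def read_predictions(path) -> list[TargetPrediction]:
    """Read the compound→target prediction table (Tanimoto-scored edges)."""
    df = _read_table(path, ("compound_id", "gene", "tanimoto"))
    return [
        TargetPrediction(
            compound_id=row.compound_id.strip(),
            gene=row.gene.strip(),
            similarity=_cell_number(row.tanimoto, path, i, "tanimoto"),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def read_disease_genes(path) -> list[DiseaseGeneRecord]:
    """Read the disease–gene table; an empty score cell means no score."""
    df = _read_table(path, ("gene", "source", "score"))
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        score_text = str(row.score).strip()
        score = _cell_number(score_text, path, i, "score") if score_text else None
        records.append(
            DiseaseGeneRecord(gene=row.gene.strip(), source=row.source.strip(), score=score)
        )
    return records


def read_literature(path) -> list[LiteratureEvidence]:
    df = _read_table(path, ("compound_id", "n_studies"))
    return [
        LiteratureEvidence(
            compound_id=row.compound_id.strip(),
            n_studies=int(_cell_number(row.n_studies, path, i, "n_studies")),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def read_docking(path) -> list[DockingRecord]:
    df = _read_table(path, ("compound_id", "target_gene", "affinity_kcal_mol"))
    return [
        DockingRecord(
            compound_id=row.compound_id.strip(),
            target_gene=row.target_gene.strip(),
            affinity_kcal_mol=_cell_number(
                row.affinity_kcal_mol, path, i, "affinity_kcal_mol"
            ),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


# --------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path, namespace: str = "custom") -> list[GeneSetAnnotation]:
    """Read gene sets in GMT format (term, description, member genes...).

    Gene symbols are upper-cased and de-duplicated per term.
    """
    annotations = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            term_id, term_name, *genes = fields
            annotations.append(
                GeneSetAnnotation(
                    term_id=term_id,
                    term_name=term_name,
                    genes=frozenset(g.strip().upper() for g in genes if g.strip()),
                    namespace=namespace,
                )
            )
    return annotations


def write_gmt(annotations: list[GeneSetAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write("\t".join([ann.term_id, ann.term_name, *sorted(ann.genes)]) + "\n")


# --------------------------------------------------------------------------
# Network export / import

NETWORK_FORMATS = ("graphml", "sif", "edge_tsv")

# SIF cannot carry node attributes, so the relation names encode the
# partitions of both endpoints (first-listed partition written first).
_SIF_RELATIONS = {
    "component-target": ("component", "target"),
    "pathway-target": ("pathway", "target"),
}
_SIF_BY_EVIDENCE = {"component-target": "component-target", "target-pathway": "pathway-target"}


def write_network(net: TripartiteNetwork, path, format: str = "graphml") -> None:
    """Export the network; round-trips node set, edge set and partitions."""
    import networkx as nx

    net.validate()
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "sif":
        lines = []
        for u, v, data in net.graph.edges(data=True):
            rel = _SIF_BY_EVIDENCE[data["evidence"]]
            first_partition = _SIF_RELATIONS[rel][0]
            if net.partition_of(u) != first_partition:
                u, v = v, u
            lines.append(f"{u}\t{rel}\t{v}")
        path.write_text("\n".join(sorted(lines)) + "\n", encoding="utf-8")
    elif format == "edge_tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["source", "source_partition", "target", "target_partition", "evidence"]
            )
            rows = sorted(
                (str(u), net.partition_of(u), str(v), net.partition_of(v),
                 data["evidence"])
                for u, v, data in net.graph.edges(data=True)
            )
            writer.writerows(rows)
    else:
        raise ConfigurationError(f"unsupported network format {format!r}")


def read_network(path, format: str = "graphml") -> TripartiteNetwork:
    import networkx as nx

    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        net = TripartiteNetwork(nx.Graph(g))
        net._annotate_edges()
        net.validate()
        return net
    if format in ("sif", "edge_tsv"):
        nodes, edges = {}, []
        if format == "sif":
            for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
                if not line.strip():
                    continue
                try:
                    u, rel, v = line.split("\t")
                    p_u, p_v = _SIF_RELATIONS[rel]
                except (ValueError, KeyError):
                    raise TableParseError(f"{path}: line {lineno}: bad SIF line") from None
                nodes[u], nodes[v] = p_u, p_v
                edges.append((u, v))
        else:
            df = _read_table(path, ("source", "source_partition", "target", "target_partition"))
            for row in df.itertuples(index=False):
                nodes[row.source] = row.source_partition
                nodes[row.target] = row.target_partition
                edges.append((row.source, row.target))
        return TripartiteNetwork.from_edges(sorted(nodes.items()), edges)
    raise ConfigurationError(f"unsupported network format {format!r}")


# --------------------------------------------------------------------------
# Packaged reference tables (safflower–MIR case study)


def _data_path(name: str):
    return resources.files("phytonet").joinpath("data", name)


def load_reference_hub_targets() -> pd.DataFrame:
    """The published hub-target table: 31 targets with degree, closeness,
    betweenness from the safflower–MIR tripartite network."""
    with resources.as_file(_data_path("hub_target_metrics.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def load_reference_key_components() -> pd.DataFrame:
    """The published key-component evidence table: 11 compounds with their
    network targets, printed degree, MS response and literature count."""
    with resources.as_file(_data_path("key_component_evidence.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    df["targets"] = df["targets"].map(lambda s: [g for g in s.split("|") if g])
    df["degree"] = df["degree"].map(int)
    df["response"] = df["response"].map(parse_number)
    df["n_studies"] = df["n_studies"].map(int)
    return df


def reference_component_network() -> TripartiteNetwork:
    """Bipartite component–target network rebuilt from the transcribed
    key-component target lists (no pathway layer)."""
    df = load_reference_key_components()
    per_compound = {row.component: set(row.targets) for row in df.itertuples(index=False)}
    effective = set().union(*per_compound.values())
    return build_network(per_compound, [], effective)
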