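"""Shared fixtures: programmatically generated evidence tables.

The component survey and pathway collection below are synthetic stand-ins
built at test time: they reproduce the published summary structure of the
safflower case study (79 compounds, 51 detected per ion mode; 34 curated
pathways) around the 11 fully transcribed key-component rows, filling the
remaining rows with generated placeholders.
"""

from __future__ import annotations

import numpy as np
import pytest

from phytonet.network import TripartiteNetwork

# the 11 transcribed key components: (name, modes, response)
KEY_COMPONENTS = [
    ("Quercetin (+40)", ["+"], 233661),
    ("Luteolin (-44, +55)", ["-", "+"], 90094),
    ("Apigenin (-47, +58)", ["-", "+"], 175455),
    ("Rutin (+33)", ["+"], 732202),
    ("HSYA (-11, +17)", ["-", "+"], 4210682),
    ("Kaempferol (-42, +44)", ["-", "+"], 876007),
    ("Baicalin (-40, +51)", ["-", "+"], 73419),
    ("Eriodictyol (+23)", ["+"], 306217),
    ("6-hydroxyapigenin (-48, +46)", ["-", "+"], 338578),
    ("6-Hydroxykaempferol (-32, +35)", ["-", "+"], 1375662),
    ("6-Hydroxykaempferol 3-Rutinoside-6-glucoside", ["-"], 1632678),
]

PATHWAY_NAMES = [
    "TNF signaling pathway", "NF-kappa B signaling pathway",
    "Natural killer cell mediated cytotoxicity",
    "T cell receptor signaling pathway", "Toll-like receptor signaling pathway",
    "NOD-like receptor signaling pathway", "AMPK signaling pathway",
    "cAMP signaling pathway", "Arachidonic acid metabolism",
    "PI3K-Akt signaling pathway", "MAPK signaling pathway",
    "HIF-1 signaling pathway", "IL-17 signaling pathway", "Apoptosis",
    "Calcium signaling pathway",
]


def write_tsv(path, header, rows):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture(scope="session")
def component_survey(tmp_path_factory):
    """A 79-compound survey table: 51 detections in each ion mode.

    The 11 transcribed key components keep their real names, modes and
    responses; the other 68 compounds are synthetic placeholders arranged
    so that 23 compounds appear in both modes (51 + 51 − 79).
    """
    rng = np.random.default_rng(20230310)
    rows = []
    compounds = []  # (id, name, modes, response)
    for i, (name, modes, response) in enumerate(KEY_COMPONENTS):
        compounds.append((f"KC{i + 1:02d}", name, modes, float(response)))
    # synthetic fill: 16 both-mode, 25 positive-only, 27 negative-only
    fills = [["-", "+"]] * 16 + [["+"]] * 25 + [["-"]] * 27
    for j, modes in enumerate(fills):
        compounds.append(
            (
                f"SYN{j + 1:02d}",
                f"synthetic_compound_{j + 1:02d}",
                modes,
                float(rng.lognormal(11, 1.5)),
            )
        )
    assert len(compounds) == 79
    for cid, name, modes, response in compounds:
        for m, mode in enumerate(modes):
            # secondary-mode detections have a lower response: max() recovers
            # the per-compound value
            resp = response if m == 0 else response * float(rng.uniform(0.3, 0.9))
            rows.append(
                (cid, name, mode, rng.integers(1, 99),
                 f"{rng.uniform(0.5, 20):.3f}", f"{rng.uniform(100, 1500):.4f}",
                 "C15H10O5", f"{resp:.2f}", "flavonoid")
            )
    path = tmp_path_factory.mktemp("survey") / "components.tsv"
    return write_tsv(
        path,
        ("compound_id", "name", "ion_mode", "peak_no", "rt_min", "mz",
         "formula", "response", "class"),
        rows,
    )


@pytest.fixture(scope="session")
def pathway_gmt(tmp_path_factory):
    """A 34-term curated pathway collection in GMT format."""
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(1, 120)]
    path = tmp_path_factory.mktemp("gmt") / "pathways.gmt"
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(34):
            name = PATHWAY_NAMES[i] if i < len(PATHWAY_NAMES) else f"pathway {i + 1}"
            members = rng.choice(genes, size=rng.integers(8, 25), replace=False)
            fh.write("\t".join([f"hsa{4600 + i:05d}", name, *members]) + "\n")
    return path


def random_tripartite(rng, max_nodes=12, edge_prob=0.4) -> TripartiteNetwork:
    """A random valid tripartite network with up to ``max_nodes`` nodes."""
    while True:
        nc = int(rng.integers(1, max(2, max_nodes - 2)))
        nt = int(rng.integers(1, max(2, max_nodes - nc)))
        np_ = int(rng.integers(0, max(1, max_nodes - nc - nt) + 1))
        comps = [f"c{i}" for i in range(nc)]
        tgts = [f"t{i}" for i in range(nt)]
        pws = [f"p{i}" for i in range(np_)]
        edges = [
            (c, t) for c in comps for t in tgts if rng.random() < edge_prob
        ] + [(p, t) for p in pws for t in tgts if rng.random() < edge_prob]
        if edges:
            nodes = (
                [(c, "component") for c in comps]
                + [(t, "target") for t in tgts]
                + [(p, "pathway") for p in pws]
            )
            return TripartiteNetwork.from_edges(nodes, edges)
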