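"""Reading evidence tables, GMT gene sets, and network round-trips."""

import numpy as np
import pytest

from phytonet import core_io
from phytonet.errors import ConfigurationError, SchemaError, TableParseError

from conftest import random_tripartite, write_tsv

COMPONENT_HEADER = ("compound_id", "name", "ion_mode", "response")


class TestReadComponents:
    @pytest.mark.parametrize(
        "agg, expected", [("max", 400.0), ("sum", 500.0), ("mean", 250.0)]
    )
    def test_ion_mode_rows_merge_into_one_component(self, tmp_path, agg, expected):
        path = write_tsv(
            tmp_path / "c.tsv", COMPONENT_HEADER,
            [("HSYA", "HSYA", "-", 100.0), ("HSYA", "HSYA", "+", 400.0)],
        )
        (comp,) = core_io.read_components(path, response_agg=agg)
        assert comp.ion_modes == frozenset({"positive", "negative"})
        assert comp.response == expected

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        path = write_tsv(tmp_path / "c.tsv", COMPONENT_HEADER, [])
        assert core_io.read_components(path) == []

    def test_survey_has_79_compounds_51_per_ion_mode(self, component_survey):
        comps = core_io.read_components(component_survey)
        assert len(comps) == 79
        n_pos = sum("positive" in c.ion_modes for c in comps)
        n_neg = sum("negative" in c.ion_modes for c in comps)
        assert (n_pos, n_neg) == (51, 51)

    def test_missing_column_raises_schema_error_naming_it(self, tmp_path):
        path = write_tsv(
            tmp_path / "c.tsv", ("compound_id", "name", "response"), []
        )
        with pytest.raises(SchemaError, match="ion_mode"):
            core_io.read_components(path)

    def test_non_numeric_response_reports_row_number(self, tmp_path):
        path = write_tsv(
            tmp_path / "c.tsv", COMPONENT_HEADER,
            [("A", "a", "+", 5.0), ("B", "b", "+", "n/a")],
        )
        with pytest.raises(TableParseError, match="row 3"):
            core_io.read_components(path)

    def test_thousands_separators_are_stripped(self, tmp_path):
        path = write_tsv(
            tmp_path / "c.tsv", COMPONENT_HEADER, [("A", "a", "+", "4,210,682")]
        )
        (comp,) = core_io.read_components(path)
        assert comp.response == 4210682.0


class TestReadGmt:
    def test_symbols_case_folded_and_deduplicated(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("T1\tdesc\ta\tb\tA\n", encoding="utf-8")
        (term,) = core_io.read_gmt(path)
        assert term.term_id == "T1"
        assert term.genes == frozenset({"A", "B"})

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("", encoding="utf-8")
        assert core_io.read_gmt(path) == []

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "t.gmt"
        path.write_text("T1\tdesc\tA\nT2\tdesc\n", encoding="utf-8")
        with pytest.raises(TableParseError, match="line 2"):
            core_io.read_gmt(path)

    def test_curated_pathway_fixture_has_34_terms(self, pathway_gmt):
        terms = core_io.read_gmt(pathway_gmt, namespace="kegg")
        assert len(terms) == 34
        assert all(t.namespace == "kegg" for t in terms)
        assert len({t.term_id for t in terms}) == 34


class TestNetworkRoundTrip:
    def test_toy_sif_has_one_line_per_edge(self, tmp_path):
        net = random_tripartite(np.random.default_rng(0))
        path = tmp_path / "net.sif"
        core_io.write_network(net, path, "sif")
        lines = path.read_text(encoding="utf-8").strip().splitlines()
        assert len(lines) == len(net.edges())

    @pytest.mark.parametrize("fmt", core_io.NETWORK_FORMATS)
    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_preserves_nodes_edges_partitions(self, tmp_path, fmt, seed):
        net = random_tripartite(np.random.default_rng(seed), max_nodes=20)
        path = tmp_path / f"net_{seed}.{fmt}"
        core_io.write_network(net, path, fmt)
        back = core_io.read_network(path, fmt)
        assert back.edges() == net.edges()
        connected = {u for e in net.edges() for u in e}
        assert {(n, back.partition_of(n)) for n in back.nodes()} >= {
            (n, net.partition_of(n)) for n in net.nodes() if n in connected
        }

    def test_unsupported_format_is_a_usage_error(self, tmp_path):
        net = random_tripartite(np.random.default_rng(1))
        with pytest.raises(ConfigurationError, match="format"):
            core_io.write_network(net, tmp_path / "x", "gexf")


class TestReferenceTables:
    def test_hub_target_table_shape(self):
        df = core_io.load_reference_hub_targets()
        assert len(df) == 31
        assert list(df.columns) == ["gene", "degree", "closeness", "betweenness"]
        assert df["degree"].is_monotonic_decreasing

    def test_key_component_table_parses_printed_numbers(self):
        df = core_io.load_reference_key_components()
        assert len(df) == 11
        row = df.set_index("component").loc["HSYA (-11, +17)"]
        assert row["response"] == 4210682
        assert row["targets"] == ["PTGS1", "HK1"]

    def test_reference_network_has_11_component_nodes(self):
        net = core_io.reference_component_network()
        assert len(net.nodes("component")) == 11
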