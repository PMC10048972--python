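"""Median-threshold screens: hubs, 2-of-3 key components, docking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet.errors import EmptyPopulationError
from phytonet.models import (
    ChemicalComponent,
    ComponentEvidence,
    DockingRecord,
    LiteratureEvidence,
    MedianThresholds,
    ScreeningCriteria,
)
from phytonet.network import NodeMetrics
from phytonet.screening import (
    compute_medians,
    screen_docking,
    screen_hub_targets,
    screen_key_components,
)
from phytonet import core_io


def target_metric(gene, deg):
    return NodeMetrics(gene, "target", deg, 0.5, 0.1)


def component_metric(cid, deg):
    return NodeMetrics(cid, "component", deg, 0.5, 0.1)


def component(cid, response):
    return ChemicalComponent(
        compound_id=cid, name=cid, ion_modes=frozenset({"positive"}),
        response=response,
    )


def thresholds(target=0, comp=0, response=0, literature=0):
    return MedianThresholds(target, comp, response, literature)


class TestMedians:
    def test_odd_and_even_count_conventions(self):
        metrics = [target_metric(f"g{i}", d) for i, d in enumerate([1, 2, 3, 4, 5])]
        metrics += [component_metric(f"c{i}", d) for i, d in enumerate([1, 2, 3, 4])]
        th = compute_medians(
            metrics,
            [LiteratureEvidence(f"c{i}", i) for i in range(4)],
            [component(f"c{i}", 10.0 * (i + 1)) for i in range(4)],
        )
        assert th.target_degree_median == 3
        assert th.component_degree_median == 2.5
        assert th.response_median == 25.0

    def test_literature_median_over_topology_passing_candidates(self):
        # component degrees [1,2,3,4] -> median 2.5 -> candidates c2,c3
        metrics = [target_metric("g", 1)]
        metrics += [component_metric(f"c{i}", i + 1) for i in range(4)]
        lit = [LiteratureEvidence("c2", 4), LiteratureEvidence("c3", 8)]
        th = compute_medians(metrics, lit, [component("c0", 1.0)])
        assert th.literature_median == 6.0

    def test_explicit_literature_cutoff_overrides(self):
        metrics = [target_metric("g", 1), component_metric("c", 2)]
        th = compute_medians(metrics, [], [component("c", 1.0)], literature_cutoff=5)
        assert th.literature_median == 5.0

    def test_empty_population_is_named_in_the_error(self):
        with pytest.raises(EmptyPopulationError, match="target degrees"):
            compute_medians([component_metric("c", 1)], [], [component("c", 1.0)])


class TestHubTargets:
    def test_strict_median_rule_on_small_population(self):
        metrics = [target_metric(f"g{i}", d) for i, d in enumerate([1, 2, 3, 4, 5])]
        hubs = screen_hub_targets(metrics, thresholds(target=3))
        assert [m.degree for m in hubs] == [5, 4]

    def test_all_equal_degrees_select_nothing(self):
        metrics = [target_metric(f"g{i}", 4) for i in range(6)]
        assert screen_hub_targets(metrics, thresholds(target=4)) == []

    def test_duplicated_metric_rows_change_nothing(self):
        metrics = [target_metric(f"g{i}", d) for i, d in enumerate([2, 5, 9])]
        once = screen_hub_targets(metrics, thresholds(target=4))
        twice = screen_hub_targets(metrics * 3, thresholds(target=4))
        assert once == twice

    def test_reference_table_yields_31_hubs_led_by_prkca(self):
        df = core_io.load_reference_hub_targets()
        metrics = [
            NodeMetrics(r.gene, "target", int(r.degree),
                        float(r.closeness), float(r.betweenness))
            for r in df.itertuples(index=False)
        ]
        # 6 is the published degree median of the full target partition
        hubs = screen_hub_targets(metrics, thresholds(target=6))
        assert len(hubs) == 31
        assert hubs[0].node_id == "PRKCA"
        assert hubs[0].degree == 46


class TestKeyComponents:
    # published medians: component degree 8, response 67667
    PUBLISHED = thresholds(comp=8, response=67667, literature=8)

    def test_quercetin_row_passes_all_three_criteria(self):
        ev = [ComponentEvidence("Quercetin (+40)", degree=12, n_studies=17,
                                response=233661)]
        (out,) = screen_key_components(ev, self.PUBLISHED)
        assert out.criteria_passed == {"topology", "literature", "quantitation"}
        assert out.selected

    def test_weak_compound_fires_no_criterion(self):
        ev = [ComponentEvidence("x", degree=1, n_studies=0, response=10.0)]
        (out,) = screen_key_components(ev, self.PUBLISHED)
        assert out.criteria_passed == frozenset()
        assert not out.selected

    def test_two_of_three_rule_on_toy_set(self):
        th = thresholds(comp=5, response=100, literature=3)
        ev = [
            ComponentEvidence("A", degree=9, n_studies=0, response=500),  # topo+quant
            ComponentEvidence("B", degree=1, n_studies=9, response=10),  # lit only
            ComponentEvidence("C", degree=9, n_studies=9, response=500),  # all
        ]
        out = {e.compound_id: e for e in screen_key_components(ev, th)}
        assert out["A"].criteria_passed == {"topology", "quantitation"}
        assert out["B"].criteria_passed == {"literature"}
        assert {cid for cid, e in out.items() if e.selected} == {"A", "C"}

    def test_selected_compounds_list_enough_fired_criteria(self):
        criteria = ScreeningCriteria(min_criteria_met=2)
        ev = [
            ComponentEvidence(f"c{i}", degree=i, n_studies=i % 5, response=float(i))
            for i in range(30)
        ]
        for out in screen_key_components(ev, thresholds(10, 10, 10.0, 2), criteria):
            assert out.selected == (len(out.criteria_passed) >= 2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        degrees=st.lists(st.integers(0, 20), min_size=1, max_size=20),
        bump=st.floats(min_value=0, max_value=10),
    )
    def test_tightening_a_criterion_never_enlarges_selection(self, degrees, bump):
        ev = [
            ComponentEvidence(f"c{i}", degree=d, n_studies=d % 7, response=float(d))
            for i, d in enumerate(degrees)
        ]
        loose = thresholds(comp=5, response=5.0, literature=2)
        for tight in (
            thresholds(comp=5 + bump, response=5.0, literature=2),
            thresholds(comp=5, response=5.0 + bump, literature=2),
            thresholds(comp=5, response=5.0, literature=2 + bump),
        ):
            selected_loose = {e.compound_id for e in screen_key_components(ev, loose)
                              if e.selected}
            selected_tight = {e.compound_id for e in screen_key_components(ev, tight)
                              if e.selected}
            assert selected_tight <= selected_loose


class TestDocking:
    def test_affinity_below_cutoff_passes(self):
        res = screen_docking([DockingRecord("c", "G", -7.9)], cutoff=-7.8)
        assert res.passes[("c", "G")]

    def test_boundary_affinity_fails_strictly(self):
        res = screen_docking([DockingRecord("c", "G", -5.0)], cutoff=-5.0)
        assert not res.passes[("c", "G")]

    def test_pass_counts_per_target(self):
        records = [DockingRecord(f"c{i}", "PRKCA", -6.0) for i in range(10)]
        records.append(DockingRecord("c10", "PRKCA", -4.0))
        res = screen_docking(records, cutoff=-5.0)
        assert sum(res.passes.values()) == 10
        assert res.per_target_pass_counts == {"PRKCA": 10}
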