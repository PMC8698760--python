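"""Unit tests for BOASP, PGE detection, injectate tracing and sweeps."""

import pytest

from btaceflow import (
    CancerScenario,
    FlowSolution,
    NetworkError,
    OcclusionState,
    PGEConsistencyError,
    apply_occlusion,
    assess_occlusion,
    build_ivm_network,
    classify_outcome,
    compute_boasp,
    detect_pge,
    occlusion_sweep,
    solve_flow,
    trace_injectate,
)
from btaceflow.analysis import injection_field
from btaceflow.ivm import outlet_tube_id


class TestComputeBoasp:
    def test_requires_an_occlusion_site(self, baseline_case1):
        _, sol = baseline_case1
        with pytest.raises(NetworkError):
            compute_boasp(sol, sol, "n_rha", None)

    def test_boasp_never_exceeds_pre_occlusion_pressure(self, config, case1):
        for site in ("b", "c", "f", "h"):
            a = assess_occlusion(config, case1, site)
            assert a.boasp <= a.pressure_before

    def test_occluding_a_no_flow_branch_changes_nothing(self, y_network):
        """A branch that carried no flow leaves the stump pressure untouched."""
        for nid in ("src", "sink_a", "sink_b"):
            y_network.set_boundary_pressure(nid, 800.0)
        baseline = solve_flow(y_network)
        y_network.block("feed")
        occluded = solve_flow(y_network)
        before, boasp = compute_boasp(baseline, occluded, "junction", "feed")
        assert boasp == pytest.approx(before, rel=1e-12)


class TestDetectPge:
    def test_strict_pressure_window(self, config, case1, baseline_case1):
        net, sol = baseline_case1
        # BOASP exactly at the threshold does not count as PGE; the baseline
        # solution has no reversed outlets, so the criteria agree on False.
        pge, reversed_normal = detect_pge(config.urp, config.urp, config.lrp, sol, case1)
        assert pge is False and reversed_normal == frozenset()

    def test_disagreement_raises(self, config, case1, baseline_case1):
        _, sol = baseline_case1
        with pytest.raises(PGEConsistencyError):
            # pressure inside the window but no reversed outlet in the solution
            detect_pge((config.urp + config.lrp) / 2, config.urp, config.lrp, sol, case1)

    def test_exp1_reversed_outlets(self, config, case1):
        a = assess_occlusion(config, case1, "c")
        assert a.pge is True
        assert a.reversed_normal_outlets == {"S5", "S6", "S8"}


class TestTraceInjectate:
    def test_baseline_injection_at_inlet_reaches_everything(self, baseline_case1):
        from btaceflow import SEGMENTS

        net, sol = baseline_case1
        assert trace_injectate(net, sol, "n_inlet") == set(SEGMENTS)

    def test_unknown_injection_node_rejected(self, baseline_case1):
        net, sol = baseline_case1
        with pytest.raises(NetworkError):
            trace_injectate(net, sol, "nowhere")

    def test_injection_field_needs_interior_node(self, baseline_case1):
        net, _ = baseline_case1
        with pytest.raises(NetworkError):
            injection_field(net, "src_pump")

    def test_stagnant_stump_follows_the_injection_limit(self, config, case2):
        """Case 2 occluded distal to the CA: the stump is a stagnation point,
        and the vanishing-injection limit carries the tracer to both tumours."""
        a = assess_occlusion(config, case2, "c")
        assert a.stagnant is True
        assert a.reached_outlets == {"S5", "S7"}

    def test_pure_flow_tracing_stops_at_a_stagnation_point(self, config, case2):
        net = build_ivm_network(config, case2)
        apply_occlusion(net, OcclusionState("c"))
        sol = solve_flow(net)
        reached = trace_injectate(net, sol, "n_rha", infinitesimal_injection=False)
        assert reached == frozenset()


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "reached,tumors,expected",
        [
            ({"S7"}, {"S7"}, "successful"),
            ({"S5", "S6", "S7", "S8"}, {"S7"}, "unsuccessful"),
            (set(), {"S7"}, "unsuccessful"),
            ({"S5", "S7"}, {"S5", "S7"}, "successful"),
            ({"S5"}, {"S5", "S7"}, "successful"),
        ],
    )
    def test_tumor_only_reachability(self, reached, tumors, expected):
        outcome = classify_outcome(frozenset(reached), CancerScenario(tumors))
        assert outcome == expected


class TestSweep:
    def test_tested_subset_classification(self, config, case1):
        curve = occlusion_sweep(config, case1, sites=("b", "c", "e", "f", "h"))
        pge_sites = {s for s, a in curve.assessments.items() if a.pge}
        good_sites = {s for s, a in curve.assessments.items() if a.outcome == "successful"}
        assert pge_sites == {"c", "f"}
        assert good_sites == {"c", "f", "h"}

    def test_reference_pressures_ordered(self, config, case1):
        curve = occlusion_sweep(config, case1, sites=("b", "c"))
        assert curve.lrp < curve.urp < curve.ip

    def test_frame_layout(self, config, case1):
        frame = occlusion_sweep(config, case1, sites=("b", "c")).to_frame()
        assert list(frame["site"]) == ["b", "c"]
        for column in ("p_before_mmHg", "boasp_mmHg", "IP_mmHg", "URP_mmHg", "LRP_mmHg",
                       "pge", "reached", "outcome", "physically_tested"):
            assert column in frame.columns
        assert frame.loc[1, "reached"] == "S7"

    def test_plot_returns_axes(self, config, case1):
        ax = occlusion_sweep(config, case1, sites=("b", "c")).plot()
        assert len(ax.lines) >= 5  # two curves + three reference lines
        ax.figure.clf()


def test_exp2_flow_decreases_but_persists(config, case1):
    """Occluding between the CA stations reroutes, rather than stops, the
    right-lobe supply; the detour's extra resistance lowers the flow."""
    from btaceflow.artery import RIGHT_SEGMENTS

    net = build_ivm_network(config, case1)
    baseline = solve_flow(net)
    apply_occlusion(net, OcclusionState("b"))
    occluded = solve_flow(net)
    right = [outlet_tube_id(s) for s in RIGHT_SEGMENTS]
    assert all(occluded.flow(t) > 0.0 for t in right)
    assert sum(occluded.flow(t) for t in right) < sum(baseline.flow(t) for t in right)
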