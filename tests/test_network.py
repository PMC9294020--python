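import dataclasses
import math

import numpy as np
import pytest

from stentflow.geometry import MM, make_scenario, random_scenario
from stentflow.network import (
    BLADDER,
    PELVIS,
    Edge,
    HydraulicNetwork,
    NetworkError,
    assemble_network,
    brute_force_solve,
    classify_active_holes,
    node_residuals,
    reynolds_reports,
    segment_decomposition,
    side_hole_flows,
    solve_network,
)

from conftest import random_test_network


def two_pipe_network(g1: float = 2e-6, g2: float = 2e-6) -> HydraulicNetwork:
    """Pelvis - node 2 - bladder, two conductances in series."""
    edges = [
        Edge(PELVIS, 2, g1, "intra_pipe", 1, 1e-3, 1e-6),
        Edge(2, BLADDER, g2, "intra_pipe", 1, 1e-3, 1e-6),
    ]
    return HydraulicNetwork(
        n_nodes=3, edges=edges, reservoir_pressures={PELVIS: 97.8, BLADDER: 0.0},
        node_labels=["pelvis", "bladder", "mid"], station_positions=np.empty(0),
        segment_bounds=np.empty((0, 2)), segment_holes=[],
    )


class TestAssembly:
    def test_case1_edge_and_node_counts(self, case_solutions):
        # 34 stations -> 35 segments: 4 end attachments, 2 intra halves and
        # 2 extra halves per segment, one wall edge per segment, one hole
        # edge per station
        net, _ = case_solutions[1]
        assert net.n_nodes == 2 + 2 * 36 + 2 * 35
        assert len(net.edges) == 4 + 4 * 35 + 35 + 34

    def test_occlusion_removes_annulus_edges(self, case_solutions):
        net1, _ = case_solutions[1]
        net8, _ = case_solutions[8]
        # the 6 mm occlusion sits inside segment 18 of the 35-segment
        # layout: both annulus halves and the wall edge of that segment go
        n1 = {k: sum(1 for e in net1.edges if e.kind == k) for k in
              ("extra_annulus", "wall_darcy")}
        n8 = {k: sum(1 for e in net8.edges if e.kind == k) for k in
              ("extra_annulus", "wall_darcy")}
        assert n1["extra_annulus"] - n8["extra_annulus"] == 2
        assert n1["wall_darcy"] - n8["wall_darcy"] == 1

    def test_no_hole_stent_uses_reference_stations(self, case_solutions):
        net7, _ = case_solutions[7]
        net2, _ = case_solutions[2]
        assert np.allclose(net7.station_positions, net2.station_positions)
        assert sum(1 for e in net7.edges if e.kind == "side_hole") == 0

    def test_end_attachment_lumps_coil_holes(self, case_solutions):
        net, _ = case_solutions[1]
        ends = [e for e in net.edges if e.kind == "end_opening" and e.n_coil_holes]
        assert len(ends) == 2
        for e in ends:
            assert e.n_coil_holes == 4
            assert e.conductance == pytest.approx(e.g_opening + 4 * e.g_coil_hole)
        idx = sorted(i for e in ends for i in e.coil_hole_indices)
        assert idx == [1, 2, 3, 4, 39, 40, 41, 42]

    def test_segment_holes_bracketing(self, case_solutions):
        net, _ = case_solutions[1]
        assert net.segment_holes[0] == (None, 5)
        assert net.segment_holes[-1] == (38, None)
        assert net.segment_holes[17] == (21, 22)

    def test_reservoir_pressures(self, case_solutions):
        net, _ = case_solutions[1]
        assert net.reservoir_pressures == {PELVIS: 97.8, BLADDER: 0.0}


class TestSolveBasics:
    def test_two_series_conductances(self):
        # hand value: m_dot = dP / (1/G1 + 1/G2) = 9.78e-5 kg/s
        sol = solve_network(two_pipe_network())
        assert sol.pelvis_outflow == pytest.approx(9.78e-5, rel=1e-12)
        assert sol.bladder_inflow == pytest.approx(9.78e-5, rel=1e-12)
        assert sol.node_pressures[2] == pytest.approx(48.9, rel=1e-12)

    def test_linearity_in_pressure_drop(self):
        net = two_pipe_network()
        base = solve_network(net).pelvis_outflow
        net.reservoir_pressures = {PELVIS: 3 * 97.8, BLADDER: 0.0}
        assert solve_network(net).pelvis_outflow == pytest.approx(3 * base, rel=1e-12)

    def test_antisymmetry_under_reversed_drop(self):
        net = two_pipe_network(g1=1e-6, g2=5e-6)
        fwd = solve_network(net)
        net.reservoir_pressures = {PELVIS: 0.0, BLADDER: 97.8}
        rev = solve_network(net)
        assert rev.edge_flows == pytest.approx(-fwd.edge_flows, rel=1e-12)

    def test_zero_pressure_drop_zero_flow(self):
        net = two_pipe_network()
        net.reservoir_pressures = {PELVIS: 50.0, BLADDER: 50.0}
        sol = solve_network(net)
        assert np.allclose(sol.edge_flows, 0.0, atol=1e-18)

    def test_empty_network_raises(self):
        net = two_pipe_network()
        net.edges = []
        with pytest.raises(NetworkError, match="empty"):
            solve_network(net)

    def test_disconnected_reservoirs_raise(self):
        net = two_pipe_network()
        net.edges = [net.edges[0]]  # drop the bladder leg
        with pytest.raises(NetworkError, match="pelvis-side component"):
            solve_network(net)

    def test_dry_side_branch_gets_nan_pressure(self):
        net = two_pipe_network()
        net.n_nodes = 5
        net.node_labels += ["dry_a", "dry_b"]
        net.edges.append(Edge(3, 4, 1e-6, "intra_pipe", 1, 1e-3, 1e-6))
        sol = solve_network(net)
        assert np.isnan(sol.node_pressures[3]) and np.isnan(sol.node_pressures[4])
        assert sol.pelvis_outflow == pytest.approx(9.78e-5, rel=1e-12)


class TestConservation:
    @pytest.mark.parametrize("cid", range(1, 10))
    def test_residual_and_global_balance(self, case_solutions, cid):
        net, sol = case_solutions[cid]
        assert node_residuals(net, sol) <= 1e-12
        assert sol.bladder_inflow == pytest.approx(sol.pelvis_outflow, rel=1e-10)

    @pytest.mark.parametrize("cid", range(1, 10))
    def test_eq7_identity_every_surface(self, case_solutions, cid):
        _, sol = case_solutions[cid]
        for seg in sol.per_segment:
            assert seg.m_total == pytest.approx(
                seg.m_intra + seg.m_extra + seg.m_wall, rel=1e-12, abs=1e-18)

    @pytest.mark.parametrize("cid", range(1, 10))
    def test_total_constant_along_ureter(self, case_solutions, cid):
        _, sol = case_solutions[cid]
        totals = np.array([s.m_total for s in sol.per_segment])
        assert np.ptp(totals) / abs(sol.total_flow) < 1e-9

    def test_perturbed_flow_breaks_residual(self, case_solutions):
        # corrupting one substantial edge flow by 1% must show up in the
        # Kirchhoff residual at the same order
        net, sol = case_solutions[1]
        i = int(np.argmax(np.abs(sol.edge_flows)))
        bad = dataclasses.replace(sol)
        bad.edge_flows = sol.edge_flows.copy()
        bad.edge_flows[i] *= 1.01
        frac = abs(sol.edge_flows[i]) / abs(sol.total_flow)
        resid = node_residuals(net, bad)
        assert resid > 0.001 * frac

    def test_m_wall_identically_zero(self, case_solutions):
        # wall transport is purely radial: the axial in-wall flow is zero
        # by construction in every case, porous or not
        for cid in range(1, 10):
            _, sol = case_solutions[cid]
            assert all(s.m_wall == 0.0 for s in sol.per_segment)

    def test_wall_exchange_zero_when_unporous(self, case_solutions):
        for cid in (1, 8):
            _, sol = case_solutions[cid]
            assert all(s.wall_exchange == 0.0 for s in sol.per_segment)


class TestOracle:
    @pytest.mark.parametrize("cid", range(1, 10))
    def test_named_cases_vs_dense(self, case_solutions, cid):
        net, sol = case_solutions[cid]
        ref = brute_force_solve(net)
        scale = abs(ref.total_flow)
        assert np.max(np.abs(sol.edge_flows - ref.edge_flows)) / scale <= 1e-10
        assert sol.total_flow == pytest.approx(ref.total_flow, rel=1e-10)

    def test_random_networks_vs_dense(self):
        for seed in range(100):
            net = random_test_network(seed)
            sol = solve_network(net)
            ref = brute_force_solve(net)
            scale = max(abs(ref.total_flow), 1e-300)
            assert np.max(np.abs(sol.edge_flows - ref.edge_flows)) / scale <= 1e-10

    def test_random_scenarios_vs_dense(self):
        for seed in range(10):
            net = assemble_network(random_scenario(seed))
            sol = solve_network(net)
            ref = brute_force_solve(net)
            scale = abs(ref.total_flow)
            assert np.max(np.abs(sol.edge_flows - ref.edge_flows)) / scale <= 1e-10

    def test_dense_refuses_large_systems(self):
        net = random_test_network(0)
        net.n_nodes = 10_000
        with pytest.raises(NetworkError, match="brute-force"):
            brute_force_solve(net)


class TestZeroPermeabilityEquivalence:
    def test_alpha_zero_matches_edge_free_network(self, case_solutions):
        # a zero-conductance wall edge must be bit-identical to no wall
        # edge at all
        net, sol = case_solutions[1]
        stripped = HydraulicNetwork(
            n_nodes=net.n_nodes,
            edges=[e for e in net.edges if e.kind != "wall_darcy"],
            reservoir_pressures=net.reservoir_pressures,
            node_labels=net.node_labels,
            station_positions=net.station_positions,
            segment_bounds=net.segment_bounds,
            segment_holes=net.segment_holes,
            scenario=net.scenario,
        )
        ref = solve_network(stripped)
        assert ref.total_flow == sol.total_flow  # exact, not approx
        kept = [q for e, q in zip(net.edges, sol.edge_flows) if e.kind != "wall_darcy"]
        assert np.array_equal(np.array(kept), ref.edge_flows)


class TestDecomposition:
    def test_segment_index_bounds(self, case_solutions):
        _, sol = case_solutions[1]
        assert segment_decomposition(sol, 1).segment_index == 1
        assert segment_decomposition(sol, 35).segment_index == 35
        with pytest.raises(IndexError):
            segment_decomposition(sol, 0)
        with pytest.raises(IndexError):
            segment_decomposition(sol, 36)

    def test_occluded_segment_all_intraluminal(self, case_solutions):
        for cid in (8, 9):
            _, sol = case_solutions[cid]
            seg = segment_decomposition(sol, 18)  # between holes 21 and 22
            assert seg.upstream_hole == 21 and seg.downstream_hole == 22
            assert seg.m_extra == 0.0
            assert seg.m_intra == pytest.approx(seg.m_total, rel=1e-12)

    def test_hole_flow_consistency_with_chain(self, case_solutions):
        # intraluminal flow change across a station equals the hole inflow
        # plus the wall exchange of the adjacent half-segments; checked via
        # global bookkeeping: sum of all hole flows + wall exchanges +
        # end-attachment intra flows is the total
        net, sol = case_solutions[2]
        hole_in = sum(q for idx, q in sol.per_hole if 5 <= idx <= 38)
        wall_in = sum(s.wall_exchange for s in sol.per_segment)
        intra_end_in = sum(
            q for e, q in zip(net.edges, sol.edge_flows)
            if e.kind == "end_opening" and e.node_a == PELVIS and e.n_coil_holes >= 0
            and e.flow_area > 0 and e.hydraulic_diameter == net.scenario.stent.inner_diameter
        )
        intra_end_out = sum(
            q for e, q in zip(net.edges, sol.edge_flows)
            if e.kind == "end_opening" and e.node_b == BLADDER
            and e.hydraulic_diameter == net.scenario.stent.inner_diameter
        )
        assert intra_end_in + hole_in + wall_in == pytest.approx(
            intra_end_out, rel=1e-9)


class TestSideHoles:
    def test_no_hole_case_has_no_hole_flows(self, case_solutions):
        _, sol = case_solutions[7]
        assert side_hole_flows(sol) == []

    def test_full_hole_set_reported(self, case_solutions):
        _, sol = case_solutions[1]
        assert [idx for idx, _ in side_hole_flows(sol)] == list(range(1, 43))

    def test_proximal_holes_drain_into_lumen(self, case_solutions):
        _, sol = case_solutions[1]
        flows = dict(side_hole_flows(sol))
        # kidney-coil and first shaft holes feed the lumen (positive)
        assert all(flows[i] > 0 for i in (1, 2, 3, 4, 5))

    def test_occluded_max_at_hole_21(self, case_solutions):
        for cid in (8, 9):
            _, sol = case_solutions[cid]
            flows = dict(side_hole_flows(sol))
            assert max(flows, key=lambda i: abs(flows[i])) == 21

    def test_classify_threshold(self):
        holes = [(1, 1e-5), (2, 1e-7), (3, -2e-6)]
        active = classify_active_holes(holes, total_flow=1e-4,
                                       threshold_fraction=0.01)
        assert active == {1, 3}

    def test_classify_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            classify_active_holes([(1, 1e-5)], total_flow=0.0)
        with pytest.raises(ValueError):
            classify_active_holes([(1, 1e-5)], total_flow=1e-4,
                                  threshold_fraction=0.0)


class TestReynolds:
    @pytest.mark.parametrize("cid", range(1, 10))
    def test_all_edges_laminar(self, case_solutions, cid):
        _, sol = case_solutions[cid]
        reports = reynolds_reports(sol)
        assert reports
        assert all(r.laminar for r in reports)

    def test_requires_scenario(self):
        net = two_pipe_network()
        sol = solve_network(net)
        with pytest.raises(NetworkError, match="scenario"):
            reynolds_reports(sol)
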