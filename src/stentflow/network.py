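"""Hydraulic network assembly and solution for the stented ureter.

The ureter is discretised at the axial stations of the shaft side holes
(the reporting surfaces sit between each pair of side holes).  Each station
carries an intraluminal and an extraluminal node; each segment between
stations is split at its midpoint so that the radial Darcy conductance of
the porous stent wall can be lumped between the intra- and extra-luminal
midpoint nodes.  Side holes connect the two chains at the stations; the
kidney pelvis and bladder are fixed-pressure reservoirs attached to both
chains at each end (the stent end openings and the coil side holes are
lumped into the intraluminal end attachments).

Sign conventions: axial flows are positive from kidney to bladder;
side-hole and wall flows are positive from the extraluminal into the
intraluminal compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from .geometry import GeometryError, Scenario, side_hole_positions
from .hydraulics import (
    ReynoldsReport,
    annulus_conductance,
    pipe_conductance,
    reynolds_number,
    side_hole_conductance,
    tapered_annulus_conductance,
    wall_radial_conductance,
)

#: relative Kirchhoff residual accepted from the direct solve
RESIDUAL_RTOL = 1e-12

PELVIS = 0
BLADDER = 1


class NetworkError(RuntimeError):
    """Raised for singular or disconnected hydraulic systems."""


@dataclass(frozen=True)
class Edge:
    node_a: int
    node_b: int
    conductance: float  # kg s^-1 Pa^-1; positive flow runs a -> b
    kind: str
    axial_index: int  # segment index for chain/wall edges, station for holes
    hydraulic_diameter: float
    flow_area: float
    hole_index: int | None = None  # shaft hole number, for side_hole edges
    # parallel composition of an intraluminal end attachment:
    g_opening: float = 0.0
    g_coil_hole: float = 0.0
    n_coil_holes: int = 0
    coil_hole_indices: tuple[int, ...] = ()
    #: chain half-edge upstream of the segment midpoint (reporting surface)
    first_half: bool = False


@dataclass
class HydraulicNetwork:
    n_nodes: int
    edges: list[Edge]
    reservoir_pressures: dict[int, float]
    node_labels: list[str]
    station_positions: np.ndarray  # interior stations, one per shaft hole
    segment_bounds: np.ndarray  # (n_segments, 2) axial intervals
    segment_holes: list[tuple[int | None, int | None]]  # (upstream, downstream) hole no.
    scenario: Scenario | None = None


@dataclass(frozen=True)
class SegmentFlows:
    """Compartment decomposition at one reporting surface.

    ``m_total = m_intra + m_extra + m_wall`` by construction.  ``m_wall``
    is the *axial* mass flow inside the porous wall, identically zero here
    because wall transport is modelled as purely radial; the radial
    exchange lumped in the segment is reported as ``wall_exchange``
    (positive into the lumen).
    """

    segment_index: int
    upstream_hole: int | None
    downstream_hole: int | None
    m_total: float
    m_intra: float
    m_extra: float
    m_wall: float
    wall_exchange: float


@dataclass
class FlowSolution:
    network: HydraulicNetwork
    node_pressures: np.ndarray  # Pa; NaN for nodes outside the wetted domain
    edge_flows: np.ndarray  # kg s^-1, signed per the edge orientation
    per_segment: list[SegmentFlows]
    per_hole: list[tuple[int, float]]  # (hole index, mass flow into lumen)
    pelvis_outflow: float
    bladder_inflow: float

    @property
    def total_flow(self) -> float:
        return self.pelvis_outflow


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    """True when (a0, a1) and (b0, b1) share an interval of positive length."""
    return min(a1, b1) - max(a0, b0) > 1e-15


def assemble_network(scenario: Scenario) -> HydraulicNetwork:
    """Build the lumped hydraulic network for one scenario.

    The axial discretisation always uses the reference 34-station layout
    (one station per shaft hole of the 42-hole stent) so that reporting
    surfaces are comparable across stents with and without side holes; hole
    edges are only created where side holes are present and enabled.
    """
    stent = scenario.stent
    fluid = scenario.fluid
    eff = scenario.effective_profile()
    L = scenario.profile.total_length

    n_stations = stent.n_shaft_holes if stent.n_shaft_holes > 0 else 34
    npc = stent.holes_per_coil
    stations = L * np.arange(1, n_stations + 1) / (n_stations + 1)
    bounds = np.column_stack((
        np.concatenate(([0.0], stations)),
        np.concatenate((stations, [L])),
    ))
    n_seg = n_stations + 1

    # node numbering: reservoirs, intra/extra station nodes, midpoints
    def node_i(j: int) -> int:  # intra node at station j (0..n_stations+1)
        return 2 + j

    def node_e(j: int) -> int:
        return 2 + (n_stations + 2) + j

    def node_im(k: int) -> int:  # intra midpoint of segment k (1-based)
        return 2 + 2 * (n_stations + 2) + (k - 1)

    def node_em(k: int) -> int:
        return 2 + 2 * (n_stations + 2) + n_seg + (k - 1)

    n_nodes = 2 + 2 * (n_stations + 2) + 2 * n_seg
    labels = ["pelvis", "bladder"]
    labels += [f"intra[{j}]" for j in range(n_stations + 2)]
    labels += [f"extra[{j}]" for j in range(n_stations + 2)]
    labels += [f"intra_mid[{k}]" for k in range(1, n_seg + 1)]
    labels += [f"extra_mid[{k}]" for k in range(1, n_seg + 1)]

    occ = scenario.occlusion
    occ_iv = (occ.start_position, occ.end_position) if occ.present else None

    d_in = stent.inner_diameter
    d_out = stent.outer_diameter
    area_in = math.pi * (0.5 * d_in) ** 2

    def annulus_area(x: float) -> float:
        dl = float(eff.diameter(x))
        return math.pi * ((0.5 * dl) ** 2 - (0.5 * d_out) ** 2)

    holes_enabled = scenario.side_holes_enabled and stent.n_shaft_holes > 0
    g_hole = (side_hole_conductance(stent.side_hole_diameter, stent.wall_thickness,
                                    fluid, model=scenario.hole_model).value
              if stent.n_side_holes > 0 else 0.0)

    edges: list[Edge] = []

    # --- end attachments ----------------------------------------------
    h_end = float(bounds[0, 1] - bounds[0, 0])
    g_open = pipe_conductance(d_in, h_end, fluid).value
    for reservoir, j, coil_first in ((PELVIS, 0, 1), (BLADDER, n_stations + 1, None)):
        n_coil = npc if holes_enabled else 0
        if reservoir == PELVIS:
            coil_idx = tuple(range(1, npc + 1)) if n_coil else ()
            a, b = PELVIS, node_i(0)
        else:
            first = npc + stent.n_shaft_holes + 1
            coil_idx = tuple(range(first, first + npc)) if n_coil else ()
            a, b = node_i(n_stations + 1), BLADDER
        edges.append(Edge(a, b, g_open + n_coil * g_hole, "end_opening",
                          0 if reservoir == PELVIS else n_seg + 1,
                          d_in, area_in,
                          g_opening=g_open, g_coil_hole=g_hole,
                          n_coil_holes=n_coil, coil_hole_indices=coil_idx))
    # extraluminal attachments: short annulus stubs at the local geometry
    x0d = float(eff.diameter(0.0))
    xLd = float(eff.diameter(L))
    dh0 = x0d - d_out
    dhL = xLd - d_out
    edges.append(Edge(PELVIS, node_e(0),
                      annulus_conductance(x0d, d_out, h_end, fluid).value,
                      "end_opening", 0, dh0, annulus_area(0.0)))
    edges.append(Edge(node_e(n_stations + 1), BLADDER,
                      annulus_conductance(xLd, d_out, h_end, fluid).value,
                      "end_opening", n_seg + 1, dhL, annulus_area(L)))

    # --- chain, wall and hole edges -------------------------------------
    hole_numbers = [npc + j for j in range(1, n_stations + 1)]  # station -> hole no.
    for k in range(1, n_seg + 1):
        x0, x1 = bounds[k - 1]
        xm = 0.5 * (x0 + x1)
        h = x1 - x0
        ia, ib = node_i(k - 1), node_i(k)
        ea, eb = node_e(k - 1), node_e(k)
        im, em = node_im(k), node_em(k)

        g_half_pipe = pipe_conductance(d_in, 0.5 * h, fluid).value
        edges.append(Edge(ia, im, g_half_pipe, "intra_pipe", k, d_in, area_in,
                          first_half=True))
        edges.append(Edge(im, ib, g_half_pipe, "intra_pipe", k, d_in, area_in))

        for (xa, xb, na, nb, first) in ((x0, xm, ea, em, True),
                                        (xm, x1, em, eb, False)):
            if occ_iv and _overlaps(xa, xb, *occ_iv):
                continue  # complete occlusion: annulus removed here
            try:
                g_ann = tapered_annulus_conductance(eff, xa, xb, d_out, fluid).value
            except Exception as exc:
                raise GeometryError(
                    f"extraluminal annulus invalid on segment {k} "
                    f"[{xa:.4g}, {xb:.4g}] m: {exc}"
                ) from exc
            xc = 0.5 * (xa + xb)
            dh = float(eff.diameter(xc)) - d_out
            edges.append(Edge(na, nb, g_ann, "extra_annulus", k, dh,
                              annulus_area(xc), first_half=first))

        if not (occ_iv and _overlaps(x0, x1, *occ_iv)):
            g_wall = wall_radial_conductance(stent.permeability, 0.5 * d_in,
                                             0.5 * d_out, h, fluid).value
            wall_area = 2.0 * math.pi * 0.25 * (d_in + d_out) * h
            edges.append(Edge(em, im, g_wall, "wall_darcy", k,
                              stent.wall_thickness, wall_area))

        if holes_enabled and k <= n_stations:
            area_hole = math.pi * (0.5 * stent.side_hole_diameter) ** 2
            edges.append(Edge(node_e(k), node_i(k), g_hole, "side_hole", k,
                              stent.side_hole_diameter, area_hole,
                              hole_index=hole_numbers[k - 1]))

    return HydraulicNetwork(
        n_nodes=n_nodes,
        edges=edges,
        reservoir_pressures={PELVIS: scenario.inlet_pressure,
                             BLADDER: scenario.outlet_pressure},
        node_labels=labels,
        station_positions=stations,
        segment_bounds=bounds,
        segment_holes=[(hole_numbers[k - 2] if k > 1 else None,
                        hole_numbers[k - 1] if k <= n_stations else None)
                       for k in range(1, n_seg + 1)],
        scenario=scenario,
    )


def _wetted_nodes(network: HydraulicNetwork) -> np.ndarray:
    """Boolean mask of nodes hydraulically connected to a reservoir."""
    rows, cols = [], []
    for e in network.edges:
        if e.conductance > 0.0:
            rows.append(e.node_a)
            cols.append(e.node_b)
    graph = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(network.n_nodes, network.n_nodes))
    n_comp, comp = connected_components(graph, directed=False)
    if comp[PELVIS] != comp[BLADDER]:
        members = [network.node_labels[i] for i in np.flatnonzero(comp == comp[PELVIS])]
        raise NetworkError(
            "network does not connect pelvis to bladder; the pelvis-side "
            f"component contains only: {members}"
        )
    reservoir_comps = {comp[PELVIS], comp[BLADDER]}
    return np.isin(comp, list(reservoir_comps))


def _extract_solution(network: HydraulicNetwork,
                      pressures: np.ndarray) -> FlowSolution:
    flows = np.empty(len(network.edges))
    for i, e in enumerate(network.edges):
        pa, pb = pressures[e.node_a], pressures[e.node_b]
        flows[i] = 0.0 if (np.isnan(pa) or np.isnan(pb)) else e.conductance * (pa - pb)

    n_seg = network.segment_bounds.shape[0]
    intra_first = np.zeros(n_seg)
    extra_first = np.zeros(n_seg)
    wall_exchange = np.zeros(n_seg)
    hole_flows: dict[int, float] = {}
    pelvis_out = 0.0
    bladder_in = 0.0
    for e, q in zip(network.edges, flows):
        if e.kind in ("intra_pipe", "extra_annulus"):
            if e.first_half:
                k = e.axial_index - 1
                if e.kind == "intra_pipe":
                    intra_first[k] = q
                else:
                    extra_first[k] = q
        elif e.kind == "wall_darcy":
            wall_exchange[e.axial_index - 1] += q
        elif e.kind == "side_hole":
            hole_flows[e.hole_index] = q
        if e.node_a == PELVIS:
            pelvis_out += q
        if e.node_b == PELVIS:
            pelvis_out -= q
        if e.node_b == BLADDER:
            bladder_in += q
        if e.node_a == BLADDER:
            bladder_in -= q
        # coil side holes share the end attachment with the open stent end
        if e.kind == "end_opening" and e.n_coil_holes:
            g_tot = e.g_opening + e.n_coil_holes * e.g_coil_hole
            share = q * e.g_coil_hole / g_tot
            into_lumen = share if e.node_a == PELVIS else -share
            for idx in e.coil_hole_indices:
                hole_flows[idx] = into_lumen

    per_segment = [
        SegmentFlows(
            segment_index=k + 1,
            upstream_hole=network.segment_holes[k][0],
            downstream_hole=network.segment_holes[k][1],
            m_total=intra_first[k] + extra_first[k],
            m_intra=intra_first[k],
            m_extra=extra_first[k],
            m_wall=0.0,
            wall_exchange=wall_exchange[k],
        )
        for k in range(n_seg)
    ]
    per_hole = sorted(hole_flows.items())
    return FlowSolution(
        network=network,
        node_pressures=pressures,
        edge_flows=flows,
        per_segment=per_segment,
        per_hole=per_hole,
        pelvis_outflow=pelvis_out,
        bladder_inflow=bladder_in,
    )


def _boundary_pressures(network: HydraulicNetwork) -> np.ndarray:
    p = np.full(network.n_nodes, np.nan)
    for node, value in network.reservoir_pressures.items():
        p[node] = value
    return p


def solve_network(network: HydraulicNetwork) -> FlowSolution:
    """Direct sparse solve of the nodal conductance system G p = b."""
    if not network.edges:
        raise NetworkError("cannot solve an empty network")
    wetted = _wetted_nodes(network)
    reservoirs = set(network.reservoir_pressures)
    free = [n for n in range(network.n_nodes) if wetted[n] and n not in reservoirs]
    index = {n: i for i, n in enumerate(free)}

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(len(free))
    for e in network.edges:
        if e.conductance <= 0.0:
            continue
        ia = index.get(e.node_a)
        ib = index.get(e.node_b)
        for i_self, self_node, other_node in ((ia, e.node_a, e.node_b),
                                              (ib, e.node_b, e.node_a)):
            if i_self is None:
                continue
            rows.append(i_self)
            cols.append(i_self)
            vals.append(e.conductance)
            i_other = index.get(other_node)
            if i_other is not None:
                rows.append(i_self)
                cols.append(i_other)
                vals.append(-e.conductance)
            else:
                b[i_self] += e.conductance * network.reservoir_pressures[other_node]

    mat = sp.coo_matrix((vals, (rows, cols)), shape=(len(free), len(free))).tocsc()
    p_free = spsolve(mat, b)
    if not np.all(np.isfinite(p_free)):
        raise NetworkError("singular nodal system (non-finite pressures)")

    pressures = _boundary_pressures(network)
    pressures[free] = p_free
    solution = _extract_solution(network, pressures)
    resid = node_residuals(network, solution)
    if resid > 10.0 * RESIDUAL_RTOL:
        raise NetworkError(f"Kirchhoff residual {resid:.3e} exceeds tolerance")
    return solution


def brute_force_solve(network: HydraulicNetwork) -> FlowSolution:
    """Independent dense solve of the same nodal system.

    Assembles the full dense conductance matrix in a separate code path and
    solves it with a dense LAPACK factorisation; serves as the oracle for
    :func:`solve_network` on small networks.
    """
    if not network.edges:
        raise NetworkError("cannot solve an empty network")
    if network.n_nodes > 502:
        raise NetworkError("brute-force oracle is limited to <= 500 free nodes")
    wetted = _wetted_nodes(network)
    reservoirs = set(network.reservoir_pressures)
    free = [n for n in range(network.n_nodes) if wetted[n] and n not in reservoirs]
    index = {n: i for i, n in enumerate(free)}
    n = len(free)
    mat = np.zeros((n, n))
    b = np.zeros(n)
    for e in network.edges:
        g = e.conductance
        if g <= 0.0:
            continue
        a_i = index.get(e.node_a)
        b_i = index.get(e.node_b)
        if a_i is not None:
            mat[a_i, a_i] += g
        if b_i is not None:
            mat[b_i, b_i] += g
        if a_i is not None and b_i is not None:
            mat[a_i, b_i] -= g
            mat[b_i, a_i] -= g
        if a_i is not None and b_i is None:
            b[a_i] += g * network.reservoir_pressures[e.node_b]
        if b_i is not None and a_i is None:
            b[b_i] += g * network.reservoir_pressures[e.node_a]
    import scipy.linalg

    p_free = scipy.linalg.solve(mat, b, assume_a="sym")
    pressures = _boundary_pressures(network)
    pressures[free] = p_free
    return _extract_solution(network, pressures)


def node_residuals(network: HydraulicNetwork, solution: FlowSolution) -> float:
    """Maximum Kirchhoff residual over free nodes, relative to the total flow."""
    if not network.edges:
        raise NetworkError("empty network has no residuals")
    net = np.zeros(network.n_nodes)
    for e, q in zip(network.edges, solution.edge_flows):
        net[e.node_a] -= q
        net[e.node_b] += q
    reservoirs = set(network.reservoir_pressures)
    free = [n for n in range(network.n_nodes)
            if n not in reservoirs and np.isfinite(solution.node_pressures[n])]
    scale = max(abs(solution.total_flow), 1e-300)
    return float(np.max(np.abs(net[free])) / scale) if free else 0.0


def segment_decomposition(solution: FlowSolution, segment_index: int) -> SegmentFlows:
    """Compartment flows at one reporting surface (1-based segment index)."""
    n = len(solution.per_segment)
    if not 1 <= segment_index <= n:
        raise IndexError(f"segment_index must be in 1..{n}, got {segment_index}")
    return solution.per_segment[segment_index - 1]


def side_hole_flows(solution: FlowSolution) -> list[tuple[int, float]]:
    """Signed mass flow through each side hole (positive into the lumen)."""
    return list(solution.per_hole)


def classify_active_holes(hole_flows: list[tuple[int, float]], total_flow: float,
                          threshold_fraction: float = 0.01) -> set[int]:
    """Side holes carrying at least ``threshold_fraction`` of the total flow."""
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    if total_flow == 0.0:
        raise ValueError("cannot classify active holes at zero total flow")
    cut = threshold_fraction * abs(total_flow)
    return {idx for idx, q in hole_flows if abs(q) >= cut}


def reynolds_reports(solution: FlowSolution) -> list[ReynoldsReport]:
    """Reynolds number of every edge of a solved network."""
    fluid = solution.network.scenario.fluid if solution.network.scenario else None
    if fluid is None:
        raise NetworkError("Reynolds reports need the originating scenario")
    reports = []
    for i, (e, q) in enumerate(zip(solution.network.edges, solution.edge_flows)):
        if e.flow_area <= 0.0:
            continue
        reports.append(reynolds_number(q, e.hydraulic_diameter, e.flow_area,
                                       fluid, edge_id=i))
    return reports
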