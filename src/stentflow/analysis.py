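"""Scenario-level experiments: permeability sweeps, flow profiles,
velocity summaries, scenario comparisons and permeability inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import Scenario
from .hydraulics import LAMINAR_RE_THRESHOLD, annulus_peak_to_mean_ratio
from .network import FlowSolution, assemble_network, reynolds_reports, solve_network

#: permeability values swept in the study (descending), plus the unporous reference
STUDY_PERMEABILITIES = (1e-10, 1e-11, 1e-12, 1e-14, 1e-18)


def solve_scenario(scenario: Scenario) -> FlowSolution:
    """Assemble and solve one scenario."""
    return solve_network(assemble_network(scenario))


def average_total_flow(solution: FlowSolution) -> float:
    """Mean of the total mass flow over all reporting surfaces (kg/s).

    The total is constant across surfaces up to the solver residual; the
    mean mirrors reporting it as an average over multiple determinations
    along the model.
    """
    return float(np.mean([s.m_total for s in solution.per_segment]))


def with_permeability(scenario: Scenario, permeability: float) -> Scenario:
    """Copy of a scenario with a different stent wall permeability."""
    return replace(scenario, stent=replace(scenario.stent, permeability=permeability),
                   case_id=None)


def permeability_sweep(base_scenario: Scenario,
                       permeabilities=STUDY_PERMEABILITIES) -> pd.DataFrame:
    """Average total flow versus stent wall permeability.

    One solve per permeability on the base geometry; an unporous (alpha=0)
    reference row is always included.  Rows are sorted by descending
    permeability and carry the relative change versus the unporous stent
    and a flag confirming that every edge stayed laminar.
    """
    values = sorted(set(float(a) for a in permeabilities) | {0.0}, reverse=True)
    if any(a < 0.0 for a in values):
        raise ValueError("permeabilities must be >= 0")
    rows = []
    for alpha in values:
        sol = solve_scenario(with_permeability(base_scenario, alpha))
        q = average_total_flow(sol)
        laminar = all(r.laminar for r in reynolds_reports(sol))
        rows.append({"permeability_m2": alpha, "avg_total_kg_s": q,
                     "all_laminar": laminar})
    table = pd.DataFrame(rows)
    q0 = float(table.loc[table["permeability_m2"] == 0.0, "avg_total_kg_s"].iloc[0])
    table["delta_vs_unporous_pct"] = (table["avg_total_kg_s"] - q0) / q0 * 100.0
    return table[["permeability_m2", "avg_total_kg_s", "delta_vs_unporous_pct",
                  "all_laminar"]]


def flow_profile(solution: FlowSolution) -> pd.DataFrame:
    """Per-surface compartment decomposition, ordered kidney to bladder.

    One row per reporting surface (between each pair of adjacent side-hole
    stations), keyed by the bounding side-hole numbers; suitable for
    plotting flow-distribution profiles along the ureter.
    """
    rows = []
    for s, (x0, x1) in zip(solution.per_segment, solution.network.segment_bounds):
        rows.append({
            "segment_index": s.segment_index,
            "upstream_hole": s.upstream_hole,
            "downstream_hole": s.downstream_hole,
            "surface_position_m": 0.5 * (x0 + x1),
            "m_total": s.m_total,
            "m_intra": s.m_intra,
            "m_extra": s.m_extra,
            "m_wall": s.m_wall,
            "wall_exchange": s.wall_exchange,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VelocitySummary:
    mean_intraluminal: float  # m/s
    peak_intraluminal: float
    mean_extraluminal: float
    peak_extraluminal: float


def velocity_summary(solution: FlowSolution, segment_index: int) -> VelocitySummary:
    """Mean and peak velocities at one reporting surface.

    Means follow from m_dot = rho * u * A; peaks use the analytic laminar
    profiles (parabola: peak = 2 x mean for the pipe; closed-form annular
    profile for the extraluminal compartment).  A closed annulus reports
    zero extraluminal velocity.
    """
    seg = solution.per_segment[segment_index - 1]
    scn = solution.network.scenario
    rho = scn.fluid.density
    d_in = scn.stent.inner_diameter
    d_out = scn.stent.outer_diameter
    x = 0.5 * sum(solution.network.segment_bounds[segment_index - 1])
    d_lumen = float(scn.effective_profile().diameter(x))
    a_in = math.pi * (0.5 * d_in) ** 2
    u_in = seg.m_intra / (rho * a_in)
    if d_lumen > d_out and seg.m_extra != 0.0:
        a_ex = math.pi * ((0.5 * d_lumen) ** 2 - (0.5 * d_out) ** 2)
        u_ex = seg.m_extra / (rho * a_ex)
        peak_ex = u_ex * annulus_peak_to_mean_ratio(d_lumen, d_out)
    else:
        u_ex = peak_ex = 0.0
    return VelocitySummary(mean_intraluminal=u_in, peak_intraluminal=2.0 * u_in,
                           mean_extraluminal=u_ex, peak_extraluminal=peak_ex)


@dataclass(frozen=True)
class ComparisonReport:
    scenario_a: int | None
    scenario_b: int | None
    m_total_a: float
    m_total_b: float

    @property
    def absolute_difference(self) -> float:
        return self.m_total_a - self.m_total_b

    @property
    def relative_difference_pct(self) -> float:
        return (self.m_total_a - self.m_total_b) / self.m_total_b * 100.0


def compare_scenarios(a: Scenario, b: Scenario) -> ComparisonReport:
    """Average-total-flow comparison of two scenarios ((a - b) / b)."""
    qa = average_total_flow(solve_scenario(a))
    qb = average_total_flow(solve_scenario(b))
    if qb == 0.0:
        raise ValueError("reference scenario b has zero total flow")
    return ComparisonReport(scenario_a=a.case_id, scenario_b=b.case_id,
                            m_total_a=qa, m_total_b=qb)


@dataclass(frozen=True)
class InversionResult:
    permeability: float  # m^2
    achieved_flow: float  # kg/s at the recovered permeability
    at_bracket_floor: bool  # observed flow already reached by the floor


def invert_permeability(base_scenario: Scenario, observed_total: float,
                        bracket: tuple[float, float] = (1e-18, 1e-10),
                        rtol_flow: float = 1e-6) -> InversionResult:
    """Recover the wall permeability that reproduces an observed total flow.

    The permeability -> flow map is strictly increasing, so a bracketing
    root find on log10(alpha) suffices.  An observed flow below what the
    bracket floor produces (e.g. the unporous value) returns the floor,
    flagged; an observed flow above the bracket ceiling's is an error
    stating the achievable interval.
    """
    lo, hi = bracket
    if not 0.0 < lo < hi:
        raise ValueError(f"invalid bracket {bracket}")

    def q_of(alpha: float) -> float:
        return average_total_flow(solve_scenario(with_permeability(base_scenario, alpha)))

    q_lo, q_hi = q_of(lo), q_of(hi)
    if observed_total > q_hi:
        raise ValueError(
            f"observed flow {observed_total:.6e} kg/s exceeds the achievable "
            f"interval [{q_lo:.6e}, {q_hi:.6e}] kg/s for bracket {bracket}"
        )
    if observed_total <= q_lo:
        return InversionResult(permeability=lo, achieved_flow=q_lo,
                               at_bracket_floor=True)

    def f(log_alpha: float) -> float:
        return q_of(10.0 ** log_alpha) - observed_total

    log_hat = brentq(f, math.log10(lo), math.log10(hi),
                     xtol=1e-12, rtol=8.9e-16, maxiter=200)
    alpha_hat = 10.0 ** log_hat
    q_hat = q_of(alpha_hat)
    if abs(q_hat - observed_total) > rtol_flow * abs(observed_total):
        raise RuntimeError(
            f"inversion did not converge: |Q(alpha_hat) - observed| = "
            f"{abs(q_hat - observed_total):.3e} kg/s"
        )
    return InversionResult(permeability=alpha_hat, achieved_flow=q_hat,
                           at_bracket_floor=False)


def max_reynolds(solution: FlowSolution) -> float:
    """Largest edge Reynolds number of a solved scenario."""
    return float(max(r.reynolds for r in reynolds_reports(solution)))


def all_laminar(solution: FlowSolution) -> bool:
    return bool(max_reynolds(solution) < LAMINAR_RE_THRESHOLD)
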