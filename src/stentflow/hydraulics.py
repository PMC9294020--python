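"""Laminar mass-flow conductance closures.

Every flow element in the network is linear: mass flow = G * (pressure
drop), with G a hydraulic conductance in kg s^-1 Pa^-1.  The closures are
the fully developed laminar solutions (Hagen-Poiseuille pipe, concentric
annulus, Sampson orifice with a short-tube correction) plus the Darcy
radial conductance of a cylindrical porous shell.  Inertial losses are
dropped everywhere, consistent with the creeping-to-laminar regime of
urinary drainage (Re well below 2300 throughout), which keeps the whole
network linear in the driving pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import AxialProfile, FluidProps

LAMINAR_RE_THRESHOLD = 2300.0

EDGE_KINDS = ("intra_pipe", "extra_annulus", "side_hole", "wall_darcy", "end_opening")


class ClosureError(ValueError):
    """Raised for physically inadmissible closure inputs."""


@dataclass(frozen=True)
class EdgeConductance:
    """Linear conductance of one flow element."""

    value: float  # kg s^-1 Pa^-1
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ClosureError(f"unknown edge kind {self.kind!r}")
        if not (self.value >= 0.0 and math.isfinite(self.value)):
            raise ClosureError(f"conductance must be finite and >= 0, got {self.value}")


@dataclass(frozen=True)
class ReynoldsReport:
    edge_id: int
    reynolds: float

    @property
    def laminar(self) -> bool:
        return self.reynolds < LAMINAR_RE_THRESHOLD


def pipe_conductance(diameter: float, length: float, fluid: FluidProps,
                     kind: str = "intra_pipe") -> EdgeConductance:
    """Hagen-Poiseuille conductance of a circular pipe.

    G = rho * pi * d^4 / (128 * mu * L).
    """
    if diameter <= 0.0 or length <= 0.0:
        raise ClosureError(f"pipe needs diameter > 0 and length > 0, got d={diameter}, L={length}")
    g = fluid.density * math.pi * diameter**4 / (128.0 * fluid.viscosity * length)
    return EdgeConductance(value=g, kind=kind)


def _annulus_bracket(ro: float, ri: float) -> float:
    """Geometric factor Ro^4 - Ri^4 - (Ro^2 - Ri^2)^2 / ln(Ro/Ri)."""
    return ro**4 - ri**4 - (ro**2 - ri**2) ** 2 / math.log(ro / ri)


def annulus_conductance(outer_diameter: float, inner_diameter: float,
                        length: float, fluid: FluidProps) -> EdgeConductance:
    """Laminar conductance of a concentric annulus.

    G = rho * pi / (8 mu L) * [Ro^4 - Ri^4 - (Ro^2 - Ri^2)^2 / ln(Ro/Ri)].
    """
    if not 0.0 < inner_diameter < outer_diameter:
        raise ClosureError(
            f"annulus needs 0 < inner ({inner_diameter}) < outer ({outer_diameter})"
        )
    if length <= 0.0:
        raise ClosureError(f"annulus length must be > 0, got {length}")
    ro, ri = 0.5 * outer_diameter, 0.5 * inner_diameter
    bracket = max(_annulus_bracket(ro, ri), 0.0)  # guards rounding at Ri ~ Ro
    g = fluid.density * math.pi * bracket / (8.0 * fluid.viscosity * length)
    return EdgeConductance(value=g, kind="extra_annulus")


def tapered_annulus_conductance(profile: AxialProfile, x0: float, x1: float,
                                inner_diameter: float, fluid: FluidProps,
                                n_sub: int = 8) -> EdgeConductance:
    """Annulus conductance over [x0, x1] of a tapered lumen.

    Series (harmonic) composition of ``n_sub`` sub-segments, each evaluated
    at its midpoint lumen diameter.  Raises if the annulus closes anywhere
    on the interval, naming the axial position.
    """
    if x1 <= x0:
        raise ClosureError(f"need x1 > x0, got [{x0}, {x1}]")
    edges = np.linspace(x0, x1, n_sub + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    resistance = 0.0
    for xm, h in zip(mids, np.diff(edges)):
        d_out = float(profile.diameter(xm))
        if d_out <= inner_diameter:
            raise ClosureError(
                f"annulus closed at axial position {xm:.4g} m "
                f"(lumen {d_out:.4g} m <= stent OD {inner_diameter:.4g} m)"
            )
        resistance += 1.0 / annulus_conductance(d_out, inner_diameter, float(h), fluid).value
    return EdgeConductance(value=1.0 / resistance, kind="extra_annulus")


def side_hole_conductance(hole_diameter: float, wall_thickness: float,
                          fluid: FluidProps, model: str = "sampson_tube") -> EdgeConductance:
    """Conductance of one circular side hole through the stent wall.

    The volumetric resistance is a short Poiseuille tube in series with the
    Sampson (creeping-flow orifice) entrance/exit resistance:

        R_vol = 128 mu t / (pi d^4) + 3 mu / (d/2)^3,   G = rho / R_vol.

    ``model="tube_only"`` drops the Sampson term (sensitivity check); a zero
    wall thickness reduces to the pure Sampson orifice.
    """
    if hole_diameter <= 0.0:
        raise ClosureError(f"hole diameter must be > 0, got {hole_diameter}")
    if wall_thickness < 0.0:
        raise ClosureError(f"wall thickness must be >= 0, got {wall_thickness}")
    mu = fluid.viscosity
    r_tube = 128.0 * mu * wall_thickness / (math.pi * hole_diameter**4)
    if model == "sampson_tube":
        r_vol = r_tube + 3.0 * mu / (0.5 * hole_diameter) ** 3
    elif model == "tube_only":
        if wall_thickness == 0.0:
            raise ClosureError("tube_only model needs a positive wall thickness")
        r_vol = r_tube
    else:
        raise ClosureError(f"unknown side-hole model {model!r}")
    return EdgeConductance(value=fluid.density / r_vol, kind="side_hole")


def wall_radial_conductance(permeability: float, inner_radius: float,
                            outer_radius: float, segment_length: float,
                            fluid: FluidProps) -> EdgeConductance:
    """Darcy conductance of a cylindrical porous shell, radial flow.

    Integrating Darcy's law dP/dr = -(mu/alpha) * q/(2 pi r dz) across the
    shell gives  G = rho * 2 pi * alpha * dz / (mu * ln(ro/ri)).  A zero
    permeability encodes the unporous wall (zero conductance).
    """
    if not 0.0 < inner_radius < outer_radius:
        raise ClosureError(
            f"need 0 < inner_radius ({inner_radius}) < outer_radius ({outer_radius})"
        )
    if segment_length <= 0.0:
        raise ClosureError(f"segment length must be > 0, got {segment_length}")
    if permeability < 0.0:
        raise ClosureError(f"permeability must be >= 0, got {permeability}")
    g = (fluid.density * 2.0 * math.pi * permeability * segment_length
         / (fluid.viscosity * math.log(outer_radius / inner_radius)))
    return EdgeConductance(value=g, kind="wall_darcy")


def flat_slab_wall_conductance(permeability: float, inner_radius: float,
                               outer_radius: float, segment_length: float,
                               fluid: FluidProps) -> float:
    """Thin-wall (flat-slab) Darcy approximation rho*alpha*A/(mu*t).

    Cross-check for the cylindrical formula; A is taken at the mid radius.
    """
    t = outer_radius - inner_radius
    area = 2.0 * math.pi * 0.5 * (inner_radius + outer_radius) * segment_length
    return fluid.density * permeability * area / (fluid.viscosity * t)


def reynolds_number(mass_flow: float, hydraulic_diameter: float,
                    flow_area: float, fluid: FluidProps,
                    edge_id: int = -1) -> ReynoldsReport:
    """Reynolds number of an edge from its mass flow.

    Re = rho * u * D_h / mu with u = m_dot / (rho * A).
    """
    if flow_area <= 0.0:
        raise ClosureError(f"flow area must be > 0, got {flow_area}")
    u = abs(mass_flow) / (fluid.density * flow_area)
    re = fluid.density * u * hydraulic_diameter / fluid.viscosity
    return ReynoldsReport(edge_id=edge_id, reynolds=re)


def annulus_peak_to_mean_ratio(outer_diameter: float, inner_diameter: float) -> float:
    """Peak/mean velocity ratio of the laminar concentric-annulus profile.

    The profile u(r) ~ Ro^2 - r^2 + (Ro^2 - Ri^2) ln(r/Ro)/ln(Ro/Ri) peaks
    at r_m^2 = (Ro^2 - Ri^2) / (2 ln(Ro/Ri)); the ratio tends to 2 (pipe)
    as Ri -> 0 and to 1.5 (plane channel) as Ri -> Ro.
    """
    if not 0.0 < inner_diameter < outer_diameter:
        raise ClosureError("need 0 < inner < outer diameter")
    ro, ri = 0.5 * outer_diameter, 0.5 * inner_diameter
    ln = math.log(ro / ri)
    a = ro**2 - ri**2
    rm2 = a / (2.0 * ln)
    peak = ro**2 - rm2 + a * math.log(math.sqrt(rm2) / ro) / ln
    mean = 0.5 * (ro**2 + ri**2 - a / ln)
    return peak / mean
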