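"""Geometry of the stented urinary tract and the study's case matrix.

The model domain runs from the ureteropelvic junction (UPJ, axial position
0) to the vesicoureteric junction (VUJ, axial position ``total_length``).
A double-J stent spans the whole ureter; its anchoring coils sit inside the
kidney-pelvis and bladder reservoirs and are therefore not resolved
geometrically (coil side holes are lumped into the end attachments by the
network builder).

Axial positions and diameters are SI (metres) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

MM = 1e-3  # metres per millimetre

#: kidney-pelvis / bladder gauge pressures (Pa) used in every case study
INLET_PRESSURE_PA = 97.8
OUTLET_PRESSURE_PA = 0.0

#: working fluid: urine approximated by water at body-ish conditions
URINE_DENSITY = 997.044  # kg m^-3
URINE_VISCOSITY = 1.0e-3  # Pa s

DEFAULT_URETER_LENGTH = 240.0 * MM

#: minimum radial gap between stent outer wall and ureter lumen after
#: stent insertion (see :func:`stented_lumen_diameter`)
DEFAULT_MIN_CLEARANCE = 0.35 * MM
#: fraction of the ex vivo diameter increments preserved where the lumen is
#: dilated by the stent
DEFAULT_DILATION_SLOPE = 0.5


class GeometryError(ValueError):
    """Raised when a geometric specification is inconsistent."""


@dataclass(frozen=True)
class FluidProps:
    """Newtonian incompressible working fluid."""

    density: float = URINE_DENSITY  # kg m^-3
    viscosity: float = URINE_VISCOSITY  # Pa s

    def __post_init__(self) -> None:
        if not (self.density > 0.0 and math.isfinite(self.density)):
            raise GeometryError(f"fluid.density must be > 0, got {self.density}")
        if not (self.viscosity > 0.0 and math.isfinite(self.viscosity)):
            raise GeometryError(f"fluid.viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class AxialProfile:
    """Piecewise-linear ureter lumen diameter versus axial position.

    ``stations`` are (position, diameter) pairs with strictly increasing
    positions spanning [0, total_length]; the diameter between stations is
    linearly interpolated.
    """

    stations: tuple[tuple[float, float], ...]
    total_length: float

    def __post_init__(self) -> None:
        if len(self.stations) < 2:
            raise GeometryError("profile needs at least two stations")
        xs = [x for x, _ in self.stations]
        ds = [d for _, d in self.stations]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise GeometryError(f"station positions must strictly increase, got {xs}")
        if xs[0] != 0.0 or not math.isclose(xs[-1], self.total_length):
            raise GeometryError(
                f"stations must span [0, total_length={self.total_length}], got [{xs[0]}, {xs[-1]}]"
            )
        if any(d <= 0.0 for d in ds):
            raise GeometryError(f"station diameters must be > 0, got {ds}")

    def diameter(self, x):
        """Lumen diameter at axial position(s) ``x`` (linear interpolation)."""
        xs = np.array([s[0] for s in self.stations])
        ds = np.array([s[1] for s in self.stations])
        return np.interp(x, xs, ds)


@dataclass(frozen=True)
class StentSpec:
    """Double-J stent dimensions, side-hole layout and wall permeability."""

    inner_diameter: float = 1.5 * MM
    outer_diameter: float = 2.5 * MM
    shaft_length: float = DEFAULT_URETER_LENGTH
    side_hole_diameter: float = 0.8 * MM
    n_side_holes: int = 42
    holes_per_coil: int = 4
    permeability: float = 0.0  # m^2; 0 encodes the unporous wall

    def __post_init__(self) -> None:
        if not 0.0 < self.inner_diameter < self.outer_diameter:
            raise GeometryError(
                f"need 0 < inner_diameter ({self.inner_diameter}) < outer_diameter ({self.outer_diameter})"
            )
        if self.permeability < 0.0:
            raise GeometryError(f"permeability must be >= 0, got {self.permeability}")
        if self.side_hole_diameter <= 0.0:
            raise GeometryError("side_hole_diameter must be > 0")
        if self.n_side_holes < 0:
            raise GeometryError("n_side_holes must be >= 0")
        if self.n_side_holes and self.n_side_holes <= 2 * self.holes_per_coil:
            raise GeometryError(
                f"{self.n_side_holes} side holes leave no shaft holes after "
                f"2 x {self.holes_per_coil} coil holes"
            )
        if self.shaft_length <= 0.0:
            raise GeometryError("shaft_length must be > 0")

    @property
    def wall_thickness(self) -> float:
        return 0.5 * (self.outer_diameter - self.inner_diameter)

    @property
    def n_shaft_holes(self) -> int:
        if self.n_side_holes == 0:
            return 0
        return self.n_side_holes - 2 * self.holes_per_coil


@dataclass(frozen=True)
class HolePosition:
    index: int  # 1-based, kidney to bladder
    position: float  # m from the UPJ; negative / > L for coil holes
    region: str  # kidney_coil | shaft | bladder_coil


@dataclass(frozen=True)
class Occlusion:
    """Complete blockage of the extraluminal annulus in the middle ureter."""

    present: bool = False
    start_position: float = 0.0
    length: float = 0.0

    def __post_init__(self) -> None:
        if self.present and self.length <= 0.0:
            raise GeometryError("an occlusion must have positive length")

    @property
    def end_position(self) -> float:
        return self.start_position + self.length


@dataclass(frozen=True)
class Scenario:
    """One simulation case: geometry + permeability + occlusion + BCs."""

    profile: AxialProfile
    stent: StentSpec
    occlusion: Occlusion = Occlusion()
    fluid: FluidProps = FluidProps()
    inlet_pressure: float = INLET_PRESSURE_PA
    outlet_pressure: float = OUTLET_PRESSURE_PA
    side_holes_enabled: bool = True
    case_id: int | None = None
    min_clearance: float = DEFAULT_MIN_CLEARANCE
    dilation_slope: float = DEFAULT_DILATION_SLOPE
    hole_model: str = "sampson_tube"  # or "tube_only"

    def __post_init__(self) -> None:
        if self.hole_model not in ("sampson_tube", "tube_only"):
            raise GeometryError(f"unknown hole_model {self.hole_model!r}")
        if self.min_clearance <= 0.0:
            raise GeometryError("min_clearance must be > 0")
        if self.case_id is not None and not 1 <= self.case_id <= 9:
            raise GeometryError(f"case_id must be in 1..9, got {self.case_id}")
        if self.side_holes_enabled and self.stent.n_side_holes == 0:
            object.__setattr__(self, "side_holes_enabled", False)
        self.validate()

    def validate(self) -> None:
        if self.inlet_pressure <= self.outlet_pressure:
            raise GeometryError(
                f"forward flow needs inlet_pressure ({self.inlet_pressure}) > "
                f"outlet_pressure ({self.outlet_pressure})"
            )
        if self.stent.shaft_length < self.profile.total_length:
            raise GeometryError(
                f"stent shaft ({self.stent.shaft_length} m) shorter than the "
                f"ureter ({self.profile.total_length} m)"
            )
        if self.occlusion.present:
            holes = {h.index: h.position for h in side_hole_positions(self.stent, self.profile)}
            lo, hi = holes.get(21), holes.get(22)
            if lo is None or hi is None:
                # a stent without shaft holes still uses the reference
                # 42-hole layout to locate the mid-ureter occlusion
                ref = {h.index: h.position for h in
                       side_hole_positions(replace(self.stent, n_side_holes=42), self.profile)}
                lo, hi = ref[21], ref[22]
            if not (lo < self.occlusion.start_position
                    and self.occlusion.end_position < hi):
                raise GeometryError(
                    f"occlusion [{self.occlusion.start_position}, "
                    f"{self.occlusion.end_position}] m must lie strictly between "
                    f"side holes 21 ({lo} m) and 22 ({hi} m)"
                )

    def effective_profile(self) -> AxialProfile:
        """Ureter lumen after stent insertion (see stented_lumen_diameter)."""
        return stented_profile(self.profile, self.stent,
                               self.min_clearance, self.dilation_slope)


def default_ureter_profile(
    total_length: float = DEFAULT_URETER_LENGTH,
    proximal_start: float = 6.0 * MM,
    proximal_end: float = 3.0 * MM,
    middle: float = 2.5 * MM,
    distal: float = 2.4 * MM,
    vuj: float = 2.9 * MM,
) -> AxialProfile:
    """Ex vivo (unstented) ureter lumen profile.

    The lumen tapers from ~6.0 to ~3.0 mm over the proximal third, holds
    ~2.5 mm in the middle third and ~2.4 mm in the distal third, then flares
    to ~2.9 mm at the VUJ.
    """
    third = total_length / 3.0
    step = 5.0 * MM  # transition length between nominally-constant regions
    flare = 8.0 * MM  # length of the VUJ flare
    stations = (
        (0.0, proximal_start),
        (third, proximal_end),
        (third + step, middle),
        (2.0 * third, middle),
        (2.0 * third + step, distal),
        (total_length - flare, distal),
        (total_length, vuj),
    )
    return AxialProfile(stations=stations, total_length=total_length)


def default_stent_spec(permeability: float = 0.0) -> StentSpec:
    """The reference double-J stent: 1.5/2.5 mm, 42 x 0.8 mm side holes."""
    return StentSpec(permeability=permeability)


def stented_lumen_diameter(d_ex_vivo, stent: StentSpec,
                           min_clearance: float = DEFAULT_MIN_CLEARANCE,
                           dilation_slope: float = DEFAULT_DILATION_SLOPE,
                           reference_diameter: float = 2.4 * MM):
    """Effective ureter lumen diameter with the stent in place.

    The ex vivo lumen of the middle/distal ureter (~2.4-2.5 mm) is no wider
    than the stent itself (OD 2.5 mm); an indwelling stent dilates these
    segments.  The post-insertion lumen is modelled as

        d_eff = max(d, d_min + s * (d - d_ref))

    with ``d_min = OD + 2 * min_clearance`` the dilated floor, ``d_ref`` the
    narrowest ex vivo diameter and ``s`` the fraction of ex vivo diameter
    increments preserved under dilation.  Wide segments (proximal ureter)
    are unaffected; narrow segments keep their relative ordering (middle >
    distal, VUJ flare) at compressed amplitude.
    """
    d = np.asarray(d_ex_vivo, dtype=float)
    floor = stent.outer_diameter + 2.0 * min_clearance
    dilated = floor + dilation_slope * (d - reference_diameter)
    out = np.maximum(d, dilated)
    return float(out) if np.isscalar(d_ex_vivo) else out


def stented_profile(profile: AxialProfile, stent: StentSpec,
                    min_clearance: float = DEFAULT_MIN_CLEARANCE,
                    dilation_slope: float = DEFAULT_DILATION_SLOPE) -> AxialProfile:
    """Apply :func:`stented_lumen_diameter` station-wise."""
    ref = min(d for _, d in profile.stations)
    stations = tuple(
        (x, stented_lumen_diameter(d, stent, min_clearance, dilation_slope, ref))
        for x, d in profile.stations
    )
    return AxialProfile(stations=stations, total_length=profile.total_length)


def side_hole_positions(stent: StentSpec, profile: AxialProfile,
                        coil_pitch: float = 5.0 * MM) -> list[HolePosition]:
    """Axial positions of all side holes, indexed 1..n kidney to bladder.

    Shaft holes are uniformly spaced over the open interval (0, L); coil
    holes sit beyond the ureter ends (inside the reservoirs) at a nominal
    pitch and are lumped into the end attachments by the network builder.
    With the default 42-hole stent, holes 1-4 are on the kidney coil, 5-38
    on the shaft and 39-42 on the bladder coil; the reference occlusion
    fits strictly between holes 21 and 22.
    """
    if stent.shaft_length < profile.total_length:
        raise GeometryError(
            f"stent shaft ({stent.shaft_length} m) is shorter than the ureter "
            f"({profile.total_length} m)"
        )
    if stent.n_side_holes == 0:
        return []
    L = profile.total_length
    n_shaft = stent.n_shaft_holes
    npc = stent.holes_per_coil
    holes: list[HolePosition] = []
    for k in range(npc):
        holes.append(HolePosition(k + 1, -(npc - k) * coil_pitch, "kidney_coil"))
    for j in range(1, n_shaft + 1):
        holes.append(HolePosition(npc + j, L * j / (n_shaft + 1), "shaft"))
    for k in range(npc):
        holes.append(HolePosition(npc + n_shaft + k + 1, L + (k + 1) * coil_pitch,
                                  "bladder_coil"))
    return holes


def default_occlusion(profile: AxialProfile, stent: StentSpec | None = None,
                      length: float = 6.0 * MM) -> Occlusion:
    """A complete mid-ureter occlusion centred between side holes 21 and 22."""
    stent = stent or default_stent_spec()
    ref = stent if stent.n_side_holes else replace(stent, n_side_holes=42)
    holes = {h.index: h.position for h in side_hole_positions(ref, profile)}
    lo, hi = holes[21], holes[22]
    gap = hi - lo
    length = min(length, 0.9 * gap)  # must fit strictly between the two holes
    centre = 0.5 * (lo + hi)
    return Occlusion(present=True, start_position=centre - 0.5 * length, length=length)


#: Case matrix of the study: (permeability m^2, number of side holes, occluded)
CASE_MATRIX: dict[int, tuple[float, int, bool]] = {
    1: (0.0, 42, False),
    2: (1e-10, 42, False),
    3: (1e-11, 42, False),
    4: (1e-12, 42, False),
    5: (1e-14, 42, False),
    6: (1e-18, 42, False),
    7: (1e-10, 0, False),
    8: (0.0, 42, True),
    9: (1e-10, 42, True),
}


def make_scenario(case_id: int, **overrides) -> Scenario:
    """Build one of the nine named case studies.

    Cases 1-6 sweep wall permeability (0, 1e-10 .. 1e-18 m^2) on the
    unoccluded, 42-hole configuration; case 7 removes the side holes from
    the most permeable stent; cases 8-9 occlude the middle ureter for the
    unporous and most permeable stents.
    """
    if case_id not in CASE_MATRIX:
        raise GeometryError(f"case_id must be in 1..9, got {case_id}")
    permeability, n_holes, occluded = CASE_MATRIX[case_id]
    profile = overrides.pop("profile", default_ureter_profile())
    stent = StentSpec(permeability=permeability, n_side_holes=n_holes)
    occ = default_occlusion(profile, stent) if occluded else Occlusion()
    return Scenario(
        profile=profile,
        stent=stent,
        occlusion=occ,
        side_holes_enabled=n_holes > 0,
        case_id=case_id,
        **overrides,
    )


def random_scenario(seed: int, *,
                    permeability_range: tuple[float, float] = (1e-18, 1e-10),
                    unporous_probability: float = 0.2,
                    occlusion_probability: float = 0.25,
                    no_hole_probability: float = 0.2,
                    geometry_jitter: float = 0.2) -> Scenario:
    """Deterministic randomized scenario for property testing.

    Geometry is perturbed within ``geometry_jitter`` (default +/-20%) of the
    defaults; permeability is log-uniform over ``permeability_range`` or 0
    with probability ``unporous_probability``.  The pressure drop and fluid
    are the fixed study conditions.
    """
    lo, hi = permeability_range
    if not (0.0 < lo <= hi):
        raise GeometryError(f"invalid permeability_range {permeability_range}")
    if not 0.0 <= geometry_jitter < 0.5:
        raise GeometryError(f"geometry_jitter must be in [0, 0.5), got {geometry_jitter}")
    rng = np.random.default_rng(seed)

    def jit() -> float:
        return 1.0 + geometry_jitter * float(rng.uniform(-1.0, 1.0))

    length = DEFAULT_URETER_LENGTH * jit()
    dscale = jit()
    profile = default_ureter_profile(
        total_length=length,
        proximal_start=6.0 * MM * dscale,
        proximal_end=3.0 * MM * dscale,
        middle=2.5 * MM * dscale,
        distal=2.4 * MM * dscale,
        vuj=2.9 * MM * dscale,
    )
    if rng.uniform() < unporous_probability:
        permeability = 0.0
    else:
        permeability = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    n_holes = 0 if rng.uniform() < no_hole_probability else 42
    stent = StentSpec(
        inner_diameter=1.5 * MM * jit(),
        shaft_length=length,
        side_hole_diameter=0.8 * MM * jit(),
        n_side_holes=n_holes,
        permeability=permeability,
    )
    occ = (default_occlusion(profile, stent)
           if rng.uniform() < occlusion_probability else Occlusion())
    return Scenario(
        profile=profile,
        stent=stent,
        occlusion=occ,
        side_holes_enabled=n_holes > 0,
    )
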