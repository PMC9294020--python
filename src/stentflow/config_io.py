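"""Configuration loading/validation, result serialisation and provenance.

Scenario files are YAML (or JSON) mappings; lengths are given in
millimetres and converted to SI on load.  A file may either name one of
the nine study cases (``case_id: 1..9``) or spell out the scenario; mixing
the two is rejected.  Unknown keys are rejected with their key path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import metadata
from pathlib import Path

import yaml

from . import geometry as geo
from .geometry import (
    AxialProfile,
    FluidProps,
    GeometryError,
    Occlusion,
    Scenario,
    StentSpec,
    default_ureter_profile,
    make_scenario,
)
from .network import RESIDUAL_RTOL


class ConfigError(ValueError):
    """Raised for malformed or contradictory configuration input."""


_GEOMETRY_KEYS = {
    "ureter_length_mm", "proximal_start_mm", "proximal_end_mm", "middle_mm",
    "distal_mm", "vuj_mm", "stent_inner_mm", "stent_outer_mm",
    "hole_diameter_mm", "n_side_holes", "holes_per_coil", "min_clearance_mm",
    "dilation_slope",
}
_TOP_KEYS = {
    "case_id", "geometry", "permeability_m2", "side_holes", "occlusion",
    "pressures_pa", "fluid", "hole_model",
}


def _require_mapping(obj, path: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(obj).__name__}")
    return obj


def _check_keys(data: dict, allowed: set[str], path: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}; "
                          f"allowed: {sorted(allowed)}")


def _number(data: dict, key: str, path: str, default):
    value = data.get(key, default)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {value!r}")
    return float(value)


def scenario_from_dict(data: dict) -> Scenario:
    """Build and validate a Scenario from a configuration mapping."""
    data = _require_mapping(data, "<config>")
    _check_keys(data, _TOP_KEYS, "<config>")
    if "case_id" in data:
        others = set(data) - {"case_id"}
        if others:
            raise ConfigError(
                f"<config>: case_id fixes the whole scenario; remove conflicting "
                f"key(s) {sorted(others)}"
            )
        case_id = data["case_id"]
        if not isinstance(case_id, int) or not 1 <= case_id <= 9:
            raise ConfigError(f"<config>.case_id: expected an integer in 1..9, got {case_id!r}")
        return make_scenario(case_id)

    g = _require_mapping(data.get("geometry", {}), "<config>.geometry")
    _check_keys(g, _GEOMETRY_KEYS, "<config>.geometry")
    mm = geo.MM
    length = _number(g, "ureter_length_mm", "geometry", geo.DEFAULT_URETER_LENGTH / mm) * mm
    profile = default_ureter_profile(
        total_length=length,
        proximal_start=_number(g, "proximal_start_mm", "geometry", 6.0) * mm,
        proximal_end=_number(g, "proximal_end_mm", "geometry", 3.0) * mm,
        middle=_number(g, "middle_mm", "geometry", 2.5) * mm,
        distal=_number(g, "distal_mm", "geometry", 2.4) * mm,
        vuj=_number(g, "vuj_mm", "geometry", 2.9) * mm,
    )
    n_holes = g.get("n_side_holes", 42)
    if not isinstance(n_holes, int) or n_holes < 0:
        raise ConfigError(f"<config>.geometry.n_side_holes: expected an integer >= 0, got {n_holes!r}")
    permeability = _number(data, "permeability_m2", "<config>", 0.0)
    try:
        stent = StentSpec(
            inner_diameter=_number(g, "stent_inner_mm", "geometry", 1.5) * mm,
            outer_diameter=_number(g, "stent_outer_mm", "geometry", 2.5) * mm,
            shaft_length=length,
            side_hole_diameter=_number(g, "hole_diameter_mm", "geometry", 0.8) * mm,
            n_side_holes=n_holes,
            holes_per_coil=int(_number(g, "holes_per_coil", "geometry", 4)),
            permeability=permeability,
        )
    except GeometryError as exc:
        raise ConfigError(f"<config>.geometry: {exc}") from exc

    o = _require_mapping(data.get("occlusion", {"present": False}), "<config>.occlusion")
    _check_keys(o, {"present", "start_mm", "length_mm"}, "<config>.occlusion")
    present = o.get("present", False)
    if not isinstance(present, bool):
        raise ConfigError(f"<config>.occlusion.present: expected a boolean, got {present!r}")
    if present:
        if "start_mm" in o:
            occlusion = Occlusion(
                present=True,
                start_position=_number(o, "start_mm", "occlusion", None) * mm,
                length=_number(o, "length_mm", "occlusion", 6.0) * mm,
            )
        else:
            occlusion = geo.default_occlusion(profile, stent,
                                              length=_number(o, "length_mm", "occlusion", 6.0) * mm)
    else:
        occlusion = Occlusion()

    p = _require_mapping(data.get("pressures_pa", {}), "<config>.pressures_pa")
    _check_keys(p, {"inlet", "outlet"}, "<config>.pressures_pa")
    f = _require_mapping(data.get("fluid", {}), "<config>.fluid")
    _check_keys(f, {"density_kg_m3", "viscosity_pa_s"}, "<config>.fluid")

    side_holes = data.get("side_holes", n_holes > 0)
    if not isinstance(side_holes, bool):
        raise ConfigError(f"<config>.side_holes: expected a boolean, got {side_holes!r}")
    hole_model = data.get("hole_model", "sampson_tube")

    try:
        return Scenario(
            profile=profile,
            stent=stent,
            occlusion=occlusion,
            fluid=FluidProps(
                density=_number(f, "density_kg_m3", "fluid", geo.URINE_DENSITY),
                viscosity=_number(f, "viscosity_pa_s", "fluid", geo.URINE_VISCOSITY),
            ),
            inlet_pressure=_number(p, "inlet", "pressures_pa", geo.INLET_PRESSURE_PA),
            outlet_pressure=_number(p, "outlet", "pressures_pa", geo.OUTLET_PRESSURE_PA),
            side_holes_enabled=side_holes,
            min_clearance=_number(g, "min_clearance_mm", "geometry",
                                  geo.DEFAULT_MIN_CLEARANCE / mm) * mm,
            dilation_slope=_number(g, "dilation_slope", "geometry",
                                   geo.DEFAULT_DILATION_SLOPE),
            hole_model=hole_model,
        )
    except GeometryError as exc:
        raise ConfigError(f"<config>: {exc}") from exc


def scenario_to_dict(scenario: Scenario) -> dict:
    """Normalised configuration mapping for a scenario (mm units)."""
    if scenario.case_id is not None:
        return {"case_id": scenario.case_id}
    mm = geo.MM
    stations = dict(scenario.profile.stations)
    xs = sorted(stations)
    # the default profile parameterisation: start, taper end, middle, distal, VUJ
    third = scenario.profile.total_length / 3.0
    return {
        "geometry": {
            "ureter_length_mm": scenario.profile.total_length / mm,
            "proximal_start_mm": float(scenario.profile.diameter(0.0)) / mm,
            "proximal_end_mm": float(scenario.profile.diameter(third)) / mm,
            "middle_mm": float(scenario.profile.diameter(2.0 * third)) / mm,
            "distal_mm": float(scenario.profile.diameter(xs[-2])) / mm,
            "vuj_mm": float(scenario.profile.diameter(xs[-1])) / mm,
            "stent_inner_mm": scenario.stent.inner_diameter / mm,
            "stent_outer_mm": scenario.stent.outer_diameter / mm,
            "hole_diameter_mm": scenario.stent.side_hole_diameter / mm,
            "n_side_holes": scenario.stent.n_side_holes,
            "holes_per_coil": scenario.stent.holes_per_coil,
            "min_clearance_mm": scenario.min_clearance / mm,
            "dilation_slope": scenario.dilation_slope,
        },
        "permeability_m2": scenario.stent.permeability,
        "side_holes": scenario.side_holes_enabled,
        "occlusion": (
            {"present": True,
             "start_mm": scenario.occlusion.start_position / mm,
             "length_mm": scenario.occlusion.length / mm}
            if scenario.occlusion.present else {"present": False}
        ),
        "pressures_pa": {"inlet": scenario.inlet_pressure,
                         "outlet": scenario.outlet_pressure},
        "fluid": {"density_kg_m3": scenario.fluid.density,
                  "viscosity_pa_s": scenario.fluid.viscosity},
        "hole_model": scenario.hole_model,
    }


def load_config(path) -> Scenario:
    """Load and validate a scenario configuration file (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if data is None:
        raise ConfigError(f"{path}: file is empty")
    return scenario_from_dict(data)


def config_hash(data: dict) -> str:
    """Stable SHA-256 of a configuration mapping."""
    return hashlib.sha256(
        json.dumps(data, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


@dataclass(frozen=True)
class RunRecord:
    """Provenance stamp embedded in every JSON output.

    Deliberately excludes wall-clock time so that identical inputs yield
    byte-identical outputs.
    """

    package: str
    version: str
    config_sha256: str
    solver: str
    residual_rtol: float
    seed: int | None = None


def make_run_record(scenario: Scenario, seed: int | None = None) -> RunRecord:
    try:
        version = metadata.version("stentflow")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    return RunRecord(
        package="stentflow",
        version=version,
        config_sha256=config_hash(scenario_to_dict(scenario)),
        solver="direct sparse LU on the nodal conductance system",
        residual_rtol=RESIDUAL_RTOL,
        seed=seed,
    )


def write_csv(frame, path, units: dict[str, str]) -> None:
    """CSV with a second header row of units; 6 significant digits."""
    path = Path(path)
    cols = list(frame.columns)
    lines = [",".join(cols), ",".join(units.get(c, "-") for c in cols)]
    for _, row in frame.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, (bool,)) or v is None:
                cells.append(str(v))
            elif isinstance(v, (int,)) and not isinstance(v, bool):
                cells.append(str(v))
            elif isinstance(v, float):
                if float(v).is_integer() and abs(v) < 1e6 and c not in (
                        "permeability_m2",):
                    cells.append(str(int(v)) if c.endswith("index") or c.endswith("hole")
                                 else f"{v:.6g}")
                else:
                    cells.append(f"{v:.6g}")
            else:
                cells.append(str(v))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_json(payload: dict, path, record: RunRecord) -> None:
    """JSON output with the run record embedded; numbers unrounded."""
    body = {"run_record": asdict(record), **payload}

    def _plain(obj):  # numpy scalars -> native Python
        if hasattr(obj, "item"):
            return obj.item()
        raise TypeError(f"cannot serialise {type(obj).__name__}")

    Path(path).write_text(
        json.dumps(body, indent=2, sort_keys=False, default=_plain) + "\n",
        encoding="utf-8",
    )
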