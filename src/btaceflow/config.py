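"""YAML/JSON configuration loading with defaults, units and validation.

Configuration files use millimetres for every geometric quantity (the
natural bench unit); loading normalizes everything to SI.  Unknown keys are
rejected with the offending key path so typos never silently fall back to a
default.  A minimal file needs nothing beyond the cancer scenario::

    scenario:
      tumors: [S7]

Full schema (every entry optional unless noted)::

    fluid: water | blood_mimic | {density: kg/m3, viscosity: Pa.s, gravity: m/s2}
    artery:
      tree:
        pha|lobar|sectional|segmental: {length_mm: , diameter_mm: }
      collaterals:
        ca|sectional|segmental: {length_mm: , diameter_mm: } | null
        attach_fractions: [f1, f2]
    ivm:
      outlet_tube_lr|outlet_tube_ur|inflow_tube: {length_mm: , diameter_mm: }
      z_lr_mm: , z_ur_mm: , h_pump_mm:
    scenario:
      tumors: [segment labels]          # required
    occlusion:
      site: a..i | null
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .artery import ArteryTreeSpec, CollateralSpec, SITE_LABELS
from .hydraulics import BLOOD_MIMIC, FluidProperties, NetworkError, TubeSpec, WATER
from .ivm import CancerScenario, IVMConfig, OcclusionState

__all__ = ["ConfigError", "LoadedRun", "load_config", "dump_config"]


class ConfigError(NetworkError):
    """A configuration file violates the schema."""


@dataclass(frozen=True)
class LoadedRun:
    """A fully-resolved run: circuit parameters, scenario and balloon state."""

    config: IVMConfig
    scenario: CancerScenario
    occlusion: OcclusionState


def _require_mapping(obj, path: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(obj).__name__}")
    return obj


def _check_keys(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


def _number(mapping: dict, key: str, path: str, default: float) -> float:
    value = mapping.get(key, default)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{path}.{key}: expected a number, got {value!r}")
    return float(value)


def _tube(obj, path: str, default: TubeSpec) -> TubeSpec:
    mapping = _require_mapping(obj, path)
    _check_keys(mapping, {"length_mm", "diameter_mm"}, path)
    length = _number(mapping, "length_mm", path, default.length * 1000.0) / 1000.0
    diameter = _number(mapping, "diameter_mm", path, default.diameter * 1000.0) / 1000.0
    try:
        return TubeSpec(length, diameter)
    except NetworkError as exc:
        raise ConfigError(f"{path}: {exc} (lengths/diameters are in mm)") from exc


def _fluid(obj) -> FluidProperties:
    if obj is None or obj == "water":
        return WATER
    if obj == "blood_mimic":
        return BLOOD_MIMIC
    mapping = _require_mapping(obj, "fluid")
    _check_keys(mapping, {"density", "viscosity", "gravity"}, "fluid")
    try:
        return FluidProperties(
            density=_number(mapping, "density", "fluid", WATER.density),
            viscosity=_number(mapping, "viscosity", "fluid", WATER.viscosity),
            gravity=_number(mapping, "gravity", "fluid", WATER.gravity),
        )
    except NetworkError as exc:
        raise ConfigError(f"fluid: {exc}") from exc


def _collateral_tube(mapping: dict, key: str, default: TubeSpec | None) -> TubeSpec | None:
    if key in mapping and mapping[key] is None:
        return None
    return _tube(mapping.get(key), f"artery.collaterals.{key}", default or TubeSpec(0.01, 0.001))


def load_config(path: str | Path) -> LoadedRun:
    """Read a YAML (or JSON — YAML is a superset) run file and resolve defaults."""
    path = Path(path)
    raw = _require_mapping(yaml.safe_load(path.read_text()), str(path))
    _check_keys(raw, {"fluid", "artery", "ivm", "scenario", "occlusion"}, "top level")

    fluid = _fluid(raw.get("fluid"))

    artery = _require_mapping(raw.get("artery"), "artery")
    _check_keys(artery, {"tree", "collaterals"}, "artery")
    tree_raw = _require_mapping(artery.get("tree"), "artery.tree")
    _check_keys(tree_raw, {"pha", "lobar", "sectional", "segmental"}, "artery.tree")
    tree_default = ArteryTreeSpec()
    try:
        tree = ArteryTreeSpec(
            **{
                gen: _tube(tree_raw.get(gen), f"artery.tree.{gen}", getattr(tree_default, gen))
                for gen in ("pha", "lobar", "sectional", "segmental")
            }
        )
    except NetworkError as exc:
        raise ConfigError(f"artery.tree: {exc}") from exc

    coll_raw = _require_mapping(artery.get("collaterals"), "artery.collaterals")
    _check_keys(coll_raw, {"ca", "sectional", "segmental", "attach_fractions"}, "artery.collaterals")
    coll_default = CollateralSpec()
    fractions = coll_raw.get("attach_fractions", list(coll_default.attach_fractions))
    if not (isinstance(fractions, (list, tuple)) and len(fractions) == 2):
        raise ConfigError("artery.collaterals.attach_fractions: expected two fractions")
    try:
        collaterals = CollateralSpec(
            ca=_collateral_tube(coll_raw, "ca", coll_default.ca),
            sectional=_collateral_tube(coll_raw, "sectional", coll_default.sectional),
            segmental=_collateral_tube(coll_raw, "segmental", coll_default.segmental),
            attach_fractions=(float(fractions[0]), float(fractions[1])),
        )
    except NetworkError as exc:
        raise ConfigError(f"artery.collaterals: {exc}") from exc

    ivm_raw = _require_mapping(raw.get("ivm"), "ivm")
    _check_keys(
        ivm_raw,
        {"outlet_tube_lr", "outlet_tube_ur", "inflow_tube", "z_lr_mm", "z_ur_mm", "h_pump_mm"},
        "ivm",
    )
    ivm_default = IVMConfig()
    try:
        config = IVMConfig(
            fluid=fluid,
            tree=tree,
            collaterals=collaterals,
            outlet_tube_lr=_tube(
                ivm_raw.get("outlet_tube_lr"), "ivm.outlet_tube_lr", ivm_default.outlet_tube_lr
            ),
            outlet_tube_ur=_tube(
                ivm_raw.get("outlet_tube_ur"), "ivm.outlet_tube_ur", ivm_default.outlet_tube_ur
            ),
            inflow_tube=_tube(ivm_raw.get("inflow_tube"), "ivm.inflow_tube", ivm_default.inflow_tube),
            z_lr=_number(ivm_raw, "z_lr_mm", "ivm", ivm_default.z_lr * 1000.0) / 1000.0,
            z_ur=_number(ivm_raw, "z_ur_mm", "ivm", ivm_default.z_ur * 1000.0) / 1000.0,
            h_pump=_number(ivm_raw, "h_pump_mm", "ivm", ivm_default.h_pump * 1000.0) / 1000.0,
        )
    except NetworkError as exc:
        raise ConfigError(f"ivm: {exc} (heights are in mm)") from exc

    scenario_raw = _require_mapping(raw.get("scenario"), "scenario")
    _check_keys(scenario_raw, {"tumors"}, "scenario")
    tumors = scenario_raw.get("tumors")
    if not isinstance(tumors, list) or not tumors:
        raise ConfigError("scenario.tumors: expected a non-empty list of segment labels")
    try:
        scenario = CancerScenario(tumors)
    except NetworkError as exc:
        raise ConfigError(f"scenario.tumors: {exc}") from exc

    occ_raw = _require_mapping(raw.get("occlusion"), "occlusion")
    _check_keys(occ_raw, {"site"}, "occlusion")
    site = occ_raw.get("site")
    if site is not None and site not in SITE_LABELS:
        raise ConfigError(f"occlusion.site: {site!r} is not one of {SITE_LABELS} or null")

    return LoadedRun(config=config, scenario=scenario, occlusion=OcclusionState(site))


def _tube_out(tube: TubeSpec | None):
    if tube is None:
        return None
    return {"length_mm": tube.length * 1000.0, "diameter_mm": tube.diameter * 1000.0}


def dump_config(run: LoadedRun, path: str | Path | None = None) -> str:
    """Serialize a resolved run back to YAML (round-trips through load_config)."""
    cfg = run.config
    doc = {
        "fluid": dataclasses.asdict(cfg.fluid),
        "artery": {
            "tree": {
                gen: _tube_out(getattr(cfg.tree, gen))
                for gen in ("pha", "lobar", "sectional", "segmental")
            },
            "collaterals": {
                "ca": _tube_out(cfg.collaterals.ca),
                "sectional": _tube_out(cfg.collaterals.sectional),
                "segmental": _tube_out(cfg.collaterals.segmental),
                "attach_fractions": list(cfg.collaterals.attach_fractions),
            },
        },
        "ivm": {
            "outlet_tube_lr": _tube_out(cfg.outlet_tube_lr),
            "outlet_tube_ur": _tube_out(cfg.outlet_tube_ur),
            "inflow_tube": _tube_out(cfg.inflow_tube),
            "z_lr_mm": cfg.z_lr * 1000.0,
            "z_ur_mm": cfg.z_ur * 1000.0,
            "h_pump_mm": cfg.h_pump * 1000.0,
        },
        "scenario": {"tumors": sorted(run.scenario.tumor_segments)},
        "occlusion": {"site": run.occlusion.site},
    }
    text = yaml.safe_dump(doc, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def resolved_parameters(run: LoadedRun) -> dict:
    """JSON-serializable dict of every resolved parameter (for run manifests)."""
    return json.loads(json.dumps(yaml.safe_load(dump_config(run))))
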