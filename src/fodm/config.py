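"""Run configuration: JSON schema, validation, bundled analysis configs."""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .structure_io import HydrophobicityScale, builtin_scale, load_scale
from .units import AnalysisParams, UnitSelection


@dataclass(frozen=True)
class UnitSpec:
    """One unit entry from a config file, before resolution."""

    label: str
    chains: tuple[str, ...] = ()
    ranges: tuple[tuple[str, int, int], ...] = ()
    mode: str = "individual"            # individual | component
    parent: str | None = None           # label of the parent unit (component mode)
    partners: str | None = None         # label of the partner unit (interface split)

    def selection(self) -> UnitSelection:
        return UnitSelection(label=self.label, chain_ids=self.chains,
                             residue_ranges=self.ranges)


@dataclass(frozen=True)
class RunConfig:
    params: AnalysisParams
    units: tuple[UnitSpec, ...]
    scale_name: str
    output_dir: Path = Path("fodm-out")
    config_hash: str = ""

    def unit(self, label: str) -> UnitSpec:
        for u in self.units:
            if u.label == label:
                return u
        raise ConfigError(f"no unit labelled {label!r} in config")


def _require(d: dict, key: str, typ, where: str):
    if key not in d:
        raise ConfigError(f"{where}: missing required field {key!r}")
    v = d[key]
    if not isinstance(v, typ):
        raise ConfigError(f"{where}: field {key!r} must be {typ.__name__}")
    return v


def _parse_ranges(raw, where: str) -> tuple[tuple[str, int, int], ...]:
    out = []
    for i, r in enumerate(raw):
        if not (isinstance(r, (list, tuple)) and len(r) == 3):
            raise ConfigError(f"{where}: ranges[{i}] must be [chain, start, end]")
        chain, start, end = r
        if not isinstance(chain, str) or not isinstance(start, int) or not isinstance(end, int):
            raise ConfigError(f"{where}: ranges[{i}] must be [str, int, int]")
        if end < start:
            raise ConfigError(f"{where}: ranges[{i}] has end < start")
        out.append((chain, start, end))
    return tuple(out)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration.

    Schema (all scalar fields optional, shown with defaults)::

        {
          "scale": "kyte_doolittle",     # bundled name or path to a scale file
          "cutoff": 9.0,
          "sigma_rule": "std",
          "sigma_floor": 1.0,
          "k_grid": [0.0, 10.0, 0.01],
          "interface_threshold": 9.0,
          "output_dir": "fodm-out",
          "units": [
            {"label": "Chain A", "chains": ["A"], "mode": "individual"},
            {"label": "Domain 1", "ranges": [["A", 4, 137]],
             "mode": "component", "parent": "Chain A", "partners": "Others"}
          ]
        }
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")

    scale_name = raw.get("scale", "kyte_doolittle")
    if not isinstance(scale_name, str):
        raise ConfigError(f"{path}: field 'scale' must be str")
    scale: HydrophobicityScale
    if scale_name.endswith(".txt") or "/" in scale_name:
        scale = load_scale(scale_name)
    else:
        scale = builtin_scale(scale_name)

    grid_raw = raw.get("k_grid", [0.0, 10.0, 0.01])
    if not (isinstance(grid_raw, list) and len(grid_raw) == 3):
        raise ConfigError(f"{path}: field 'k_grid' must be [min, max, step]")
    for num_field in ("cutoff", "sigma_floor", "interface_threshold"):
        if num_field in raw and not isinstance(raw[num_field], (int, float)):
            raise ConfigError(f"{path}: field {num_field!r} must be numeric")
    sigma_rule = raw.get("sigma_rule", "std")
    if sigma_rule not in ("extent3", "extent6", "std"):
        raise ConfigError(f"{path}: field 'sigma_rule' must be extent3|extent6|std")

    params = AnalysisParams(
        scale=scale,
        cutoff=float(raw.get("cutoff", 9.0)),
        sigma_rule=sigma_rule,
        sigma_floor=float(raw.get("sigma_floor", 1.0)),
        k_grid=tuple(float(g) for g in grid_raw),
        interface_threshold=float(raw.get("interface_threshold", 9.0)),
        include_self=bool(raw.get("include_self", False)),
        centroid=str(raw.get("centroid", "heavy")),
    )

    units_raw = _require(raw, "units", list, str(path))
    units: list[UnitSpec] = []
    for i, u in enumerate(units_raw):
        where = f"{path}: units[{i}]"
        if not isinstance(u, dict):
            raise ConfigError(f"{where}: must be an object")
        label = _require(u, "label", str, where)
        mode = u.get("mode", "individual")
        if mode not in ("individual", "component"):
            raise ConfigError(f"{where}: field 'mode' must be individual|component")
        if mode == "component" and not isinstance(u.get("parent"), str):
            raise ConfigError(f"{where}: component mode requires field 'parent'")
        chains = tuple(u.get("chains", []))
        ranges = _parse_ranges(u.get("ranges", []), where)
        units.append(UnitSpec(label=label, chains=chains, ranges=ranges,
                              mode=mode, parent=u.get("parent"),
                              partners=u.get("partners")))
    labels = [u.label for u in units]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"{path}: duplicate unit labels")
    for u in units:
        for ref, fname in ((u.parent, "parent"), (u.partners, "partners")):
            if ref is not None and ref not in labels:
                raise ConfigError(
                    f"{path}: unit {u.label!r} field {fname!r} references "
                    f"unknown unit {ref!r}")

    digest = hashlib.sha256(
        json.dumps(raw, sort_keys=True).encode()).hexdigest()[:12]
    return RunConfig(params=params, units=tuple(units), scale_name=scale.name,
                     output_dir=Path(raw.get("output_dir", "fodm-out")),
                     config_hash=digest)


def bundled_config_path(name: str) -> Path:
    """Path of a config shipped with the package (actin_1d4x, tubulin_1ffx,
    prefoldin_template)."""
    ref = importlib.resources.files("fodm.data").joinpath(f"configs/{name}.json")
    p = Path(str(ref))
    if not p.exists():
        raise ConfigError(f"no bundled config named {name!r}")
    return p
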