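"""Configuration handling and run provenance.

Configs are flat JSON/TOML mappings with explicit keys; unknown keys are
rejected, units are coerced to mm (keys ending in ``_um`` are converted),
and missing keys take the model defaults. A :class:`RunManifest` snapshot
(config, seeds, photon counts, package version, output checksums) is
written next to every CLI output bundle so a run can be reproduced
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from . import __version__ as _pkg_version
from .illumination import TL2X_SAP, TL10X_2P, ObjectiveModel
from .scene import LayeredScene, build_scene

__all__ = ["validate_config", "load_config", "objective_from_config", "RunManifest"]

_SCENE_KEYS = {
    "preset", "volume_radius", "tissue_depth", "coverslip_diameter",
    "coverslip_thickness", "skull_thickness", "voxel_pitch", "vessels",
    "grey_matter_480", "grey_matter_560", "skull_props",
}
_OBJECTIVE_KEYS = {
    "objective", "numerical_aperture", "field_of_view_diameter",
    "working_distance", "front_window_radius", "focal_depth_below_surface",
    "magnification",
}
_MM_KEYS = {
    "volume_radius", "tissue_depth", "coverslip_diameter", "coverslip_thickness",
    "skull_thickness", "voxel_pitch", "field_of_view_diameter",
    "working_distance", "front_window_radius", "focal_depth_below_surface",
    "radius", "offset",
}

OBJECTIVE_PRESETS = {"TL2X-SAP": TL2X_SAP, "TL10X-2P": TL10X_2P}


def _coerce_units(cfg: Mapping[str, Any], errors: list[str]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in cfg.items():
        if key.endswith("_um"):
            base = key[:-3]
            if base not in _MM_KEYS:
                errors.append(f"unknown key {key!r}")
                continue
            try:
                out[base] = float(value) * 1e-3
            except (TypeError, ValueError):
                errors.append(f"{key!r}: expected a number, got {value!r}")
        elif isinstance(value, list) and key == "vessels":
            out[key] = [_coerce_units(v, errors) for v in value]
        else:
            out[key] = value
    return out


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Normalize a config mapping: coerce units, fill defaults, reject
    unknown keys. Returns the normalized config; raises ValueError with
    a per-key error list otherwise."""
    errors: list[str] = []
    cfg = _coerce_units(config, errors)
    unknown = set(cfg) - _SCENE_KEYS - _OBJECTIVE_KEYS
    for key in sorted(unknown):
        errors.append(f"unknown key {key!r}")
    for key in ("volume_radius", "tissue_depth", "coverslip_diameter",
                "coverslip_thickness", "skull_thickness", "voxel_pitch"):
        if key in cfg:
            try:
                if float(cfg[key]) < 0:
                    errors.append(f"{key!r}: must be >= 0")
            except (TypeError, ValueError):
                errors.append(f"{key!r}: expected a number, got {cfg[key]!r}")
    for key in ("grey_matter_480", "grey_matter_560", "skull_props"):
        if key in cfg:
            val = cfg[key]
            if not (isinstance(val, (list, tuple)) and len(val) == 3):
                errors.append(f"{key!r}: expected [mu_a, mu_s, g]")
            elif float(val[0]) < 0 or float(val[1]) < 0:
                errors.append(f"{key!r}: coefficients must be >= 0")
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    scene_cfg = {k: v for k, v in cfg.items() if k in _SCENE_KEYS}
    # build once to apply defaults and structural validation
    scene = build_scene(scene_cfg)
    normalized = {
        "volume_radius": scene.volume_radius,
        "tissue_depth": scene.tissue_depth,
        "coverslip_diameter": 2 * scene.coverslip_radius,
        "coverslip_thickness": scene.coverslip_thickness,
        "skull_thickness": scene.skull_thickness,
        "voxel_pitch": scene.voxel_pitch,
        "grey_matter_480": list(dataclasses.astuple(scene.grey_matter[480])),
        "grey_matter_560": list(dataclasses.astuple(scene.grey_matter[560])),
        "skull_props": list(dataclasses.astuple(scene.skull_props)),
        "vessels": [
            {"radius": v.radius, "axis_direction": list(v.axis_direction),
             "offset": v.offset}
            for v in scene.vessels
        ],
    }
    for key in cfg.keys() & _OBJECTIVE_KEYS:
        normalized[key] = cfg[key]
    return normalized


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a JSON or TOML config file and validate it."""
    p = Path(path)
    if p.suffix == ".toml":
        cfg = tomllib.loads(p.read_text())
    else:
        cfg = json.loads(p.read_text())
    return validate_config(cfg)


def scene_from_config(config: Mapping[str, Any] | str | None) -> LayeredScene:
    if config is None or isinstance(config, str):
        return build_scene(config)
    cfg = validate_config(config)
    return build_scene({k: v for k, v in cfg.items() if k in _SCENE_KEYS})


def objective_from_config(spec: str | Mapping[str, Any]) -> ObjectiveModel:
    """An objective from a preset name ("TL2X-SAP", "TL10X-2P") or a
    mapping of ObjectiveModel fields (based on the 2x preset)."""
    if isinstance(spec, str):
        try:
            return OBJECTIVE_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown objective preset {spec!r}; "
                f"presets: {sorted(OBJECTIVE_PRESETS)}"
            ) from None
    fields = {f.name for f in dataclasses.fields(ObjectiveModel)}
    unknown = set(spec) - fields
    if unknown:
        raise ValueError(f"unknown objective keys: {sorted(unknown)}")
    return dataclasses.replace(TL2X_SAP, **dict(spec))


@dataclass
class RunManifest:
    """Provenance snapshot written alongside every output bundle."""

    command: str
    config: dict
    seed: int
    n_photons: int
    version: str = _pkg_version
    checksums: dict[str, str] = field(default_factory=dict)

    def add_outputs(self, directory: str | Path) -> None:
        d = Path(directory)
        for f in sorted(d.iterdir()):
            if f.is_file() and f.name != "manifest.json":
                self.checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()

    def write(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.add_outputs(d)
        out = d / "manifest.json"
        out.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return out
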