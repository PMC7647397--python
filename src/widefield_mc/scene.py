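"""Simulation geometry: layered cylindrical volume with window, skull, vessels.

The scene is a cylinder of grey matter (default radius 8 mm, depth 4 mm)
whose planar top surface sits at z = 0, with z increasing downward into
tissue. Above the tissue, a glass coverslip (the cranial window, default
7.5 mm diameter) covers the central aperture and may be surrounded by
skull; alternatively skull may cover the whole surface (intact-skull
imaging). Surface blood vessels are horizontal cylinders tangent to the
tissue surface in which all photon weight is absorbed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .optics import (
    GLASS,
    GREY_MATTER_480,
    GREY_MATTER_560,
    SKULL,
    OpticalProperties,
)

__all__ = [
    "Vessel",
    "LayeredScene",
    "VoxelGrid",
    "VESSEL_ABSORBER",
    "build_scene",
    "medium_at",
    "distance_to_boundary",
]

#: Sentinel returned by :func:`medium_at` for positions inside a vessel.
VESSEL_ABSORBER = "vessel"

_EPS = 1e-12


@dataclass(frozen=True)
class Vessel:
    """A totally absorbing surface blood vessel.

    A horizontal cylinder whose top is tangent to the tissue surface
    (centre depth equals the radius). ``axis_direction`` is the horizontal
    unit 2-vector along the vessel; ``offset`` is the signed lateral
    distance of the axis from the origin, measured along the in-plane
    normal to the axis.
    """

    radius: float
    axis_direction: tuple[float, float] = (0.0, 1.0)
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("vessel radius must be > 0")
        ax, ay = self.axis_direction
        n = math.hypot(ax, ay)
        if n == 0:
            raise ValueError("axis direction must be non-zero")
        object.__setattr__(self, "axis_direction", (ax / n, ay / n))

    @property
    def normal(self) -> tuple[float, float]:
        """In-plane unit normal to the axis (the shadow cross-section axis)."""
        ax, ay = self.axis_direction
        return (-ay, ax)

    @property
    def center_depth(self) -> float:
        return self.radius

    def perp_coords(self, x: float, y: float, z: float) -> tuple[float, float]:
        """Coordinates in the plane perpendicular to the axis: (lateral, vertical)."""
        nx, ny = self.normal
        return (nx * x + ny * y - self.offset, z - self.center_depth)

    def contains(self, x: float, y: float, z: float) -> bool:
        d, h = self.perp_coords(x, y, z)
        return d * d + h * h < self.radius * self.radius


@dataclass(frozen=True)
class LayeredScene:
    """Cylindrical simulation volume: window/skull stack over grey matter.

    ``grey_matter`` maps a wavelength tag (nm) to the bulk tissue optical
    properties; runs select the tag appropriate to excitation (480) or
    emission (560). ``coverslip_radius = 0`` removes the window (skull, if
    present, then covers the full surface); ``skull_thickness = 0`` removes
    the skull.
    """

    volume_radius: float = 8.0
    tissue_depth: float = 4.0
    coverslip_radius: float = 3.75
    coverslip_thickness: float = 0.17
    coverslip_props: OpticalProperties = GLASS
    skull_thickness: float = 0.0
    skull_props: OpticalProperties = SKULL
    grey_matter: Mapping[int, OpticalProperties] = field(
        default_factory=lambda: {480: GREY_MATTER_480, 560: GREY_MATTER_560}
    )
    vessels: tuple[Vessel, ...] = ()
    voxel_pitch: float = 0.01

    def __post_init__(self) -> None:
        if self.volume_radius <= 0 or self.tissue_depth <= 0:
            raise ValueError("volume dimensions must be > 0")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel pitch must be > 0")
        if self.coverslip_radius > self.volume_radius:
            raise ValueError("coverslip must fit inside the volume")
        if self.coverslip_radius < 0 or self.skull_thickness < 0:
            raise ValueError("negative dimensions")
        object.__setattr__(self, "vessels", tuple(self.vessels))
        for v in self.vessels:
            if abs(v.offset) + v.radius > self.volume_radius:
                raise ValueError("vessel cross-section must lie within the volume")

    def props_for(self, wavelength: int) -> OpticalProperties:
        try:
            return self.grey_matter[wavelength]
        except KeyError:
            raise KeyError(
                f"no grey-matter properties for wavelength {wavelength} nm; "
                f"available: {sorted(self.grey_matter)}"
            ) from None

    def with_grey_matter(self, wavelength: int, props: OpticalProperties) -> "LayeredScene":
        gm = dict(self.grey_matter)
        gm[wavelength] = props
        return replace(self, grey_matter=gm)

    def without_vessels(self) -> "LayeredScene":
        return replace(self, vessels=())

    def top_thickness_at(self, x: float, y: float) -> float:
        """Thickness of the medium stack above the tissue at (x, y)."""
        if math.hypot(x, y) < self.coverslip_radius:
            return self.coverslip_thickness
        return self.skull_thickness

    @property
    def n_depth_bins(self) -> int:
        return int(round(self.tissue_depth / self.voxel_pitch))


class VoxelGrid:
    """Half-open voxel accumulation buffer on a regular grid.

    Voxel index ``i`` along an axis covers ``[origin + i*pitch,
    origin + (i+1)*pitch)``; z = 0 is the tissue surface. Values
    accumulate weight x path length (mm) for track-length fluence
    estimation and are therefore non-negative.
    """

    def __init__(self, pitch: float, shape: tuple[int, ...], origin: Sequence[float] | None = None):
        if pitch <= 0:
            raise ValueError("pitch must be > 0")
        self.pitch = float(pitch)
        self.origin = tuple(origin) if origin is not None else (0.0,) * len(shape)
        self.values = np.zeros(shape, dtype=np.float64)

    def index_of(self, coords: Sequence[float]) -> tuple[int, ...]:
        return tuple(
            int(math.floor((c - o) / self.pitch)) for c, o in zip(coords, self.origin)
        )

    def deposit(self, coords: Sequence[float], amount: float) -> None:
        if amount < 0:
            raise ValueError("accumulated values must be >= 0")
        idx = self.index_of(coords)
        if all(0 <= i < n for i, n in zip(idx, self.values.shape)):
            self.values[idx] += amount


# ---------------------------------------------------------------------------
# Point queries


def medium_at(
    scene: LayeredScene, position: Sequence[float], wavelength: int = 480
):
    """Medium at a position: OpticalProperties, VESSEL_ABSORBER, or None.

    Returns ``None`` when the position is outside the simulation volume
    (above the local top surface, below the tissue, or beyond the lateral
    wall), which callers treat as an exit.
    """
    x, y, z = position
    rho = math.hypot(x, y)
    if rho >= scene.volume_radius:
        return None
    if z > scene.tissue_depth:
        return None
    if z < 0:
        if rho < scene.coverslip_radius:
            return scene.coverslip_props if z >= -scene.coverslip_thickness else None
        if scene.skull_thickness > 0 and z >= -scene.skull_thickness:
            return scene.skull_props
        return None
    for v in scene.vessels:
        if v.contains(x, y, z):
            return VESSEL_ABSORBER
    return scene.props_for(wavelength)


def _ray_circle(px: float, py: float, ux: float, uy: float, r: float) -> float:
    """Smallest positive distance to the circle of radius r about the origin."""
    a = ux * ux + uy * uy
    if a < 1e-20:
        return math.inf
    b = 2.0 * (px * ux + py * uy)
    c = px * px + py * py - r * r
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return math.inf
    sq = math.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    if t1 > _EPS:
        return t1
    t2 = (-b + sq) / (2.0 * a)
    if t2 > _EPS:
        return t2
    return math.inf


def _ray_plane(z: float, uz: float, z_plane: float) -> float:
    if abs(uz) < 1e-300:  # parallel to the plane (guards overflow too)
        return math.inf
    t = (z_plane - z) / uz
    return t if t > _EPS else math.inf


def distance_to_boundary(
    scene: LayeredScene, position: Sequence[float], direction: Sequence[float]
) -> float:
    """Distance along ``direction`` to the nearest medium change.

    Candidate surfaces are the layer planes (tissue surface, tissue
    bottom, underside of coverslip or skull), the coverslip rim, vessel
    cylinders, and the lateral wall of the volume; returns ``inf`` if the
    ray meets none of them (cannot occur from inside the volume).
    """
    x, y, z = position
    ux, uy, uz = direction
    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")

    d = _ray_circle(x, y, ux, uy, scene.volume_radius)
    if z >= 0:  # tissue
        d = min(d, _ray_plane(z, uz, 0.0), _ray_plane(z, uz, scene.tissue_depth))
        for v in scene.vessels:
            nx, ny = v.normal
            pd, ph = v.perp_coords(x, y, z)
            ud = nx * ux + ny * uy
            d = min(d, _ray_circle(pd, ph, ud, uz, v.radius))
    else:  # above the tissue surface
        rho = math.hypot(x, y)
        if rho < scene.coverslip_radius:
            d = min(d, _ray_plane(z, uz, 0.0), _ray_plane(z, uz, -scene.coverslip_thickness))
            d = min(d, _ray_circle(x, y, ux, uy, scene.coverslip_radius))
        else:
            d = min(d, _ray_plane(z, uz, 0.0))
            if scene.skull_thickness > 0:
                d = min(d, _ray_plane(z, uz, -scene.skull_thickness))
            if scene.coverslip_radius > 0:
                d = min(d, _ray_circle(x, y, ux, uy, scene.coverslip_radius))
    return d


# ---------------------------------------------------------------------------
# Construction

_DEFAULTS = {
    "volume_radius": 8.0,
    "tissue_depth": 4.0,
    "coverslip_diameter": 7.5,
    "coverslip_thickness": 0.17,
    "skull_thickness": 0.0,
    "voxel_pitch": 0.01,
}


def _preset_config(name: str) -> dict:
    """Configs for the named presets: window, skull-<um>, vessel-<um>."""
    if name == "window":
        return {}
    if name.startswith("skull-") and name.endswith("um"):
        t_um = float(name[len("skull-"):-2])
        if t_um <= 0:
            raise ValueError(f"bad skull thickness in preset {name!r}")
        # Intact skull over the whole surface: no window aperture.
        return {"coverslip_diameter": 0.0, "skull_thickness": t_um * 1e-3}
    if name.startswith("vessel-") and name.endswith("um"):
        r_um = float(name[len("vessel-"):-2])
        if r_um <= 0:
            raise ValueError(f"bad vessel radius in preset {name!r}")
        return {"vessels": [{"radius": r_um * 1e-3}]}
    raise ValueError(f"unknown scene preset {name!r}")


def build_scene(config: str | Path | Mapping | None = None) -> LayeredScene:
    """Build a LayeredScene from a preset name, config mapping, or JSON file.

    With no argument, returns the default cranial-window scene. String
    arguments are preset names (``"window"``, ``"skull-300um"``,
    ``"vessel-250um"``) unless they name an existing JSON file. Mapping
    keys mirror the LayeredScene fields, with ``coverslip_diameter`` (mm)
    accepted in place of the radius and vessels given as
    ``{"radius": mm, "axis_direction": [ax, ay], "offset": mm}``.
    """
    if config is None:
        cfg: dict = {}
    elif isinstance(config, Mapping):
        cfg = dict(config)
    else:
        p = Path(config)
        if p.suffix == ".json" or p.is_file():
            cfg = json.loads(p.read_text())
        else:
            cfg = _preset_config(str(config))
    if "preset" in cfg:
        base = _preset_config(cfg.pop("preset"))
        base.update(cfg)
        cfg = base

    merged = dict(_DEFAULTS)
    optics_cfg: dict[str, OpticalProperties] = {}
    for key in ("grey_matter_480", "grey_matter_560", "skull_props"):
        if key in cfg:
            val = cfg.pop(key)
            optics_cfg[key] = (
                val if isinstance(val, OpticalProperties) else OpticalProperties(*val)
            )
    vessels_cfg = cfg.pop("vessels", [])
    unknown = set(cfg) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
    merged.update(cfg)
    for key in ("volume_radius", "tissue_depth", "coverslip_diameter",
                "coverslip_thickness", "skull_thickness", "voxel_pitch"):
        if merged[key] < 0:
            raise ValueError(f"negative dimension for {key!r}")

    vessels = []
    for v in vessels_cfg:
        if isinstance(v, Vessel):
            vessels.append(v)
        else:
            vessels.append(
                Vessel(
                    radius=v["radius"],
                    axis_direction=tuple(v.get("axis_direction", (0.0, 1.0))),
                    offset=v.get("offset", 0.0),
                )
            )

    grey = {
        480: optics_cfg.get("grey_matter_480", GREY_MATTER_480),
        560: optics_cfg.get("grey_matter_560", GREY_MATTER_560),
    }
    return LayeredScene(
        volume_radius=merged["volume_radius"],
        tissue_depth=merged["tissue_depth"],
        coverslip_radius=merged["coverslip_diameter"] / 2.0,
        coverslip_thickness=merged["coverslip_thickness"],
        skull_thickness=merged["skull_thickness"],
        skull_props=optics_cfg.get("skull_props", SKULL),
        grey_matter=grey,
        vessels=tuple(vessels),
        voxel_pitch=merged["voxel_pitch"],
    )
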