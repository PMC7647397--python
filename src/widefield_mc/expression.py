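"""Laminar indicator-expression profiles.

Expression versus cortical depth is represented on a normalized axis in
which the brain surface is 0 and the layer-6 / white-matter border is
1 mm. Profiles can be extracted from 2-D grayscale section images (row
sums over a 0.75 mm-wide strip of cortex perpendicular to the surface,
rescaled and peak-normalized) or generated synthetically. The synthetic
generator emulates the laminar GCaMP patterns of six transgenic mouse
lines — high expression in the layers holding labelled somata, moderate
neuropil expression elsewhere — without requiring the original section
images: a uniform neuropil baseline plus smoothed plateaus over the
somatic layers, normalized to a maximum of 1.

Layer boundaries on the normalized axis are not a measured quantity
here; the defaults are conventional mouse V1 proportions
(L1 0-0.10, L2/3 0.10-0.30, L4 0.30-0.42, L5 0.42-0.62, L6 0.62-1.0)
and every boundary-dependent output carries the table it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "LayerBoundaries",
    "DEFAULT_LAYER_BOUNDARIES",
    "ExpressionProfile",
    "profile_from_section_image",
    "load_section_image",
    "synthetic_profile",
    "line_profile",
    "LINE_SOMATIC_LAYERS",
    "LAYER_NAMES",
]

LAYER_NAMES = ("L1", "L2/3", "L4", "L5", "L6")


@dataclass(frozen=True)
class LayerBoundaries:
    """Ordered layer-delimiting depths on the normalized [0, 1] mm axis.

    ``edges`` holds the six depths delimiting L1, L2/3, L4, L5, L6; they
    must start at 0, end at 1, and increase strictly, so the layers tile
    [0, 1] with no gaps.
    """

    edges: tuple[float, ...] = (0.0, 0.10, 0.30, 0.42, 0.62, 1.0)

    def __post_init__(self) -> None:
        e = tuple(float(x) for x in self.edges)
        if len(e) != len(LAYER_NAMES) + 1:
            raise ValueError(f"expected {len(LAYER_NAMES) + 1} edges")
        if e[0] != 0.0 or e[-1] != 1.0:
            raise ValueError("edges must span [0, 1]")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("edges must increase strictly")
        object.__setattr__(self, "edges", e)

    def span(self, layer: str) -> tuple[float, float]:
        i = LAYER_NAMES.index(layer)
        return self.edges[i], self.edges[i + 1]

    def thickness_fractions(self) -> dict[str, float]:
        return {
            name: self.edges[i + 1] - self.edges[i]
            for i, name in enumerate(LAYER_NAMES)
        }

    def layer_of(self, depth: float) -> str | None:
        if not 0 <= depth < 1:
            return None
        for i, name in enumerate(LAYER_NAMES):
            if depth < self.edges[i + 1]:
                return name
        return None


DEFAULT_LAYER_BOUNDARIES = LayerBoundaries()


@dataclass
class ExpressionProfile:
    """Normalized fluorescence versus depth for one mouse line."""

    line_label: str
    depth_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depth_mm.shape != self.values.shape:
            raise ValueError("depth grid and values must match")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depth grid must increase strictly")
        if np.any(self.values < 0):
            raise ValueError("values must be >= 0")
        vmax = self.values.max()
        if vmax <= 0:
            raise ValueError("profile must be somewhere positive")
        self.values = self.values / vmax  # normalize to max = 1

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto a new depth grid (0 outside support)."""
        return np.interp(grid, self.depth_mm, self.values, left=0.0, right=0.0)


def load_section_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG grayscale section image as a float 2-D array."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        img = iio.imread(p)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse colour channels
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return img


def profile_from_section_image(
    image: np.ndarray,
    surface_row: int,
    wm_row: int,
    pixel_pitch_mm: float,
    strip_width_mm: float = 0.75,
    strip_center_col: int | None = None,
    line_label: str = "section",
) -> ExpressionProfile:
    """Extract an expression profile from a coronal-section image.

    Fluorescence is summed over a ``strip_width_mm``-wide strip of
    columns, perpendicular to the brain surface (rows parallel to the
    surface), between ``surface_row`` and ``wm_row``; the depth axis is
    rescaled linearly so those rows map to 0 and 1 mm, and the profile is
    normalized to its maximum (so it is invariant to global intensity
    scaling of the image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if not 0 <= surface_row < wm_row <= img.shape[0] - 1:
        raise ValueError("need 0 <= surface_row < wm_row within the image")
    half_px = max(1, int(round(strip_width_mm / pixel_pitch_mm / 2)))
    c = img.shape[1] // 2 if strip_center_col is None else int(strip_center_col)
    lo, hi = c - half_px, c + half_px
    if lo < 0 or hi > img.shape[1]:
        raise ValueError("strip does not fit laterally in the image")
    rows = img[surface_row : wm_row + 1, lo:hi]
    values = rows.sum(axis=1)
    if values.max() <= 0:
        raise ValueError("zero image in the sampled strip")
    depth = np.linspace(0.0, 1.0, values.size)  # wm_row maps exactly to 1 mm
    return ExpressionProfile(line_label=line_label, depth_mm=depth, values=values)


#: Somatic layers of the six GCaMP lines the generator emulates.
LINE_SOMATIC_LAYERS: dict[str, tuple[str, ...]] = {
    "Slc17a7-Ai93": ("L1", "L2/3", "L4", "L5", "L6"),  # all layers
    "Cux2-Ai93": ("L2/3", "L4"),  # layers 2-4
    "Rorb-Ai93": ("L4",),
    "Rbp4-Ai93": ("L5",),
    "Fezf2-Ai148": ("L5", "L6"),
    "Ntsr1-Ai148": ("L6",),
}


def synthetic_profile(
    line_label: str,
    somatic_layers: tuple[str, ...],
    soma_amplitude: float = 1.0,
    neuropil_baseline: float = 0.3,
    smoothing_scale: float = 0.04,
    boundaries: LayerBoundaries = DEFAULT_LAYER_BOUNDARIES,
    pitch: float = 0.01,
) -> ExpressionProfile:
    """Deterministic synthetic laminar profile: baseline + smoothed plateaus.

    ``soma_amplitude`` is the plateau height added over each somatic
    layer, ``neuropil_baseline`` the uniform dendrite/axon background,
    and ``smoothing_scale`` (mm) the Gaussian sigma blurring the layer
    edges. The result is sampled at ``pitch`` over [0, 1] mm and
    normalized to a maximum of 1. No randomness is involved.
    """
    unknown = set(somatic_layers) - set(LAYER_NAMES)
    if unknown:
        raise ValueError(f"unknown layers: {sorted(unknown)}")
    if not somatic_layers and neuropil_baseline <= 0:
        raise ValueError("empty somatic set with zero baseline")
    depth = np.arange(0.0, 1.0 + pitch / 2, pitch)
    values = np.full_like(depth, float(neuropil_baseline))
    plateau = np.zeros_like(depth)
    for layer in somatic_layers:
        lo, hi = boundaries.span(layer)
        plateau[(depth >= lo) & (depth < hi)] = float(soma_amplitude)
    if smoothing_scale > 0:
        plateau = gaussian_filter1d(plateau, sigma=smoothing_scale / pitch)
    values = values + plateau
    return ExpressionProfile(line_label=line_label, depth_mm=depth, values=values)


def line_profile(
    line_label: str,
    boundaries: LayerBoundaries = DEFAULT_LAYER_BOUNDARIES,
    **kwargs,
) -> ExpressionProfile:
    """Bundled synthetic preset for one of the six mouse lines."""
    try:
        layers = LINE_SOMATIC_LAYERS[line_label]
    except KeyError:
        raise ValueError(
            f"unknown line {line_label!r}; presets: {sorted(LINE_SOMATIC_LAYERS)}"
        ) from None
    return synthetic_profile(line_label, layers, boundaries=boundaries, **kwargs)
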