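"""Attribution of widefield fluorescence to cortical depths and volumes.

Steady-state widefield fluorescence from depth z is proportional to
W(z) = I(z) * E(z) * C(z): illumination intensity, indicator expression,
and collection efficiency, each as a function of depth. Integrating W
over the layer spans gives the percentage of total fluorescence (pia to
the layer-6/white-matter border) contributed by each layer. A linear
neuropil/soma mixture per layer converts these steady-state weights into
shares of the total fluorescence *change* under Delta-F/F scenarios, and
combining W with the per-pixel collection kernel K(z, r) maps the 3-D
volume of tissue feeding a single surface pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .collection import CollectionKernel
from .expression import (
    DEFAULT_LAYER_BOUNDARIES,
    LAYER_NAMES,
    ExpressionProfile,
    LayerBoundaries,
)

__all__ = [
    "FluorescenceWeighting",
    "fluorescence_by_depth",
    "DffScenario",
    "apply_dff_scenario",
    "cumulative_contour_volumes",
    "SourceVolumeMap",
    "source_volume_map",
]


@dataclass
class FluorescenceWeighting:
    """Depth-resolved fluorescence weight and per-layer percentages."""

    depth_mm: np.ndarray
    weights: np.ndarray
    layer_percentages: dict[str, float]
    boundaries: LayerBoundaries
    provenance: dict = field(default_factory=dict)


def _renormalize(shares: dict[str, float]) -> dict[str, float]:
    total = sum(shares.values())
    if total <= 0:
        raise ValueError("all layer weights are zero")
    out = {k: 100.0 * v / total for k, v in shares.items()}
    # force an exact sum of 100 against float rounding
    drift = 100.0 - sum(out.values())
    key = max(out, key=out.get)
    out[key] += drift
    return out


def fluorescence_by_depth(
    illumination: tuple[np.ndarray, np.ndarray],
    expr: ExpressionProfile,
    collection: tuple[np.ndarray, np.ndarray],
    boundaries: LayerBoundaries = DEFAULT_LAYER_BOUNDARIES,
    pitch: float = 0.01,
    provenance: dict | None = None,
) -> FluorescenceWeighting:
    """Pointwise product I(z)*E(z)*C(z) and per-layer percentages.

    ``illumination`` and ``collection`` are (depth_mm, value) curve pairs
    from the transport simulations; all three inputs are linearly
    resampled to a common grid over [0, 1] mm (pia to the layer-6 /
    white-matter border). Percentages are of the 0-1 mm total and sum to
    exactly 100; multiplying any input curve by a constant leaves them
    unchanged.
    """
    grid = np.arange(pitch / 2, 1.0, pitch)
    iz, iv = illumination
    cz, cv = collection
    i_res = np.interp(grid, np.asarray(iz, float), np.asarray(iv, float))
    c_res = np.interp(grid, np.asarray(cz, float), np.asarray(cv, float))
    e_res = expr.resample(grid)
    w = i_res * e_res * c_res
    if np.any(w < 0):
        raise ValueError("negative weights: check the input curves")
    shares = {}
    for name in LAYER_NAMES:
        lo, hi = boundaries.span(name)
        sel = (grid >= lo) & (grid < hi)
        shares[name] = float(w[sel].sum())
    return FluorescenceWeighting(
        depth_mm=grid,
        weights=w,
        layer_percentages=_renormalize(shares),
        boundaries=boundaries,
        provenance={"line": expr.line_label, **(provenance or {})},
    )


@dataclass(frozen=True)
class DffScenario:
    """Fractional-change scenario: per-layer neuropil volume fractions,
    the neuropil/soma Delta-F/F ratio, and a layer-1 multiplier.

    Defaults: neuropil fraction 0.994 in L1 and 0.8 (midpoint of the
    0.77-0.84 literature range) in deeper layers; ratio and multiplier 1
    reproduce the steady-state percentages.
    """

    neuropil_volume_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "L1": 0.994, "L2/3": 0.8, "L4": 0.8, "L5": 0.8, "L6": 0.8,
        }
    )
    dff_ratio_neuropil_over_soma: float = 1.0
    layer1_dff_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for k, f in self.neuropil_volume_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"neuropil fraction for {k} must be in [0, 1]")
        if self.dff_ratio_neuropil_over_soma <= 0 or self.layer1_dff_multiplier <= 0:
            raise ValueError("ratios/multipliers must be > 0")


def apply_dff_scenario(
    weighting: FluorescenceWeighting, scenario: DffScenario
) -> dict[str, float]:
    """Per-layer percentages of the total fluorescence change.

    Each layer's steady-state weight is multiplied by the linear mixture
    f_np * r_np + (1 - f_np), where f_np is the layer's neuropil volume
    fraction and r_np the neuropil/soma Delta-F/F ratio, and by the
    layer-1 multiplier for L1; the result is renormalized to 100%.
    """
    r = scenario.dff_ratio_neuropil_over_soma
    adjusted = {}
    for name, pct in weighting.layer_percentages.items():
        f_np = scenario.neuropil_volume_fraction.get(name, 0.8)
        factor = f_np * r + (1.0 - f_np)
        if name == "L1":
            factor *= scenario.layer1_dff_multiplier
        adjusted[name] = pct * factor
    return _renormalize(adjusted)


def cumulative_contour_volumes(
    values: np.ndarray,
    volumes: np.ndarray,
    fractions=(0.25, 0.5, 0.75, 0.9, 0.95),
) -> dict[float, float]:
    """Volume (mm^3) of the brightest cells that together contribute the
    given fractions of the total.

    ``values`` are per-unit-volume contribution densities of grid cells,
    ``volumes`` the cell volumes. Cells are ranked by density
    (descending, stable order) and accumulated greedily until the
    running contribution reaches the fraction; whole cells are counted,
    so the result is the volume of the smallest such set of cells.
    Equivalent to a flatten-and-sort oracle on a voxel grid.
    """
    values = np.asarray(values, dtype=float).ravel()
    volumes = np.asarray(volumes, dtype=float).ravel()
    if values.shape != volumes.shape:
        raise ValueError("values and volumes must match")
    if np.any(values < 0) or np.any(volumes < 0):
        raise ValueError("values and volumes must be >= 0")
    order = np.argsort(-values, kind="stable")
    v = values[order]
    vol = volumes[order]
    contrib = v * vol
    total = contrib.sum()
    if total <= 0:
        raise ValueError("total contribution is zero")
    cum = np.cumsum(contrib) / total
    cum_vol = np.cumsum(vol)
    out = {}
    for f in sorted(fractions):
        if not 0 < f < 1:
            raise ValueError("fractions must be in (0, 1)")
        i = int(np.searchsorted(cum, f))  # first cell index reaching f
        out[f] = float(cum_vol[i])
    return out


@dataclass
class SourceVolumeMap:
    """Contribution of each (r, z) cell to one surface pixel's signal."""

    depths: np.ndarray
    r_edges: np.ndarray
    #: per-voxel contribution density over the (depth, radius) grid
    density: np.ndarray
    #: annulus volume of each (depth, radius) cell (mm^3)
    cell_volumes: np.ndarray
    contour_volumes: dict[float, float]
    line_label: str


def source_volume_map(
    illumination: tuple[np.ndarray, np.ndarray],
    expr: ExpressionProfile,
    kernel: CollectionKernel,
    fractions=(0.25, 0.5, 0.75, 0.9, 0.95),
) -> SourceVolumeMap:
    """Volume of tissue from which photons reach one surface pixel.

    By lateral translation symmetry the surface-exit distribution of a
    point source at depth z equals the source-sensitivity profile of a
    surface pixel, so the per-voxel contribution at depth z and lateral
    distance r is I(z) * E(z) * k(z, r), with k the per-area collection
    kernel. Voxels are ranked by contribution and the cumulative-contour
    volumes evaluated at the requested fractions (25-95% by default).
    """
    iz, iv = illumination
    depths = kernel.depths
    dz = float(np.diff(depths).mean()) if depths.size > 1 else 0.01
    i_res = np.interp(depths, np.asarray(iz, float), np.asarray(iv, float))
    e_res = expr.resample(depths)
    k_area = kernel.area_density()  # (n_depth, n_r), mm^-2
    density = i_res[:, None] * e_res[:, None] * k_area
    annulus_area = math.pi * np.diff(kernel.r_edges**2)
    cell_volumes = np.broadcast_to(annulus_area[None, :] * dz, density.shape)
    contours = cumulative_contour_volumes(density, cell_volumes, fractions)
    return SourceVolumeMap(
        depths=depths,
        r_edges=kernel.r_edges,
        density=density,
        cell_volumes=np.array(cell_volumes),
        contour_volumes=contours,
        line_label=expr.line_label,
    )
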