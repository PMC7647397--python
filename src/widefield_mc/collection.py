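"""Fluorescence collection: point emitters, objective acceptance, surface spread.

Fluorescence photons (560 nm: mu_a = 0.26 mm^-1, mu_s = 10 mm^-1,
g = 0.89) are emitted isotropically from a point source at a chosen
depth and propagated until absorbed or exited. A photon contributes to
the image if it leaves the tissue surface within the objective's
acceptance cone (half-angle asin(NA), 5.74 degrees at NA 0.1) and inside
the field of view. The lateral exit positions of collected photons
define the surface "patch" of fluorescence whose quantile diameters
quantify the lateral point spread; by lateral translation symmetry the
same distribution, read per source depth, is the source-sensitivity
kernel of a single surface pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import RecorderSpec, TransportRun, run_photons
from .illumination import ObjectiveModel
from .scene import LayeredScene

__all__ = [
    "CollectionResult",
    "is_collected",
    "run_collection_from_point",
    "collection_efficiency_vs_depth",
    "surface_spread_quantiles",
    "CollectionKernel",
    "collection_kernel",
]


@dataclass
class CollectionResult:
    """Outcome of emitting photons from one point source."""

    source_depth: float
    source_xy: tuple[float, float]
    n_emitted: int
    emitted_weight: float
    collected_weight: float
    #: lateral exit positions (mm, at the z = 0 plane) of collected photons
    exit_positions: np.ndarray
    #: statistical weights of the collected photons
    collected_weights: np.ndarray
    seed: int

    @property
    def collected_fraction(self) -> float:
        return self.collected_weight / self.emitted_weight

    @property
    def n_collected(self) -> int:
        return int(self.exit_positions.shape[0])

    def radial_distances(self) -> np.ndarray:
        """Radial exit distance of each collected photon from the source."""
        dx = self.exit_positions[:, 0] - self.source_xy[0]
        dy = self.exit_positions[:, 1] - self.source_xy[1]
        return np.hypot(dx, dy)

    def exit_histogram(self, bin_width: float = 0.01, r_max: float = 5.5):
        """Radial histogram of collected weight in ``bin_width`` (mm) bins."""
        edges = np.arange(0.0, r_max + bin_width, bin_width)
        counts, _ = np.histogram(
            self.radial_distances(), bins=edges, weights=self.collected_weights
        )
        return edges, counts


def is_collected(
    exit_direction: np.ndarray,
    exit_position: np.ndarray,
    objective: ObjectiveModel,
    criterion: str = "aperture",
) -> bool:
    """Does an exiting photon enter the objective?

    Two acceptance criteria are implemented; both also require the
    lateral exit position to lie inside the field of view (vignetting
    gate):

    ``"aperture"`` (default)
        The exit ray reaches the objective's front window: its
        intersection with the front plane, one working distance above
        the surface, lies within the front-window radius. For the 2x
        objective (7 mm window, 56.3 mm working distance) an on-axis
        source sees a half-angle of atan(7/56.3) = 7.09 degrees; this
        physical acceptance is what the simulated collection
        efficiencies are quoted with.
    ``"cone"``
        The nominal numerical-aperture gate: angle to the surface
        normal within asin(NA) (5.74 degrees at NA 0.1). Used for
        NA-dependence comparisons.
    """
    ux, uy, uz = (float(c) for c in exit_direction)
    if uz >= 0:  # z is positive into tissue; an exiting photon has uz < 0
        raise ValueError("exit direction must point out of the tissue")
    x, y = (float(c) for c in exit_position)
    if math.hypot(x, y) > objective.field_of_view_diameter / 2.0:
        return False
    if criterion == "cone":
        return -uz >= objective.cos_theta_max
    if criterion == "aperture":
        t = objective.working_distance / (-uz)
        return math.hypot(x + ux * t, y + uy * t) <= objective.front_window_radius
    raise ValueError(f"unknown collection criterion {criterion!r}")


def _collected_mask(run: TransportRun, objective: ObjectiveModel,
                    criterion: str) -> np.ndarray:
    from . import _kernel as K

    top = run.status == K.ST_EXIT_TOP
    mask = top & (np.hypot(run.exit_x, run.exit_y)
                  <= objective.field_of_view_diameter / 2.0)
    if criterion == "cone":
        mask &= -run.exit_uz >= objective.cos_theta_max
    elif criterion == "aperture":
        t = objective.working_distance / np.where(run.exit_uz < 0, -run.exit_uz, 1.0)
        fx = run.exit_x + run.exit_ux * t
        fy = run.exit_y + run.exit_uy * t
        mask &= np.hypot(fx, fy) <= objective.front_window_radius
    else:
        raise ValueError(f"unknown collection criterion {criterion!r}")
    return mask


def run_collection_from_point(
    scene: LayeredScene,
    source_depth: float,
    objective: ObjectiveModel,
    n_photons: int,
    seed: int,
    wavelength: int = 560,
    source_xy: tuple[float, float] = (0.0, 0.0),
    criterion: str = "aperture",
) -> CollectionResult:
    """Emit ``n_photons`` isotropically from a point source and score
    which exit the surface into the objective's acceptance cone."""
    if not 0 <= source_depth <= scene.tissue_depth:
        raise ValueError("source depth must lie within the tissue")
    ss = np.random.SeedSequence(seed)
    s_launch, s_kernel = ss.spawn(2)
    rng = np.random.Generator(np.random.PCG64(s_launch))
    n = int(n_photons)
    cos_t = 1.0 - 2.0 * rng.random(n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = 2.0 * math.pi * rng.random(n)
    dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    # sources exactly at the surface or on a vessel wall: nudge into tissue
    z0 = max(source_depth, 1e-9)
    pos = np.tile(np.array([source_xy[0], source_xy[1], z0]), (n, 1))
    run = run_photons(
        scene, wavelength, pos, dirs,
        seed=int(s_kernel.generate_state(1, np.uint32)[0]),
        recorders=RecorderSpec(),
    )
    mask = _collected_mask(run, objective, criterion)
    return CollectionResult(
        source_depth=float(source_depth),
        source_xy=source_xy,
        n_emitted=n,
        emitted_weight=run.launched_weight,
        collected_weight=float(run.exit_w[mask].sum()),
        exit_positions=np.column_stack([run.exit_x[mask], run.exit_y[mask]]),
        collected_weights=run.exit_w[mask].copy(),
        seed=int(seed),
    )


def collection_efficiency_vs_depth(
    scene: LayeredScene,
    objective: ObjectiveModel,
    depth_grid: np.ndarray,
    n_photons_per_depth: int,
    seed: int,
    **kwargs,
) -> tuple[np.ndarray, np.ndarray, list[CollectionResult]]:
    """Percentage of emitted photons collected, per source depth.

    Returns (depths, percentages, per-depth CollectionResults). Each
    depth uses an independent child seed of ``seed``.
    """
    depths = np.asarray(depth_grid, dtype=float)
    if depths.min() < 0 or depths.max() > scene.tissue_depth:
        raise ValueError("depth grid must lie within the tissue")
    child_seeds = np.random.SeedSequence(seed).spawn(len(depths))
    results = []
    for d, cs in zip(depths, child_seeds):
        results.append(
            run_collection_from_point(
                scene, float(d), objective, n_photons_per_depth,
                seed=int(cs.generate_state(1, np.uint32)[0]), **kwargs,
            )
        )
    pct = np.array([100.0 * r.collected_fraction for r in results])
    return depths, pct, results


def surface_spread_quantiles(
    result: CollectionResult,
    fractions=(0.5, 0.95),
    min_collected: int = 100,
    convention: str = "marginal",
    bin_width: float | None = None,
) -> dict[float, float]:
    """Diameters of the surface patch enclosing given fractions of
    collected photons.

    ``convention="marginal"`` (default) works on the 1-D histogram of
    exit positions along one surface axis, the representation the
    surface distributions are reported in: the diameter for fraction f
    is the width of the central interval containing f of the collected
    weight, i.e. twice the weighted f-quantile of |x - x_source|.
    ``convention="radial"`` uses the radial exit distance instead (the
    2-D quantile; wider than the marginal for the same cloud).

    Quantiles interpolate linearly between order statistics; with
    ``bin_width`` set, the diameter is instead resolved on a histogram
    of that bin width (e.g. 0.01 mm) and rounded up to whole bins, never
    below one bin.
    """
    if result.n_collected < min_collected:
        raise ValueError(
            f"too few collected photons ({result.n_collected} < {min_collected})"
        )
    if convention == "marginal":
        r = np.abs(result.exit_positions[:, 0] - result.source_xy[0])
    elif convention == "radial":
        r = result.radial_distances()
    else:
        raise ValueError(f"unknown convention {convention!r}")
    w = result.collected_weights
    order = np.argsort(r, kind="stable")
    r = r[order]
    w = w[order]
    cum = np.cumsum(w) - 0.5 * w  # midpoint rule for weighted quantiles
    cum /= w.sum()
    out = {}
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError("fractions must be in (0, 1)")
        q = float(np.interp(f, cum, r))
        d = 2.0 * q
        if bin_width is not None:
            d = max(bin_width, bin_width * math.ceil(d / bin_width - 1e-9))
        out[f] = d
    return out


@dataclass
class CollectionKernel:
    """Per-depth radial profile of collected-photon surface arrivals.

    ``mass[i, j]`` is the collected weight fraction (of emitted) from
    source depth ``depths[i]`` arriving in the radial annulus
    ``[r_edges[j], r_edges[j+1])``; summing over j recovers the
    collected fraction at that depth. By translation symmetry this is
    also the sensitivity of one surface pixel to sources at depth
    ``depths[i]`` and lateral distance r.
    """

    depths: np.ndarray
    r_edges: np.ndarray
    mass: np.ndarray
    efficiency: np.ndarray  # collected fraction per depth

    def area_density(self) -> np.ndarray:
        """Mass per unit surface area (mm^-2) in each annulus."""
        areas = math.pi * np.diff(self.r_edges**2)
        return self.mass / areas[None, :]


def collection_kernel(
    scene: LayeredScene,
    objective: ObjectiveModel,
    depth_grid: np.ndarray,
    n_photons_per_depth: int,
    seed: int,
    r_max: float = 4.0,
    bin_width: float = 0.01,
    **kwargs,
) -> CollectionKernel:
    """Simulate point sources on a depth grid and histogram the surface
    arrival radii of collected photons."""
    depths, pct, results = collection_efficiency_vs_depth(
        scene, objective, depth_grid, n_photons_per_depth, seed, **kwargs
    )
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    mass = np.zeros((len(depths), len(edges) - 1))
    for i, res in enumerate(results):
        counts, _ = np.histogram(
            res.radial_distances(), bins=edges, weights=res.collected_weights
        )
        mass[i] = counts / res.emitted_weight
    return CollectionKernel(
        depths=depths, r_edges=edges, mass=mass, efficiency=pct / 100.0
    )
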