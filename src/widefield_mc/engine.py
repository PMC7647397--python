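"""High-level driver around the compiled transport kernel.

:func:`run_photons` takes a scene, a wavelength tag, and arrays of launch
states, runs the compiled walk, and returns a :class:`TransportRun` with
per-photon terminal states, optional fluence recorders, and the weight
tallies needed for energy-conservation accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .scene import LayeredScene
from .transport import MAX_STEPS, ROULETTE_SURVIVAL, WEIGHT_ROULETTE_THRESHOLD

__all__ = ["RecorderSpec", "TransportRun", "run_photons"]


@dataclass(frozen=True)
class RecorderSpec:
    """Which track-length recorders to fill during a run.

    depth_profile_radius : lateral radius (mm) of the central cylinder in
        which the z fluence/direction profile is tallied. The beam is
        uniform and far from the window rim there, so the laterally
        averaged profile equals the on-axis intensity-vs-depth curve.
    dz_plane : if set, (axis_x, axis_y, half_width_mm, half_length_mm) of
        a vertical slab recorder perpendicular to the given horizontal
        axis through the origin, binned at the voxel pitch in (d, z);
        used for under-vessel intensity columns.
    rz : if set, maximum radius (mm) of a cylindrical (r, z) fluence map.
    """

    depth_profile_radius: float = 2.0
    dz_plane: tuple[float, float, float, float] | None = None
    rz: float | None = None


@dataclass
class TransportRun:
    scene: LayeredScene
    wavelength: int
    seed: int
    n_photons: int
    status: np.ndarray
    exit_x: np.ndarray
    exit_y: np.ndarray
    exit_ux: np.ndarray
    exit_uy: np.ndarray
    exit_uz: np.ndarray
    exit_w: np.ndarray
    tallies: np.ndarray
    pitch: float
    fluence_z: np.ndarray
    fluence_z_cos: np.ndarray
    profile_radius: float
    fluence_dz: np.ndarray | None = None
    dz_plane: tuple[float, float, float, float] | None = None
    fluence_rz: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.fluence_z.size) + 0.5) * self.pitch

    @property
    def launched_weight(self) -> float:
        return float(self.tallies[K.T_LAUNCHED])

    @property
    def exited_top(self) -> np.ndarray:
        return self.status == K.ST_EXIT_TOP

    def energy_balance(self) -> dict:
        """launched vs deposited + exited + roulette_net + cap_killed."""
        t = self.tallies
        accounted = float(
            t[K.T_DEPOSITED] + t[K.T_EXIT_TOP] + t[K.T_EXIT_LAT]
            + t[K.T_EXIT_BOT] + t[K.T_ROULETTE] + t[K.T_CAP_KILLED]
        )
        return {
            "launched": float(t[K.T_LAUNCHED]),
            "deposited": float(t[K.T_DEPOSITED]),
            "exited_top": float(t[K.T_EXIT_TOP]),
            "exited_lateral": float(t[K.T_EXIT_LAT]),
            "exited_bottom": float(t[K.T_EXIT_BOT]),
            "roulette_net": float(t[K.T_ROULETTE]),
            "cap_killed": float(t[K.T_CAP_KILLED]),
            "cap_count": int(t[K.T_CAP_COUNT]),
            "accounted": accounted,
        }


def run_photons(
    scene: LayeredScene,
    wavelength: int,
    positions: np.ndarray,
    directions: np.ndarray,
    seed: int,
    weights: np.ndarray | None = None,
    recorders: RecorderSpec | None = None,
) -> TransportRun:
    """Propagate an array of launch states through the scene.

    ``positions`` and ``directions`` are (n, 3) arrays (mm / unit
    vectors); ``seed`` drives the kernel's internal random stream, so
    identical inputs give bit-identical outputs.
    """
    rec = recorders or RecorderSpec()
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    dirs = np.ascontiguousarray(directions, dtype=np.float64)
    n = pos.shape[0]
    if dirs.shape != pos.shape:
        raise ValueError("positions and directions must have the same shape")
    norms = np.linalg.norm(dirs, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise ValueError("directions must be unit vectors")
    w0 = (
        np.ones(n) if weights is None
        else np.ascontiguousarray(weights, dtype=np.float64)
    )

    gm = scene.props_for(wavelength)
    sk = scene.skull_props
    v_nx = np.array([v.normal[0] for v in scene.vessels], dtype=np.float64)
    v_ny = np.array([v.normal[1] for v in scene.vessels], dtype=np.float64)
    v_off = np.array([v.offset for v in scene.vessels], dtype=np.float64)
    v_r = np.array([v.radius for v in scene.vessels], dtype=np.float64)

    pitch = scene.voxel_pitch
    nz = scene.n_depth_bins
    fl_z = np.zeros(nz)
    fl_z_cos = np.zeros(nz)

    if rec.dz_plane is not None:
        ax, ay, dmax, yhalf = rec.dz_plane
        nrm = math.hypot(ax, ay)
        ax, ay = ax / nrm, ay / nrm
        nd = 2 * int(round(dmax / pitch)) + 1  # central bin centred on d = 0
        fl_dz = np.zeros((nd, nz))
        rec_dz = True
    else:
        ax = 0.0
        ay = 1.0
        dmax = 0.0
        yhalf = 0.0
        fl_dz = np.zeros((1, 1))
        rec_dz = False

    if rec.rz is not None:
        nr = int(round(rec.rz / pitch))
        fl_rz = np.zeros((nr, nz))
        rec_rz = True
    else:
        fl_rz = np.zeros((1, 1))
        rec_rz = False

    status = np.zeros(n, dtype=np.int64)
    exit_x = np.zeros(n)
    exit_y = np.zeros(n)
    exit_ux = np.zeros(n)
    exit_uy = np.zeros(n)
    exit_uz = np.zeros(n)
    exit_w = np.zeros(n)
    tallies = np.zeros(K.N_TALLIES)

    K.run_kernel(
        np.int64(seed % (2**31)),
        pos[:, 0].copy(), pos[:, 1].copy(), pos[:, 2].copy(),
        dirs[:, 0].copy(), dirs[:, 1].copy(), dirs[:, 2].copy(), w0,
        scene.volume_radius, scene.tissue_depth,
        scene.coverslip_radius, scene.coverslip_thickness, scene.skull_thickness,
        gm.mu_a, gm.mu_s, gm.g, sk.mu_a, sk.mu_s, sk.g,
        v_nx, v_ny, v_off, v_r,
        pitch, rec.depth_profile_radius, fl_z, fl_z_cos,
        rec_dz, ax, ay, dmax, yhalf, fl_dz,
        rec_rz, float(rec.rz or 0.0), fl_rz,
        WEIGHT_ROULETTE_THRESHOLD, ROULETTE_SURVIVAL, MAX_STEPS,
        status, exit_x, exit_y, exit_ux, exit_uy, exit_uz, exit_w,
        tallies,
    )
    return TransportRun(
        scene=scene,
        wavelength=wavelength,
        seed=int(seed),
        n_photons=n,
        status=status,
        exit_x=exit_x,
        exit_y=exit_y,
        exit_ux=exit_ux,
        exit_uy=exit_uy,
        exit_uz=exit_uz,
        exit_w=exit_w,
        tallies=tallies,
        pitch=pitch,
        fluence_z=fl_z,
        fluence_z_cos=fl_z_cos,
        profile_radius=rec.depth_profile_radius,
        fluence_dz=fl_dz if rec_dz else None,
        dz_plane=rec.dz_plane,
        fluence_rz=fl_rz if rec_rz else None,
    )
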