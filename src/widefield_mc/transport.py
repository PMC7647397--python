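"""Random-walk photon transport: step sampling, Henyey-Greenstein
scattering, and a reference single-packet propagator.

Weighted-packet (MCML-style) transport: at each interaction a packet
deposits ``weight * mu_a / mu_t`` locally and continues with its weight
multiplied by the single-scattering albedo, sampling a Henyey-Greenstein
deflection. Packets whose weight falls below a threshold play Russian
roulette (survival probability p, surviving weight divided by p), which
terminates deep histories without bias. Boundary crossings between media
re-sample the remaining optical depth in the new medium, the standard
unbiased treatment of layered geometries. Interfaces are index-matched:
no Fresnel reflection or refraction, directions cross boundaries
unchanged.

:func:`propagate` here is the plainly-written reference implementation
used by the tests and for small-n exploration; the production runs in
:mod:`widefield_mc.illumination` and :mod:`widefield_mc.collection` use
the compiled kernel in :mod:`widefield_mc._kernel`, which implements the
same walk.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .optics import OpticalProperties
from .scene import VESSEL_ABSORBER, LayeredScene, distance_to_boundary, medium_at

__all__ = [
    "PhotonStatus",
    "PhotonPacket",
    "RandomStream",
    "NonInteractingMediumError",
    "sample_step_length",
    "sample_hg_deflection",
    "rotate_direction",
    "propagate",
    "DepthRecorder",
    "WEIGHT_ROULETTE_THRESHOLD",
    "ROULETTE_SURVIVAL",
    "MAX_STEPS",
]

#: Packet weight below which Russian roulette is played.
WEIGHT_ROULETTE_THRESHOLD = 1e-4
#: Roulette survival probability; survivors' weight is divided by this.
ROULETTE_SURVIVAL = 0.1
#: Hard cap on interactions per packet (guards non-absorbing configs).
MAX_STEPS = 10**5

_BOUNDARY_NUDGE = 1e-7  # mm; pushes a packet cleanly across a boundary


class PhotonStatus(enum.Enum):
    PROPAGATING = "propagating"
    ABSORBED = "absorbed"
    EXITED_TOP = "exited_top"
    EXITED_LATERAL = "exited_lateral"
    EXITED_BOTTOM = "exited_bottom"
    KILLED = "killed"  # step-count cap exceeded


@dataclass
class PhotonPacket:
    """Position (mm; z >= 0 is depth below the tissue surface), unit
    direction, and statistical weight of a propagating packet."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    status: PhotonStatus = PhotonStatus.PROPAGATING
    #: lateral position of the last upward crossing of the z = 0 plane
    surface_exit_xy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).copy()
        self.direction = np.asarray(self.direction, dtype=float).copy()
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")


class RandomStream:
    """Seeded random-number stream; identical seeds give identical walks."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.generator = np.random.Generator(np.random.PCG64(self.seed))

    def uniform(self) -> float:
        return float(self.generator.random())

    def spawn(self, n: int) -> list["RandomStream"]:
        """Independent child streams, reproducibly derived from the seed."""
        children = np.random.SeedSequence(self.seed).spawn(n)
        return [RandomStream(int(c.generate_state(1, np.uint32)[0])) for c in children]


class NonInteractingMediumError(ValueError):
    """The medium has mu_a + mu_s = 0; free paths are infinite and the
    caller must handle straight-line transit to the next boundary."""


def sample_step_length(props: OpticalProperties, u: float) -> float:
    """Exponential free path: s = -ln(u) / (mu_a + mu_s), u in (0, 1)."""
    if props.mu_t <= 0:
        raise NonInteractingMediumError("mu_a + mu_s = 0")
    if not 0 < u < 1:
        raise ValueError("u must be in (0, 1)")
    return -math.log(u) / props.mu_t


def sample_hg_deflection(g: float, u: float) -> float:
    """Cosine of a Henyey-Greenstein deflection angle via the inverse CDF.

    For g != 0, cos(theta) = (1 + g^2 - ((1 - g^2)/(1 - g + 2 g u))^2) / (2 g);
    isotropic (g = 0) reduces to cos(theta) = 2u - 1. E[cos(theta)] = g.
    """
    if not abs(g) < 1:
        raise ValueError("|g| must be < 1")
    if abs(g) < 1e-12:
        ct = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


def rotate_direction(
    direction: np.ndarray, cos_theta: float, phi: float
) -> np.ndarray:
    """Deflect a unit vector by angle acos(cos_theta) at azimuth phi.

    Standard spherical rotation with a stable branch when the direction
    is nearly parallel to the z axis.
    """
    ux, uy, uz = (float(c) for c in direction)
    n = math.sqrt(ux * ux + uy * uy + uz * uz)
    if abs(n - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    ct = min(1.0, max(-1.0, cos_theta))
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        out = np.array([st * cp, st * sp, ct * math.copysign(1.0, uz)])
    else:
        den = math.sqrt(1.0 - uz * uz)
        out = np.array(
            [
                st * (ux * uz * cp - uy * sp) / den + ux * ct,
                st * (uy * uz * cp + ux * sp) / den + uy * ct,
                -st * cp * den + uz * ct,
            ]
        )
    return out / np.linalg.norm(out)


@dataclass
class DepthRecorder:
    """Track-length fluence tally per depth bin within a lateral radius.

    ``fluence[i]`` accumulates weight x path length (mm) for track in the
    depth bin [i*pitch, (i+1)*pitch); ``cos_sum[i]`` additionally weights
    by the z direction cosine, so ``cos_sum / fluence`` is the
    track-length-weighted mean propagation-angle cosine.
    """

    pitch: float
    n_bins: int
    radius: float = math.inf
    fluence: np.ndarray = field(init=False)
    cos_sum: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fluence = np.zeros(self.n_bins)
        self.cos_sum = np.zeros(self.n_bins)

    def record_segment(
        self, x: float, y: float, z: float,
        ux: float, uy: float, uz: float,
        length: float, weight: float,
    ) -> None:
        """Split a straight segment across depth bins and tally each part."""
        if length <= 0:
            return
        if abs(uz) < 1e-12:
            iz = int(math.floor(z / self.pitch))
            tm = 0.5 * length
            if 0 <= iz < self.n_bins and math.hypot(x + ux * tm, y + uy * tm) < self.radius:
                self.fluence[iz] += weight * length
                self.cos_sum[iz] += weight * length * uz
            return
        # iterate bin indices so progress is guaranteed at bin edges
        inv = 1.0 / uz
        iz = int(math.floor(z / self.pitch))
        t = 0.0
        while True:
            tb = (((iz + 1) * self.pitch - z) if uz > 0 else (iz * self.pitch - z)) * inv
            t_next = min(tb, length)
            seg = t_next - t
            if seg > 0:
                tm = 0.5 * (t + t_next)
                if 0 <= iz < self.n_bins and math.hypot(x + ux * tm, y + uy * tm) < self.radius:
                    self.fluence[iz] += weight * seg
                    self.cos_sum[iz] += weight * seg * uz
            if t_next >= length:
                break
            t = t_next
            iz += 1 if uz > 0 else -1


def propagate(
    packet: PhotonPacket,
    scene: LayeredScene,
    rng: RandomStream,
    recorder: DepthRecorder | None = None,
    wavelength: int = 480,
    weight_threshold: float = WEIGHT_ROULETTE_THRESHOLD,
    roulette_survival: float = ROULETTE_SURVIVAL,
    max_steps: int = MAX_STEPS,
    tallies: dict | None = None,
) -> PhotonPacket:
    """Walk one packet to termination; reference implementation.

    Returns the packet with terminal status. ``tallies``, if given, is
    updated in place with deposited / exited / roulette-balance weights so
    that launched = deposited + exited + roulette_net (+ cap-killed)
    exactly, up to float rounding.
    """
    if packet.status is not PhotonStatus.PROPAGATING:
        raise ValueError("packet is not propagating")
    t = tallies if tallies is not None else {}
    for key in ("deposited", "exited_top", "exited_lateral", "exited_bottom",
                "roulette_net", "cap_killed", "cap_count"):
        t.setdefault(key, 0.0)

    x, y, z = (float(c) for c in packet.position)
    ux, uy, uz = (float(c) for c in packet.direction)
    w = packet.weight
    exit_xy = packet.surface_exit_xy or (x, y)
    tau = -math.log(rng.uniform())

    for _ in range(max_steps):
        med = medium_at(scene, (x, y, z), wavelength)
        if med is None:
            if math.hypot(x, y) >= scene.volume_radius:
                packet.status = PhotonStatus.EXITED_LATERAL
                t["exited_lateral"] += w
            elif z > 0:
                packet.status = PhotonStatus.EXITED_BOTTOM
                t["exited_bottom"] += w
            else:
                packet.status = PhotonStatus.EXITED_TOP
                t["exited_top"] += w
            break
        if med is VESSEL_ABSORBER:
            t["deposited"] += w
            w = 0.0
            packet.status = PhotonStatus.ABSORBED
            break

        mu_t = med.mu_t
        db = distance_to_boundary(scene, (x, y, z), (ux, uy, uz)) + _BOUNDARY_NUDGE
        s = tau / mu_t if mu_t > 0 else math.inf
        step = min(s, db)
        in_tissue = z >= 0 and med is not VESSEL_ABSORBER
        if recorder is not None and in_tissue:
            recorder.record_segment(x, y, z, ux, uy, uz, step, w)
        if uz < 0 and z > 0 and z + uz * step <= 0:
            t0 = -z / uz
            exit_xy = (x + ux * t0, y + uy * t0)
        x += ux * step
        y += uy * step
        z += uz * step

        if s < db:  # interaction
            t["deposited"] += w * med.mu_a / mu_t
            w *= med.mu_s / mu_t
            if w <= 0.0:  # fully absorbing medium: nothing left to scatter
                packet.status = PhotonStatus.ABSORBED
                break
            ct = sample_hg_deflection(med.g, rng.uniform())
            phi = 2.0 * math.pi * rng.uniform()
            ux, uy, uz = rotate_direction(np.array([ux, uy, uz]), ct, phi)
            tau = -math.log(rng.uniform())
            if w < weight_threshold:
                if rng.uniform() < roulette_survival:
                    boosted = w / roulette_survival
                    t["roulette_net"] += w - boosted
                    w = boosted
                else:
                    t["roulette_net"] += w
                    w = 0.0
                    packet.status = PhotonStatus.ABSORBED
                    break
        else:  # boundary crossing: re-sample remaining optical depth
            tau -= step * mu_t
            if tau <= 0:
                tau = 1e-12
    else:
        packet.status = PhotonStatus.KILLED
        t["cap_killed"] += w
        t["cap_count"] += 1

    packet.position = np.array([x, y, z])
    packet.direction = np.array([ux, uy, uz])
    packet.weight = w
    packet.surface_exit_xy = exit_xy
    return packet
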