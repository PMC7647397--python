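"""Optical properties of the media in the model.

All lengths are millimetres; absorption and scattering coefficients are
mm^-1. Literature values for in vivo grey matter and skull are bundled as
module-level constants, keyed by the two wavelengths the model uses: 480 nm
(excitation, GFP-family indicators) and 560 nm (green-yellow emission).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OpticalProperties",
    "transport_length",
    "GREY_MATTER_480",
    "GREY_MATTER_560",
    "GREY_MATTER_480_HIGH_SCATTER",
    "SKULL",
    "GLASS",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption/scattering coefficients and anisotropy of one medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (mm^-1), >= 0.
    mu_s : float
        Scattering coefficient (mm^-1), >= 0.
    g : float
        Scattering anisotropy, the mean cosine of the single-scattering
        deflection angle, |g| < 1. g -> 1 is strongly forward scattering.
    """

    mu_a: float
    mu_s: float
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not abs(self.g) < 1:
            raise ValueError(f"|g| must be < 1, got {self.g}")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def albedo(self) -> float:
        """Single-scattering albedo mu_s / (mu_a + mu_s)."""
        if self.mu_t == 0:
            raise ValueError("albedo undefined for a non-interacting medium")
        return self.mu_s / self.mu_t

    @property
    def mean_free_path(self) -> float:
        """Mean distance between interactions, 1 / (mu_a + mu_s) (mm)."""
        if self.mu_t == 0:
            return math.inf
        return 1.0 / self.mu_t

    @property
    def interacting(self) -> bool:
        return self.mu_t > 0


def transport_length(props: OpticalProperties) -> float:
    """Transport (direction-randomisation) length (1/mu_s)/(1-g) in mm.

    The distance over which scattering randomises the propagation
    direction; for grey matter at 480 nm (mu_s = 11 mm^-1, g = 0.89) this
    is 0.826 mm.

    Raises
    ------
    ValueError
        If the medium does not scatter (mu_s = 0), for which the transport
        length is infinite.
    """
    if props.mu_s == 0:
        raise ValueError("transport length is infinite for mu_s = 0")
    return (1.0 / props.mu_s) / (1.0 - props.g)


#: Grey matter at 480 nm excitation (in vivo human values).
GREY_MATTER_480 = OpticalProperties(mu_a=0.37, mu_s=11.0, g=0.89)

#: Grey matter at 560 nm emission.
GREY_MATTER_560 = OpticalProperties(mu_a=0.26, mu_s=10.0, g=0.89)

#: Grey matter with the higher scattering coefficient reported for mouse
#: cortical slices at 473 nm (mu_s = 21.1 mm^-1).
GREY_MATTER_480_HIGH_SCATTER = OpticalProperties(mu_a=0.37, mu_s=21.1, g=0.89)

#: Cranial bone.
SKULL = OpticalProperties(mu_a=0.12, mu_s=35.0, g=0.9)

#: Coverslip glass, modelled as non-scattering and non-absorbing.
GLASS = OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.0)
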