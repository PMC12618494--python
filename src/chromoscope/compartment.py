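"""Diffusion-lifetime model of the semi-open microfluidic compartment.

A flat circular chamber (radius ``R``, height ``h``) exchanges material with
the flow channels only through a thin capillary (length ``L``, width ``W``),
so transport is purely diffusive. The mean residence time of a species with
diffusion coefficient ``D`` is

    tau = pi * R**2 * L / (2 * D * W)

i.e. the chamber volume divided by the diffusive conductance of the
capillary. Units are fixed at micrometres, seconds and um^2/s throughout;
minutes appear only in reporting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = [
    "CompartmentGeometry",
    "LifetimeResult",
    "compartment_lifetime",
    "solve_radius_for_lifetime",
]


def _require_positive(name: str, value: float) -> float:
    if not (value > 0) or not math.isfinite(value):
        raise DomainError(f"{name} must be strictly positive, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class CompartmentGeometry:
    """Layout of one semi-open compartment (all lengths in um).

    ``radius_um`` is the chamber radius R; ``capillary_length_um`` and
    ``capillary_width_um`` are L and W of the exchange capillary. The chamber
    height and the constriction height of the cell-trapping capillary do not
    enter the lifetime formula but are part of the physical layout.
    """

    radius_um: float
    capillary_length_um: float
    capillary_width_um: float
    chamber_height_um: float = 1.5
    constriction_height_um: float = 0.4

    def __post_init__(self) -> None:
        for name in (
            "radius_um",
            "capillary_length_um",
            "capillary_width_um",
            "chamber_height_um",
            "constriction_height_um",
        ):
            _require_positive(name, getattr(self, name))
        if not self.capillary_width_um < 2 * self.radius_um:
            raise DomainError(
                "capillary_width_um must be smaller than the compartment diameter "
                f"(W={self.capillary_width_um}, 2R={2 * self.radius_um})"
            )


@dataclass(frozen=True)
class LifetimeResult:
    """Diffusive residence time of one species in one compartment layout."""

    lifetime_s: float
    diffusion_um2_per_s: float
    geometry: CompartmentGeometry = field(repr=False)

    @property
    def lifetime_min(self) -> float:
        return self.lifetime_s / 60.0


def compartment_lifetime(
    geometry: CompartmentGeometry, diffusion_um2_per_s: float
) -> LifetimeResult:
    """Mean residence time tau = pi R^2 L / (2 D W) of a diffusing species.

    Parameters
    ----------
    geometry:
        Compartment layout.
    diffusion_um2_per_s:
        Diffusion coefficient D of the species, um^2/s. Must be > 0.
    """
    d = _require_positive("diffusion_um2_per_s", diffusion_um2_per_s)
    g = geometry
    tau = (
        math.pi
        * g.radius_um**2
        * g.capillary_length_um
        / (2.0 * d * g.capillary_width_um)
    )
    return LifetimeResult(lifetime_s=tau, diffusion_um2_per_s=d, geometry=g)


def solve_radius_for_lifetime(
    target_lifetime_s: float,
    diffusion_um2_per_s: float,
    capillary_length_um: float,
    capillary_width_um: float,
) -> float:
    """Chamber radius (um) giving a target residence time; inverts the lifetime formula.

    R = sqrt(2 D W tau / (pi L)). Useful when designing a layout around a
    required retention time for a species of known mobility.
    """
    tau = _require_positive("target_lifetime_s", target_lifetime_s)
    d = _require_positive("diffusion_um2_per_s", diffusion_um2_per_s)
    length = _require_positive("capillary_length_um", capillary_length_um)
    width = _require_positive("capillary_width_um", capillary_width_um)
    return math.sqrt(2.0 * d * width * tau / (math.pi * length))
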