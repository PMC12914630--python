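"""Diffusive EV transport through neurofluidic junction channels.

The neurofluidic device connects somatic culture wells to a peripheric
channel through junction channels 5 µm high and 557-1353 µm long. With no
flow, vesicles cross by Brownian motion: the Stokes-Einstein relation
D = k_B T / (6 pi eta r) gives the diffusion coefficient of a particle of
hydrodynamic radius r in a medium of viscosity eta, and the 1-D
two-reservoir scaling t = L^2 / (2 D) estimates the channel transit time.
Steady-state transport is estimated with Fick's first law, and the fraction
of particles that have arrived by time t with the semi-infinite 1-D
solution erfc(L / (2 sqrt(D t))). These are deliberately simple textbook
models: no convection, entrance effects or 3-D geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import erfc

__all__ = [
    "BOLTZMANN_J_PER_K",
    "ChannelGeometry",
    "MediumSpec",
    "diffusion_coefficient",
    "diffusion_time",
    "steady_flux",
    "fraction_arrived",
]

BOLTZMANN_J_PER_K = 1.380649e-23


def _positive(x: float, what: str) -> float:
    x = float(x)
    if not math.isfinite(x) or x <= 0:
        raise ValueError(f"{what} must be positive and finite, got {x!r}")
    return x


@dataclass(frozen=True)
class ChannelGeometry:
    """Junction-channel geometry, µm (device: height 5, lengths 557-1353)."""

    length_um: float = 557.0
    height_um: float = 5.0
    width_um: float = 10.0

    def __post_init__(self) -> None:
        for name in ("length_um", "height_um", "width_um"):
            _positive(getattr(self, name), name)

    @property
    def cross_section_m2(self) -> float:
        return (self.height_um * 1e-6) * (self.width_um * 1e-6)

    @property
    def length_m(self) -> float:
        return self.length_um * 1e-6


@dataclass(frozen=True)
class MediumSpec:
    """Suspending medium (defaults: water at culture temperature, 37 °C)."""

    temperature_K: float = 310.15
    viscosity_Pa_s: float = 6.9e-4

    def __post_init__(self) -> None:
        _positive(self.temperature_K, "temperature_K")
        _positive(self.viscosity_Pa_s, "viscosity_Pa_s")


def diffusion_coefficient(r_nm: float, medium: MediumSpec | None = None) -> float:
    """Stokes-Einstein D = k_B T / (6 pi eta r), in m^2/s, for radius in nm."""
    r = _positive(r_nm, "radius") * 1e-9
    medium = medium or MediumSpec()
    return BOLTZMANN_J_PER_K * medium.temperature_K \
        / (6.0 * math.pi * medium.viscosity_Pa_s * r)


def diffusion_time(geometry: ChannelGeometry, d_m2_s: float) -> float:
    """Characteristic 1-D channel transit time t = L^2 / (2 D), seconds."""
    d = _positive(d_m2_s, "diffusion coefficient")
    return geometry.length_m ** 2 / (2.0 * d)


def steady_flux(geometry: ChannelGeometry, d_m2_s: float,
                concentration_difference_per_m3: float) -> float:
    """Fick's-first-law steady rate J = D * A * dC / L, particles/s."""
    d = _positive(d_m2_s, "diffusion coefficient")
    dc = float(concentration_difference_per_m3)
    if not math.isfinite(dc) or dc < 0:
        raise ValueError("concentration difference must be finite and >= 0")
    return d * geometry.cross_section_m2 * dc / geometry.length_m


def fraction_arrived(geometry: ChannelGeometry, d_m2_s: float, t_s: float) -> float:
    """Fraction of source-side particles past distance L by time t.

    Semi-infinite 1-D solution: C(L, t)/C0 = erfc(L / (2 sqrt(D t))).
    """
    d = _positive(d_m2_s, "diffusion coefficient")
    t = _positive(t_s, "time")
    return float(erfc(geometry.length_m / (2.0 * math.sqrt(d * t))))
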