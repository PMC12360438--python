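"""Ultrasound-microbubble sonopermeation laws.

Sonopermeation transiently enlarges the pores of the tumor vessel wall
and exerts a microstreaming shear stress on the endothelium. This
module implements the empirical laws tying the transducer settings to
those two effects:

* acoustic pressure from the mechanical index and frequency,
  ``p_ac = MI * sqrt(fr)`` (MPa for fr in MHz);
* an experimentally fitted quadratic mapping acoustic pressure (MPa)
  to vessel-wall pore radius (nm), clamped to a physical range;
* the Nyborg-type microstreaming wall shear stress of an oscillating
  shelled microbubble near the endothelium;
* fitted quadratics converting that shear stress into multiplicative
  modulation factors for endothelial proliferation and apoptosis;
* the temporal envelope of a sonopermeation application (the pore
  dilation persists for up to ~6 h after the pulse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MicrobubbleParams",
    "SonoPulse",
    "PoreLaw",
    "acoustic_pressure",
    "pore_radius",
    "pore_radius_raw",
    "wall_shear_stress",
    "proliferation_factor",
    "apoptosis_factor",
    "sono_effect",
    "PROLIFERATION_AT_REST",
    "APOPTOSIS_AT_REST",
]

#: Eq-of-fit coefficients for the pore-radius law (nm as a function of
#: acoustic pressure in MPa).
PORE_QUAD_COEFF = -14977.9087
PORE_LIN_COEFF = 8208.3947
PORE_CONST_COEFF = -69.0722

#: Proliferation / apoptosis modulation quadratics (tau in Pa).
PROLIF_COEFFS = (-3e-6, 0.0067, 0.2533)
APOPT_COEFFS = (-3e-5, 0.0126, 0.6666)

#: Values of the fitted quadratics at zero shear stress; vascular
#: dynamics normalize by these so that "no ultrasound" means a neutral
#: modulation factor of 1.
PROLIFERATION_AT_REST = PROLIF_COEFFS[2]
APOPTOSIS_AT_REST = APOPT_COEFFS[2]


@dataclass(frozen=True)
class MicrobubbleParams:
    """Physical parameters of the oscillating shelled microbubble.

    The surrounding liquid is blood. ``wall_displacement_amplitude`` is
    the amplitude of the radial oscillation of the bubble wall and
    ``equilibrium_radius`` its resting radius.
    """

    liquid_density: float = 1050.0          # kg/m^3
    liquid_viscosity: float = 3.0e-3        # Pa s
    wall_displacement_amplitude: float = 5.0e-8   # m
    equilibrium_radius: float = 1.0e-6      # m

    def __post_init__(self) -> None:
        for name in ("liquid_density", "liquid_viscosity",
                     "equilibrium_radius"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"microbubble parameter {name} must be > 0")
        if self.wall_displacement_amplitude < 0.0:
            raise ValueError("wall_displacement_amplitude must be >= 0")


@dataclass(frozen=True)
class SonoPulse:
    """One sonopermeation application and its effect window."""

    mechanical_index: float = 0.4
    frequency: float = 1.0          # MHz
    start_time: float = 0.0         # hours from simulation start
    effect_duration: float = 6.0    # hours
    microbubble: MicrobubbleParams = field(default_factory=MicrobubbleParams)

    def __post_init__(self) -> None:
        if self.mechanical_index < 0.0:
            raise ValueError("mechanical_index must be >= 0")
        if self.frequency <= 0.0:
            raise ValueError("frequency must be > 0")
        if self.effect_duration <= 0.0:
            raise ValueError("effect_duration must be > 0")


@dataclass(frozen=True)
class PoreLaw:
    """Quadratic pore-radius law with clamping to a physical range.

    The raw fit is negative at zero pressure and beyond ~0.55 MPa, so
    the effective pore radius is clamped to
    [baseline_pore_radius, max_pore_radius].
    """

    quad_coeff: float = PORE_QUAD_COEFF     # nm / MPa^2
    lin_coeff: float = PORE_LIN_COEFF       # nm / MPa
    const_coeff: float = PORE_CONST_COEFF   # nm
    baseline_pore_radius: float = 100.0     # nm, resting tumor-vessel pore
    max_pore_radius: float = 1250.0         # nm

    def __post_init__(self) -> None:
        if self.baseline_pore_radius <= 0.0:
            raise ValueError("baseline_pore_radius must be > 0")
        if self.max_pore_radius < self.baseline_pore_radius:
            raise ValueError("max_pore_radius must be >= baseline_pore_radius")


def acoustic_pressure(pulse: SonoPulse) -> float:
    """Peak acoustic pressure in MPa: MI times sqrt(frequency in MHz)."""
    return pulse.mechanical_index * math.sqrt(pulse.frequency)


def pore_radius_raw(p_ac: float, law: PoreLaw = PoreLaw()) -> float:
    """Unclamped quadratic pore-radius fit (nm), valid near 0.2-0.5 MPa."""
    return (law.quad_coeff * p_ac + law.lin_coeff) * p_ac + law.const_coeff


def pore_radius(p_ac: float, law: PoreLaw = PoreLaw()) -> float:
    """Effective vessel-wall pore radius (nm) at acoustic pressure p_ac.

    Evaluates the fitted quadratic and clamps the result into
    [baseline, max]; pressures outside the fitted range therefore fall
    back to the resting pore radius rather than the unphysical negative
    values of the raw polynomial.
    """
    if p_ac < 0.0:
        raise ValueError("acoustic pressure must be >= 0")
    raw = pore_radius_raw(p_ac, law)
    return min(max(raw, law.baseline_pore_radius), law.max_pore_radius)


def wall_shear_stress(pulse: SonoPulse) -> float:
    """Microstreaming shear stress (Pa) exerted on the endothelium.

    tau = sqrt(2 rho_L mu_L) * (2 pi fr)^{3/2} * eta_m^2 / R_0 with the
    frequency converted to Hz. The scalings tau ~ eta_m^2, fr^{3/2},
    1/R_0 and sqrt(rho_L mu_L) are the load-bearing structure; the
    dimensionless prefactor is taken as 1.
    """
    mb = pulse.microbubble
    fr_hz = pulse.frequency * 1e6
    return (
        math.sqrt(2.0 * mb.liquid_density * mb.liquid_viscosity)
        * (2.0 * math.pi * fr_hz) ** 1.5
        * mb.wall_displacement_amplitude**2
        / mb.equilibrium_radius
    )


def _quad(coeffs: tuple[float, float, float], tau: float) -> float:
    a, b, c = coeffs
    return (a * tau + b) * tau + c


def proliferation_factor(tau: float) -> float:
    """Endothelial proliferation modulation at wall shear stress tau (Pa).

    Fitted quadratic, floored at 0 (the fit goes negative at very
    large stresses, where a negative proliferation multiplier would be
    unphysical). Multiplies the endothelial proliferation term.
    """
    if tau < 0.0:
        raise ValueError("shear stress must be >= 0")
    return max(_quad(PROLIF_COEFFS, tau), 0.0)


def apoptosis_factor(tau: float) -> float:
    """Endothelial apoptosis modulation at wall shear stress tau (Pa)."""
    if tau < 0.0:
        raise ValueError("shear stress must be >= 0")
    return max(_quad(APOPT_COEFFS, tau), 0.0)


def sono_effect(t: float, pulses: list[SonoPulse],
                law: PoreLaw = PoreLaw(),
                envelope: str = "rect") -> tuple[float, float]:
    """Active (pore radius nm, wall shear stress Pa) at time t (hours).

    Outside every pulse window the vessel wall is at its resting state
    ``(law.baseline_pore_radius, 0)``. Within a window the dilated pore
    radius and shear stress apply, either at full strength for the whole
    window (``envelope="rect"``, default) or decaying linearly back to
    baseline so the effect closes continuously (``envelope="linear"``).
    Overlapping pulses resolve to the maximum effect.
    """
    if envelope not in ("rect", "linear"):
        raise ValueError(f"unknown envelope {envelope!r}")
    best_r = law.baseline_pore_radius
    best_tau = 0.0
    for pulse in pulses:
        dt = t - pulse.start_time
        if dt < 0.0 or dt > pulse.effect_duration:
            continue
        weight = 1.0
        if envelope == "linear":
            weight = 1.0 - dt / pulse.effect_duration
        r_full = pore_radius(acoustic_pressure(pulse), law)
        r = law.baseline_pore_radius + weight * (r_full - law.baseline_pore_radius)
        tau = weight * wall_shear_stress(pulse)
        best_r = max(best_r, r)
        best_tau = max(best_tau, tau)
    return best_r, best_tau
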