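"""Ketotifen mechanotherapy: tissue softening and decompression.

Ketotifen acts on the tumor's mechanical phase, not through a
concentration field: over a ~3-day dosing ramp the tumor's shear and
bulk moduli fall linearly to half their pre-treatment baseline while
the interstitial hydraulic conductivity rises linearly by two orders
of magnitude. The factors hold at (0.5, 100) while dosing continues
(the experimental arms dose daily without interruption). Host tissue
is never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

logger = logging.getLogger(__name__)

__all__ = [
    "MechanicsParams",
    "KetotifenCourse",
    "ketotifen_modulation",
    "apply_mechanotherapy",
]

#: Endpoint values of the ramp: moduli halve, conductivity x100.
MODULUS_FACTOR_FLOOR = 0.5
CONDUCTIVITY_FACTOR_CEIL = 100.0


@dataclass(frozen=True)
class MechanicsParams:
    """Poroelastic parameters of one tissue compartment."""

    shear_modulus: float            # Pa
    bulk_modulus: float             # Pa
    hydraulic_conductivity: float   # m^2 / (Pa s)
    tissue_class: str = "tumor_untreated"  # host | tumor_untreated | tumor_treated

    def __post_init__(self) -> None:
        for name in ("shear_modulus", "bulk_modulus", "hydraulic_conductivity"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        if self.tissue_class not in ("host", "tumor_untreated", "tumor_treated"):
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")

    @property
    def is_tumor(self) -> bool:
        return self.tissue_class != "host"


@dataclass(frozen=True)
class KetotifenCourse:
    """Daily ketotifen dosing; the dose itself is record-keeping only."""

    start_time: float               # hours
    ramp_duration: float = 72.0     # hours
    daily_dose: float = 10.0        # mg/kg

    def __post_init__(self) -> None:
        if self.ramp_duration <= 0.0:
            raise ValueError("ramp_duration must be > 0")


def ketotifen_modulation(t: float,
                         course: KetotifenCourse | None) -> tuple[float, float]:
    """(modulus_factor, conductivity_factor) at time t hours.

    Before the course starts both factors are 1. During the ramp the
    modulus factor falls linearly 1 -> 0.5 and the conductivity factor
    rises linearly 1 -> 100; both then hold for the rest of the course.
    """
    if course is None or t < course.start_time:
        return 1.0, 1.0
    frac = min((t - course.start_time) / course.ramp_duration, 1.0)
    modulus = 1.0 + frac * (MODULUS_FACTOR_FLOOR - 1.0)
    conductivity = 1.0 + frac * (CONDUCTIVITY_FACTOR_CEIL - 1.0)
    return modulus, conductivity


def apply_mechanotherapy(params: MechanicsParams,
                         factors: tuple[float, float]) -> MechanicsParams:
    """Scale a tumor parameter bundle by the ketotifen factors.

    Host tissue is returned unchanged (with a logged warning), since
    mechanotherapy remodels the tumor interstitium only.
    """
    modulus_factor, conductivity_factor = factors
    if not params.is_tumor:
        logger.warning("mechanotherapy applied to host tissue: ignored")
        return params
    tissue_class = ("tumor_treated" if (modulus_factor, conductivity_factor)
                    != (1.0, 1.0) else params.tissue_class)
    return replace(
        params,
        shear_modulus=params.shear_modulus * modulus_factor,
        bulk_modulus=params.bulk_modulus * modulus_factor,
        hydraulic_conductivity=params.hydraulic_conductivity * conductivity_factor,
        tissue_class=tissue_class,
    )
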