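"""Solid stress, vessel compression, interstitial fluid pressure, flow.

The growth of the tumor against its surroundings accumulates solid
stress; solid stress compresses intratumoral vessels and reduces the
functional vascular surface Sv; the remaining functional vessels leak
plasma, which the poorly conducting interstitium cannot drain, raising
the interstitial fluid pressure (IFP) toward the microvascular
pressure and abolishing convective delivery. Mechanotherapy acts on
both couplings: halving the moduli halves the accumulated stress
(decompressing vessels), and raising the hydraulic conductivity lets
the pressure drain (restoring filtration).

The full tensorial solid-mechanics problem is reduced to a scalar
growth-induced bulk stress linear in the effective confined modulus,
which preserves exactly the two couplings above. Vessel compression is
exponential in stress. The IFP obeys the classical steady filtration
balance div(-k_th grad p) = L_p Sv (P_V - p) on the sphere with the
pressure datum p = 0 at the well-drained host interface, solved
quasi-statically (pressure equilibrates fast relative to growth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._radial import RadialGrid
from .mechanotherapy import MechanicsParams

__all__ = [
    "VascularParams",
    "solid_stress",
    "functional_vascular_density",
    "interstitial_fluid_pressure",
    "velocities",
    "perfusion_metric",
]


@dataclass(frozen=True)
class VascularParams:
    """Anatomic vasculature and the stress-compression law."""

    sv_anatomic: float = 20.0     # 1/mm, uncompressed vascular surface density
    vascular_pressure: float = 2000.0   # P_V, Pa
    beta_c: float = 1.0           # compression sensitivity
    sigma_ref: float = 1000.0     # Pa, stress scale of compression
    endo_ref: float = 0.5         # endothelial density giving anatomic Sv


def solid_stress(growth: np.ndarray, mechanics: MechanicsParams,
                 modulus_factor: float = 1.0,
                 stress_coeff: float = 0.05) -> np.ndarray:
    """Growth-induced bulk solid stress field (Pa).

    sigma_s = stress_coeff * modulus_factor * (k + 4 mu / 3) * max(G, 0)
    with G the accumulated volumetric growth. Linear in the effective
    confined modulus, so halving the moduli at fixed growth history
    halves the stress; zero net growth is the stress-free reference.
    """
    modulus = mechanics.bulk_modulus + 4.0 * mechanics.shear_modulus / 3.0
    return stress_coeff * modulus_factor * modulus * np.maximum(growth, 0.0)


def functional_vascular_density(endo: np.ndarray, sigma_s: np.ndarray,
                                params: VascularParams) -> np.ndarray:
    """Perfused vascular surface density Sv (same units as sv_anatomic).

    Anatomic density scales with the endothelial density; compression
    by solid stress reduces the functional fraction exponentially:
    Sv = Sv_anat * (endo / endo_ref) * exp(-beta_c sigma_s / sigma_ref).
    """
    anatomic = params.sv_anatomic * np.maximum(endo, 0.0) / params.endo_ref
    return anatomic * np.exp(-params.beta_c * np.maximum(sigma_s, 0.0)
                             / params.sigma_ref)


def interstitial_fluid_pressure(grid: RadialGrid, sv: np.ndarray,
                                l_p: float, p_v: float, k_th: float,
                                radius: float,
                                host_conductivity: float | None = None) -> np.ndarray:
    """Quasi-static IFP field p_i (Pa) on the tumor sphere.

    Solves div(k_th grad p) + L_p Sv (P_V - p) = 0 with symmetry at the
    center. By default the margin is pinned to the far-field datum
    p = 0 (a perfectly drained host), which for uniform parameters
    reproduces the closed form
    p(r)/P_V = 1 - (R/r) sinh(a r/R)/sinh(a), a = R sqrt(L_p Sv/k_th).
    When ``host_conductivity`` is given, the filtrate instead drains
    through a resistive host interstitium extending to the far field:
    the margin obeys -k_th dp/dr = (k_host/R) p, the exact matching
    condition to the source-free host solution p ~ 1/r. This throttles
    the outflow when mechanotherapy makes the tumor more conductive
    than its surroundings.

    Units must be consistent: k_th in mm^2/(Pa h) and L_p in mm/(Pa h)
    with the radius in mm, or any equivalent system.
    """
    sv = np.asarray(sv, dtype=float)
    uptake = l_p * sv
    source = l_p * sv * p_v
    conductance = (None if host_conductivity is None
                   else host_conductivity / radius)
    return grid.solve_reaction_diffusion(k_th, radius, uptake, source, 0.0,
                                         outer_conductance=conductance)


def velocities(grid: RadialGrid, p_i: np.ndarray, growth: np.ndarray,
               k_th: float, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Fluid and solid phase velocities (length/time of the unit system).

    v_f = -k_th dp/dr (Darcy flow down the IFP gradient); v_s is the
    radial accumulation of the net volumetric growth rate, so that
    v_s(R) is the boundary growth speed dR/dt. Both vanish at r = 0 by
    symmetry.
    """
    dr = grid.dx * radius
    dpdr = np.gradient(p_i, dr)
    v_f = -k_th * dpdr
    v_f[0] = 0.0
    v_s = grid.cumulative_shell_integral(growth, radius)
    return v_f, v_s


def perfusion_metric(grid: RadialGrid, sv: np.ndarray) -> float:
    """Volume-averaged functional vascular density over the tumor."""
    return grid.volume_average(sv)
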