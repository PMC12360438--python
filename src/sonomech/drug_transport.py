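"""Transvascular and interstitial transport of the therapeutic agents.

Three coupled states describe the nanomedicine (Doxil): the circulating
nanocarrier that extravasates into the interstitium (c_n), the free
chemotherapeutic released from it (c_f), and the drug internalized by
cells (c_int). The anti-PD-1 checkpoint antibody is transported as a
fourth free species (c_fi); anti-CTLA-4 acts pharmacodynamically only.

Transvascular exchange follows Starling's approximation with a
diffusive term P_er*Sv*(C_iv - c) and a convective filtration term
L_p*Sv*(P_V - p_i)*(1 - sigma_f)*C_iv. The wall coefficients P_er,
sigma_f and L_p depend on the ratio of the solute radius to the
vessel-wall pore radius through the classical cylindrical-pore
hindered-transport closure, which is how sonopermeation (pore
dilation) feeds into delivery.

All concentrations are dimensionless, normalized to the plasma peak of
the respective agent at injection (= 1); doses in mg/kg are metadata.
Functions are unit-agnostic as long as lengths, times and diffusivities
are consistent; the simulator uses mm and hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._radial import RadialGrid

__all__ = [
    "DrugSpecies",
    "VesselWall",
    "DrugFields",
    "plasma_concentration",
    "hindrance_coefficients",
    "wall_coefficients",
    "starling_flux",
    "transport_rhs",
    "ici_pharmacodynamics",
    "ICIParams",
]


@dataclass(frozen=True)
class DrugSpecies:
    """Transport and kinetic parameters of one administered agent."""

    name: str
    molecular_radius: float           # nm
    diffusivity: float                # interstitial diffusivity
    release_rate: float = 0.0         # k_el, nanocarrier only
    internalization_rate: float = 0.0  # k_int
    degradation_rate: float = 0.0     # k_deg
    payload_count: float = 1.0        # alpha, molecules per carrier
    plasma_decay: float = 24.0        # k_d, hours (bolus decay constant)
    dose: float = 0.0                 # mg/kg, record keeping
    injection_times: tuple[float, ...] = ()  # hours
    #: free-solution diffusivity inside the wall pores; defaults to the
    #: (slower) interstitial value when not given
    wall_diffusivity: float | None = None

    def __post_init__(self) -> None:
        if self.molecular_radius <= 0.0:
            raise ValueError("molecular_radius must be > 0")
        for name in ("release_rate", "internalization_rate",
                     "degradation_rate", "diffusivity"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if self.payload_count < 1.0:
            raise ValueError("payload_count must be >= 1")
        if self.plasma_decay <= 0.0:
            raise ValueError("plasma_decay must be > 0")


@dataclass(frozen=True)
class VesselWall:
    """Pore-size-dependent transport coefficients of the vessel wall.

    ``permeability_scale`` (1/length) collapses pore areal fraction and
    wall thickness into one anchor: P_er = permeability_scale * H(lambda)
    * D_species. ``hydraulic_conductivity_wall`` is L_p at
    ``base_pore_radius`` and rescales as (r_o / r_o_base)^2 (Poiseuille
    flow through the pores at fixed areal fraction).
    """

    pore_radius: float                        # nm
    hydraulic_conductivity_wall: float        # L_p at base_pore_radius
    vascular_pressure: float                  # P_V, Pa
    base_pore_radius: float                   # nm
    permeability_scale: float                 # 1/length
    permeability: Mapping[str, float] = field(default_factory=dict)
    reflection: Mapping[str, float] = field(default_factory=dict)

    @property
    def effective_hydraulic_conductivity(self) -> float:
        """L_p at the current pore radius."""
        return (self.hydraulic_conductivity_wall
                * (self.pore_radius / self.base_pore_radius) ** 2)


def plasma_concentration(t: float, t_0: float | Sequence[float],
                         k_d: float, ceiling: float = 2.0) -> float:
    """Normalized vascular concentration after bolus injection(s).

    ``exp(-(t - t_0)/k_d)`` per injection for t >= t_0 (0 before);
    multiple injections superpose and the sum is capped at ``ceiling``.
    """
    if k_d <= 0.0:
        raise ValueError("plasma decay constant must be > 0")
    times = np.atleast_1d(np.asarray(t_0, dtype=float))
    dt = t - times
    total = float(np.sum(np.exp(-dt[dt >= 0.0] / k_d)))
    return min(total, ceiling)


def hindrance_coefficients(lam: float) -> tuple[float, float, float]:
    """Cylindrical-pore hindered-transport closure.

    For the ratio lam = r_s / r_o of solute to pore radius, returns
    (diffusive hindrance H, osmotic reflection sigma_f, steric
    partition Phi):

      Phi      = (1 - lam)^2
      H        = Phi * (1 - 2.104 lam + 2.089 lam^3 - 0.948 lam^5)
      sigma_f  = 1 - Phi (2 - Phi) G(lam),
      G(lam)   = 1 - (2/3) lam^2 - 0.163 lam^3   (convective hindrance)

    All three lie in [0, 1]; H -> 0 and sigma_f -> 1 as the solute
    approaches the pore size.
    """
    if lam < 0.0 or lam > 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    phi = (1.0 - lam) ** 2
    h = phi * (1.0 - 2.104 * lam + 2.089 * lam**3 - 0.948 * lam**5)
    g = 1.0 - (2.0 / 3.0) * lam**2 - 0.163 * lam**3
    sigma = 1.0 - phi * (2.0 - phi) * g
    return h, min(max(sigma, 0.0), 1.0), phi


def wall_coefficients(r_o: float, species: Sequence[DrugSpecies],
                      base: VesselWall) -> VesselWall:
    """Vessel wall with per-species coefficients at pore radius ``r_o``.

    Pore radii below the resting baseline are clamped up to it.
    Enlarging the pore never decreases P_er or L_p and never increases
    sigma_f.
    """
    r_o = max(r_o, base.base_pore_radius)
    perm: dict[str, float] = {}
    refl: dict[str, float] = {}
    for sp in species:
        lam = min(sp.molecular_radius / r_o, 1.0)
        h, sigma, _ = hindrance_coefficients(lam)
        d_wall = (sp.wall_diffusivity if sp.wall_diffusivity is not None
                  else sp.diffusivity)
        perm[sp.name] = base.permeability_scale * h * d_wall
        refl[sp.name] = sigma
    return replace(base, pore_radius=r_o, permeability=perm, reflection=refl)


def starling_flux(p_er, sv, c_iv, c, l_p, p_v, p_i, sigma_f):
    """Transvascular source (concentration/time) by Starling's law.

    Diffusive exchange down the plasma-tissue gradient plus convective
    filtration carried by the transmural pressure difference, reduced
    by the reflection coefficient. Element-wise over radial fields.
    """
    return (p_er * sv * (c_iv - c)
            + l_p * sv * (p_v - p_i) * (1.0 - sigma_f) * c_iv)


@dataclass
class DrugFields:
    """The four radial drug concentration fields."""

    c_n: np.ndarray     # nanocarrier in the interstitium
    c_f: np.ndarray     # free chemotherapeutic
    c_int: np.ndarray   # internalized drug
    c_f_i: np.ndarray   # free checkpoint antibody (anti-PD-1)

    @classmethod
    def zeros(cls, n: int) -> "DrugFields":
        return cls(*(np.zeros(n) for _ in range(4)))

    def stack(self) -> np.ndarray:
        return np.concatenate([self.c_n, self.c_f, self.c_int, self.c_f_i])

    @classmethod
    def unstack(cls, y: np.ndarray) -> "DrugFields":
        return cls(*np.split(np.asarray(y, dtype=float), 4))


def transport_rhs(grid: RadialGrid, radius: float, fields: DrugFields,
                  nanocarrier: DrugSpecies, antibody: DrugSpecies,
                  free_diffusivity: float, free_degradation: float,
                  wall: VesselWall, sv: np.ndarray, p_i: np.ndarray,
                  v_f: np.ndarray, v_s: np.ndarray, t: float,
                  u_grid: np.ndarray | None = None,
                  c_iv_n: float | None = None,
                  c_iv_i: float | None = None) -> DrugFields:
    """Time derivatives of the four drug fields (method of lines).

    Spherical-symmetric advection (first-order upwind), diffusion
    (finite volume, zero flux at both ends), Starling transvascular
    sources and the release / internalization / degradation chain:

      dc_n/dt   = -div(c_n v_f)  + D_n lap c_n + Q_sta   - k_el c_n
      dc_f/dt   = -div(c_f v_f)  + D_f lap c_f + a k_el c_n - k_int c_f
      dc_int/dt = -div(c_int v_s)               + k_int c_f - k_deg c_int
      dc_fi/dt  = -div(c_fi v_f) + D_i lap c_fi + Q_sta^i - k_deg^i c_fi

    ``u_grid`` (optional) is the grid velocity x*dR/dt for a moving
    tumor boundary; plasma levels may be supplied precomputed.
    """
    if c_iv_n is None:
        c_iv_n = plasma_concentration(t, nanocarrier.injection_times,
                                      nanocarrier.plasma_decay)
    if c_iv_i is None:
        c_iv_i = plasma_concentration(t, antibody.injection_times,
                                      antibody.plasma_decay)
    if u_grid is None:
        u_grid = np.zeros(grid.n)

    l_p = wall.effective_hydraulic_conductivity
    q_n = starling_flux(wall.permeability[nanocarrier.name], sv, c_iv_n,
                        fields.c_n, l_p, wall.vascular_pressure, p_i,
                        wall.reflection[nanocarrier.name])
    q_i = starling_flux(wall.permeability[antibody.name], sv, c_iv_i,
                        fields.c_f_i, l_p, wall.vascular_pressure, p_i,
                        wall.reflection[antibody.name])

    div_vf = grid.divergence(v_f, radius)
    div_vs = grid.divergence(v_s, radius)
    uf = v_f - u_grid
    us = v_s - u_grid

    def convect(c: np.ndarray, u: np.ndarray, divv: np.ndarray) -> np.ndarray:
        # -div(c v) in the moving frame: -u_rel dc/dr - c div(v)
        return grid.advect_upwind(c, u, radius) - c * divv

    d_n = (convect(fields.c_n, uf, div_vf)
           + grid.laplacian(fields.c_n, nanocarrier.diffusivity, radius)
           + q_n - nanocarrier.release_rate * fields.c_n)
    d_f = (convect(fields.c_f, uf, div_vf)
           + grid.laplacian(fields.c_f, free_diffusivity, radius)
           + nanocarrier.payload_count * nanocarrier.release_rate * fields.c_n
           - nanocarrier.internalization_rate * fields.c_f)
    d_int = (convect(fields.c_int, us, div_vs)
             + nanocarrier.internalization_rate * fields.c_f
             - free_degradation * fields.c_int)
    d_fi = (convect(fields.c_f_i, uf, div_vf)
            + grid.laplacian(fields.c_f_i, antibody.diffusivity, radius)
            + q_i - antibody.degradation_rate * fields.c_f_i)
    return DrugFields(d_n, d_f, d_int, d_fi)


@dataclass(frozen=True)
class ICIParams:
    """Pharmacodynamics of the checkpoint-inhibitor cocktail.

    anti-PD-1 boosts the CD8+ T-cell source saturably in the local
    antibody concentration (Hill coefficient 1); anti-CTLA-4 raises the
    Treg mortality during a fixed window after each dose (it is not
    spatially transported).
    """

    pd1_max_boost: float = 2.0       # a_pd1: source up to (1 + a) fold
    pd1_half_conc: float = 0.1       # c_half in normalized units
    ctla4_mortality_boost: float = 1.5
    ctla4_window: float = 96.0       # hours of effect after each dose


def ici_pharmacodynamics(c_f_i: np.ndarray | float, sigma_t8: float,
                         m_reg: float, params: ICIParams = ICIParams(),
                         ctla4_active: bool = False):
    """(effective CD8 source, effective Treg mortality).

    With no antibody present and no active anti-CTLA-4 dose, the
    baselines are returned unchanged.
    """
    c = np.maximum(np.asarray(c_f_i, dtype=float), 0.0)
    boost = params.pd1_max_boost * c / (params.pd1_half_conc + c)
    sigma_eff = sigma_t8 * (1.0 + boost)
    m_eff = m_reg * (1.0 + (params.ctla4_mortality_boost if ctla4_active
                            else 0.0))
    return sigma_eff, m_eff
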