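"""Population dynamics of the tumor microenvironment.

Cell populations (all number densities normalized to carrying
capacity = 1, defined per radial node):

* cancer: non-stem cancer cells (cc), stem-like cancer cells (scc) and
  treatment-induced cancer cells (icc), sharing one logistic carrying
  capacity; proliferation is proportional to k_1 * c_ox (oxygen-coupled
  growth), killing comes from the internalized drug and from immune
  effectors;
* immune: NK cells, CD8+ and CD4+ T cells, regulatory T cells and
  M1/M2 tumor-associated macrophages, each with a source/death balance;
  effector activity is suppressed by Tregs and M2 TAMs, boosted by
  checkpoint inhibition and by immunogenic cell death;
* vascular: endothelial cells driven by VEGF and the Ang1/Ang2 balance,
  with the sonopermeation shear-stress factors multiplying the
  proliferation and apoptosis terms;
* oxygen: supplied across the functional vascular surface, consumed by
  cells, held at the healthy-tissue reference (0.2 mol/m^3) at the
  host interface.

Immune evasion is modeled as an activation threshold: effector killing
engages only when the suppression-weighted effector activity exceeds
its healthy-tissue set point, so an untreated tumor is not controlled
by baseline immunity, while checkpoint inhibition (raising CD8 sources
and Treg mortality) and immunogenic cell death push the activity above
threshold. This closure realizes the stated interaction network with
the simplest standard forms (logistic growth, mass action,
saturation); it is structurally, not equation-by-equation, identical
to any particular reference formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._radial import RadialGrid

__all__ = [
    "CellPopulations",
    "AngiogenicFactors",
    "GrowthParams",
    "HOST_OXYGEN",
    "cancer_rhs",
    "immune_rhs",
    "tam_polarization",
    "vascular_rhs",
    "oxygen_rhs",
    "solve_oxygen",
    "hypoxia_percent",
]

#: Oxygen concentration of well-perfused healthy tissue, mol/m^3.
HOST_OXYGEN = 0.2

POPULATION_NAMES = ("cc", "scc", "icc", "nk", "t8", "t4", "treg",
                    "tam_m1", "tam_m2", "endo")


@dataclass
class CellPopulations:
    """Radial density fields of every modeled cell population."""

    cc: np.ndarray
    scc: np.ndarray
    icc: np.ndarray
    nk: np.ndarray
    t8: np.ndarray
    t4: np.ndarray
    treg: np.ndarray
    tam_m1: np.ndarray
    tam_m2: np.ndarray
    endo: np.ndarray

    @classmethod
    def uniform(cls, n: int, values: Mapping[str, float]) -> "CellPopulations":
        return cls(**{name: np.full(n, float(values.get(name, 0.0)))
                      for name in POPULATION_NAMES})

    @property
    def cancer_total(self) -> np.ndarray:
        return self.cc + self.scc + self.icc

    @property
    def metabolic_total(self) -> np.ndarray:
        """Density of oxygen-consuming cells."""
        return (self.cancer_total + self.nk + self.t8 + self.t4 + self.treg
                + self.tam_m1 + self.tam_m2)


@dataclass
class AngiogenicFactors:
    """Normalized VEGF / Ang1 / Ang2 concentration fields."""

    vegf: np.ndarray
    ang1: np.ndarray
    ang2: np.ndarray


@dataclass(frozen=True)
class GrowthParams:
    """Rate constants of the population network (all 1/h unless noted).

    Baseline numerical values are placeholders chosen for realistic
    murine-breast-tumor behavior (see docs/methods.md); k_1 is the one
    constant calibrated against control-arm growth data.
    """

    # cancer
    k_1: float = 0.12              # 1/h per (mol/m^3): oxygen-proliferation coupling
    scc_k1_fraction: float = 0.5   # SCC proliferate slower
    icc_k1_fraction: float = 0.5
    scc_differentiation: float = 2e-3   # SCC -> CC
    icc_death: float = 1e-3
    drug_kill: float = 0.05        # 1/h per unit internalized drug
    scc_kill_fraction: float = 0.3  # stem-like resistance
    drug_conversion: float = 0.1   # fraction-style CC -> ICC flux coefficient
    immune_kill: float = 0.15      # 1/h per unit above-threshold activity

    # immune sources / deaths (steady state sigma/m)
    sigma_nk: float = 2.0e-4
    m_nk: float = 0.02
    sigma_t8: float = 3.0e-4
    m_t8: float = 0.02
    sigma_t4: float = 4.0e-4
    m_t4: float = 0.02
    sigma_treg: float = 1.2e-3
    m_reg: float = 0.02
    sigma_m1: float = 4.0e-4
    sigma_m2: float = 1.6e-3
    m_tam: float = 0.02

    suppression_coeff: float = 5.0   # Treg + M2 suppression of effectors
    nk_weight: float = 0.5           # NK weight in effector activity
    m1_weight: float = 0.5           # M1 TAM weight in effector activity
    icd_recruitment: float = 0.15    # effector source per unit drug-kill flux

    # TAM polarization
    polarization_rate: float = 0.05
    polarization_oxygen_threshold: float = 0.5   # fraction of host oxygen
    polarization_vegf_weight: float = 1.0
    polarization_vegf_half: float = 0.2

    # vasculature
    endo_proliferation: float = 0.02
    endo_death: float = 0.004
    vegf_half: float = 0.1
    ang_eps: float = 0.01
    vegf_production: float = 0.01
    vegf_decay: float = 0.02
    ang1_production: float = 0.01
    ang1_decay: float = 0.01
    ang2_production: float = 0.01
    ang2_decay: float = 0.01

    # oxygen (mm / h units)
    oxygen_diffusivity: float = 7.2        # mm^2/h  (2e-9 m^2/s)
    oxygen_wall_permeability: float = 54.0  # mm/h across the vessel wall
    oxygen_consumption: float = 1200.0      # 1/h per unit cell density

    def baseline_activity(self) -> float:
        """Effector-activity set point of healthy, fully oxygenated tissue.

        The analytic fixed point of the immune subsystem at the host
        oxygen reference with no VEGF, including the steady TAM
        polarization toward M1 that full oxygenation sustains. Killing
        engages only above this threshold (immune tolerance of the
        baseline state); without it, the normoxic tumor rim would be
        slowly eroded even in an untreated animal.
        """
        treg0 = self.sigma_treg / self.m_reg
        drive0 = max(1.0 - self.polarization_oxygen_threshold, 0.0)
        pol0 = self.polarization_rate * drive0
        m2_0 = self.sigma_m2 / (self.m_tam + pol0)
        m1_0 = (self.sigma_m1 + pol0 * m2_0) / self.m_tam
        supp = 1.0 / (1.0 + self.suppression_coeff * (treg0 + m2_0))
        return supp * (self.sigma_t8 / self.m_t8
                       + self.nk_weight * self.sigma_nk / self.m_nk
                       + self.m1_weight * m1_0)


def effector_activity(pops: CellPopulations, params: GrowthParams) -> np.ndarray:
    """Suppression-weighted effector activity field."""
    supp = 1.0 / (1.0 + params.suppression_coeff * (pops.treg + pops.tam_m2))
    return supp * (pops.t8 + params.nk_weight * pops.nk
                   + params.m1_weight * pops.tam_m1)


def _kill_rates(pops: CellPopulations, c_int: np.ndarray,
                params: GrowthParams):
    """Per-capita drug and immune kill rates (cc/icc vs scc)."""
    act = effector_activity(pops, params)
    excess = np.maximum(act - params.baseline_activity(), 0.0)
    drug = params.drug_kill * np.maximum(c_int, 0.0)
    immune = params.immune_kill * excess
    return drug, immune


def cancer_rhs(pops: CellPopulations, c_ox: np.ndarray, c_int: np.ndarray,
               params: GrowthParams):
    """Derivatives of (cc, scc, icc) and the net volumetric growth rate.

    Logistic oxygen-coupled proliferation with a shared carrying
    capacity, drug kill through the internalized concentration, immune
    kill through above-threshold effector activity, conservative
    SCC -> CC differentiation and drug-induced CC -> ICC conversion.

    The returned ``growth`` field is the net volumetric source that
    drives the solid-phase velocity: the division rate minus the
    removal rate (interconversions cancel). Divisions enter unthrottled
    by the carrying capacity - at local packing the excess divisions
    displace tissue outward instead of raising the density, which is
    what sustains radial growth of a packed tumor - while the density
    equations keep the logistic crowding term.
    """
    total = pops.cancer_total
    room = np.maximum(1.0 - total, 0.0)
    drug, immune = _kill_rates(pops, c_int, params)

    rate_cc = params.k_1 * c_ox * pops.cc
    rate_scc = params.scc_k1_fraction * params.k_1 * c_ox * pops.scc
    rate_icc = params.icc_k1_fraction * params.k_1 * c_ox * pops.icc

    kill_cc = (drug + immune) * pops.cc
    kill_scc = params.scc_kill_fraction * (drug + immune) * pops.scc
    kill_icc = (drug + immune) * pops.icc

    diff = params.scc_differentiation * pops.scc          # SCC -> CC
    conv = params.drug_conversion * drug * pops.cc        # CC -> ICC
    death_icc = params.icc_death * pops.icc

    d_cc = rate_cc * room - kill_cc + diff - conv
    d_scc = rate_scc * room - kill_scc - diff
    d_icc = rate_icc * room - kill_icc + conv - death_icc

    growth = (rate_cc + rate_scc + rate_icc
              - kill_cc - kill_scc - kill_icc - death_icc)
    return d_cc, d_scc, d_icc, growth


def tam_polarization(c_ox: np.ndarray, vegf: np.ndarray,
                     pops: CellPopulations, params: GrowthParams) -> np.ndarray:
    """Net M2 -> M1 conversion flux (conserves tam_m1 + tam_m2).

    Oxygenation above the polarization threshold pushes macrophages
    toward the immunostimulatory M1 phenotype; VEGF pushes toward M2.
    """
    drive = (c_ox / HOST_OXYGEN - params.polarization_oxygen_threshold
             - params.polarization_vegf_weight * vegf
             / (params.polarization_vegf_half + np.maximum(vegf, 0.0)))
    pool = np.where(drive > 0.0, pops.tam_m2, pops.tam_m1)
    return params.polarization_rate * drive * pool


def immune_rhs(pops: CellPopulations, c_ox: np.ndarray,
               sigma_t8_eff: np.ndarray | float, m_reg_eff: float,
               drug_kill_flux: np.ndarray, vegf: np.ndarray,
               params: GrowthParams):
    """Derivatives of (nk, t8, t4, treg, tam_m1, tam_m2).

    Sources scale with local oxygenation (recruitment needs perfusion);
    immunogenic cell death from drug-mediated cancer kill recruits
    effectors; anti-PD-1 enters through ``sigma_t8_eff`` and anti-CTLA-4
    through ``m_reg_eff``; polarization moves TAMs between phenotypes.
    """
    f_ox = c_ox / HOST_OXYGEN
    icd = params.icd_recruitment * drug_kill_flux
    pol = tam_polarization(c_ox, vegf, pops, params)

    d_nk = params.sigma_nk * f_ox + 0.5 * icd - params.m_nk * pops.nk
    d_t8 = sigma_t8_eff * f_ox + icd - params.m_t8 * pops.t8
    d_t4 = params.sigma_t4 * f_ox - params.m_t4 * pops.t4
    d_treg = params.sigma_treg * f_ox - m_reg_eff * pops.treg
    d_m1 = params.sigma_m1 * f_ox + pol - params.m_tam * pops.tam_m1
    d_m2 = params.sigma_m2 * f_ox - pol - params.m_tam * pops.tam_m2
    return d_nk, d_t8, d_t4, d_treg, d_m1, d_m2


def vascular_rhs(pops: CellPopulations, factors: AngiogenicFactors,
                 sono_factors: tuple[float, float], c_ox: np.ndarray,
                 params: GrowthParams):
    """Derivatives of (endo, vegf, ang1, ang2).

    Endothelial proliferation is driven by VEGF and the Ang1 share of
    the angiopoietin pool and multiplied by the (baseline-normalized)
    sonopermeation proliferation factor; apoptosis is multiplied by
    the apoptosis factor. VEGF and Ang2 are produced under hypoxia;
    Ang1 tracks the stable (endothelial) vasculature.
    """
    pr, ap = sono_factors
    hypoxia = np.maximum(1.0 - c_ox / HOST_OXYGEN, 0.0)
    vegf_drive = np.maximum(factors.vegf, 0.0)
    vegf_term = vegf_drive / (params.vegf_half + vegf_drive)
    ang_term = ((np.maximum(factors.ang1, 0.0) + params.ang_eps)
                / (np.maximum(factors.ang1, 0.0)
                   + np.maximum(factors.ang2, 0.0) + params.ang_eps))

    prolif = (pr * params.endo_proliferation * pops.endo
              * np.maximum(1.0 - pops.endo, 0.0) * vegf_term * ang_term)
    death = ap * params.endo_death * pops.endo
    d_endo = prolif - death

    cells = pops.cancer_total
    d_vegf = params.vegf_production * cells * hypoxia - params.vegf_decay * factors.vegf
    d_ang1 = params.ang1_production * pops.endo - params.ang1_decay * factors.ang1
    d_ang2 = (params.ang2_production * pops.endo * hypoxia
              - params.ang2_decay * factors.ang2)
    return d_endo, d_vegf, d_ang1, d_ang2


def oxygen_rhs(grid: RadialGrid, radius: float, c_ox: np.ndarray,
               sv: np.ndarray, pops: CellPopulations,
               params: GrowthParams) -> np.ndarray:
    """Dynamic oxygen balance (used for verification; the simulator
    applies the quasi-static fast-diffusion limit of the same balance).

    Diffusion + transvascular supply proportional to the functional
    vascular surface Sv times (host reference - c_ox), minus
    consumption by the metabolically active cell density. The host
    interface is held at the healthy reference.
    """
    supply = params.oxygen_wall_permeability * sv * (HOST_OXYGEN - c_ox)
    consumption = params.oxygen_consumption * pops.metabolic_total * c_ox
    out = (grid.laplacian(c_ox, params.oxygen_diffusivity, radius,
                          dirichlet_outer=HOST_OXYGEN)
           + supply - consumption)
    out[-1] = 0.0  # boundary node pinned at the host reference
    return out


def solve_oxygen(grid: RadialGrid, radius: float, sv: np.ndarray,
                 pops: CellPopulations, params: GrowthParams) -> np.ndarray:
    """Quasi-static oxygen field (diffusion fast vs. cell dynamics)."""
    uptake = (params.oxygen_wall_permeability * sv
              + params.oxygen_consumption * pops.metabolic_total)
    source = params.oxygen_wall_permeability * sv * HOST_OXYGEN
    c = grid.solve_reaction_diffusion(params.oxygen_diffusivity, radius,
                                      uptake, source, HOST_OXYGEN)
    return np.clip(c, 0.0, HOST_OXYGEN)


def hypoxia_percent(c_ox_tumor_mean: float) -> float:
    """Hypoxia level: the complement of tumor oxygen relative to host.

    100 * (1 - c_ox / 0.2); values above the host reference clamp to
    0% hypoxia.
    """
    if c_ox_tumor_mean < 0.0:
        raise ValueError("oxygen concentration must be >= 0")
    return max(100.0 * (1.0 - c_ox_tumor_mean / HOST_OXYGEN), 0.0)
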