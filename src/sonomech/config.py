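"""Run configuration: defaults, YAML loading, unit handling.

The configuration is a nested plain dict (YAML-serializable). External
values use SI-flavored units spelled out in the key names
(``*_m2_per_s``, ``*_Pa`` ...); internally the simulator works in
millimetres and hours, and the builder functions below perform the
conversion while constructing the typed parameter bundles of the other
modules.

Baseline numerical values that the underlying experimental studies do
not print (rate constants, moduli, conductivities ...) are declared
here as documented placeholders; see docs/methods.md for the rationale
behind each default.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from typing import Any, Mapping

import yaml

from .drug_transport import DrugSpecies, ICIParams, VesselWall
from .mechanotherapy import KetotifenCourse, MechanicsParams
from .biomechanics import VascularParams
from .sonopermeation import MicrobubbleParams, PoreLaw, SonoPulse
from .tme_dynamics import GrowthParams

__all__ = [
    "default_config",
    "load_config",
    "merge_config",
    "config_hash",
    "M2S_TO_MM2H",
    "MPAS_TO_MMPAH",
    "PERS_TO_PERH",
]

# unit conversion factors (SI -> mm / h)
M2S_TO_MM2H = 3.6e9      # m^2/s  -> mm^2/h
MPAS_TO_MMPAH = 3.6e6    # m/(Pa s) -> mm/(Pa h)
PERS_TO_PERH = 3600.0    # 1/s -> 1/h
PERM_TO_PERMM = 1e-3     # 1/m -> 1/mm

_BOLTZMANN_T = 4.28e-21  # k_B * 310 K, J


def _stokes_einstein_mm2h(radius_nm: float, viscosity: float = 1.2e-3) -> float:
    """Free-solution diffusivity (mm^2/h) of a sphere in plasma."""
    d = _BOLTZMANN_T / (6.0 * math.pi * viscosity * radius_nm * 1e-9)
    return d * M2S_TO_MM2H


DEFAULT_CONFIG: dict[str, Any] = {
    "geometry": {
        "initial_tumor_radius_mm": 1.875,   # ~28 mm^3 at first caliper measurement
        "host_domain_factor": 100.0,        # host extent relative to tumor
        "n_radial_nodes": 40,
    },
    "time": {
        "horizon_h": 720.0,        # 30 simulated days
        "output_cadence_h": 6.0,
        "macro_step_h": 2.0,       # quasi-static refresh of IFP/oxygen/flow
        "rtol": 1e-6,
        "atol": 1e-9,
    },
    "mechanics": {
        "host": {
            "shear_modulus_Pa": 1000.0,
            "bulk_modulus_Pa": 5000.0,
            "hydraulic_conductivity": 3.0e-13,   # m^2/(Pa s)
        },
        "tumor": {
            "shear_modulus_Pa": 5000.0,
            "bulk_modulus_Pa": 15000.0,
            "hydraulic_conductivity": 3.0e-14,
        },
        "stress_growth_coeff": 0.02,
    },
    "vasculature": {
        "Sv_anatomic_per_m": 2.0e4,
        "P_V_Pa": 2000.0,
        "beta_c": 0.6,
        "sigma_ref_Pa": 1000.0,
        "endo_ref": 0.5,
        "L_p_m_per_Pa_s": 7.0e-12,          # at the resting pore radius
        "base_pore_radius_nm": 100.0,
        "max_pore_radius_nm": 1250.0,
        "permeability_scale_per_m": 300.0,  # pore areal fraction / wall thickness
        "host_drainage": "drained",         # or "resistive" (host throttles outflow)
    },
    "sonopermeation": {
        "pulses": [],     # list of {start_time_h, mechanical_index,
                          #          frequency_MHz, effect_duration_h}
        "envelope": "rect",
    },
    "microbubble": {
        "liquid_density": 1050.0,             # kg/m^3, blood
        "liquid_viscosity": 3.0e-3,           # Pa s, blood
        "wall_displacement_amplitude": 5.0e-8,  # m
        "equilibrium_radius": 1.0e-6,         # m
    },
    "ketotifen": None,   # or {start_time_h, ramp_duration_h, daily_dose_mg_per_kg}
    "drugs": {
        "doxil": {
            "molecular_radius_nm": 50.0,
            "D_m2_per_s": 1.0e-13,
            "k_el_per_s": 3.0e-5,
            "k_int_per_s": 2.8e-4,
            "alpha": 1.0,          # free drug counted in carrier equivalents
            "k_d_h": 24.0,
            "dose_mg_per_kg": 3.0,
            "injection_times_h": [],
        },
        "doxorubicin": {           # the released free agent
            "molecular_radius_nm": 0.8,
            "D_m2_per_s": 3.0e-10,
            "k_deg_per_s": 1.0e-5,
        },
        "anti_pd1": {
            "molecular_radius_nm": 5.0,
            "D_m2_per_s": 1.0e-11,
            "k_deg_per_s": 8.0e-6,
            "k_d_h": 72.0,
            "dose_mg_per_kg": 10.0,
            "injection_times_h": [],
        },
        "anti_ctla4": {
            "dose_mg_per_kg": 5.0,
            "effect_window_h": 96.0,
            "injection_times_h": [],
        },
        "plasma_ceiling": 2.0,
    },
    "ici": {
        "pd1_max_boost": 2.0,
        "pd1_half_conc": 0.3,
        "ctla4_mortality_boost": 1.5,
    },
    "populations": {
        "initial": {
            "cc": 0.55, "scc": 0.05, "icc": 0.0,
            "nk": 0.01, "t8": 0.015, "t4": 0.02, "treg": 0.06,
            "tam_m1": 0.02, "tam_m2": 0.08, "endo": 0.5,
        },
        "rates": {},   # overrides of GrowthParams fields (already 1/h)
    },
    "factors": {
        "initial": {"vegf": 0.1, "ang1": 0.5, "ang2": 0.1},
    },
    "protocol": {
        "trigger_volume_mm3": 150.0,
        "ketotifen_lead_h": 72.0,   # sono starts this long after ketotifen
        "injection_offset_h": 1.0,  # nano-immuno after sonopermeation
        "cycle_gap_h": 72.0,        # second sono + injection cycle
        "fallback_start_day": 14.0,
        "sweep_anchor_days": [19.0, 22.0],
        "sweep_intervals_h": [1.0, 3.0, 6.0, 24.0],
    },
}


def default_config() -> dict[str, Any]:
    """A deep copy of the default configuration."""
    return copy.deepcopy(DEFAULT_CONFIG)


def merge_config(base: Mapping[str, Any],
                 override: Mapping[str, Any] | None) -> dict[str, Any]:
    """Recursively merge ``override`` into a copy of ``base``."""
    out = copy.deepcopy(dict(base))
    for key, value in (override or {}).items():
        if (key in out and isinstance(out[key], dict)
                and isinstance(value, Mapping)):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | None = None) -> dict[str, Any]:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return default_config()
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(DEFAULT_CONFIG, user)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(config, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# builders: config dict -> typed parameter bundles in mm / h units
# ---------------------------------------------------------------------------

def build_growth_params(config: Mapping[str, Any]) -> GrowthParams:
    overrides = dict(config["populations"].get("rates") or {})
    return GrowthParams(**overrides)


def build_mechanics(config: Mapping[str, Any], tissue: str) -> MechanicsParams:
    block = config["mechanics"][tissue]
    return MechanicsParams(
        shear_modulus=block["shear_modulus_Pa"],
        bulk_modulus=block["bulk_modulus_Pa"],
        hydraulic_conductivity=block["hydraulic_conductivity"],
        tissue_class="host" if tissue == "host" else "tumor_untreated",
    )


def build_vascular_params(config: Mapping[str, Any]) -> VascularParams:
    v = config["vasculature"]
    return VascularParams(
        sv_anatomic=v["Sv_anatomic_per_m"] * PERM_TO_PERMM,
        vascular_pressure=v["P_V_Pa"],
        beta_c=v["beta_c"],
        sigma_ref=v["sigma_ref_Pa"],
        endo_ref=v["endo_ref"],
    )


def build_pore_law(config: Mapping[str, Any]) -> PoreLaw:
    v = config["vasculature"]
    return PoreLaw(baseline_pore_radius=v["base_pore_radius_nm"],
                   max_pore_radius=v["max_pore_radius_nm"])


def build_microbubble(config: Mapping[str, Any]) -> MicrobubbleParams:
    return MicrobubbleParams(**config["microbubble"])


def build_pulses(config: Mapping[str, Any]) -> list[SonoPulse]:
    mb = build_microbubble(config)
    pulses = []
    for p in config["sonopermeation"]["pulses"]:
        pulses.append(SonoPulse(
            mechanical_index=p.get("mechanical_index", 0.4),
            frequency=p.get("frequency_MHz", 1.0),
            start_time=p["start_time_h"],
            effect_duration=p.get("effect_duration_h", 6.0),
            microbubble=mb,
        ))
    return pulses


def build_ketotifen(config: Mapping[str, Any]) -> KetotifenCourse | None:
    block = config.get("ketotifen")
    if not block:
        return None
    return KetotifenCourse(
        start_time=block["start_time_h"],
        ramp_duration=block.get("ramp_duration_h", 72.0),
        daily_dose=block.get("daily_dose_mg_per_kg", 10.0),
    )


def build_species(config: Mapping[str, Any]) -> dict[str, DrugSpecies]:
    """Doxil nanocarrier and anti-PD-1 antibody bundles (mm/h units).

    The released free chemotherapeutic is folded into the carrier
    bundle (its interstitial diffusivity and degradation rate are taken
    from the ``doxorubicin`` block); ``wall_diffusivity`` for
    transvascular permeability is the Stokes-Einstein free-solution
    value at the species' molecular radius.
    """
    d = config["drugs"]
    doxil = d["doxil"]
    free = d["doxorubicin"]
    pd1 = d["anti_pd1"]
    carrier = DrugSpecies(
        name="doxil",
        molecular_radius=doxil["molecular_radius_nm"],
        diffusivity=doxil["D_m2_per_s"] * M2S_TO_MM2H,
        release_rate=doxil["k_el_per_s"] * PERS_TO_PERH,
        internalization_rate=doxil["k_int_per_s"] * PERS_TO_PERH,
        degradation_rate=free["k_deg_per_s"] * PERS_TO_PERH,
        payload_count=doxil.get("alpha", 1.0),
        plasma_decay=doxil["k_d_h"],
        dose=doxil.get("dose_mg_per_kg", 0.0),
        injection_times=tuple(doxil.get("injection_times_h", [])),
        wall_diffusivity=_stokes_einstein_mm2h(doxil["molecular_radius_nm"]),
    )
    antibody = DrugSpecies(
        name="anti_pd1",
        molecular_radius=pd1["molecular_radius_nm"],
        diffusivity=pd1["D_m2_per_s"] * M2S_TO_MM2H,
        degradation_rate=pd1["k_deg_per_s"] * PERS_TO_PERH,
        plasma_decay=pd1["k_d_h"],
        dose=pd1.get("dose_mg_per_kg", 0.0),
        injection_times=tuple(pd1.get("injection_times_h", [])),
        wall_diffusivity=_stokes_einstein_mm2h(pd1["molecular_radius_nm"]),
    )
    return {"doxil": carrier, "anti_pd1": antibody}


def free_drug_transport(config: Mapping[str, Any]) -> tuple[float, float]:
    """(diffusivity mm^2/h, degradation 1/h) of the released agent."""
    free = config["drugs"]["doxorubicin"]
    return (free["D_m2_per_s"] * M2S_TO_MM2H,
            free["k_deg_per_s"] * PERS_TO_PERH)


def wall_diffusivity(species: DrugSpecies) -> float:
    """Free-solution (plasma) diffusivity used inside the wall pores."""
    return _stokes_einstein_mm2h(species.molecular_radius)


def build_vessel_wall(config: Mapping[str, Any]) -> VesselWall:
    v = config["vasculature"]
    return VesselWall(
        pore_radius=v["base_pore_radius_nm"],
        hydraulic_conductivity_wall=v["L_p_m_per_Pa_s"] * MPAS_TO_MMPAH,
        vascular_pressure=v["P_V_Pa"],
        base_pore_radius=v["base_pore_radius_nm"],
        permeability_scale=v["permeability_scale_per_m"] * PERM_TO_PERMM,
    )


def build_ici_params(config: Mapping[str, Any]) -> ICIParams:
    block = config["ici"]
    return ICIParams(
        pd1_max_boost=block["pd1_max_boost"],
        pd1_half_conc=block["pd1_half_conc"],
        ctla4_mortality_boost=block["ctla4_mortality_boost"],
        ctla4_window=config["drugs"]["anti_ctla4"].get("effect_window_h", 96.0),
    )
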