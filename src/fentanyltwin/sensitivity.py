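"""Local sensitivity analysis of the coupled model.

Computes the elasticity-type index SI = (U(x+) - U(x-)) / dx * x / U(x)
for the therapy outputs of interest (total delivered drug, mean plasma
concentration over the 72-h wear, mean pain score) with respect to any
scalar model parameter, by rebuilding the virtual patient with the
perturbed value and re-running a single-patch simulation.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .aging import VirtualPatientSpec, build_patient
from .engine import SolverSettings
from .errors import InvalidParameterError
from .metrics import sensitivity_index, total_delivered
from .therapy import run_conventional

__all__ = ["parameter_value", "perturbed_patient", "therapy_output", "therapy_sensitivity", "PARAMETERS", "OUTPUTS"]

#: parameter name -> (getter from a patient spec, builder kwarg route)
PARAMETERS = (
    "d_sc_um", "d_vep_um", "d_edm_um", "d_patch_um",
    "D_patch", "D_epidermis", "D_dermis", "K_epidermis",
    "patch_load_mg", "patch_area_cm2",
    "Vc_L", "Vs_L", "Vr_L", "Vg_L", "Vl_L",
    "kcs", "kcr", "kcg", "kch", "ksc", "krc", "khc", "kgl", "kmet", "kre", "fu",
    "ec50_vas", "gamma_vas", "ke_vas", "ec50_rd", "gamma_rd", "ke_rd",
)

OUTPUTS = ("m_ts", "avg_cp", "avg_vas")


def parameter_value(patient: VirtualPatientSpec, name: str) -> float:
    """Baseline value of a named scalar parameter of a patient spec."""
    st = patient.stack
    skin = {lay.name: lay for lay in st.skin_layers}
    table = {
        "d_sc_um": skin["stratum_corneum"].thickness_m * 1e6,
        "d_vep_um": skin["viable_epidermis"].thickness_m * 1e6,
        "d_edm_um": skin["equivalent_dermis"].thickness_m * 1e6,
        "d_patch_um": st.patch.layer.thickness_m * 1e6,
        "D_patch": st.patch.layer.diffusivity_m2_s,
        "D_epidermis": skin["stratum_corneum"].diffusivity_m2_s,
        "D_dermis": skin["equivalent_dermis"].diffusivity_m2_s,
        "K_epidermis": skin["stratum_corneum"].capacity,
        "patch_load_mg": st.patch.drug_mass_kg * 1e6,
        "patch_area_cm2": st.patch.area_m2 * 1e4,
        "ec50_vas": patient.vas.ec50_ng_ml,
        "gamma_vas": patient.vas.gamma,
        "ke_vas": patient.vas.ke_s,
        "ec50_rd": patient.ventilation.ec50_ng_ml,
        "gamma_rd": patient.ventilation.gamma,
        "ke_rd": patient.ventilation.ke_s,
    }
    if name in table:
        return float(table[name])
    if hasattr(patient.pbpk, name):
        return float(getattr(patient.pbpk, name))
    raise InvalidParameterError(f"unknown parameter {name!r}; choose from {PARAMETERS}")


def perturbed_patient(patient: VirtualPatientSpec, name: str, value: float) -> VirtualPatientSpec:
    """Rebuild a patient spec with one parameter replaced."""
    from .skin import LayerSpec, PatchSpec, SkinStack

    st = patient.stack
    skin = list(st.skin_layers)

    def relayer(idx, **kw):
        lay = skin[idx]
        skin[idx] = LayerSpec(
            lay.name,
            kw.get("thickness_m", lay.thickness_m),
            kw.get("diffusivity_m2_s", lay.diffusivity_m2_s),
            kw.get("capacity", lay.capacity),
        )

    patch = st.patch
    if name == "d_sc_um":
        relayer(0, thickness_m=value * 1e-6)
    elif name == "d_vep_um":
        relayer(1, thickness_m=value * 1e-6)
    elif name == "d_edm_um":
        relayer(2, thickness_m=value * 1e-6)
    elif name == "D_epidermis":
        relayer(0, diffusivity_m2_s=value)
        relayer(1, diffusivity_m2_s=value)
    elif name == "D_dermis":
        relayer(2, diffusivity_m2_s=value)
    elif name == "K_epidermis":
        relayer(0, capacity=value)
        relayer(1, capacity=value)
    elif name == "d_patch_um":
        patch = PatchSpec(
            LayerSpec(patch.layer.name, value * 1e-6, patch.layer.diffusivity_m2_s, patch.layer.capacity),
            patch.area_m2, patch.drug_mass_kg, patch.nominal_flux_ug_h,
        )
    elif name == "D_patch":
        patch = PatchSpec(
            LayerSpec(patch.layer.name, patch.layer.thickness_m, value, patch.layer.capacity),
            patch.area_m2, patch.drug_mass_kg, patch.nominal_flux_ug_h,
        )
    elif name == "patch_load_mg":
        patch = PatchSpec(patch.layer, patch.area_m2, value * 1e-6, patch.nominal_flux_ug_h)
    elif name == "patch_area_cm2":
        patch = PatchSpec(patch.layer, value * 1e-4, patch.drug_mass_kg, patch.nominal_flux_ug_h)
    elif name in ("ec50_vas", "gamma_vas", "ke_vas"):
        key = {"ec50_vas": "ec50_ng_ml", "gamma_vas": "gamma", "ke_vas": "ke_s"}[name]
        return patient.with_(vas=patient.vas.with_(**{key: value}))
    elif name in ("ec50_rd", "gamma_rd", "ke_rd"):
        key = {"ec50_rd": "ec50_ng_ml", "gamma_rd": "gamma", "ke_rd": "ke_s"}[name]
        return patient.with_(ventilation=patient.ventilation.with_(**{key: value}))
    elif hasattr(patient.pbpk, name):
        return patient.with_(pbpk=patient.pbpk.with_(**{name: value}))
    else:
        raise InvalidParameterError(f"unknown parameter {name!r}")
    return patient.with_(stack=SkinStack(patch=patch, skin_layers=tuple(skin)))


def therapy_output(
    patient: VirtualPatientSpec, output: str, settings: SolverSettings | None = None,
    wear_h: float = 72.0,
) -> float:
    """One single-patch therapy run reduced to a scalar output."""
    res = run_conventional(patient, n_patches=1, wear_h=wear_h, horizon_h=wear_h,
                           settings=settings)
    if output == "m_ts":
        return float(total_delivered(res.patch_loads_mg, res.patch_masses_mg)[-1])
    if output == "avg_cp":
        return float(np.mean(res.cp_ng_ml))
    if output == "avg_vas":
        return float(np.mean(res.vas))
    raise InvalidParameterError(f"unknown output {output!r}; choose from {OUTPUTS}")


def therapy_sensitivity(
    patient: VirtualPatientSpec,
    parameter: str,
    output: str,
    delta_frac: float = 0.01,
    settings: SolverSettings | None = None,
) -> float:
    """Sensitivity index of a therapy output to one model parameter."""
    x0 = parameter_value(patient, parameter)

    def model(x: float) -> float:
        return therapy_output(perturbed_patient(patient, parameter, x), output, settings)

    return sensitivity_index(model, x0, delta_frac)
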