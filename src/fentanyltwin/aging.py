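"""Age-specific parameterization of the virtual patient.

Aging affects the skin barrier and the analgesic sensitivity, while the
pharmacokinetic parameters are held age-independent:

* the stratum corneum thickens linearly with age,
* the equivalent diffusive dermis length shrinks linearly with age,
* the half-maximal analgesic concentration EC50 for the pain score falls
  with age (older patients need less opioid), with the slope borrowed from
  the EEG-potency-vs-age literature.

Two EC50 conventions are supported: ``"equation"`` evaluates the borrowed
linear relation literally, while the default ``"anchored"`` rescales it so
that a 20-year-old reproduces the calibrated 1.35 ng ml^-1 while preserving
the normalized age slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError
from .pbpk import PBPKParams
from .pd_models import VAS_DEFAULTS, VENTILATION_DEFAULTS, EffectParams
from .skin import DEFAULT_DERMIS_DIFFUSIVITY, LayerSpec, PatchSpec, SkinStack

__all__ = [
    "AGE_RANGE",
    "VirtualPatientSpec",
    "sc_thickness",
    "dermis_equivalent_thickness",
    "ec50_vas",
    "build_patient",
    "base_case_patient",
    "duragesic_patch",
]

AGE_RANGE = (20.0, 80.0)

# Skin and patch constants for the reference (age-20) adult male.
PATCH_THICKNESS_UM = 50.8
PATCH_DIFFUSIVITY = 6.91e-16
PATCH_CAPACITY = 1.0
VIABLE_EPIDERMIS_UM = 36.5
EPIDERMIS_DIFFUSIVITY = 3.00e-14
EPIDERMIS_CAPACITY = 3.4
DERMIS_CAPACITY = 3.4  # assumed equal to the epidermis
#: Equivalent dermis length tabulated for the age-20 reference patient; the
#: age relation gives 309.5 um at age 20 instead, both conventions are used
#: in practice (tabulated value for the base case, relation for age sweeps).
TABULATED_DERMIS_UM = 320.0

# Reference 75 ug h^-1 drug-in-adhesive patch (Duragesic-like).
REF_PATCH_AREA_CM2 = 30.0
REF_PATCH_LOAD_MG = 12.6
REF_PATCH_NOMINAL_UG_H = 75.0


def _check_age(age: float) -> None:
    if not AGE_RANGE[0] <= age <= AGE_RANGE[1]:
        warnings.warn(
            f"age {age} outside the studied range {AGE_RANGE}; the linear "
            "age relations are extrapolated",
            stacklevel=3,
        )


def sc_thickness(age: float) -> float:
    """Stratum-corneum thickness (um): ``0.125 * age + 11.8``."""
    _check_age(age)
    return 0.125 * age + 11.8


def dermis_equivalent_thickness(age: float) -> float:
    """Equivalent diffusive dermis length (um): ``-2.25 * age + 354.5``."""
    _check_age(age)
    return -2.25 * age + 354.5


def ec50_vas(age: float, mode: str = "anchored") -> float:
    """Half-maximal analgesic concentration (ng ml^-1) at a given age.

    ``"equation"``: evaluate ``-1.148e-2 * age + 1.96`` literally.
    ``"anchored"``: rescale so age 20 gives the calibrated 1.35 ng ml^-1
    while keeping the same relative age slope.
    """
    _check_age(age)
    linear = -1.148e-2 * age + 1.96
    if mode == "equation":
        return linear
    if mode == "anchored":
        at20 = -1.148e-2 * 20.0 + 1.96
        return 1.35 * linear / at20
    raise InvalidParameterError(f"unknown EC50 mode {mode!r} (use 'equation' or 'anchored')")


def duragesic_patch(nominal_flux_ug_h: float = REF_PATCH_NOMINAL_UG_H) -> PatchSpec:
    """Drug-in-matrix patch scaled linearly from the 75 ug h^-1 reference
    (30 cm^2, 12.6 mg); commercial strengths scale area and load with the
    labelled flux."""
    scale = nominal_flux_ug_h / REF_PATCH_NOMINAL_UG_H
    layer = LayerSpec(
        "patch", PATCH_THICKNESS_UM * 1e-6, PATCH_DIFFUSIVITY, PATCH_CAPACITY
    )
    return PatchSpec(
        layer=layer,
        area_m2=REF_PATCH_AREA_CM2 * scale * 1e-4,
        drug_mass_kg=REF_PATCH_LOAD_MG * scale * 1e-6,
        nominal_flux_ug_h=nominal_flux_ug_h,
    )


@dataclass(frozen=True)
class VirtualPatientSpec:
    """Complete parameter set of one virtual patient."""

    age: float
    stack: SkinStack
    pbpk: PBPKParams
    vas: EffectParams
    ventilation: EffectParams
    ec50_mode: str = "anchored"
    baseline_vas: float = 7.0

    def with_(self, **kw) -> "VirtualPatientSpec":
        return replace(self, **kw)


def build_patient(
    age: float,
    *,
    d_sc_um: float | None = None,
    d_edm_um: float | None = None,
    dermis_diffusivity_m2_s: float = DEFAULT_DERMIS_DIFFUSIVITY,
    ec50_mode: str = "anchored",
    patch: PatchSpec | None = None,
    pbpk: PBPKParams | None = None,
    ventilation: EffectParams | None = None,
    vas_ec50_ng_ml: float | None = None,
) -> VirtualPatientSpec:
    """Assemble the full parameter set for a patient of a given age.

    Only the stratum-corneum thickness, the equivalent dermis length and the
    analgesic EC50 depend on age; the pharmacokinetic and ventilation
    parameters are age-independent (insufficient data to model their age
    dependence).  Explicit keyword overrides win over the age relations,
    e.g. ``d_edm_um=320`` reproduces the tabulated base-case geometry.
    """
    if vas_ec50_ng_ml is not None and ec50_mode not in ("equation", "anchored"):
        raise InvalidParameterError("contradictory EC50 overrides")
    d_sc = sc_thickness(age) if d_sc_um is None else d_sc_um
    d_edm = dermis_equivalent_thickness(age) if d_edm_um is None else d_edm_um
    if d_sc <= 0 or d_edm <= 0:
        raise InvalidParameterError("derived skin thicknesses must be positive")
    patch = patch or duragesic_patch()
    stack = SkinStack(
        patch=patch,
        skin_layers=(
            LayerSpec("stratum_corneum", d_sc * 1e-6, EPIDERMIS_DIFFUSIVITY, EPIDERMIS_CAPACITY),
            LayerSpec("viable_epidermis", VIABLE_EPIDERMIS_UM * 1e-6, EPIDERMIS_DIFFUSIVITY, EPIDERMIS_CAPACITY),
            LayerSpec("equivalent_dermis", d_edm * 1e-6, dermis_diffusivity_m2_s, DERMIS_CAPACITY),
        ),
    )
    ec50 = ec50_vas(age, ec50_mode) if vas_ec50_ng_ml is None else vas_ec50_ng_ml
    return VirtualPatientSpec(
        age=age,
        stack=stack,
        pbpk=pbpk or PBPKParams(),
        vas=VAS_DEFAULTS.with_(ec50_ng_ml=ec50),
        ventilation=ventilation or VENTILATION_DEFAULTS,
        ec50_mode=ec50_mode,
    )


def base_case_patient(**kw) -> VirtualPatientSpec:
    """The age-20 reference patient with the tabulated 320 um equivalent
    dermis (the configuration behind the conventional-therapy analysis)."""
    kw.setdefault("d_edm_um", TABULATED_DERMIS_UM)
    return build_patient(20.0, **kw)
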