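"""Five-compartment physiologically based pharmacokinetics of fentanyl.

Compartments: central (plasma + lungs), rapidly equilibrating (brain, heart,
kidneys, skin), slowly equilibrating (muscle, carcass, fat), gastrointestinal
(spleen, gut, pancreas; drains to the liver) and hepatic (CYP3A4 metabolism,
the dominant elimination route).  Renal clearance removes drug from the
central compartment.  The input is the dermal flux delivered over the patch
area.

The first-order rate constants are taken from the fentanyl PBPK literature
as clearances divided by the central volume (outbound) or the tissue volume
(return); written in concentration form the system is not strictly
flow-balanced, which is inherent to this parameterization.

How the unbound plasma fraction ``fu`` enters the transfer terms is a genuine
model choice; see :data:`FU_MODES`.  The default, ``"distribution"``, applies
``fu`` to the permeability-limited exchange with the two equilibrating tissue
compartments while the clearance pathways (hepatic artery + portal inflow,
renal filtration) operate on total plasma concentration, their rate constants
having been calibrated as clearances over total concentration.  This is the
only stable reading that yields a whole-body fentanyl clearance in the
clinically reported range (~0.6-1 L min^-1).  The alternatives are kept for
sensitivity studies; ``"literal"`` (fu on the pooled outbound bracket only)
is dynamically unstable with these rate constants because the return from the
slow compartment then exceeds every central loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .units import KG_M3_TO_NG_ML

__all__ = ["PBPKParams", "PBPKState", "FU_MODES", "pbpk_rhs"]

FU_MODES = ("distribution", "unbound-all", "none", "literal")

_RATE_FIELDS = ("kcs", "kcr", "kcg", "kch", "ksc", "krc", "khc", "kgl", "kmet", "kre")


@dataclass(frozen=True)
class PBPKParams:
    """Volumes (L), first-order rate constants (s^-1) and unbound fraction.

    Defaults are the adult-male fentanyl values used throughout the package.
    """

    Vc_L: float = 23.8
    Vs_L: float = 808.0
    Vr_L: float = 24.5
    Vg_L: float = 17.3
    Vl_L: float = 20.4
    kcs: float = 1.5e-3   # central -> slow
    kcr: float = 1.2e-3   # central -> rapid
    kcg: float = 5.0e-4   # central -> gastrointestinal
    kch: float = 1.2e-4   # central -> hepatic (hepatic artery)
    ksc: float = 5.0e-5   # slow -> central
    krc: float = 1.2e-3   # rapid -> central
    khc: float = 7.0e-4   # hepatic -> central
    kgl: float = 5.0e-5   # gastrointestinal -> hepatic (portal)
    kmet: float = 4.2e-3  # hepatic CYP metabolism
    kre: float = 3.0e-5   # renal clearance (from central)
    fu: float = 0.22
    fu_mode: str = "distribution"

    def __post_init__(self) -> None:
        for name in ("Vc_L", "Vs_L", "Vr_L", "Vg_L", "Vl_L", *_RATE_FIELDS):
            if getattr(self, name) < 0 or (name.startswith("V") and getattr(self, name) <= 0):
                raise InvalidParameterError(f"{name} must be positive")
        if not 0.0 < self.fu <= 1.0:
            raise InvalidParameterError("fu must be in (0, 1]")
        if self.fu_mode not in FU_MODES:
            raise InvalidParameterError(f"fu_mode must be one of {FU_MODES}")

    def with_(self, **kwargs) -> "PBPKParams":
        return replace(self, **kwargs)

    @property
    def volumes_m3(self) -> np.ndarray:
        return np.array([self.Vc_L, self.Vr_L, self.Vs_L, self.Vg_L, self.Vl_L]) * 1e-3


@dataclass
class PBPKState:
    """Compartment concentrations in ng ml^-1 (reporting units)."""

    cp: float = 0.0
    cr: float = 0.0
    cs: float = 0.0
    cg: float = 0.0
    cl: float = 0.0

    def as_array_si(self) -> np.ndarray:
        return np.array([self.cp, self.cr, self.cs, self.cg, self.cl]) / KG_M3_TO_NG_ML

    @classmethod
    def from_array_si(cls, arr: np.ndarray) -> "PBPKState":
        cp, cr, cs, cg, cl = (float(x) * KG_M3_TO_NG_ML for x in arr)
        return cls(cp, cr, cs, cg, cl)


def pbpk_rhs_si(
    c: np.ndarray, dermal_flux_si: float, params: PBPKParams, area_m2: float
) -> np.ndarray:
    """Time derivatives of [cp, cr, cs, cg, cl] in SI concentration units.

    ``dermal_flux_si`` is the total flux out of the dermis (kg m^-2 s^-1)
    over ``area_m2`` of application area; the source term is
    ``flux * A / Vc``.
    """
    p = params
    cp, cr, cs, cg, cl = c
    inp = dermal_flux_si * area_m2 / (p.Vc_L * 1e-3)
    returns = p.krc * cr + p.ksc * cs + p.khc * cl
    if p.fu_mode == "distribution":
        dcp = inp - (p.kcs + p.kcr) * p.fu * cp - (p.kcg + p.kch + p.kre) * cp + returns
        u_dist, u_cl = p.fu * cp, cp
    elif p.fu_mode == "unbound-all":
        dcp = inp - (p.kcs + p.kcr + p.kcg + p.kch + p.kre) * p.fu * cp + returns
        u_dist = u_cl = p.fu * cp
    elif p.fu_mode == "none":
        dcp = inp - (p.kcs + p.kcr + p.kcg + p.kch + p.kre) * cp + returns
        u_dist = u_cl = cp
    else:  # literal: fu on the pooled outbound bracket, tissues see total cp
        dcp = inp - (p.kcs + p.kcr + p.kcg + p.kch + p.kre) * p.fu * cp + returns
        u_dist = u_cl = cp
    dcr = p.kcr * u_dist - p.krc * cr
    dcs = p.kcs * u_dist - p.ksc * cs
    dcg = p.kcg * u_cl - p.kgl * cg
    dcl = p.kch * u_cl - p.khc * cl + p.kgl * cg - p.kmet * cl
    return np.array([dcp, dcr, dcs, dcg, dcl])


def pbpk_rhs(
    state: PBPKState, dermal_flux_si: float, params: PBPKParams, area_m2: float | None = None
) -> PBPKState:
    """Derivatives of the compartment concentrations (ng ml^-1 s^-1).

    Raises if any state component is meaningfully negative.
    """
    if dermal_flux_si < 0:
        raise InvalidParameterError("dermal flux must be >= 0")
    arr = state.as_array_si()
    if arr.min() < -1e-12:
        raise InvalidParameterError("negative compartment concentration")
    a = area_m2 if area_m2 is not None else 30e-4
    d = pbpk_rhs_si(arr, dermal_flux_si, params, a)
    return PBPKState(*(float(x) * KG_M3_TO_NG_ML for x in d))
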