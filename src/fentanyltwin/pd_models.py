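"""Effect-compartment pharmacodynamics: pain score and minute ventilation.

Each effect has a hypothetical effect compartment whose concentration ``ce``
follows plasma with a first-order rate ``ke`` (``dce/dt = ke (cp - ce)``),
and a sigmoid maximum-effect (Hill) concentration-effect relation

    E(ce) = E0 - Emax * ce^gamma / (EC50^gamma + ce^gamma)

Pain is measured on the visual analog scale (VAS, 0-10; baseline 7, target
below 3); the respiratory effect is tracked as minute ventilation in
L min^-1 (baseline 20).  ``fit_emax`` calibrates the Hill parameters from a
concentration-effect table by bounded nonlinear least squares with a small
deterministic multistart, as Hill fits are multimodal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidParameterError

__all__ = [
    "EffectParams",
    "EffectSeries",
    "VAS_DEFAULTS",
    "VENTILATION_DEFAULTS",
    "effect_compartment_rhs",
    "emax_effect",
    "concentration_for_effect",
    "fit_emax",
    "EmaxFit",
]


@dataclass(frozen=True)
class EffectParams:
    """Parameters of one effect-compartment + sigmoid-Emax model.

    ``baseline`` is the drug-free effect level E0; ``emax`` the maximum
    reduction from baseline; ``ec50_ng_ml`` the effect-compartment
    concentration at half-maximal effect; ``gamma`` the Hill coefficient.
    """

    ke_s: float
    baseline: float
    emax: float
    ec50_ng_ml: float
    gamma: float

    def __post_init__(self) -> None:
        if self.ke_s <= 0:
            raise InvalidParameterError("ke must be > 0")
        if self.ec50_ng_ml <= 0:
            raise InvalidParameterError("EC50 must be > 0")
        if self.gamma <= 0:
            raise InvalidParameterError("gamma must be > 0")
        if self.emax < 0:
            raise InvalidParameterError("Emax must be >= 0")

    def with_(self, **kw) -> "EffectParams":
        return replace(self, **kw)


#: VAS pain score model for a 20-year-old (full pain suppression possible).
VAS_DEFAULTS = EffectParams(ke_s=2e-3, baseline=7.0, emax=7.0, ec50_ng_ml=1.35, gamma=2.7)

#: Minute-ventilation depression model (maximum effect 12 * 0.91 L min^-1).
VENTILATION_DEFAULTS = EffectParams(
    ke_s=7e-4, baseline=20.0, emax=12.0 * 0.91, ec50_ng_ml=1.14, gamma=2.68
)


@dataclass
class EffectSeries:
    """Aligned pharmacodynamic trajectories of a simulation."""

    time_h: np.ndarray
    ce_vas_ng_ml: np.ndarray
    ce_rd_ng_ml: np.ndarray
    vas: np.ndarray
    ventilation_l_min: np.ndarray


def effect_compartment_rhs(ce: float, cp: float, ke_s: float) -> float:
    """First-order approach of the effect-site concentration toward plasma."""
    if ke_s <= 0:
        raise InvalidParameterError("ke must be > 0")
    return ke_s * (cp - ce)


def emax_effect(ce_ng_ml, params: EffectParams):
    """Sigmoid-Emax effect at effect-site concentration ``ce`` (vectorized).

    Monotone non-increasing in ``ce``; bounded in
    ``[baseline - emax, baseline]``.
    """
    ce = np.asarray(ce_ng_ml, dtype=float)
    if np.any(ce < 0):
        raise InvalidParameterError("effect-site concentration must be >= 0")
    x = (ce / params.ec50_ng_ml) ** params.gamma
    out = params.baseline - params.emax * x / (1.0 + x)
    return float(out) if np.isscalar(ce_ng_ml) else out


def concentration_for_effect(level: float, params: EffectParams) -> float:
    """Inverse of :func:`emax_effect`: ce at which the effect equals ``level``."""
    lo, hi = params.baseline - params.emax, params.baseline
    if not lo < level < hi:
        raise InvalidParameterError(f"effect level must lie strictly in ({lo}, {hi})")
    h = (params.baseline - level) / params.emax  # fractional effect in (0, 1)
    return params.ec50_ng_ml * (h / (1.0 - h)) ** (1.0 / params.gamma)


@dataclass
class EmaxFit:
    """Result of a sigmoid-Emax calibration."""

    baseline: float
    emax: float
    ec50_ng_ml: float
    gamma: float
    rmsd: float
    residuals: np.ndarray

    def as_effect_params(self, ke_s: float) -> EffectParams:
        return EffectParams(ke_s, self.baseline, self.emax, self.ec50_ng_ml, self.gamma)


def fit_emax(
    concentration_ng_ml: Sequence[float],
    effect: Sequence[float],
    fixed: dict[str, float] | None = None,
) -> EmaxFit:
    """Least-squares calibration of the Hill relation to a data table.

    Parameters
    ----------
    concentration_ng_ml, effect:
        Paired observations; at least 4 points spanning both sides of the
        inflection are needed for a well-posed fit.
    fixed:
        Optionally pin ``baseline`` (E0) and/or ``emax``; the remaining
        parameters are estimated.

    The optimizer multistarts over gamma in {1, 2, 4} and EC50 at the data
    quantiles, keeping the best converged solution; the reported RMSD is in
    effect units.
    """
    c = np.asarray(concentration_ng_ml, dtype=float)
    e = np.asarray(effect, dtype=float)
    if c.size != e.size or c.size < 4:
        raise FitFailureError("need >= 4 paired (concentration, effect) points")
    if np.any(c < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    if np.ptp(e) == 0.0:
        raise FitFailureError("constant effect table: Emax model is unidentifiable")

    fixed = fixed or {}
    e0_fix = fixed.get("baseline", fixed.get("E0"))
    emax_fix = fixed.get("emax", fixed.get("Emax"))
    free_e0 = e0_fix is None
    free_emax = emax_fix is None

    def unpack(theta):
        i = 0
        if free_e0:
            e0 = theta[i]; i += 1
        else:
            e0 = e0_fix
        if free_emax:
            em = theta[i]; i += 1
        else:
            em = emax_fix
        ec50, gamma = theta[i], theta[i + 1]
        return e0, em, ec50, gamma

    def resid(theta):
        e0, em, ec50, gamma = unpack(theta)
        x = (c / ec50) ** gamma
        return e0 - em * x / (1.0 + x) - e

    e0_guess = float(e.max())
    emax_guess = float(np.ptp(e))
    pos = c[c > 0]
    if pos.size == 0:
        raise FitFailureError("all concentrations are zero")
    ec50_starts = np.quantile(pos, [0.25, 0.5, 0.75])
    lo, hi = [], []
    if free_e0:
        lo.append(0.0); hi.append(np.inf)
    if free_emax:
        lo.append(0.0); hi.append(np.inf)
    lo += [1e-6, 0.2]
    hi += [np.inf, 12.0]

    best = None
    for g0 in (1.0, 2.0, 4.0):
        for ec0 in ec50_starts:
            x0 = []
            if free_e0:
                x0.append(e0_guess)
            if free_emax:
                x0.append(emax_guess)
            x0 += [float(ec0), g0]
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi))
            except ValueError:
                continue
            if not sol.success:
                continue
            cost = float(sol.cost)
            if best is None or cost < best[0]:
                best = (cost, sol)
    if best is None:
        raise FitFailureError("Emax fit did not converge from any start point")
    sol = best[1]
    e0, em, ec50, gamma = unpack(sol.x)
    r = resid(sol.x)
    rmsd = float(np.sqrt(np.mean(r**2)))
    return EmaxFit(float(e0), float(em), float(ec50), float(gamma), rmsd, r)
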