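"""Mass bookkeeping, therapy-quality summaries and local sensitivity.

Drug-mass accounting mirrors the three therapy metrics used for transdermal
systems: the residual patch content m_pt(t) (initial load minus the
time-integral of the patch outflux), the total delivered amount m_ts(t)
(summed over all patches used) and the drug stored in the skin m_s(t)
(spatial integral of the concentration field).  "Time without pain" is the
cumulative duration with VAS strictly below the target, with linear
interpolation at threshold crossings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .errors import FentanylTwinError, InvalidParameterError
from .units import HYPOVENTILATION_THRESHOLD_L_MIN

__all__ = [
    "remaining_drug",
    "total_delivered",
    "drug_in_skin",
    "time_without_pain",
    "time_below_threshold",
    "sensitivity_index",
    "TherapySummary",
    "summarize",
    "compare_therapies",
]


def remaining_drug(
    time_h: np.ndarray,
    flux_patch_ug_cm2_h: np.ndarray,
    m0_mg: float,
    area_cm2: float,
    conservation_tol: float = 1e-3,
) -> np.ndarray:
    """Residual patch drug mass (mg) from the patch-outflux series.

    Trapezoidal cumulative integral of flux * area subtracted from the
    initial load.  A result below ``-conservation_tol * m0`` indicates an
    inconsistent flux series and raises.
    """
    t = np.asarray(time_h, float)
    f = np.asarray(flux_patch_ug_cm2_h, float)
    released_ug = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(t))]) * area_cm2
    m = m0_mg - released_ug * 1e-3
    if m.min() < -conservation_tol * max(m0_mg, 1e-12):
        raise FentanylTwinError(
            f"patch mass went negative ({m.min():.4g} mg): flux series inconsistent with load"
        )
    return m


def total_delivered(
    patch_loads_mg: Sequence[float], patch_masses_mg: Sequence[np.ndarray] | np.ndarray
) -> np.ndarray:
    """Total drug delivered out of all patches used so far (mg).

    ``patch_masses_mg`` holds one residual-mass series per patch (NaN before
    the patch is applied, frozen at its removal residual afterwards).
    """
    masses = np.atleast_2d(np.asarray(patch_masses_mg, float))
    loads = np.asarray(patch_loads_mg, float)
    if masses.shape[0] != loads.size:
        raise InvalidParameterError("one load per patch series required")
    filled = np.where(np.isnan(masses), loads[:, None], masses)
    return np.sum(loads[:, None] - filled, axis=0)


def drug_in_skin(
    concentration_kg_m3: np.ndarray, cell_widths_m: np.ndarray, area_m2: float
) -> float:
    """Spatial integral of a skin concentration field: mass in mg."""
    c = np.asarray(concentration_kg_m3, float)
    dz = np.asarray(cell_widths_m, float)
    if c.shape[-1] != dz.size:
        raise InvalidParameterError("field and grid sizes differ")
    return float(np.sum(c * dz, axis=-1) * area_m2 * 1e6)


def time_below_threshold(
    time_h: np.ndarray, series: np.ndarray, threshold: float
) -> float:
    """Cumulative time (h) a sampled series spends strictly below a
    threshold, locating crossings by linear interpolation."""
    t = np.asarray(time_h, float)
    y = np.asarray(series, float)
    if t.size != y.size or t.size < 2:
        raise InvalidParameterError("need aligned series with >= 2 samples")
    below = y < threshold
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        b0, b1 = below[i], below[i + 1]
        if b0 and b1:
            total += dt
        elif b0 != b1:
            # fraction of the interval on the below side
            denom = y[i + 1] - y[i]
            frac = (threshold - y[i]) / denom if denom != 0 else 0.5
            total += dt * (frac if b0 else 1.0 - frac)
    return total


def time_without_pain(
    time_h: np.ndarray, vas: np.ndarray, target: float = 3.0
) -> float:
    """Total duration (h) with the VAS pain score strictly under the target."""
    return time_below_threshold(time_h, vas, target)


def sensitivity_index(
    model: Callable[[float], float],
    x0: float,
    delta_frac: float = 0.01,
) -> float:
    """Local elasticity ``SI = dU/dx * x/U`` by central differences.

    ``model(x)`` evaluates the output of interest at parameter value ``x``;
    the derivative uses symmetric perturbations ``x0 * (1 +- delta_frac)``.
    A zero baseline output leaves the index undefined and raises.
    """
    if x0 == 0:
        raise InvalidParameterError("central relative perturbation needs x0 != 0")
    u0 = model(x0)
    if u0 == 0:
        raise FentanylTwinError("baseline output is zero: sensitivity index undefined")
    dx = x0 * delta_frac
    up, dn = model(x0 + dx), model(x0 - dx)
    return (up - dn) / (2.0 * dx) * x0 / u0


@dataclass(frozen=True)
class TherapySummary:
    """Per-run therapy quality metrics."""

    max_cp_ng_ml: float
    avg_cp_wear_ng_ml: float
    avg_vas: float
    time_without_pain_h: float
    min_ventilation_l_min: float
    hypoventilation_h: float
    hypoventilation_threshold_l_min: float
    unused_drug_fraction: float
    n_patches: int
    horizon_h: float


def _avg_cp_over_wear(result: SimulationResult) -> float:
    """Mean plasma concentration over each patch's wear window, then
    averaged over patches."""
    applications = [e for e in result.events if e.trigger in ("scheduled", "pain", "feedback")]
    if not applications:
        return float(np.mean(result.cp_ng_ml))
    bounds = [e.time_h for e in applications] + [result.time_h[-1]]
    means = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        m = (result.time_h >= a) & (result.time_h <= b)
        if m.sum() >= 2:
            means.append(float(np.mean(result.cp_ng_ml[m])))
    return float(np.mean(means)) if means else float(np.mean(result.cp_ng_ml))


def summarize(
    result: SimulationResult,
    pain_target: float = 3.0,
    hypoventilation_threshold_l_min: float | None = None,
) -> TherapySummary:
    """Therapy-quality summary of one simulation."""
    thr = (
        HYPOVENTILATION_THRESHOLD_L_MIN
        if hypoventilation_threshold_l_min is None
        else hypoventilation_threshold_l_min
    )
    final_masses = np.where(
        np.isnan(result.patch_masses_mg[:, -1]),
        result.patch_loads_mg,
        result.patch_masses_mg[:, -1],
    )
    total_load = float(np.sum(result.patch_loads_mg))
    unused = float(np.sum(final_masses) / total_load) if total_load > 0 else 1.0
    return TherapySummary(
        max_cp_ng_ml=float(np.max(result.cp_ng_ml)),
        avg_cp_wear_ng_ml=_avg_cp_over_wear(result),
        avg_vas=float(np.mean(result.vas)),
        time_without_pain_h=time_without_pain(result.time_h, result.vas, pain_target),
        min_ventilation_l_min=float(np.min(result.ventilation_l_min)),
        hypoventilation_h=time_below_threshold(result.time_h, result.ventilation_l_min, thr),
        hypoventilation_threshold_l_min=thr,
        unused_drug_fraction=unused,
        n_patches=result.n_patches,
        horizon_h=float(result.time_h[-1]),
    )


def compare_therapies(
    results: dict[str, SimulationResult],
    pain_target: float = 3.0,
    hypoventilation_threshold_l_min: float | None = None,
) -> pd.DataFrame:
    """Side-by-side therapy comparison table, one row per arm."""
    if len(results) < 2:
        raise InvalidParameterError("need at least two therapy arms to compare")
    horizons = {round(float(r.time_h[-1]), 6) for r in results.values()}
    if len(horizons) > 1:
        raise InvalidParameterError(f"therapy arms have mismatched horizons: {sorted(horizons)}")
    rows = {}
    for name, res in results.items():
        s = summarize(res, pain_target, hypoventilation_threshold_l_min)
        rows[name] = {
            "max_cp_ng_ml": s.max_cp_ng_ml,
            "avg_vas": s.avg_vas,
            "time_without_pain_h": s.time_without_pain_h,
            "min_ventilation_l_min": s.min_ventilation_l_min,
            "hypoventilation_h": s.hypoventilation_h,
            "unused_drug_fraction": s.unused_drug_fraction,
            "n_patches": s.n_patches,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
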