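"""Therapy policies: conventional fixed-interval replacement, the
pain-triggered precalibrated twin, and the feedback-updated real-time twin.

The precalibrated controller replaces the worn patch whenever the computed
VAS pain score is above the target (default 3) *and* rising, with a minimum
wear time guarding the application lag.  The real-time variant additionally
ingests the patient's reported integer pain score every 24 hours; the
difference between the report and the model prediction persists as an
additive correction to the controller's working pain score until the next
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aging import VirtualPatientSpec, duragesic_patch
from .engine import ReplacementPolicy, SimulationResult, SolverSettings, run_therapy
from .errors import InvalidParameterError
from .skin import PatchSpec

__all__ = [
    "TherapySchedule",
    "ControllerConfig",
    "FeedbackTrace",
    "FixedIntervalPolicy",
    "PainControllerPolicy",
    "run_conventional",
    "run_precalibrated",
    "run_feedback",
    "generate_population",
    "run_population",
]


@dataclass(frozen=True)
class TherapySchedule:
    """Fixed application plan: (apply_h, remove_h, site_id) per patch."""

    entries: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        last_end = -1.0
        for a, r, _ in self.entries:
            if r <= a:
                raise InvalidParameterError("patch removal must follow application")
            if a < last_end:
                raise InvalidParameterError("at most one patch may be worn at a time")
            last_end = r

    @classmethod
    def conventional(cls, n_patches: int = 3, wear_h: float = 72.0) -> "TherapySchedule":
        return cls(tuple((i * wear_h, (i + 1) * wear_h, i) for i in range(n_patches)))


@dataclass(frozen=True)
class ControllerConfig:
    """Decision parameters of the pain-triggered controller."""

    pain_target: float = 3.0
    gradient_epsilon: float = 1e-3  # VAS h^-1; guards chattering at the target
    #: A decision taken sooner than this after a fresh application carries no
    #: information about the new patch: fentanyl reaches plasma with a ~1.5 h
    #: skin time-lag and the pain effect lags plasma further, so the guard
    #: must cover the whole uptake chain or every change double-fires.
    min_wear_h: float = 3.0
    horizon_h: float = 216.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pain_target < 10.0:
            raise InvalidParameterError("pain_target must be in (0, 10)")
        if self.min_wear_h <= 0:
            raise InvalidParameterError("min_wear_h must be > 0")


@dataclass(frozen=True)
class FeedbackTrace:
    """Reported-pain deviations of one virtual patient.

    ``deviations[k]`` is the integer difference (in [-2, 2]) between the
    patient's reported pain and the model's rounded prediction at
    ``times_h[k]`` (every 24 h; 8 moments over a 9-day therapy).
    """

    patient_id: int
    deviations: tuple[int, ...]
    times_h: tuple[float, ...] = tuple(24.0 * k for k in range(1, 9))

    def __post_init__(self) -> None:
        if len(self.deviations) != len(self.times_h):
            raise InvalidParameterError("one deviation per feedback moment required")
        if any(abs(d) > 2 for d in self.deviations):
            raise InvalidParameterError("|deviation| must be <= 2 VAS units")


class FixedIntervalPolicy(ReplacementPolicy):
    """Conventional therapy: n patches, each worn for a fixed interval."""

    def __init__(self, n_patches: int = 3, wear_h: float = 72.0,
                 patch: PatchSpec | None = None):
        if n_patches < 1:
            raise InvalidParameterError("need at least one patch")
        self.n_patches = n_patches
        self.wear_h = wear_h
        self.patch = patch

    def scheduled_actions(self, horizon_h: float) -> list[tuple[float, str]]:
        acts: list[tuple[float, str]] = []
        for i in range(1, self.n_patches):
            t = i * self.wear_h
            if t < horizon_h:
                acts.append((t, "replace"))
        t_off = self.n_patches * self.wear_h
        if t_off < horizon_h:
            acts.append((t_off, "remove"))
        return acts

    def replacement_patch(self, default: PatchSpec) -> PatchSpec:
        return self.patch or default


class PainControllerPolicy(ReplacementPolicy):
    """Replace the patch when pain is above target and rising.

    With a :class:`FeedbackTrace` the controller's working pain score is the
    model score corrected by the patient's last report.
    """

    def __init__(self, config: ControllerConfig | None = None,
                 trace: FeedbackTrace | None = None,
                 patch: PatchSpec | None = None):
        self.config = config or ControllerConfig()
        self.trace = trace
        self.patch = patch
        self.feedback_times = tuple(trace.times_h) if trace is not None else ()

    def trigger_mask(self, t_h, working_vas, dvas_dt, wear_h):
        c = self.config
        return (
            (working_vas > c.pain_target)
            & (dvas_dt > c.gradient_epsilon)
            & (wear_h >= c.min_wear_h)
        )

    def deviation_at(self, time_h: float) -> int:
        for t, d in zip(self.trace.times_h, self.trace.deviations):
            if abs(t - time_h) < 1e-6:
                return int(d)
        return 0

    def replacement_patch(self, default: PatchSpec) -> PatchSpec:
        return self.patch or default


def run_conventional(
    patient: VirtualPatientSpec,
    n_patches: int = 3,
    wear_h: float = 72.0,
    horizon_h: float = 216.0,
    settings: SolverSettings | None = None,
    patch: PatchSpec | None = None,
) -> SimulationResult:
    """Fixed-interval therapy (default: three 72-h patches over 9 days)."""
    if wear_h <= 0:
        # degenerate request: nothing is ever worn; simulate a drug-free patch
        empty = (patch or patient.stack.patch)
        zero = PatchSpec(empty.layer, empty.area_m2, 0.0, empty.nominal_flux_ug_h)
        return run_therapy(patient, FixedIntervalPolicy(1, horizon_h * 2, zero),
                           horizon_h, settings)
    return run_therapy(
        patient, FixedIntervalPolicy(n_patches, wear_h, patch), horizon_h, settings
    )


def run_precalibrated(
    patient: VirtualPatientSpec,
    config: ControllerConfig | None = None,
    settings: SolverSettings | None = None,
) -> SimulationResult:
    """Pain-triggered therapy driven by the precalibrated twin."""
    config = config or ControllerConfig()
    return run_therapy(patient, PainControllerPolicy(config), config.horizon_h, settings)


def run_feedback(
    patient: VirtualPatientSpec,
    trace: FeedbackTrace,
    config: ControllerConfig | None = None,
    settings: SolverSettings | None = None,
) -> SimulationResult:
    """Pain-triggered therapy updated by the patient's reported pain."""
    config = config or ControllerConfig()
    return run_therapy(
        patient, PainControllerPolicy(config, trace=trace), config.horizon_h, settings
    )


def generate_population(
    n: int = 100, seed: int | None = None, n_moments: int = 8, cadence_h: float = 24.0
) -> list[FeedbackTrace]:
    """Seeded virtual population of reported-pain deviation traces.

    Deviations are integers drawn uniformly from {-2, ..., 2} at each
    feedback moment — a maximum-entropy choice under the stated +-2 bound.
    """
    if n < 1:
        raise InvalidParameterError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    times = tuple(cadence_h * k for k in range(1, n_moments + 1))
    devs = rng.integers(-2, 3, size=(n, n_moments))
    return [FeedbackTrace(i, tuple(int(d) for d in devs[i]), times) for i in range(n)]


def run_population(
    patient: VirtualPatientSpec,
    traces: Sequence[FeedbackTrace],
    config: ControllerConfig | None = None,
    settings: SolverSettings | None = None,
    hypoventilation_threshold_l_min: float | None = None,
) -> pd.DataFrame:
    """One feedback therapy per trace; returns a summary row per patient."""
    from .metrics import summarize

    rows = []
    for trace in traces:
        res = run_feedback(patient, trace, config, settings)
        s = summarize(res, hypoventilation_threshold_l_min=hypoventilation_threshold_l_min)
        rows.append(
            {
                "patient_id": trace.patient_id,
                "avg_cp_ng_ml": float(np.mean(res.cp_ng_ml)),
                "avg_vas": s.avg_vas,
                "avg_ventilation_l_min": float(np.mean(res.ventilation_l_min)),
                "time_without_pain_h": s.time_without_pain_h,
                "n_patches": s.n_patches,
            }
        )
    return pd.DataFrame(rows)
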