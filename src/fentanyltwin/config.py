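"""Run configuration: a fully serializable description of one simulation.

A run re-executed from its dumped configuration (same seed) is reproducible
bit-for-bit; every physical quantity in the file carries an explicit unit
suffix in its key name.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .aging import VirtualPatientSpec, build_patient
from .engine import SolverSettings
from .errors import InvalidParameterError
from .therapy import ControllerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    age_years: float = 20.0
    d_edm_um: float | None = None
    d_sc_um: float | None = None
    ec50_mode: str = "anchored"
    fu_mode: str = "distribution"
    patch_nominal_flux_ug_h: float = 75.0
    policy: str = "conventional"  # conventional | precalibrated | feedback
    n_patches: int = 3
    wear_h: float = 72.0
    horizon_h: float = 216.0
    pain_target: float = 3.0
    gradient_epsilon_vas_h: float = 1e-3
    min_wear_h: float = 3.0
    site_mode: str = "multi"
    output_step_h: float = 0.1
    rtol: float = 1e-8
    atol: float = 1e-12
    population_n: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.policy not in ("conventional", "precalibrated", "feedback"):
            raise InvalidParameterError(f"unknown policy {self.policy!r}")

    def patient(self) -> VirtualPatientSpec:
        from .aging import duragesic_patch
        from .pbpk import PBPKParams

        return build_patient(
            self.age_years,
            d_edm_um=self.d_edm_um,
            d_sc_um=self.d_sc_um,
            ec50_mode=self.ec50_mode,
            patch=duragesic_patch(self.patch_nominal_flux_ug_h),
            pbpk=PBPKParams(fu_mode=self.fu_mode),
        )

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            rtol=self.rtol, atol=self.atol, output_step_h=self.output_step_h,
            site_mode=self.site_mode,
        )

    def controller(self) -> ControllerConfig:
        return ControllerConfig(
            pain_target=self.pain_target,
            gradient_epsilon=self.gradient_epsilon_vas_h,
            min_wear_h=self.min_wear_h,
            horizon_h=self.horizon_h,
        )

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg
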