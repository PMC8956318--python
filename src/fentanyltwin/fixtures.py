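"""Deterministic synthetic input generators for tests and demos."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .pd_models import VAS_DEFAULTS, emax_effect
from .therapy import generate_population

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("emax_table", "feedback_traces", "toy_membrane")


def make_fixture(kind: str, seed: int = 0, out_dir: str | Path | None = None,
                 n: int = 30, noise_sd: float = 0.0):
    """Create a small deterministic input of the requested kind.

    ``emax_table``: (concentration, effect) pairs sampled from the sigmoid
    pain model, optionally with Gaussian noise — consumable by ``fit_emax``.
    ``feedback_traces``: a seeded population deviation matrix.
    ``toy_membrane``: a single-slab membrane configuration whose analytic
    lag time is d^2 / (6 D).

    Returns the in-memory object; also writes a file when ``out_dir`` is
    given (CSV for tables/traces, YAML for configs).
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    if kind == "emax_table":
        conc = np.linspace(0.05, 4.0, n)
        eff = emax_effect(conc, VAS_DEFAULTS) + rng.normal(0.0, noise_sd, size=n)
        table = pd.DataFrame({"concentration_ng_ml": conc, "effect": eff})
        if out_dir is not None:
            table.to_csv(out_dir / "emax_table.csv", index=False)
        return table

    if kind == "feedback_traces":
        traces = generate_population(n=n, seed=seed)
        frame = pd.DataFrame(
            [t.deviations for t in traces],
            columns=[f"t{int(h)}h" for h in traces[0].times_h],
        )
        frame.insert(0, "patient_id", [t.patient_id for t in traces])
        if out_dir is not None:
            frame.to_csv(out_dir / "feedback_traces.csv", index=False)
        return traces

    if kind == "toy_membrane":
        cfg = {
            "membrane": {
                "thickness_um": 100.0,
                "diffusivity_m2_s": 1.0e-12,
                "capacity": 1.0,
                "analytic_lag_s": (100e-6) ** 2 / (6 * 1.0e-12),
            },
            "donor_concentration_kg_m3": 10.0,
            "seed": seed,
        }
        if out_dir is not None:
            (out_dir / "toy_membrane.yaml").write_text(yaml.safe_dump(cfg))
        return cfg

    raise InvalidParameterError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
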