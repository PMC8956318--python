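"""Coupled simulation engine: conservation, qualitative pharmacology, modes."""

import numpy as np
import pytest

from fentanyltwin import (
    InvalidParameterError,
    SolverSettings,
    run_conventional,
    run_therapy,
)
from fentanyltwin.engine import ReplacementPolicy
from fentanyltwin.units import THERAPEUTIC_MAX_NG_ML, THERAPEUTIC_MIN_NG_ML


def cumulative_to_blood_mg(result):
    area_cm2 = result.patient.stack.patch.area_m2 * 1e4
    flux = result.flux_dermis_ug_cm2_h
    t = result.time_h
    return (
        np.concatenate([[0.0], np.cumsum(0.5 * (flux[1:] + flux[:-1]) * np.diff(t))])
        * area_cm2 * 1e-3
    )


class TestConservation:
    def test_mass_closure_within_half_percent(self, conventional_result):
        res = conventional_result
        masses = np.where(
            np.isnan(res.patch_masses_mg), res.patch_loads_mg[:, None], res.patch_masses_mg
        )
        in_system = masses.sum(axis=0) + res.skin_mass_mg + cumulative_to_blood_mg(res)
        closure = in_system / res.patch_loads_mg.sum()
        assert np.abs(closure - 1.0).max() < 5e-3

    def test_delivered_mass_monotone(self, conventional_result):
        assert np.all(np.diff(conventional_result.delivered_mg) >= -1e-9)

    def test_patch_mass_frozen_after_removal(self, conventional_result):
        res = conventional_result
        first = res.patch_masses_mg[0]
        after = first[res.time_h >= 73.0]
        assert np.allclose(after, after[0])


class TestPharmacologyShape:
    def test_concentrations_nonnegative(self, conventional_result):
        for series in (
            conventional_result.cp_ng_ml,
            conventional_result.cr_ng_ml,
            conventional_result.cs_ng_ml,
            conventional_result.cg_ng_ml,
            conventional_result.cl_ng_ml,
        ):
            assert series.min() > -1e-9

    def test_single_patch_band_residence_then_decay(self, base_patient):
        res = run_conventional(base_patient, n_patches=1, wear_h=72.0, horizon_h=216.0)
        cp = res.cp_ng_ml
        assert cp.max() < THERAPEUTIC_MAX_NG_ML
        in_band = cp >= THERAPEUTIC_MIN_NG_ML
        assert in_band.any()
        # contiguous residence: once the concentration leaves the band after
        # depletion it does not re-enter
        last_in = np.where(in_band)[0][-1]
        assert np.all(~in_band[last_in + 1:])
        tail = cp[res.time_h > res.time_h[last_in]]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_effect_compartment_lags_plasma(self, single_patch_result):
        res = single_patch_result
        t_cp = res.time_h[np.argmax(res.cp_ng_ml)]
        t_ce = res.time_h[np.argmax(res.ce_vas_ng_ml)]
        assert t_ce >= t_cp
        # the two profiles nearly coincide (high permeability effect site)
        assert np.max(np.abs(res.ce_vas_ng_ml - res.cp_ng_ml)) < 0.2 * res.cp_ng_ml.max()

    def test_effects_bounded(self, conventional_result):
        res = conventional_result
        assert np.all((res.vas >= 0.0) & (res.vas <= 7.0 + 1e-9))
        assert np.all(
            (res.ventilation_l_min >= 20.0 - 10.92 - 1e-9)
            & (res.ventilation_l_min <= 20.0 + 1e-9)
        )

    def test_zero_load_patch_keeps_baseline(self, base_patient):
        res = run_conventional(base_patient, wear_h=0.0, horizon_h=24.0)
        assert np.allclose(res.vas, 7.0)
        assert np.allclose(res.cp_ng_ml, 0.0)


class TestModesAndBookkeeping:
    def test_conventional_event_log(self, conventional_result):
        frame = conventional_result.events_frame()
        applications = frame[frame.trigger == "scheduled"]
        assert list(np.round(applications.change_time_h, 6)) == [0.0, 72.0, 144.0]
        assert conventional_result.n_patches == 3

    def test_reset_mode_matches_multi_until_first_change(self, base_patient, conventional_result):
        res_reset = run_conventional(
            base_patient, settings=SolverSettings(site_mode="reset")
        )
        m = conventional_result.time_h <= 72.0
        assert np.allclose(
            res_reset.cp_ng_ml[m], conventional_result.cp_ng_ml[m], rtol=1e-6, atol=1e-9
        )
        # after the change the fresh-site depot is absent, so less drug reaches
        # the blood late in the therapy
        assert res_reset.cp_ng_ml.max() <= conventional_result.cp_ng_ml.max() + 1e-9

    def test_rerun_is_bitwise_reproducible(self, base_patient, single_patch_result):
        again = run_conventional(base_patient, n_patches=1, wear_h=72.0, horizon_h=72.0)
        assert np.array_equal(again.cp_ng_ml, single_patch_result.cp_ng_ml)
        assert np.array_equal(again.flux_dermis_ug_cm2_h, single_patch_result.flux_dermis_ug_cm2_h)

    def test_invalid_settings_rejected(self):
        with pytest.raises(InvalidParameterError):
            SolverSettings(site_mode="both")
        with pytest.raises(InvalidParameterError):
            SolverSettings(output_step_h=0.0)

    def test_default_policy_keeps_first_patch(self, base_patient):
        res = run_therapy(base_patient, ReplacementPolicy(), horizon_h=12.0)
        assert res.n_patches == 1
        assert [e.trigger for e in res.events] == ["scheduled"]
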