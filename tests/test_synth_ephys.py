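"""Tests of the oocyte-level peak generator, presets and gating simulator."""

import numpy as np
import pandas as pd
import pytest

from casite.ephys import fit_hill, fit_peak_table, inhibition_curve, normalize_series
from casite.errors import DomainError, LookupError_, ScheduleError
from casite.synth_ephys import (
    EphysPreset,
    GatingModel,
    PhDependenceSpec,
    gating_peak_response,
    get_preset,
    peak_per_step,
    simulate_peak_series,
    simulate_three_state_trace,
    wt_and_variant_presets,
)


class TestPresets:
    def test_registry_contents(self):
        reg = wt_and_variant_presets()
        for name in ("wt_ca", "wt_mg", "wt_kinetics", "asic1b", "ap_act",
                     "d409a", "ap_ssd", "cv_ssd", "asic1b_cv_ssd"):
            assert name in reg
        wt = reg["wt_ca"]
        assert wt.activation.mid_high == 6.50
        assert wt.activation.delta_mean == 0.25
        assert wt.ssd.mid_high == 7.14
        assert wt.kinetics.tau_recovery_low == 22.8
        assert reg["wt_mg"].ssd.conc_high == 10.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(LookupError_):
            get_preset("mystery")

    def test_inhibition_preset_block_at_10mM(self):
        spec = get_preset("wt_ca").inhibition
        block = 100 * (1 - inhibition_curve(10.0, 1.0, spec.non_in, spec.ic50,
                                            spec.n_hill))
        assert round(block) == 51

    def test_ph50_vs_ca_curve_passes_printed_endpoints(self):
        curve = get_preset("wt_ca").ph50_vs_ca
        assert curve.curve(2.0) == pytest.approx(6.50, abs=0.02)
        assert curve.curve(1e-4) == pytest.approx(6.78, abs=0.01)


class TestSimulatePeaks:
    def test_seed_determinism(self):
        a = simulate_peak_series("activation", "wt_ca", 5, seed=42)
        b = simulate_peak_series("activation", "wt_ca", 5, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_round_trip_returns_preset_midpoint(self):
        preset = EphysPreset(
            "exact", "WT",
            activation=PhDependenceSpec("Ca", 2.0, 1e-4, 6.50, 0.0, 0.25, 0.0,
                                        1.5),
            noise_sigma=0.0,
        )
        table = simulate_peak_series("activation", preset, 1, seed=0)
        for conc, truth in ((2.0, 6.50), (1e-4, 6.75)):
            sub = table[np.isclose(table["conc_mM"], conc)]
            fit = fit_hill(normalize_series(sub), kind="activation")
            assert fit.ph50 == pytest.approx(truth, abs=1e-6)

    def test_paired_arms_share_oocytes(self):
        table = simulate_peak_series("ssd", "wt_ca", 4, seed=1)
        arms = table.groupby("conc_mM")["oocyte_id"].unique()
        assert set(arms.iloc[0]) == set(arms.iloc[1])

    def test_recovery_table_has_controls_and_fits(self):
        table = simulate_peak_series("recovery", "wt_kinetics", 3, seed=2)
        assert table["stimulus"].isna().sum() == 3 * 2  # one control per arm
        fits = fit_peak_table(table)
        assert len(fits) == 6 and (fits["tau"] > 0).all()

    def test_invalid_n_rejected(self):
        with pytest.raises(DomainError):
            simulate_peak_series("activation", "wt_ca", 0, seed=1)


class TestGatingModel:
    def test_occupancies_conserved_and_bounded(self):
        trace = simulate_three_state_trace(
            GatingModel(), [(7.4, 2.0, 30.0), (5.0, 2.0, 10.0), (7.4, 2.0, 60.0)]
        )
        total = trace[["C", "O", "D"]].sum(axis=1)
        assert np.abs(total - 1.0).max() < 1e-9
        assert ((trace[["C", "O", "D"]] >= -1e-12).all()).all()

    def test_no_activation_at_resting_ph(self):
        trace = simulate_three_state_trace(GatingModel(), [(7.8, 2.0, 60.0)])
        assert trace["O"].max() < 1e-3

    def test_peak_extraction_identifies_stimulation_step(self):
        trace = simulate_three_state_trace(
            GatingModel(), [(7.4, 2.0, 10.0), (5.0, 2.0, 10.0)]
        )
        peaks = peak_per_step(trace)
        assert peaks.loc[peaks["step"] == 1, "peak_O"].iloc[0] > 0.5
        assert peaks.loc[peaks["step"] == 0, "peak_O"].iloc[0] < 0.01

    def test_ca_competition_shifts_midpoint_by_closed_form(self):
        """Lowering [Ca] 2 mM -> 100 nM shifts the peak-response midpoint
        alkaline by ~log10(1 + 2/K_Ca)."""
        model = GatingModel()
        grid = np.linspace(7.6, 5.0, 10)
        mids = {}
        for ca in (2.0, 1e-4):
            pk = gating_peak_response(model, grid, ca)
            pk["response"] = pk["response"] / pk["response"].max()
            mids[ca] = fit_hill(pk, kind="activation").ph50
        expected = np.log10(1 + 2.0 / model.k_ca) - np.log10(1 + 1e-4 / model.k_ca)
        assert mids[1e-4] - mids[2.0] == pytest.approx(expected, abs=0.02)

    def test_midpoints_monotone_alkaline_with_lower_ca(self):
        model = GatingModel()
        grid = np.linspace(7.6, 5.0, 10)
        mids = []
        for ca in (1e-4, 0.5, 2.0, 10.0):
            pk = gating_peak_response(model, grid, ca)
            pk["response"] = pk["response"] / pk["response"].max()
            mids.append(fit_hill(pk, kind="activation").ph50)
        assert all(np.diff(mids) < 0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ScheduleError):
            simulate_three_state_trace(GatingModel(), [(7.4, 2.0, -1.0)])
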