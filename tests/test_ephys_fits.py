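"""Tests of normalization, curve fits and paired summaries."""

import numpy as np
import pandas as pd
import pytest

from casite.ephys import (
    fit_hill,
    fit_inhibition,
    fit_onset,
    fit_recovery,
    hill_curve,
    inhibition_curve,
    normalize_series,
    onset_curve,
    paired_shift,
    recovery_curve,
    tau_ratio,
)
from casite.errors import (
    DegenerateSeriesError,
    DomainError,
    FitError,
    InsufficientPairsError,
    UnidentifiableError,
)


def _series(protocol, stimulus, peaks, oocyte="oo1"):
    return pd.DataFrame({
        "oocyte_id": oocyte, "construct": "WT", "protocol": protocol,
        "divalent": "Ca", "conc_mM": 2.0, "stimulus": stimulus, "peak_nA": peaks,
    })


class TestNormalize:
    def test_activation_scaling(self):
        out = normalize_series(_series("activation", [7.0, 6.5, 6.0],
                                       [-1000.0, -2000.0, -4000.0]))
        assert np.allclose(out["response"], [0.25, 0.5, 1.0])
        assert out["response"].max() == 1.0

    def test_single_record_normalizes_to_one(self):
        out = normalize_series(_series("activation", [6.0], [-123.0]))
        assert out["response"].tolist() == [1.0]

    def test_recovery_control_normalization(self):
        out = normalize_series(_series("recovery", [np.nan, 4.0],
                                       [-3000.0, -1500.0]))
        assert out["response"].tolist() == [0.5]
        assert len(out) == 1  # control row dropped

    def test_zero_control_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            normalize_series(_series("recovery", [np.nan, 4.0], [0.0, -1500.0]))


class TestHillFit:
    def test_noiseless_recovery_and_midpoint_closed_form(self):
        ph = np.array([7.4, 7.1, 6.9, 6.7, 6.5, 6.3, 6.0, 5.0])
        y = hill_curve(ph, 1.0, 6.5, 1.5, kind="activation")
        fit = fit_hill((ph, y), kind="activation")
        assert fit.ph50 == pytest.approx(6.5, abs=1e-6)
        assert fit.nh == pytest.approx(1.5, abs=1e-6)
        assert fit.imax == pytest.approx(1.0, abs=1e-6)
        # I(pH50) = Imax/2 exactly on the fitted curve
        assert hill_curve(fit.ph50, fit.imax, fit.ph50, fit.nh) == pytest.approx(
            fit.imax / 2.0
        )

    def test_ssd_orientation(self):
        ph = np.array([7.8, 7.6, 7.4, 7.2, 7.0, 6.8, 6.6])
        y = hill_curve(ph, 1.0, 7.14, 3.0, kind="ssd")
        assert y[0] > 0.9 and y[-1] < 0.1  # availability falls with acidity
        fit = fit_hill((ph, y), kind="ssd")
        assert fit.phd50 == pytest.approx(7.14, abs=1e-6)

    def test_refit_idempotence(self):
        ph = np.array([7.4, 7.0, 6.8, 6.6, 6.4, 6.0, 5.5, 5.0])
        rng = np.random.default_rng(0)
        y = hill_curve(ph, 1.0, 6.4, 1.5) * (1 + rng.normal(0, 0.03, ph.size))
        fit1 = fit_hill((ph, y))
        y2 = hill_curve(ph, fit1.imax, fit1.ph50, fit1.nh)
        fit2 = fit_hill((ph, y2))
        assert fit2.ph50 == pytest.approx(fit1.ph50, abs=1e-9)
        assert fit2.nh == pytest.approx(fit1.nh, abs=1e-9)

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(FitError):
            fit_hill(([7.0, 6.5, 6.0], [0.1, 0.5, 0.9]))


class TestInhibitionFit:
    def test_noiseless_recovery(self):
        x = np.array([0.1, 1.0, 3.0, 10.0, 30.0])
        y = inhibition_curve(x, 1.0, 0.0, 9.6, 1.0)
        fit = fit_inhibition((x, y))
        assert fit.ic50 == pytest.approx(9.6, rel=1e-6)
        assert fit.non_in == pytest.approx(0.0, abs=1e-6)
        # closed form: at x = IC50 with NonIn = 0, I = Imax/2
        assert inhibition_curve(fit.ic50, fit.imax, 0.0, fit.ic50, fit.nh) == (
            pytest.approx(fit.imax / 2.0)
        )

    def test_ph50_vs_conc_usage(self):
        x = np.array([1e-4, 0.3, 1.0, 3.0, 10.0, 30.0])
        y = inhibition_curve(x, 6.78, 6.01, 3.5, 1.0)
        fit = fit_inhibition((x, y))
        assert fit.ic50 == pytest.approx(3.5, rel=1e-5)
        assert fit.imax == pytest.approx(6.78, abs=1e-5)
        assert fit.non_in == pytest.approx(6.01, abs=1e-5)

    def test_flat_series_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_inhibition(([0.1, 1.0, 3.0, 10.0], [0.5, 0.5, 0.5, 0.5]))


class TestExponentialFits:
    def test_recovery_noiseless_and_closed_form(self):
        t = np.array([0.5, 1, 2, 5, 10, 30, 60, 180], dtype=float)
        y = recovery_curve(t, 1.0, 4.0)
        fit = fit_recovery((t, y))
        assert fit.tau == pytest.approx(4.0, rel=1e-6)
        # at t = tau the curve passes 1 - 1/e of Imax
        assert recovery_curve(fit.tau, fit.imax, fit.tau) == pytest.approx(
            fit.imax * (1 - np.exp(-1))
        )

    def test_onset_noiseless_and_plateau(self):
        t = np.array([1, 2.5, 5, 10, 20, 50, 100, 300], dtype=float)
        y = onset_curve(t, 1.0, 0.05, 63.6)
        fit = fit_onset((t, y))
        assert fit.tau == pytest.approx(63.6, rel=1e-6)
        assert fit.non_des == pytest.approx(0.05, abs=1e-6)
        # long-time limit of the fitted curve equals NonDes
        assert onset_curve(1e9, fit.imax, fit.non_des, fit.tau) == pytest.approx(
            fit.non_des
        )

    def test_constant_series_rejected(self):
        with pytest.raises(UnidentifiableError):
            fit_onset(([1, 2, 5, 10], [0.4, 0.4, 0.4, 0.4]))


class TestPairedSummaries:
    def test_identical_arms_zero_shift(self):
        arm = {"a": 6.5, "b": 6.6, "c": 6.4}
        shift = paired_shift(arm, dict(arm))
        assert shift.mean == 0.0 and shift.sd == 0.0 and shift.n == 3

    def test_single_oocyte_delta(self):
        shift = paired_shift({"a": 6.75, "b": 6.80}, {"a": 6.50, "b": 6.55})
        assert shift.mean == pytest.approx(0.25)

    def test_unpaired_dropped_and_counted(self):
        shift = paired_shift({"a": 6.7, "b": 6.8, "x": 6.9},
                             {"a": 6.5, "b": 6.5})
        assert shift.n == 2 and shift.n_dropped == 1

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(InsufficientPairsError):
            paired_shift({"a": 6.7}, {"a": 6.5})

    def test_tau_ratio_orientation(self):
        lo = {"a": 20.0, "b": 24.0}
        hi = {"a": 4.0, "b": 4.0}
        rec = tau_ratio(lo, hi, "recovery")
        assert rec.mean == pytest.approx((5.0 + 6.0) / 2)
        onset = tau_ratio({"a": 4.0, "b": 4.0}, {"a": 68.0, "b": 60.0}, "onset")
        assert onset.mean == pytest.approx((17.0 + 15.0) / 2)
        same = tau_ratio({"a": 5.0, "b": 5.0}, {"a": 5.0, "b": 5.0}, "recovery")
        assert same.mean == 1.0

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(DomainError):
            tau_ratio({"a": -1.0, "b": 2.0}, {"a": 1.0, "b": 1.0}, "recovery")
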