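"""Compartmental iohexol fitting: parameter recovery, the dose/AUC identity,
fallback behaviour and equivariance properties."""

import numpy as np
import pytest

from crushkit.pk_gfr import (
    IohexolSeries,
    ModelSelectionPolicy,
    PKFitError,
    estimate_gfr,
    fit_one_compartment,
    fit_two_compartment,
)
from crushkit.synthetic_cohort import simulate_iohexol_series

OFFSETS = (15.0, 30.0, 90.0, 120.0, 180.0, 240.0, 300.0)


def biexp_series(A, alpha, B, beta, dose=3235.0, times=OFFSETS):
    t = np.asarray(times)
    conc = A * np.exp(-alpha * t) + B * np.exp(-beta * t)
    return IohexolSeries(dose, tuple(t), tuple(conc))


def monoexp_series(c0, k, dose=1000.0, times=OFFSETS):
    t = np.asarray(times)
    return IohexolSeries(dose, tuple(t), tuple(c0 * np.exp(-k * t)))


class TestTwoCompartment:
    def test_noiseless_parameter_recovery(self):
        fit = fit_two_compartment(biexp_series(50.0, 0.15, 10.0, 0.01))
        assert fit.converged
        assert fit.A_ug_ml == pytest.approx(50.0, rel=1e-6)
        assert fit.alpha_per_min == pytest.approx(0.15, rel=1e-6)
        assert fit.B_ug_ml == pytest.approx(10.0, rel=1e-6)
        assert fit.beta_per_min == pytest.approx(0.01, rel=1e-6)
        assert fit.auc_mg_min_per_l == pytest.approx(50 / 0.15 + 10 / 0.01, rel=1e-6)

    def test_all_zero_concentrations_rejected(self):
        s = IohexolSeries(1000.0, OFFSETS, (0.0,) * len(OFFSETS))
        with pytest.raises(PKFitError):
            fit_two_compartment(s)

    def test_monoexponential_data_flagged_poor_and_fallback_recovers(self):
        s = monoexp_series(10.0, 0.01)
        fit2 = fit_two_compartment(s)
        selected = estimate_gfr(s)
        # degenerate biexponential must trigger the one-compartment fallback
        assert (not fit2.converged) or selected.fallback_used
        assert selected.model_order == 1
        assert selected.A_ug_ml == pytest.approx(10.0, rel=1e-6)
        assert selected.alpha_per_min == pytest.approx(0.01, rel=1e-6)


class TestOneCompartment:
    def test_closed_form_auc(self):
        fit = fit_one_compartment(monoexp_series(10.0, 0.01, dose=1000.0))
        assert fit.auc_mg_min_per_l == pytest.approx(1000.0, rel=1e-9)
        assert fit.gfr_ml_min == pytest.approx(1000.0, rel=1e-9)

    def test_rising_concentrations_rejected(self):
        t = (15.0, 30.0, 90.0)
        s = IohexolSeries(500.0, t, (1.0, 2.0, 4.0))
        with pytest.raises(PKFitError):
            fit_one_compartment(s)

    def test_three_point_exact_recovery(self):
        s = monoexp_series(8.0, 0.004, times=(15.0, 120.0, 300.0))
        fit = fit_one_compartment(s)
        assert fit.A_ug_ml == pytest.approx(8.0, rel=1e-9)
        assert fit.alpha_per_min == pytest.approx(0.004, rel=1e-9)


class TestEstimateGfr:
    def test_one_compartment_analytic_gfr(self):
        fit = estimate_gfr(monoexp_series(10.0, 0.01, dose=1000.0))
        assert fit.gfr_ml_min == pytest.approx(1000.0, rel=1e-6)

    def test_two_compartment_closed_form_auc(self):
        # AUC = 60/0.05 + 20/0.0005 = 41,200 mg*min/L; GFR = 3235/41200 L/min
        fit = estimate_gfr(biexp_series(60.0, 0.05, 20.0, 0.0005, dose=3235.0))
        assert fit.model_order == 2
        assert fit.auc_mg_min_per_l == pytest.approx(41200.0, rel=1e-6)
        assert fit.gfr_ml_min == pytest.approx(3235.0 / 41200.0 * 1000, rel=1e-6)
        assert fit.gfr_ml_min == pytest.approx(78.52, abs=0.01)

    def test_nested_model_consistency(self):
        s = monoexp_series(12.0, 0.008, dose=2000.0)
        selected = estimate_gfr(s)
        direct = fit_one_compartment(s)
        assert selected.gfr_ml_min == pytest.approx(direct.gfr_ml_min, rel=1e-6)

    def test_both_fits_failing_raises_with_diagnostics(self):
        t = (15.0, 30.0, 90.0, 120.0, 180.0)
        s = IohexolSeries(500.0, t, (1.0, 2.0, 3.0, 4.0, 5.0))
        with pytest.raises(PKFitError, match="one-compartment"):
            estimate_gfr(s)


class TestInvariants:
    @pytest.mark.parametrize(
        "series",
        [
            biexp_series(50.0, 0.15, 10.0, 0.01),
            biexp_series(60.0, 0.05, 20.0, 0.0005),
            monoexp_series(10.0, 0.01),
        ],
        ids=["fast-slow", "shallow-terminal", "monoexponential"],
    )
    def test_gfr_auc_dose_identity(self, series):
        fit = estimate_gfr(series)
        assert fit.gfr_ml_min * fit.auc_mg_min_per_l == pytest.approx(
            1000.0 * series.dose_mg, rel=1e-9
        )

    def test_identity_holds_under_noise(self, rng):
        s = simulate_iohexol_series(
            80.0, 3235.0, 3.0, 0.05, 0.04, OFFSETS, noise_cv=0.05, rng=rng
        )
        fit = estimate_gfr(s)
        assert fit.gfr_ml_min * fit.auc_mg_min_per_l == pytest.approx(
            1000.0 * s.dose_mg, rel=1e-9
        )

    def test_scale_equivariance(self):
        s = biexp_series(50.0, 0.15, 10.0, 0.01)
        scaled = IohexolSeries(
            s.dose_mg, s.times_min, tuple(3.0 * c for c in s.concentrations_ug_ml)
        )
        f, fs = estimate_gfr(s), estimate_gfr(scaled)
        assert fs.auc_mg_min_per_l == pytest.approx(3 * f.auc_mg_min_per_l, rel=1e-6)
        assert fs.gfr_ml_min == pytest.approx(f.gfr_ml_min / 3, rel=1e-6)

    def test_uniformly_higher_curve_gives_lower_gfr(self, rng):
        base = simulate_iohexol_series(90.0, 3235.0, 3.0, 0.05, 0.04, OFFSETS)
        lower = simulate_iohexol_series(60.0, 3235.0, 3.0, 0.05, 0.04, OFFSETS)
        # lower GFR produces the uniformly higher curve
        assert all(
            hi > lo
            for hi, lo in zip(lower.concentrations_ug_ml, base.concentrations_ug_ml)
        )
        assert estimate_gfr(lower).gfr_ml_min < estimate_gfr(base).gfr_ml_min

    def test_closed_form_auc_matches_trapezoid_with_tail(self):
        fit = estimate_gfr(biexp_series(50.0, 0.15, 10.0, 0.01))
        t = np.linspace(0, 300, 20001)
        numeric = np.trapezoid(fit.predict(t), t)
        tail = fit.predict([300.0])[0] / fit.beta_per_min  # exponential tail
        assert fit.auc_mg_min_per_l == pytest.approx(numeric + tail, rel=5e-3)

    def test_weighted_loss_policy_accepted(self):
        policy = ModelSelectionPolicy(weighting="1/C2")
        fit = fit_two_compartment(biexp_series(50.0, 0.15, 10.0, 0.01), policy)
        assert fit.converged
        assert fit.A_ug_ml == pytest.approx(50.0, rel=1e-5)
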