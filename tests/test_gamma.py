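"""Compensation-point estimation: exact regression cases, estimator
calibration, CI widening, and the indirect layer-inversion oracle."""

from dataclasses import replace

import numpy as np
import pytest

import leafcos as lc
from leafcos.gamma import (
    indirect_gamma,
    indirect_gamma_dataset,
    line_through_points,
    regress_gamma,
    widen_ci_with_chamber_residual,
)
from leafcos.kinetics import CAKinetics, GammaCosSpec
from leafcos.synthdata import (
    ChamberEmissionModel,
    ExperimentDesign,
    NoiseModel,
    generate_dataset,
)


class TestLineThroughPoints:
    def test_two_anchor_compensation_line(self):
        slope, t_ref = line_through_points((20.0, 58.9), (25.0, 139.9))
        assert slope == pytest.approx(16.2, abs=1e-12)
        assert t_ref == pytest.approx(16.4, abs=0.05)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            line_through_points((20.0, 50.0), (20.0, 60.0))


class TestRegressGamma:
    def test_exact_line(self):
        res = regress_gamma([(200.0, 1.0), (400.0, 3.0), (600.0, 5.0)])
        assert res.gamma_hat == pytest.approx(100.0, rel=1e-9)
        assert res.slope == pytest.approx(0.01, rel=1e-9)
        assert res.ci95_half_width == pytest.approx(0.0, abs=1e-6)

    def test_duplicated_points_leave_estimate_unchanged(self):
        pts = [(200.0, 1.1), (400.0, 2.8), (600.0, 5.2)]
        a = regress_gamma(pts)
        b = regress_gamma(pts + pts)
        assert a.gamma_hat == pytest.approx(b.gamma_hat, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            regress_gamma([(200.0, 1.0), (400.0, 3.0)])

    def test_nonpositive_slope_flagged(self):
        with pytest.raises(ValueError, match="slope"):
            regress_gamma([(200.0, 5.0), (400.0, 3.0), (600.0, 1.0)])

    def test_degenerate_abscissa_rejected(self):
        with pytest.raises(ValueError):
            regress_gamma([(200.0, 1.0), (200.0, 3.0), (200.0, 5.0)])

    def test_first_order_unbiasedness(self):
        """Under Gaussian flux noise the x-intercept estimator is unbiased
        to first order: bias over 1000 replicates stays well inside CI/10."""
        rng = np.random.default_rng(5)
        conc = np.array([150.0, 300.0, 450.0, 600.0])
        truth_gamma, slope = 100.0, 0.02
        flux_true = slope * (conc - truth_gamma)
        est, ci = [], []
        for _ in range(1000):
            flux = flux_true + rng.normal(0.0, 0.5, size=len(conc))
            try:
                r = regress_gamma(zip(conc, flux))
            except ValueError:
                continue
            est.append(r.gamma_hat)
            ci.append(r.ci95_half_width)
        bias = abs(np.mean(est) - truth_gamma)
        assert bias < np.median(ci) / 10.0

    def test_fieller_interval_close_to_delta_when_precise(self):
        pts = [(c, 0.02 * (c - 100.0) + e) for c, e in
               zip([150, 300, 450, 600, 750], [0.1, -0.05, 0.02, -0.08, 0.04])]
        d = regress_gamma(pts, method="delta")
        f = regress_gamma(pts, method="fieller")
        assert f.ci95_half_width == pytest.approx(d.ci95_half_width, rel=0.25)

    def test_recovers_forward_model_zero_crossing(self, chamber, posterior_leaf):
        """Noise-free concentration ramp: the regression intercept must sit
        at the concentration where the forward model's flux crosses zero
        (independently located by bisection on the inflow)."""
        t_leaf, g_sw = 25.0, 0.9
        ramp = np.linspace(94.0, 707.0, 6)
        sim = lc.forward_simulate(chamber, posterior_leaf, ramp, 445.0, 15.0,
                                  t_leaf, g_sw=g_sw)
        res = regress_gamma(zip(np.asarray(sim.cos_out_dry), np.asarray(sim.f_cos)),
                            t_leaf=t_leaf)
        lo, hi = 1.0, 2000.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            f = lc.forward_simulate(chamber, posterior_leaf, mid, 445.0, 15.0,
                                    t_leaf, g_sw=g_sw).f_cos
            lo, hi = (mid, hi) if f < 0 else (lo, mid)
        x_in_zero = 0.5 * (lo + hi)
        out_zero = lc.forward_simulate(chamber, posterior_leaf, x_in_zero, 445.0,
                                       15.0, t_leaf, g_sw=g_sw).cos_out_dry
        assert res.gamma_hat == pytest.approx(out_zero, rel=1e-6)


class TestWidenCI:
    def _noisy_exp1(self):
        design = ExperimentDesign.cos_ramp(25.0, levels=np.linspace(94, 707, 8))
        data, _ = generate_dataset(design, lc.default_truth(),
                                   noise=NoiseModel(),
                                   emission=ChamberEmissionModel.off(), seed=3)
        q = data["af_mol_s"] / data["s_m2"]
        flux = q * (data["cos_in_dry"] - data["cos_out_dry"])
        return regress_gamma(zip(data["cos_out_dry"], flux), t_leaf=25.0)

    def test_zero_residuals_leave_ci_unchanged(self):
        res = self._noisy_exp1()
        assert widen_ci_with_chamber_residual(res, 0.0, 0.0).ci95_half_width == \
            pytest.approx(res.ci95_half_width, rel=1e-12)

    def test_monotone_in_flux_residual(self):
        res = self._noisy_exp1()
        widths = [widen_ci_with_chamber_residual(res, s, 0.0).ci95_half_width
                  for s in (0.0, 1.0, 2.73, 5.0)]
        assert np.all(np.diff(widths) > 0)

    def test_study_residuals_widen_moderately(self):
        """With the reported chamber-correction residuals (flux 2.73
        pmol m-2 s-1, concentration 6.9 pmol mol-1) the CI grows by a
        factor between 1 and 2.2 on ramp data at the study noise level."""
        res = self._noisy_exp1()
        wide = widen_ci_with_chamber_residual(res, 2.73, 6.9)
        factor = wide.ci95_half_width / res.ci95_half_width
        assert 1.0 < factor < 2.2

    def test_negative_residual_rejected(self):
        res = self._noisy_exp1()
        with pytest.raises(ValueError):
            widen_ci_with_chamber_residual(res, -1.0, 0.0)


class TestIndirectGamma:
    def test_round_trip_recovers_prescribed_gamma(self, clean_suite, posterior_leaf):
        """The defining oracle: the indirect inversion applied to noise-free
        forward-model output returns Gamma_COS(T) exactly (the layer
        equations are inverted algebraically)."""
        data, truth = clean_suite
        out = indirect_gamma_dataset(data, posterior_leaf,
                                     g_sw_opt=truth["g_sw_true"])
        expected = lc.gamma_cos(out["t_leaf_C"].to_numpy(), posterior_leaf.gamma)
        rel = np.abs(out["cos_c"].to_numpy() - expected) / np.maximum(expected, 1.0)
        assert np.max(rel) < 1e-8

    def test_infinite_mesophyll_conductance_limit(self, chamber, posterior_leaf):
        sim = lc.forward_simulate(chamber, posterior_leaf, 1000.0, 445.0, 15.0, 25.0)
        row = {"t_leaf_C": 25.0, "cos_in_dry": 1000.0,
               "cos_out_dry": float(sim.cos_out_dry), "h2o_in": 15.0,
               "h2o_out": float(sim.h2o_out), "point_id": "x"}
        big = replace(posterior_leaf, ca=CAKinetics(v_max_ca=1e9, t_eq_ca=39.7))
        pt = indirect_gamma(row, big, chamber)
        assert pt.cos_c == pytest.approx(pt.cos_i, rel=1e-6)

    def test_equilibrium_chamber_all_layers_equal(self, chamber, posterior_leaf):
        h_sat = lc.kinetics.h2o_saturated_mole_fraction(25.0, chamber.p_air)
        row = {"t_leaf_C": 25.0, "cos_in_dry": 500.0, "cos_out_dry": 500.0,
               "h2o_in": h_sat, "h2o_out": h_sat, "point_id": "x"}
        pt = indirect_gamma(row, posterior_leaf, chamber)
        wet = lc.dry_to_wet(500.0, h_sat)
        assert pt.cos_b == pytest.approx(wet, rel=1e-12)
        assert pt.cos_i == pytest.approx(wet, rel=1e-12)
        assert pt.cos_c == pytest.approx(wet, rel=1e-12)

    def test_appends_layer_columns(self, clean_suite, posterior_leaf):
        data, truth = clean_suite
        out = indirect_gamma_dataset(data.head(4), posterior_leaf,
                                     g_sw_opt=truth["g_sw_true"][:4])
        assert {"cos_b", "cos_i", "cos_c"} <= set(out.columns)
        assert len(out) == 4
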