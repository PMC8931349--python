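"""KVM curve fit: recovery, reductions, corrections, diagnostics, writer."""

import json
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kvmfit import (
    FitConfig,
    KVMModel,
    ProbeGeometry,
    SyntheticCurveSpec,
    ViscoelasticParams,
    bottom_effect_estimate,
    confinement_correction,
    confinement_factor,
    ding_force,
    effective_radius,
    fit_kvm_curve,
    generate_kvm_curve,
    indentation_for_semiinfinite_force,
    split_segments,
    tip_sample_separation,
    write_results,
)
from .conftest import CP_TRUE, DELTA_MAX, R, T_IND, V


def _best_ding_sse(model: KVMModel) -> float:
    """Independent pure-elastic reference: profile E (linear) over a cp grid."""
    best = np.inf
    for cp in np.linspace(model.contact0.cp - 0.05e-6, model.contact0.cp + 0.1e-6, 61):
        delta = np.clip(model._indentation(cp), 0.0, None)
        shape = ding_force(1.0, 0.5, model._R_fit, delta, clip=True)
        denom = shape @ shape
        if denom == 0:
            continue
        E = max(float(shape @ model._F_fit) / denom, 0.0)
        r = E * shape - model._F_fit
        best = min(best, float(r @ r))
    return best


class TestKVMFit:
    def test_noiseless_recovery_within_one_percent(self, kvm_curve, kvm_params):
        res = fit_kvm_curve(kvm_curve)
        assert res.params.E0 == pytest.approx(kvm_params.E0, rel=0.01)
        assert res.params.E1 == pytest.approx(kvm_params.E1, rel=0.01)
        assert res.params.lam == pytest.approx(kvm_params.lam, rel=0.01)
        assert res.params.eta == pytest.approx(kvm_params.eta, rel=0.01)
        assert res.cp == pytest.approx(CP_TRUE, abs=2e-9)
        assert not res.flags["lam_at_upper_bound"]
        assert not res.flags["lam_at_lower_bound"]

    def test_slow_relaxation_saturates_upper_bound_but_eu_survives(self, kvm_spec):
        # generator lam = 100 t_ind: E0/E1 redundant, material looks elastic
        p = ViscoelasticParams(E0=1000.0, E1=800.0, lam=100 * T_IND, eta=1.0)
        res = fit_kvm_curve(generate_kvm_curve(replace(kvm_spec, params=p)))
        assert res.flags["lam_at_upper_bound"]
        assert res.derived.Eu == pytest.approx(1800.0, rel=0.05)

    def test_purely_elastic_material_reduces_to_ding_fit(self, ding_curve):
        m = KVMModel(ding_curve)
        res = m.fit()
        assert res.params.E1 <= 0.01 * res.params.E0
        assert res.params.eta <= 0.01  # Pa s; negligible dashpot
        E_ding = None
        # independent Ding-only estimate at the fitted cp (linear in E)
        delta = np.clip(m._indentation(res.cp), 0.0, None)
        shape = ding_force(1.0, 0.5, m._R_fit, delta, clip=True)
        E_ding = float(shape @ m._F_fit) / float(shape @ shape)
        assert res.params.E0 == pytest.approx(E_ding, rel=0.01)

    def test_model_nesting_beats_pure_ding_on_kvm_data(self, kvm_curve):
        m = KVMModel(kvm_curve)
        res = m.fit()
        assert res.sse <= _best_ding_sse(m) * (1 + 1e-9)

    def test_velocity_estimated_from_piezo_when_absent(self, kvm_curve):
        curve = replace_meta_velocity(kvm_curve, None)
        m = KVMModel(curve)
        assert m.v == pytest.approx(V, rel=0.02)

    def test_setpoint_trimming_excludes_overshoot(self, kvm_curve):
        curve = replace_meta_velocity(kvm_curve, V)
        curve.meta.setpoint = 0.5 * float(curve.F.max())
        m = KVMModel(curve)
        assert m._F_fit.max() <= curve.meta.setpoint * 1.001
        res = m.fit()  # still fits the truncated curve
        assert res.params.E0 == pytest.approx(1000.0, rel=0.05)

    def test_non_contact_curve_raises(self):
        import kvmfit

        n = 512
        t = np.linspace(0, 0.3, n)
        z = -np.linspace(0, 1.5e-6, n)
        curve = kvmfit.ForceCurve(
            t, z, np.zeros(n),
            meta=kvmfit.CurveMeta(spring_constant=0.05, velocity=V, radius=R),
        )
        with pytest.raises(kvmfit.NoContactError):
            KVMModel(curve)

    def test_summary_reports_fitted_state(self, kvm_curve):
        res = fit_kvm_curve(kvm_curve)
        text = res.summary()
        for token in ("E0", "lambda", "eta", "Eu", "Eapp", "contact point", "flags"):
            assert token in text


def replace_meta_velocity(curve, v):
    import copy

    c = copy.copy(curve)
    c.meta = copy.deepcopy(curve.meta)
    c.meta.velocity = v
    return c


class TestGeometryCorrections:
    def test_effective_radius_worked_value(self):
        assert effective_radius(7.5e-6, 2.5e-6) == pytest.approx(1.875e-6)

    def test_effective_radius_flat_sample_limit(self):
        assert effective_radius(1e3, 2.5e-6) == pytest.approx(2.5e-6, rel=1e-8)

    def test_effective_radius_symmetric(self):
        assert effective_radius(2e-6, 2e-6) == pytest.approx(1e-6)

    def test_confinement_factor_worked_value(self):
        assert confinement_factor(7.5e-6, 1.875e-6) == pytest.approx(0.613, abs=1e-3)

    def test_confinement_point_contact_limit(self):
        assert confinement_factor(7.5e-6, 0.0) == 1.0

    @given(st.floats(1e-8, 1e-5), st.floats(1e-8, 1e-5), st.floats(1.01, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_confinement_strictly_decreasing_in_reff(self, Rcell, Reff, f):
        assert confinement_factor(Rcell, Reff * f) < confinement_factor(Rcell, Reff)

    def test_confinement_scales_indentation(self):
        d = np.array([0.0, 1e-7, 5e-7])
        K = confinement_factor(7.5e-6, 1.875e-6)
        np.testing.assert_allclose(confinement_correction(d, 7.5e-6, 1.875e-6), K * d)

    def test_rounded_cell_round_trip(self, kvm_params):
        """Generate with the sphere-on-sphere convention, fit with Rcell set."""
        geom = ProbeGeometry(R=2.5e-6, Rcell=7.5e-6)
        spec = SyntheticCurveSpec(params=kvm_params, geom=geom, sampling_rate=2000.0)
        res = fit_kvm_curve(generate_kvm_curve(spec))
        assert res.params.E0 == pytest.approx(kvm_params.E0, rel=0.02)
        assert res.params.E1 == pytest.approx(kvm_params.E1, rel=0.02)
        assert res.params.eta == pytest.approx(kvm_params.eta, rel=0.05)


class TestBottomEffect:
    def test_semi_infinite_limit(self):
        be = bottom_effect_estimate(2.7e3, 1.71, R, 1e6, 2e-6, 0.5e-6)
        assert be.overestimation < 1e-9

    def test_elastic_reduction(self):
        # eta = 0, v = 0: ratio reduces to 1.133*sqrt(R*I)/h
        I, h = 0.4e-6, 12e-6
        be = bottom_effect_estimate(2.7e3, 0.0, R, h, 0.0, I)
        assert be.overestimation == pytest.approx(1.133 * np.sqrt(R * I) / h, rel=1e-12)

    def test_mitotic_overestimation_eight_percent(self):
        I = indentation_for_semiinfinite_force(2.5e-9, 2.7e3, 1.71, R, 2e-6)
        be = bottom_effect_estimate(2.7e3, 1.71, R, 15e-6, 2e-6, I)
        assert be.F0 == pytest.approx(2.5e-9, rel=1e-9)
        assert 100 * be.overestimation == pytest.approx(8.0, abs=1.0)

    def test_invalid_thickness_raises(self):
        with pytest.raises(ValueError):
            bottom_effect_estimate(2.7e3, 1.71, R, 0.0, 2e-6, 0.5e-6)


class TestResultsWriter:
    def test_csv_row_and_provenance(self, kvm_curve, tmp_path):
        import pandas as pd

        res = fit_kvm_curve(kvm_curve)
        out = tmp_path / "results.csv"
        write_results([res], out)
        df = pd.read_csv(out)
        assert len(df) == 1
        for col in ("curve_id", "E0_Pa", "E1_Pa", "lambda_s", "eta_Pa_s",
                    "Eu_Pa", "Eapp_Pa", "cp_m", "delta_max_m", "t_ind_s", "sse"):
            assert col in df.columns
        prov = json.loads(out.with_suffix(".provenance.json").read_text())
        assert prov["constants"]["alpha1"] == 0.365
        assert prov["nu"] == 0.5


class TestFitConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"lam_bounds": (10.0, 0.2)}, {"lam_bounds": (0.0, 10.0)}, {"xatol": 0.0},
    ])
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FitConfig(**kwargs)
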