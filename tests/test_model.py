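"""Global fitting: objective structure, locks, recovery, reparameterization."""

import numpy as np
import pytest

import strandsep as ss


def _model_at_truth(dataset, rates, coeffs, **kw):
    return ss.GlobalKineticModel(dataset.traces, rates, coeffs, **kw)


class TestObjective:
    def test_zero_residuals_at_generating_truth(self, wt_noiseless_dataset, wt,
                                                truth_coeffs):
        m = _model_at_truth(wt_noiseless_dataset, wt, truth_coeffs, weights="unit")
        r = m.objective(m._pack(m._initial_values()))
        assert np.max(np.abs(r)) < 1e-6
        assert (r @ r) / m.data_scale < 1e-12

    def test_output_scale_doubles_pydc_prediction(self, wt_noiseless_dataset, wt,
                                                  truth_coeffs):
        m = _model_at_truth(wt_noiseless_dataset, wt, truth_coeffs)
        base = m.predict()
        doubled = m.predict({"a1": 2.0 * truth_coeffs.a1})
        for tr, y1, y2 in zip(m.traces, base, doubled):
            if tr.design.kind == "pydc":
                assert np.allclose(y2, 2 * y1, rtol=1e-12)
            else:
                assert np.allclose(y2, y1, rtol=1e-12)

    def test_perturbing_k2_is_detectable(self, wt_noiseless_dataset, wt,
                                         truth_coeffs):
        m = _model_at_truth(wt_noiseless_dataset, wt, truth_coeffs, weights="unit")
        vals = m._initial_values()
        assert m.ssr(vals) < 1e-10
        vals["k2"] = 2 * wt.k2
        assert m.ssr(vals) > 1.0

    def test_clamp_of_unknown_parameter_rejected(self, wt_noiseless_dataset, wt,
                                                 truth_coeffs):
        m = _model_at_truth(wt_noiseless_dataset, wt, truth_coeffs)
        with pytest.raises(ValueError, match="k3r"):
            m.objective(np.zeros(m.n_floats - 1), clamp={"k3r": 0.1})


class TestFit:
    def test_everything_locked_is_an_error(self, wt_noiseless_dataset, wt):
        rates = wt.replace(locked=frozenset(
            ("k1", "k1r", "k2", "k2r", "k3", "k3r", "k4", "k4r")))
        coeffs = ss.default_truth_coefficients()
        coeffs = coeffs.replace(locked=frozenset(coeffs.to_dict()))
        m = ss.GlobalKineticModel(wt_noiseless_dataset.traces, rates, coeffs)
        with pytest.raises(ValueError, match="nothing to fit"):
            m.fit()

    def test_noiseless_recovery_from_perturbed_start(self, wt_noiseless_dataset,
                                                     wt, truth_coeffs):
        # mutant-style locks: only k1r, k2, k2r, k3 and the fluorescence
        # coefficients float; start each rate a factor of two off
        rates0 = wt.replace(
            k1r=2 * wt.k1r, k2=wt.k2 / 2, k2r=2 * wt.k2r, k3=wt.k3 / 2,
            locked=wt.locked | {"k4"},
        )
        m = ss.GlobalKineticModel(wt_noiseless_dataset.traces, rates0,
                                  truth_coeffs, weights="unit")
        res = m.fit(multistart=1)
        for name, target in (("k1r", wt.k1r), ("k2", wt.k2), ("k2r", wt.k2r),
                             ("k3", wt.k3)):
            assert getattr(res.rates, name) == pytest.approx(target, rel=1e-3)
        assert res.ssr_unweighted / m.data_scale < 1e-10

    def test_locked_parameters_bit_identical(self, wt_noisy_dataset, wt,
                                             truth_coeffs):
        rates0 = wt.replace(k2=20.0, k3=0.15, locked=wt.locked | {"k4"})
        m = ss.GlobalKineticModel(wt_noisy_dataset.traces, rates0, truth_coeffs)
        res = m.fit(multistart=1, max_nfev=30)
        assert res.rates.k1 == rates0.k1
        assert res.rates.k3r == rates0.k3r
        assert res.rates.k4 == rates0.k4
        assert res.rates.k4r == rates0.k4r
        assert res.coeffs.bkg2 == truth_coeffs.bkg2

    def test_log_and_linear_transforms_agree_on_noiseless_data(
            self, wt_noiseless_dataset, wt, truth_coeffs):
        rates0 = wt.replace(k2=1.5 * wt.k2, locked=wt.locked | {"k4"})
        for transform in ("log", "linear"):
            m = ss.GlobalKineticModel(wt_noiseless_dataset.traces, rates0,
                                      truth_coeffs, weights="unit",
                                      transform=transform)
            res = m.fit(multistart=1)
            assert res.ssr_unweighted / m.data_scale < 1e-10, transform

    def test_floating_scale_factor_recovers_trace_drift(self, wt, truth_coeffs):
        cfg = ss.SyntheticConfig(seed=7, n_points_fluor=100)
        ds = ss.generate_full_dataset(cfg)
        drift_index = 5
        ds.traces[drift_index].signal = ds.traces[drift_index].signal * 1.1
        coeffs = truth_coeffs.replace(
            locked=truth_coeffs.locked | {"a1", "a3"})
        m = ss.GlobalKineticModel(ds.traces, wt, coeffs, scale_factors="float")
        res = m.fit(multistart=1)
        assert res.scale_factors[drift_index] == pytest.approx(1.1, abs=0.02)
        others = np.delete(res.scale_factors, drift_index)[:-1]
        assert np.allclose(others, 1.0, atol=0.02)


class TestMutantRecoverability:
    """The identical pipeline recovers each published variant's kinetics
    from synthetic data generated at that variant's parameter set."""

    @pytest.mark.parametrize("enzyme", ["F125L", "F125A", "F125W", "R129A",
                                        "N124A", "R44A"])
    def test_variant_rates_recovered_within_ten_percent(self, enzyme):
        truth = ss.reference_rate_constants(enzyme)
        ds = ss.generate_full_dataset(
            ss.SyntheticConfig(rates=enzyme, seed=5, n_points_fluor=150))
        start = truth.replace(k1r=300.0, k2=5.0, k2r=5.0, k3=0.05)
        g = ss.initial_rate_guess(ds.traces, start)
        m = ss.GlobalKineticModel(ds.traces, g,
                                  ss.linear_coefficient_seed(ds.traces, g))
        res = m.fit(multistart=1, seed=5)
        for name in ("k2", "k2r", "k3"):
            assert getattr(res.rates, name) == pytest.approx(
                getattr(truth, name), rel=0.10), name
        assert res.rates.k4 == truth.k4  # locked at the reference value


class TestSeeding:
    def test_prefit_seed_lands_near_truth(self, wt_noisy_dataset, wt):
        template = wt.replace(k1r=300.0, k2=10.0, k2r=5.0, k3=0.1, k4=1.0)
        g = ss.initial_rate_guess(wt_noisy_dataset.traces, template)
        assert g.k2 + g.k2r == pytest.approx(wt.k2 + wt.k2r, rel=0.25)
        assert g.k3 == pytest.approx(wt.k3, rel=0.7)
        assert g.k1r == template.k1r  # not informed by pre-fits

    def test_linear_coefficient_seed_recovers_truth_at_true_rates(
            self, wt_noiseless_dataset, wt, truth_coeffs):
        seeded = ss.linear_coefficient_seed(wt_noiseless_dataset.traces, wt)
        for name in ("a1", "pydc_gsi", "pydc_gsp", "pydc_sp",
                     "a3", "trp_fs", "trp_gsi", "trp_gsp"):
            assert getattr(seeded, name) == pytest.approx(
                getattr(truth_coeffs, name), abs=0.02), name


class TestResults:
    def test_summary_and_dict_round_trip(self, wt_noiseless_dataset, wt,
                                         truth_coeffs):
        import json

        m = ss.GlobalKineticModel(wt_noiseless_dataset.traces, wt, truth_coeffs,
                                  weights="unit")
        res = m.fit(multistart=1, max_nfev=5)
        text = res.summary()
        assert "k2" in text and "SSR" in text
        payload = json.loads(json.dumps(res.to_dict()))
        assert payload["rates"]["k1"] == 100.0
        assert payload["float_names"] == list(res.float_names)
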