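"""Subthreshold moment calculus, the erfc rate formula, and the
two-stage threshold-polynomial fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from spikemf.errors import FitError, ParameterError
from spikemf.neuron_models import simulate_passive_membrane
from spikemf.params import ADEX_RS, SynapseParams, default_synapse
from spikemf.transfer_function import (SubthresholdMoments,
                                       ThresholdPolynomial,
                                       TransferFunctionModel,
                                       conductance_moments,
                                       effective_threshold,
                                       fit_transfer_function, invert_rate,
                                       load_reference_thresholds,
                                       measure_transfer_function,
                                       predicted_rate, voltage_moments)

SYN = default_synapse("adex")
CELL = dict(g_L=10.0, c_m=150.0, E_L=-65.0, K_e=400, K_i=100)


def _moments(nu_e, nu_i):
    return voltage_moments(nu_e, nu_i, CELL["g_L"], CELL["c_m"], CELL["E_L"],
                           CELL["K_e"], CELL["K_i"], SYN)


class TestConductanceMoments:
    def test_hand_computed_values(self):
        mu_ge, s_ge, mu_gi, s_gi = conductance_moments(4.0, 8.0, 400, 100, SYN)
        assert mu_ge == pytest.approx(12.0)   # 4e-3 * 400 * 5 * 1.5 nS
        assert s_ge == pytest.approx(3.0)     # sqrt(4e-3*400*5/2) * 1.5
        assert mu_gi == pytest.approx(20.0)
        assert s_gi == pytest.approx(5.0 * np.sqrt(2.0))

    def test_zero_rate_gives_zero_moments(self):
        assert all(np.all(x == 0) for x in
                   conductance_moments(0.0, 0.0, 400, 100, SYN))

    def test_scaling_laws(self):
        base = conductance_moments(4.0, 8.0, 400, 100, SYN)
        double_q = conductance_moments(4.0, 8.0, 400, 100,
                                       SYN._replace(Q_e=3.0, Q_i=10.0))
        double_nu = conductance_moments(8.0, 16.0, 400, 100, SYN)
        # doubling Q doubles mean and sd; doubling nu doubles the mean but
        # scales the sd by sqrt(2)
        assert double_q[0] == pytest.approx(2 * base[0])
        assert double_q[1] == pytest.approx(2 * base[1])
        assert double_nu[0] == pytest.approx(2 * base[0])
        assert double_nu[1] == pytest.approx(np.sqrt(2) * base[1])

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            conductance_moments(-1.0, 0.0, 400, 100, SYN)

    def test_match_monte_carlo_conductance_trace(self):
        # the shot-noise formulas against an actual simulated conductance
        t, v, ge, gi = simulate_passive_membrane(
            150.0, 10.0, -65.0, SYN, nu_e=4.0, nu_i=8.0,
            duration=100_000.0, seed=17)
        mu_ge, s_ge, mu_gi, s_gi = conductance_moments(4.0, 8.0, 400, 100, SYN)
        assert ge.mean() == pytest.approx(mu_ge, rel=0.05)
        assert ge.std() == pytest.approx(s_ge, rel=0.05)
        assert gi.mean() == pytest.approx(mu_gi, rel=0.05)
        assert gi.std() == pytest.approx(s_gi, rel=0.05)


class TestVoltageMoments:
    def test_leak_only_limit(self):
        m = _moments(0.0, 0.0)
        assert m.mu_V == pytest.approx(-65.0)
        assert m.sigma_V == 0.0
        assert m.tau_m_eff == pytest.approx(15.0)  # c_m / g_L

    def test_hand_computed_operating_point(self):
        m = _moments(4.0, 8.0)
        assert m.mu_G == pytest.approx(42.0)
        assert m.tau_m_eff == pytest.approx(150.0 / 42.0)
        assert m.mu_V == pytest.approx((20.0 * -80.0 + 10.0 * -65.0) / 42.0,
                                       rel=1e-12)
        assert m.mu_V == pytest.approx(-53.6, abs=0.05)

    def test_invariants(self):
        for ne, ni in [(0.5, 0.5), (4, 8), (20, 2), (1, 30)]:
            m = _moments(ne, ni)
            assert m.mu_G >= CELL["g_L"]
            assert min(SYN.E_i, CELL["E_L"]) <= m.mu_V <= SYN.E_e
            assert m.tau_m_eff <= CELL["c_m"] / CELL["g_L"]
            assert m.sigma_V >= 0

    def test_sigma_v_matches_passive_membrane_simulation(self):
        t, v, *_ = simulate_passive_membrane(
            150.0, 10.0, -65.0, SYN, nu_e=4.0, nu_i=8.0,
            duration=100_000.0, seed=3)
        m = _moments(4.0, 8.0)
        burn = t > 200.0
        assert v[burn].std() == pytest.approx(float(m.sigma_V), rel=0.15)
        assert v[burn].mean() == pytest.approx(float(m.mu_V), abs=0.5)


class TestThresholdPolynomial:
    def test_constant_polynomial(self):
        poly = ThresholdPolynomial(np.array([-50.0] + [0.0] * 9))
        m = _moments(4.0, 8.0)
        assert effective_threshold(m, poly) == pytest.approx(-50.0)

    def test_centers_return_p0_exactly(self):
        rng = np.random.default_rng(0)
        poly = ThresholdPolynomial(rng.normal(size=10))
        val = poly(poly.centers[0], poly.centers[1], poly.centers[2])
        assert val == pytest.approx(poly.coeffs[0], abs=1e-12)

    def test_matches_independent_symbolic_evaluation(self):
        import sympy as sp

        rng = np.random.default_rng(1)
        coeffs = rng.normal(size=10)
        poly = ThresholdPolynomial(coeffs)
        mu, sig, tau = -55.3, 3.7, 0.62
        x, y, z = sp.symbols("x y z")
        expr = (coeffs[0] + coeffs[1] * x + coeffs[2] * y + coeffs[3] * z
                + coeffs[4] * x ** 2 + coeffs[5] * y ** 2 + coeffs[6] * z ** 2
                + coeffs[7] * x * y + coeffs[8] * x * z + coeffs[9] * y * z)
        expected = float(expr.subs({
            x: (mu - poly.centers[0]) / poly.scales[0],
            y: (sig - poly.centers[1]) / poly.scales[1],
            z: (tau - poly.centers[2]) / poly.scales[2]}))
        assert poly(mu, sig, tau) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.2, 5.0), st.floats(0.2, 5.0), st.floats(0.2, 5.0))
    def test_normalization_is_pure_reparameterization(self, k1, k2, k3):
        # rescaling the normalization widths with compensating coefficients
        # leaves the polynomial (hence the predicted rate) unchanged
        rng = np.random.default_rng(2)
        coeffs = rng.normal(size=10)
        poly = ThresholdPolynomial(coeffs)
        k = np.array([1.0, k1, k2, k3, k1 * k1, k2 * k2, k3 * k3,
                      k1 * k2, k1 * k3, k2 * k3])
        poly2 = ThresholdPolynomial(
            coeffs * k,
            scales=(poly.scales[0] * k1, poly.scales[1] * k2,
                    poly.scales[2] * k3))
        pts = [(-60.0, 4.0, 0.5), (-52.0, 2.0, 0.3), (-70.0, 6.0, 0.9)]
        for mu, sig, tau in pts:
            assert poly2(mu, sig, tau) == pytest.approx(poly(mu, sig, tau),
                                                        rel=1e-9, abs=1e-9)


def _synthetic_moments(mu_v=-55.0, sigma_v=4.0, tau_v=10.0, g_l=10.0, c_m=150.0):
    arr = lambda x: np.asarray(float(x))
    return SubthresholdMoments(arr(0), arr(0), arr(0), arr(0), arr(20),
                               arr(c_m / 20), arr(mu_v), arr(sigma_v),
                               arr(tau_v), arr(tau_v * g_l / c_m))


class TestRateFormulaAndInverse:
    def test_rate_at_threshold_is_half_maximum(self):
        # mu_V = V_thr: erfc(0) = 1 so F = alpha / (2 tau_V); 50 Hz at 10 ms
        poly = ThresholdPolynomial(np.array([-55.0] + [0.0] * 9))
        m = _synthetic_moments(mu_v=-55.0, tau_v=10.0)
        from spikemf.transfer_function import _erfc_rate
        rate = _erfc_rate(m.mu_V, m.sigma_V, m.tau_V,
                          effective_threshold(m, poly), 1.0)
        assert rate == pytest.approx(50.0)

    def test_rate_vanishes_far_below_threshold(self):
        from spikemf.transfer_function import _erfc_rate
        rate = _erfc_rate(-75.0, 2.0, 10.0, -45.0, 1.0)
        assert rate < 1e-15

    def test_monotone_in_mean_voltage(self):
        from spikemf.transfer_function import _erfc_rate
        mus = np.linspace(-70.0, -45.0, 40)
        rates = _erfc_rate(mus, 4.0, 10.0, -50.0, 1.0)
        assert np.all(np.diff(rates) > 0)

    def test_invert_rate_round_trip(self):
        m = _synthetic_moments()
        for v_thr in (-60.0, -52.0, -48.0):
            from spikemf.transfer_function import _erfc_rate
            rate = float(_erfc_rate(m.mu_V, m.sigma_V, m.tau_V, v_thr, 1.0))
            assert float(invert_rate(rate, m)) == pytest.approx(v_thr,
                                                                abs=1e-9)

    def test_invert_rate_at_half_maximum_returns_mu_v(self):
        m = _synthetic_moments(tau_v=10.0)
        assert float(invert_rate(50.0, m)) == pytest.approx(float(m.mu_V))

    def test_invert_rate_diverges_for_vanishing_rate(self):
        m = _synthetic_moments()
        thr = [float(invert_rate(r, m)) for r in (1.0, 0.1, 0.01, 1e-4)]
        assert all(b > a for a, b in zip(thr, thr[1:]))
        assert thr[-1] > float(m.mu_V) + 10.0

    def test_invert_rate_domain_errors(self):
        m = _synthetic_moments(tau_v=10.0)
        with pytest.raises(ParameterError):
            invert_rate(0.0, m)
        with pytest.raises(ParameterError):
            invert_rate(101.0, m)  # above alpha/tau_V = 100 Hz


class TestFit:
    def _generating_model(self):
        coeffs = np.array([-50.0, 4.0, -8.0, 0.3, -0.5, 1.4, -14.0,
                           4.5, 2.8, -15.0])
        return TransferFunctionModel(ThresholdPolynomial(coeffs), SYN,
                                     K_e=400, K_i=100, g_L=10.0, c_m=150.0,
                                     E_L=-65.0)

    def _noiseless_samples(self, model):
        grid = [(ne, ni) for ni in (2.0, 6.0, 10.0, 16.0)
                for ne in np.linspace(0.5, 10.0, 10)]
        nu_e = np.array([g[0] for g in grid])
        nu_i = np.array([g[1] for g in grid])
        return pd.DataFrame({"nu_e": nu_e, "nu_i": nu_i,
                             "rate": model.rate(nu_e, nu_i)})

    def test_noiseless_parameter_recovery(self):
        gen = self._generating_model()
        samples = self._noiseless_samples(gen)
        fitted, rms = fit_transfer_function(samples, **{k: CELL[k] for k in
                                                        ("g_L", "c_m", "E_L", "K_e", "K_i")},
                                            synapse=SYN)
        assert rms < 1e-6
        check = np.linspace(0.5, 12.0, 30)
        np.testing.assert_allclose(fitted.rate(check, np.full(30, 7.0)),
                                   gen.rate(check, np.full(30, 7.0)),
                                   atol=1e-6)

    def test_degenerate_design_raises(self):
        gen = self._generating_model()
        nu_e = np.full(20, 4.0)
        nu_i = np.full(20, 8.0)
        samples = pd.DataFrame({"nu_e": nu_e, "nu_i": nu_i,
                                "rate": gen.rate(nu_e, nu_i)})
        with pytest.raises(FitError, match="grid"):
            fit_transfer_function(samples, **{k: CELL[k] for k in
                                              ("g_L", "c_m", "E_L", "K_e", "K_i")},
                                  synapse=SYN)

    def test_all_zero_rates_raise(self):
        samples = pd.DataFrame({"nu_e": np.linspace(0, 5, 20),
                                "nu_i": np.full(20, 30.0),
                                "rate": np.zeros(20)})
        with pytest.raises(FitError, match="nonzero"):
            fit_transfer_function(samples, **{k: CELL[k] for k in
                                              ("g_L", "c_m", "E_L", "K_e", "K_i")},
                                  synapse=SYN)

    def test_fitted_adex_quality_and_shape(self, adex_tf_pair):
        # rms below 1.5 Hz on the low-rate validity domain, and the
        # fluctuation-driven monotonicities: rising in nu_e, falling in nu_i
        for cell in ("rs", "fs"):
            tf, samples, rms = adex_tf_pair[cell]
            low = samples[samples["rate"] < 30.0]
            resid = tf.rate(low["nu_e"].to_numpy(),
                            low["nu_i"].to_numpy()) - low["rate"].to_numpy()
            assert float(np.sqrt(np.mean(resid ** 2))) < 1.5
        tf_fs = adex_tf_pair["fs"][0]
        nes = np.linspace(1.0, 6.0, 20)
        assert np.all(np.diff(tf_fs.rate(nes, np.full(20, 8.0))) > 0)
        nis = np.linspace(4.0, 16.0, 20)
        assert np.all(np.diff(tf_fs.rate(np.full(20, 4.0), nis)) < 0)

    def test_save_load_round_trip(self, tmp_path, adex_tf_pair):
        tf = adex_tf_pair["rs"][0]
        path = tmp_path / "tf.tsv"
        tf.save(path)
        back = TransferFunctionModel.load(path)
        pts = np.array([1.0, 3.0, 6.0])
        np.testing.assert_allclose(back.rate(pts, pts), tf.rate(pts, pts),
                                   rtol=1e-6)


class TestMeasurement:
    def test_pure_inhibition_is_silent(self):
        df = measure_transfer_function("adex", ADEX_RS, SYN, [(0.0, 8.0)],
                                       duration=1000.0, n_seeds=2)
        assert df["rate"].iloc[0] == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            measure_transfer_function("adex", ADEX_RS, SYN, [])

    def test_ml_transfer_function_is_bell_shaped(self):
        from spikemf.params import ML_RS
        syn = default_synapse("ml")
        rates = {ne: np.mean([measure_transfer_function(
            "ml", ML_RS, syn, [(ne, 8.0)], duration=4000.0, n_seeds=2,
            base_seed=s)["rate"].iloc[0] for s in (0,)])
            for ne in (2.0, 7.5, 16.0)}
        assert rates[7.5] > rates[2.0]
        assert rates[7.5] > rates[16.0]


def test_reference_threshold_fixtures_load():
    for model in ("adex", "hh", "ml"):
        refs = load_reference_thresholds(model)
        assert set(refs) == {"rs", "fs"}
        for poly in refs.values():
            assert np.all(np.isfinite(poly.coeffs))
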