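"""MVAR fitting, PDC identities, TPDC, surrogates, DICS and group stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anxnet import NumericalError, PreconditionError, effconn, simulate
from anxnet.validation import _brute_force_pdc, random_stable_mvar


def _signal(data, fs=100.0):
    return effconn.MultichannelSignal(np.asarray(data, dtype=float), fs)


class TestFitMvar:
    def test_univariate_ar1_consistency(self):
        model = effconn.MVARModel(np.array([[[0.5]]]), np.eye(1), 100.0)
        sig = simulate.gen_mvar_signals(model, 50000, seed=0)
        fit = effconn.fit_mvar(sig, order=1)
        assert fit.coeffs[0, 0, 0] == pytest.approx(0.5, abs=0.02)

    def test_white_noise_coefficients_near_zero(self, rng):
        sig = _signal(rng.standard_normal((3, 20000)))
        fit = effconn.fit_mvar(sig, order=1)
        assert np.abs(fit.coeffs).max() < 0.05

    def test_residual_covariance_recovered(self):
        model = effconn.MVARModel(np.array([[[0.4]]]), np.array([[2.25]]), 50.0)
        sig = simulate.gen_mvar_signals(model, 40000, seed=3)
        fit = effconn.fit_mvar(sig, order=1)
        assert fit.resid_cov[0, 0] == pytest.approx(2.25, rel=0.05)

    def test_too_short_rejected(self, rng):
        with pytest.raises(PreconditionError):
            effconn.fit_mvar(_signal(rng.standard_normal((2, 30))), order=5)


class TestSelectOrder:
    def test_recovers_ar2_order(self):
        model = simulate.oscillatory_mvar_model(100.0, 2, peak_hz=8.0)
        correct = 0
        for s in range(5):
            sig = simulate.gen_mvar_signals(model, 8000, seed=s)
            order, trace = effconn.select_order(sig, max_order=6)
            correct += order == 2
        assert correct >= 4

    def test_max_order_one_returns_one(self, rng):
        sig = _signal(rng.standard_normal((2, 500)))
        order, trace = effconn.select_order(sig, max_order=1)
        assert order == 1
        assert len(trace) == 1

    def test_short_series_warns_and_caps(self, rng):
        sig = _signal(rng.standard_normal((2, 80)))
        with pytest.warns(UserWarning):
            order, _ = effconn.select_order(sig, max_order=20)
        assert order >= 1


class TestPDC:
    def test_diagonal_model_has_zero_offdiagonal_pdc(self):
        model = effconn.MVARModel(0.5 * np.eye(3)[None], np.eye(3), 100.0)
        pdc = effconn.pdc_spectrum(model, np.linspace(0, 50, 11))
        off = pdc[:, ~np.eye(3, dtype=bool)]
        assert np.abs(off).max() == 0.0

    def test_worked_two_channel_example(self):
        A = np.array([[[0.5, 0.0], [0.3, 0.5]]])
        model = effconn.MVARModel(A, np.eye(2), fs_hz=2.0)
        pdc0 = effconn.pdc_spectrum(model, np.array([0.0]))[0]
        assert pdc0[1, 0] == pytest.approx(0.3 / np.sqrt(0.34), abs=1e-10)
        assert pdc0[1, 0] == pytest.approx(0.5145, abs=1e-4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_normalization_identity_random_models(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(2, 6))
        p = int(rng.integers(1, 4))
        model = random_stable_mvar(rng, c, p)
        freqs = np.linspace(0, 50, 7)
        pdc = effconn.pdc_spectrum(model, freqs)
        assert np.abs((pdc**2).sum(axis=1) - 1.0).max() < 1e-10

    def test_matches_brute_force_on_random_model(self, rng):
        model = random_stable_mvar(rng, 3, 2)
        for f in (0.0, 10.0, 33.0):
            pdc = effconn.pdc_spectrum(model, np.array([f]))[0]
            for i in range(3):
                for j in range(3):
                    ref = _brute_force_pdc(model.coeffs, model.fs_hz, f, i, j)
                    assert pdc[i, j] == pytest.approx(ref, abs=1e-10)


class TestTPDC:
    def test_window_count_arithmetic(self, rng):
        sig = _signal(rng.standard_normal((2, 1000)), fs=100.0)
        res = effconn.tpdc(sig, window_s=2.0, step_s=3.0, order=2,
                           freqs=np.array([5.0]), bands={"b": (4.0, 6.0)})
        # floor((N - W)/S) + 1 with W=200, S=300
        assert res.n_windows == (1000 - 200) // 300 + 1

    def test_stationary_time_average_matches_global_pdc(self):
        model = simulate.oscillatory_mvar_model(100.0, 2, peak_hz=8.0,
                                                couplings=[(1, 0, 0.3)])
        sig = simulate.gen_mvar_signals(model, 20000, seed=2)
        freqs = np.arange(2.0, 20.0)
        res = effconn.tpdc(sig, window_s=4.0, step_s=2.0, order=2, freqs=freqs,
                           bands={"all": (2.0, 19.0)})
        full = effconn.pdc_spectrum(effconn.fit_mvar(sig, 2), freqs)
        # windowed estimates carry per-window noise and a small Jensen bias
        assert np.abs(res.time_avg - full).max() < 0.12

    def test_time_varying_coupling_detected_in_second_half(self, rng):
        n = 16000
        fs = 100.0
        noise = rng.standard_normal((2, n))
        x = noise.copy()
        for t in range(1, n):
            x[0, t] += 0.5 * x[0, t - 1]
            x[1, t] += 0.5 * x[1, t - 1]
            if t >= n // 2:
                x[1, t] += 0.6 * x[0, t - 1]
        res = effconn.tpdc(_signal(x, fs), window_s=4.0, step_s=4.0, order=2,
                           freqs=np.arange(1.0, 30.0), bands={"lo": (1.0, 29.0)})
        half = res.n_windows // 2
        first = res.values[:half, :, 1, 0].mean()
        second = res.values[half + 1 :, :, 1, 0].mean()
        assert second > first + 0.1

    def test_signal_shorter_than_window_rejected(self, rng):
        sig = _signal(rng.standard_normal((2, 100)), fs=100.0)
        with pytest.raises(PreconditionError):
            effconn.tpdc(sig, window_s=2.0, order=2)


class TestBootstrap:
    def _params(self):
        return dict(window_s=2.0, step_s=1.0, order=2,
                    freqs=np.array([5.0, 6.0]), bands={"theta": (4.0, 7.0)})

    def test_zero_bootstrap_rejected(self, rng):
        sig = _signal(rng.standard_normal((2, 4000)))
        with pytest.raises(PreconditionError):
            effconn.bootstrap_threshold(sig, n_boot=0, **self._params())

    def test_shuffle_window_must_cover_order(self, rng):
        sig = _signal(rng.standard_normal((2, 4000)))
        with pytest.raises(PreconditionError):
            effconn.bootstrap_threshold(sig, n_boot=5, shuffle_window_s=0.05,
                                        **self._params())

    def test_deterministic_given_seed(self, rng):
        sig = _signal(rng.standard_normal((2, 6000)))
        a = effconn.bootstrap_threshold(sig, n_boot=10, seed=5, **self._params())
        b = effconn.bootstrap_threshold(sig, n_boot=10, seed=5, **self._params())
        assert a.threshold_global == b.threshold_global
        assert np.array_equal(a.null_values, b.null_values)

    def test_white_noise_connections_fail(self, rng):
        # with the stricter per-connection 95th-percentile threshold, white
        # noise should produce essentially no passing connections
        sig = _signal(rng.standard_normal((3, 12000)))
        null = effconn.bootstrap_threshold(sig, n_boot=30, seed=0, **self._params())
        decisions = effconn.time_reversal_test(
            sig, null, threshold_mode="per_connection", **self._params()
        )
        assert decisions["passes"].sum() <= 1


class TestTimeReversal:
    def test_planted_coupling_passes_and_reverse_fails(self):
        model = simulate.oscillatory_mvar_model(125.0, 3, couplings=[(1, 0, 0.35)])
        sig = simulate.gen_mvar_signals(model, 30000, seed=4)
        params = dict(window_s=2.0, step_s=1.0, order=3,
                      freqs=np.array([4.0, 5.0, 6.0, 7.0]), bands={"theta": (4.0, 7.0)})
        null = effconn.bootstrap_threshold(sig, n_boot=50, seed=1, **params)
        out = effconn.time_reversal_test(sig, null, **params)
        row = out[(out["target"] == "ch1") & (out["source"] == "ch0")].iloc[0]
        rev = out[(out["target"] == "ch0") & (out["source"] == "ch1")].iloc[0]
        assert row["passes"]
        assert not rev["passes"]
        assert row["net_forward"] > 0 and row["net_reversed"] < 0


class TestDICS:
    def test_identity_csd_gives_equal_power(self):
        lf = simulate.gen_leadfield(16, 3, seed=0)
        power, _ = effconn.dics_power(np.eye(16, dtype=complex), lf, reg_lambda=0.0)
        assert np.allclose(power, power[0], rtol=1e-8)

    def test_large_regularization_flattens_power(self, rng):
        lf = simulate.gen_leadfield(16, 3, seed=1)
        src = rng.standard_normal(2000)
        sensors = np.outer(lf.gain[:, 1], src) * 5 + 0.1 * rng.standard_normal((16, 2000))
        csd = effconn.cross_spectral_density(_signal(sensors, 100.0), (5.0, 45.0))
        p_small, _ = effconn.dics_power(csd, lf, reg_lambda=0.01)
        p_huge, _ = effconn.dics_power(csd, lf, reg_lambda=1e6)
        assert p_small.max() / p_small.min() > p_huge.max() / p_huge.min()

    def test_singular_csd_without_regularization_errors(self):
        lf = simulate.gen_leadfield(8, 2, seed=2)
        c = np.zeros((8, 8), dtype=complex)
        with pytest.raises(NumericalError, match="reg"):
            effconn.dics_power(c, lf, reg_lambda=0.0)

    def test_filters_extract_source(self, rng):
        lf = simulate.gen_leadfield(32, 2, seed=3)
        t = np.arange(4000) / 250.0
        src = np.sin(2 * np.pi * 10 * t)
        sensors = np.outer(lf.gain[:, 0], src) + 0.05 * rng.standard_normal((32, 4000))
        csd = effconn.cross_spectral_density(_signal(sensors, 250.0), (8.0, 12.0))
        power, filters = effconn.dics_power(csd, lf, reg_lambda=0.05)
        est = effconn.extract_source_timecourses(sensors, filters)[0]
        r = np.corrcoef(est, src)[0, 1]
        assert abs(r) > 0.9


class TestCompareGroups:
    def _table(self, shift=0.0, rng=None, n_per_cell=20):
        rng = rng or np.random.default_rng(0)
        rows = []
        for group, delta in (("patients", shift), ("controls", 0.0)):
            for conn in ("a", "b", "c"):
                for _ in range(n_per_cell):
                    rows.append({"group": group, "connection": conn,
                                 "value": rng.standard_normal() + delta})
        return pd.DataFrame(rows)

    def test_identical_groups_null_f(self):
        rng = np.random.default_rng(3)
        df = self._table(0.0, rng)
        # make groups literally identical per connection
        vals = df[df["group"] == "controls"]["value"].to_numpy()
        df.loc[df["group"] == "patients", "value"] = vals
        anova, _ = effconn.compare_groups(df)
        assert anova.loc["C(group)", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_detected(self):
        anova, posthoc = effconn.compare_groups(self._table(shift=2.0))
        assert anova.loc["C(group)", "PR(>F)"] < 1e-6
        assert (posthoc["p"] < 0.01).all()

    def test_hand_computed_sums_of_squares(self):
        # balanced 2x2 toy: group A conn x = (1,2), conn y = (3,4);
        #                   group B conn x = (5,6), conn y = (7,8)
        df = pd.DataFrame(
            {
                "group": ["A"] * 4 + ["B"] * 4,
                "connection": ["x", "x", "y", "y"] * 2,
                "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            }
        )
        anova, _ = effconn.compare_groups(df)
        # hand calculation: SS_group = 8*(2^2) = 32, SS_conn = 8*(1^2) = 8,
        # SS_resid = 8 * 0.25 = 2 -> with df_resid = 5: MS_resid = 0.4
        assert anova.loc["C(group)", "sum_sq"] == pytest.approx(32.0)
        assert anova.loc["C(connection)", "sum_sq"] == pytest.approx(8.0)
        assert anova.loc["Residual", "sum_sq"] == pytest.approx(2.0)
        assert anova.loc["C(group)", "F"] == pytest.approx(32.0 / 0.4)

    def test_missing_cell_rejected(self):
        df = self._table()
        df = df[~((df["group"] == "patients") & (df["connection"] == "b"))]
        with pytest.raises(PreconditionError):
            effconn.compare_groups(df)
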