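"""Generators: determinism, planted effects, and precondition handling."""

import numpy as np
import pandas as pd
import pytest

from anxnet import PreconditionError, effconn, morphometry, sem, simulate


class TestThicknessCohort:
    def test_degenerate_interval_range_is_exact(self):
        ds = simulate.gen_thickness_cohort(10, 5, dt_range_years=(2.0, 2.0), seed=0)
        assert np.allclose(ds["delta_years"], 2.0)

    def test_deterministic_given_seed(self):
        a = simulate.gen_thickness_cohort(12, 6, seed=42)
        b = simulate.gen_thickness_cohort(12, 6, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_schema_and_ranges(self):
        ds = simulate.gen_thickness_cohort(30, 8, seed=3)
        assert set(morphometry.THICKNESS_COLUMNS) <= set(ds.columns)
        assert ds["symptom"].between(0, 21).all()
        assert (ds["ct_baseline"] > 0).all()
        assert set(ds["sex"].unique()) <= {0, 1}
        assert len(ds) == 30 * 8

    def test_null_effect_mean_correlation_near_zero(self):
        rs = []
        for s in range(100):
            ds = simulate.gen_thickness_cohort(40, 3, planted_region=1, r_pop=0.0, seed=s)
            atr = morphometry.compute_atrophy(ds)
            wide = atr.pivot(index="subject", columns="region", values="atrophy_rate")
            symptom = ds.drop_duplicates("subject").set_index("subject")["symptom"]
            rs.append(np.corrcoef(wide[1], symptom)[0, 1])
        # mean sample r under the null: SE ~ 1/sqrt(n_reps * (n-1))
        assert abs(np.mean(rs)) < 3 / np.sqrt(100 * 39)

    def test_planted_correlation_within_sampling_band(self):
        # r_pop = 0.3 at n = 92: Fisher z band atanh(0.3) +- 3/sqrt(89)
        rs = []
        for s in range(30):
            ds = simulate.gen_thickness_cohort(92, 68, planted_region=7, r_pop=0.3, seed=s)
            atr = morphometry.compute_atrophy(ds)
            wide = atr.pivot(index="subject", columns="region", values="atrophy_rate")
            symptom = ds.drop_duplicates("subject").set_index("subject")["symptom"]
            rs.append(np.corrcoef(wide[7], symptom)[0, 1])
        z = np.arctanh(rs)
        assert abs(z.mean() - np.arctanh(0.3)) < 3 / np.sqrt(30 * 89) + 0.02  # rounding attenuation

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_regions=0),
            dict(r_pop=1.2),
            dict(planted_region=99),
            dict(n_subjects=2),
            dict(dt_range_years=(0.0, 1.0)),
        ],
    )
    def test_preconditions(self, kwargs):
        base = dict(n_subjects=10, n_regions=5, seed=0)
        base.update(kwargs)
        with pytest.raises(PreconditionError):
            simulate.gen_thickness_cohort(**base)


class TestNormativeBold:
    def test_within_module_correlation_matches_target(self):
        labels = np.zeros((2, 1, 1), dtype=int)
        labels[:, 0, 0] = 1
        datasets, _ = simulate.gen_normative_bold(1, (2, 1, 1), labels, 0.6,
                                                  n_frames=5000, seed=0)
        x = datasets[0].data.reshape(2, -1)
        r = np.corrcoef(x)[0, 1]
        assert abs(r - 0.6) < 0.03

    def test_zero_rho_gives_independent_voxels(self):
        labels = np.ones((4, 1, 1), dtype=int)
        datasets, _ = simulate.gen_normative_bold(1, (4, 1, 1), labels, 0.0,
                                                  n_frames=4000, seed=1)
        c = np.corrcoef(datasets[0].data.reshape(4, -1))
        off = c[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.06

    def test_cross_module_independent(self):
        labels = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        datasets, _ = simulate.gen_normative_bold(1, (4, 1, 1), labels, 0.7,
                                                  n_frames=4000, seed=2)
        c = np.corrcoef(datasets[0].data.reshape(4, -1))
        assert c[0, 1] > 0.6 and c[2, 3] > 0.6
        assert abs(c[0, 2]) < 0.06

    def test_deterministic(self):
        labels = np.ones((3, 2, 1), dtype=int)
        a, _ = simulate.gen_normative_bold(2, (3, 2, 1), labels, 0.4, n_frames=50, seed=9)
        b, _ = simulate.gen_normative_bold(2, (3, 2, 1), labels, 0.4, n_frames=50, seed=9)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_preconditions(self):
        labels = np.ones((2, 1, 1), dtype=int)
        with pytest.raises(PreconditionError):
            simulate.gen_normative_bold(1, (2, 1, 1), labels, 0.5, n_frames=2)
        with pytest.raises(PreconditionError):
            simulate.gen_normative_bold(1, (1, 1, 1), np.ones((1, 1, 1), int), 0.5)


class TestMVARSignals:
    def test_diagonal_model_has_no_cross_coupling(self):
        model = effconn.MVARModel(0.5 * np.eye(3)[None], np.eye(3), 100.0)
        sig = simulate.gen_mvar_signals(model, 20000, seed=0)
        fit = effconn.fit_mvar(sig, order=1)
        off = fit.coeffs[0][~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_coefficient_recovery(self):
        model = simulate.oscillatory_mvar_model(125.0, 3, couplings=[(1, 0, 0.3)])
        sig = simulate.gen_mvar_signals(model, 30000, seed=1)
        fit = effconn.fit_mvar(sig, order=2)
        assert np.abs(fit.coeffs - model.coeffs).max() < 0.05

    def test_zero_samples_rejected(self):
        model = effconn.MVARModel(0.5 * np.eye(2)[None], np.eye(2), 100.0)
        with pytest.raises(PreconditionError):
            simulate.gen_mvar_signals(model, 0, seed=0)

    def test_unstable_model_rejected_with_radius(self):
        model = effconn.MVARModel(1.1 * np.eye(2)[None], np.eye(2), 100.0)
        with pytest.raises(PreconditionError, match="spectral radius"):
            simulate.gen_mvar_signals(model, 1000, seed=0)


class TestSemCohort:
    def test_sample_covariance_matches_implied(self):
        model = sem.PathModel.from_text("y ~ x")
        theta = np.array([0.8, 1.0, 1.0])  # path, var(x), resid(y)
        _, data = simulate.gen_sem_cohort(model, theta, 100_000, seed=0)
        implied = sem.implied_covariance(model, theta)
        assert np.abs(data.cov - implied).max() < 0.01 * np.abs(implied).max() + 0.01

    def test_zero_paths_uncorrelated(self):
        model = sem.PathModel.from_text("y ~ x")
        _, data = simulate.gen_sem_cohort(model, np.array([0.0, 1.0, 1.0]), 20000, seed=1)
        r = data.cov[0, 1] / np.sqrt(data.cov[0, 0] * data.cov[1, 1])
        assert abs(r) < 0.03

    def test_deterministic(self):
        model = sem.PathModel.from_text("y ~ x")
        t1, _ = simulate.gen_sem_cohort(model, np.array([0.5, 1.0, 1.0]), 100, seed=5)
        t2, _ = simulate.gen_sem_cohort(model, np.array([0.5, 1.0, 1.0]), 100, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestTaskEEG:
    def test_shock_fraction_on_threat_trials(self):
        _, events = simulate.gen_task_eeg(n_trials=400, n_channels=4, fs_hz=250.0,
                                          shock_trial_fraction=0.33, seed=0,
                                          trial_spacing_s=(2.0, 2.0), pre_record_s=1.0)
        threat = events[events["condition"] == "threat"]
        frac = threat["shock"].mean()
        assert abs(frac - 0.33) < 3 * np.sqrt(0.33 * 0.67 / len(threat))
        assert not events.loc[events["condition"] == "safe", "shock"].any()

    def test_tms_sample_offset(self):
        cont, events = simulate.gen_task_eeg(n_trials=5, n_channels=4, fs_hz=250.0, seed=1,
                                             trial_spacing_s=(3.0, 3.0))
        assert (events["tms_sample"] - events["sample"] == 250).all()
        assert (events["sample"] < cont.data.shape[1]).all()

    def test_fs_too_low_for_band_rejected(self):
        eff = simulate.ConditionEffect("threat", (30.0, 70.0), (0,), (0.0, 1.0), 2.0)
        with pytest.raises(PreconditionError):
            simulate.gen_task_eeg(n_trials=4, fs_hz=100.0, condition_effects=[eff], seed=0)


class TestLeadField:
    def test_unit_norm_columns_and_rank(self):
        lf = simulate.gen_leadfield(64, 3, seed=0)
        assert np.allclose(np.linalg.norm(lf.gain, axis=0), 1.0)
        assert np.linalg.matrix_rank(lf.gain) == 3

    def test_deterministic(self):
        a = simulate.gen_leadfield(16, 2, seed=7)
        b = simulate.gen_leadfield(16, 2, seed=7)
        assert np.array_equal(a.gain, b.gain)

    def test_requires_more_channels_than_sources(self):
        with pytest.raises(PreconditionError):
            simulate.gen_leadfield(3, 3, seed=0)
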