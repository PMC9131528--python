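"""Epoching, TMS excision, referencing, band power and cluster statistics."""

import numpy as np
import pandas as pd
import pytest

from anxnet import PreconditionError, eegtask, simulate


def _record(rng, n_channels=4, n_samples=5000, fs=250.0, cues=(500, 2000, 3500)):
    data = rng.standard_normal((n_channels, n_samples))
    events = pd.DataFrame(
        {
            "sample": list(cues),
            "condition": ["threat", "safe", "threat"][: len(cues)],
            "shock": [False, False, True][: len(cues)],
            "tms_sample": [c + 250 for c in cues],
        }
    )
    return eegtask.ContinuousEEG(data=data, fs_hz=fs, events=events)


class TestEpoch:
    def test_sample_count_at_250hz(self, rng):
        ep = eegtask.epoch(_record(rng), tmin=-2.0, tmax=5.0)
        assert ep.data.shape[2] == 1750

    def test_zero_events_empty(self, rng):
        cont = _record(rng)
        cont.events = cont.events.iloc[:0]
        ep = eegtask.epoch(cont)
        assert ep.n_trials == 0

    def test_slicing_oracle(self, rng):
        cont = _record(rng)
        ep = eegtask.epoch(cont, tmin=-0.5, tmax=1.0)
        for k, cue in enumerate([500, 2000, 3500]):
            lo = cue + int(round(-0.5 * 250))
            assert np.array_equal(ep.data[k], cont.data[:, lo : lo + 375])

    def test_boundary_trials_dropped(self, rng):
        cont = _record(rng, cues=(100, 2000))
        ep = eegtask.epoch(cont, tmin=-2.0, tmax=5.0)
        assert ep.n_trials == 1  # first cue has no full pre-window

    def test_trial_bookkeeping_conserved(self, rng):
        cont = _record(rng, cues=(100, 2000, 3000))
        ep = eegtask.epoch(cont, tmin=-2.0, tmax=5.0)
        kept = ep.n_trials
        assert kept + 1 == len(cont.events)
        assert any("dropped 1" in line for line in ep.log)


class TestExciseTMS:
    def test_excised_sample_count_at_250hz(self, rng):
        ep = eegtask.epoch(_record(rng), tmin=-1.0, tmax=2.0)
        out = eegtask.excise_tms(ep, pre_s=0.005, post_s=0.02, mode="remove")
        n_cut = ep.data.shape[2] - out.data.shape[2]
        # 0.025 s of samples: round(0.005*250) + round(0.02*250) + 1 = 7
        assert n_cut == 7
        assert n_cut / 250.0 == pytest.approx(0.025, abs=0.005)

    def test_injected_transient_removed(self, rng):
        cont = _record(rng)
        for tms in cont.events["tms_sample"]:
            cont.data[:, tms - 1 : tms + 5] += 500.0
        ep = eegtask.epoch(cont, tmin=-1.0, tmax=2.0)
        out = eegtask.excise_tms(ep, mode="remove")
        assert np.abs(out.data).max() < 10.0

    def test_interpolation_reproduces_linear_ramp(self):
        fs = 250.0
        ramp = np.arange(1000, dtype=float)
        data = np.tile(ramp, (2, 1))
        events = pd.DataFrame({"sample": [300], "condition": ["safe"],
                               "shock": [False], "tms_sample": [500]})
        cont = eegtask.ContinuousEEG(data, fs, events)
        ep = eegtask.epoch(cont, tmin=-1.0, tmax=1.0)
        out = eegtask.excise_tms(ep, mode="interpolate")
        assert np.allclose(out.data[0], ep.data[0], atol=1e-9)

    def test_window_outside_epoch_rejected(self, rng):
        cont = _record(rng)
        cont.events["tms_sample"] = cont.events["sample"]  # pulse at epoch edge
        ep = eegtask.epoch(cont, tmin=0.0, tmax=1.0)
        with pytest.raises(PreconditionError):
            eegtask.excise_tms(ep)


class TestDropAndRereference:
    def test_shock_trial_counting(self, rng):
        ep = eegtask.epoch(_record(rng))
        out = eegtask.drop_shock_trials(ep)
        assert out.n_trials == 2
        assert not out.shock.any()

    def test_all_flagged_empty(self, rng):
        ep = eegtask.epoch(_record(rng))
        ep.shock[:] = True
        assert eegtask.drop_shock_trials(ep).n_trials == 0

    def test_rereference_zeroes_channel_means(self, rng):
        ep = eegtask.epoch(_record(rng))
        out = eegtask.rereference_average(ep)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12

    def test_rereference_idempotent(self, rng):
        ep = eegtask.epoch(_record(rng))
        once = eegtask.rereference_average(ep)
        twice = eegtask.rereference_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_identical_constant_channels_zeroed(self):
        data = np.full((3, 1000), 4.2)
        events = pd.DataFrame({"sample": [500], "condition": ["safe"],
                               "shock": [False], "tms_sample": [600]})
        ep = eegtask.epoch(eegtask.ContinuousEEG(data, 250.0, events),
                           tmin=-1.0, tmax=1.0)
        out = eegtask.rereference_average(ep)
        assert np.abs(out.data).max() < 1e-12

    def test_mean_zero_input_unchanged(self, rng):
        ep = eegtask.epoch(_record(rng))
        ep.data -= ep.data.mean(axis=1, keepdims=True)
        out = eegtask.rereference_average(ep)
        assert np.allclose(out.data, ep.data, atol=1e-12)


class TestBandPower:
    def _sine_epochs(self, freq, amp=1.0, fs=250.0):
        t = np.arange(1000) / fs
        data = amp * np.sin(2 * np.pi * freq * t)
        return eegtask.EpochedEEG(
            data=np.tile(data, (3, 2, 1)),  # 3 trials, 2 channels
            fs_hz=fs,
            times=t,
            conditions=np.array(["a", "a", "a"], dtype=object),
            shock=np.zeros(3, bool),
            tms_index=np.full(3, -1),
        )

    def test_in_band_sinusoid_envelope(self):
        ep = self._sine_epochs(5.0, amp=2.0)
        pmap = eegtask.band_power(ep, band=(4.0, 7.0))
        mid = pmap.power["a"][0, 300:700]
        assert np.allclose(mid, 4.0, rtol=0.1)  # amplitude^2

    def test_out_of_band_sinusoid_suppressed(self):
        ep = self._sine_epochs(5.0)
        pmap = eegtask.band_power(ep, band=(30.0, 70.0))
        assert pmap.power["a"][0, 300:700].max() < 0.01

    def test_quadratic_amplitude_scaling(self):
        p1 = eegtask.band_power(self._sine_epochs(5.0, 1.0), (4.0, 7.0)).power["a"]
        p2 = eegtask.band_power(self._sine_epochs(5.0, 2.0), (4.0, 7.0)).power["a"]
        assert np.allclose(p2, 4.0 * p1, rtol=1e-6)

    def test_band_above_nyquist_rejected(self):
        ep = self._sine_epochs(5.0, fs=100.0)
        with pytest.raises(PreconditionError):
            eegtask.band_power(ep, band=(30.0, 70.0))


class TestClusterPermutation:
    def test_matches_mne_observed_clusters(self, rng):
        mne = pytest.importorskip("mne")
        import scipy.sparse as sp

        from anxnet._clustering import lattice_edges

        n1 = n2 = 8
        C, T = 6, 20
        a = rng.standard_normal((n1, C, T))
        b = rng.standard_normal((n2, C, T))
        b[:, 2:4, 5:12] += 1.2
        adj_ch = np.column_stack([np.arange(C - 1), np.arange(1, C)])
        res = eegtask.cluster_permutation_test(a, b, adj_ch, n_perm=100, seed=1)
        edges = lattice_edges(C, T, adj_ch)
        n = C * T
        A = sp.coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        )
        obs, clusters, _, _ = mne.stats.permutation_cluster_test(
            [a.reshape(n1, -1), b.reshape(n2, -1)],
            threshold=res.t_crit, n_permutations=50, tail=0,
            stat_fun=mne.stats.ttest_ind_no_p, adjacency=(A + A.T).tocsr(),
            out_type="indices", verbose=False,
        )
        assert np.allclose(obs, res.t_map.ravel(), atol=1e-10)
        mine = sorted(np.round(res.clusters["mass"].to_numpy(), 8))
        theirs = sorted(round(float(abs(obs[c[0]].sum())), 8) for c in clusters)
        assert mine == theirs

    def test_planted_effect_found(self, rng):
        a = rng.standard_normal((12, 8, 30))
        b = rng.standard_normal((12, 8, 30))
        b[:, 2:5, 10:20] += 1.5
        adj = np.column_stack([np.arange(7), np.arange(1, 8)])
        res = eegtask.cluster_permutation_test(a, b, adj, n_perm=200, seed=0)
        sig = res.clusters[res.clusters["significant"]]
        assert len(sig) >= 1
        planted = np.zeros((8, 30), bool)
        planted[2:5, 10:20] = True
        top = res.clusters.loc[res.clusters["mass"].idxmax(), "cluster_id"]
        assert ((res.labels == top) & planted).any()

    def test_p_values_in_valid_range(self, rng):
        a = rng.standard_normal((5, 4, 10))
        b = rng.standard_normal((5, 4, 10))
        adj = np.empty((0, 2), dtype=int)
        res = eegtask.cluster_permutation_test(a, b, adj, n_perm=99, seed=2)
        if len(res.clusters):
            assert res.clusters["p"].between(1 / 100, 1.0).all()

    def test_exact_enumeration_small_groups(self, rng):
        a = rng.standard_normal((3, 2, 5))
        b = rng.standard_normal((3, 2, 5))
        adj = np.empty((0, 2), dtype=int)
        res = eegtask.cluster_permutation_test(a, b, adj, n_perm=10_000, seed=0)
        assert res.exact
        assert res.n_perm == 20  # C(6, 3)

    def test_deterministic_given_seed(self, rng):
        a = rng.standard_normal((6, 4, 12))
        b = rng.standard_normal((6, 4, 12))
        adj = np.column_stack([np.arange(3), np.arange(1, 4)])
        r1 = eegtask.cluster_permutation_test(a, b, adj, n_perm=50, seed=9)
        r2 = eegtask.cluster_permutation_test(a, b, adj, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(r1.clusters, r2.clusters)

    def test_group_size_precondition(self, rng):
        with pytest.raises(PreconditionError):
            eegtask.cluster_permutation_test(
                rng.standard_normal((1, 2, 5)), rng.standard_normal((4, 2, 5)),
                np.empty((0, 2), int), n_perm=10,
            )
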