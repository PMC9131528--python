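"""End-to-end calibration and recovery benchmarks on synthetic ground truth.

Every function simulates data with a planted, known effect (or a full null),
runs the matching estimator from this package, and returns the measured
recovery or error-rate summary. They are the package's self-checks: false
positive rates of the permutation procedures, detection rates of planted
effects at the study's sample sizes, and exactness of the closed-form
pieces. All routines are deterministic given ``seed`` (child seeds are
spawned via ``numpy.random.SeedSequence``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import eegtask, effconn, morphometry, netmap, sem, simulate
from ._seeds import child_seeds as _child_seeds

__all__ = [
    "pdc_normalization_deviation",
    "pdc_worked_example",
    "tpdc_recovery",
    "morphometry_fwe_rate",
    "atrophy_detection_rate",
    "netmap_recovery_dice",
    "fisher_transform_checks",
    "sem_benchmark",
    "cluster_test_calibration",
    "cluster_test_power",
    "dics_localization_rate",
    "eeg_plumbing_checks",
]


def random_stable_mvar(rng: np.random.Generator, n_channels: int, order: int,
                       target_radius: float = 0.9) -> effconn.MVARModel:
    """Random MVAR model rescaled to a companion spectral radius < 1."""
    A = rng.normal(0.0, 0.4, size=(order, n_channels, n_channels))
    model = effconn.MVARModel(A, np.eye(n_channels), fs_hz=100.0)
    rho = model.spectral_radius()
    if rho > 0:
        scale = target_radius / rho
        A = np.stack([A[k] * scale ** (k + 1) for k in range(order)])
    return effconn.MVARModel(A, np.eye(n_channels), fs_hz=100.0)


# ---------------------------------------------------------------------------
# PDC identities
# ---------------------------------------------------------------------------


def pdc_normalization_deviation(n_models: int = 100, seed: int | None = 0) -> float:
    """Max deviation of sum_i pdc[i<-j](f)^2 from 1 over random stable models."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    freqs = np.linspace(0.0, 50.0, 26)
    for _ in range(n_models):
        c = int(rng.integers(2, 6))
        p = int(rng.integers(1, 4))
        model = random_stable_mvar(rng, c, p)
        pdc = effconn.pdc_spectrum(model, freqs)
        colsums = (pdc**2).sum(axis=1)
        worst = max(worst, float(np.abs(colsums - 1.0).max()))
    return worst


def _brute_force_pdc(coeffs: np.ndarray, fs: float, f: float, i: int, j: int) -> float:
    """Literal evaluation of the PDC definition with explicit loops."""
    p, c, _ = coeffs.shape
    abar = np.zeros((c, c), dtype=complex)
    for m in range(c):
        for nn in range(c):
            abar[m, nn] = (1.0 if m == nn else 0.0) - sum(
                coeffs[k, m, nn] * np.exp(-2j * np.pi * f * (k + 1) / fs)
                for k in range(p)
            )
    denom = np.sqrt(sum(abs(abar[m, j]) ** 2 for m in range(c)))
    return abs(abar[i, j]) / denom


def pdc_worked_example() -> dict[str, float]:
    """PDC of the worked 2-channel model at f = 0, against brute force.

    A_1 = [[0.5, 0], [0.3, 0.5]] gives pdc[2<-1](0) = 0.3 / sqrt(0.34)
    = 0.514496...
    """
    A = np.array([[[0.5, 0.0], [0.3, 0.5]]])
    model = effconn.MVARModel(A, np.eye(2), fs_hz=2.0)
    value = float(effconn.pdc_spectrum(model, np.array([0.0]))[0, 1, 0])
    brute = _brute_force_pdc(A, 2.0, 0.0, 1, 0)
    return {"value": value, "brute_force": brute, "deviation": abs(value - brute)}


# ---------------------------------------------------------------------------
# TPDC recovery with bootstrap and time reversal
# ---------------------------------------------------------------------------


def tpdc_recovery(
    n_seeds: int = 20,
    n_samples: int = 30_000,
    n_boot: int = 200,
    seed: int | None = 0,
    coupling: float = 0.35,
) -> dict[str, float]:
    """Directed recovery of a planted theta-band 1 -> 2 coupling.

    A 3-channel MVAR of theta-resonant oscillators with a single lag-1
    coupling from channel 1 to channel 2 is simulated at 125 Hz; the planted
    connection should exceed the window-shuffle bootstrap threshold, the
    reverse connection should stay below it, and the net direction should
    flip under time reversal.
    """
    fs = 125.0
    model = simulate.oscillatory_mvar_model(
        fs, n_channels=3, peak_hz=5.5, pole_radius=0.8, couplings=[(1, 0, coupling)]
    )
    params = dict(
        window_s=2.0, step_s=1.0, order=3,
        freqs=np.array([4.0, 5.0, 6.0, 7.0]), bands={"theta": (4.0, 7.0)},
    )
    seeds = _child_seeds(seed, 2 * n_seeds)
    planted_above = reverse_below = flips = 0
    for k in range(n_seeds):
        sig = simulate.gen_mvar_signals(model, n_samples, seed=seeds[2 * k])
        fwd = effconn.tpdc(sig, **params)
        null = effconn.bootstrap_threshold(
            sig, n_boot=n_boot, shuffle_window_s=1.0, seed=seeds[2 * k + 1], **params
        )
        rev = effconn.tpdc(sig.reversed(), **params)
        thr = null.threshold_global["theta"]
        f = fwd.band_avg["theta"]
        r = rev.band_avg["theta"]
        planted_above += f[1, 0] > thr
        reverse_below += f[0, 1] < thr
        flips += (f[1, 0] - f[0, 1]) * (r[1, 0] - r[0, 1]) < 0
    return {
        "planted_above_threshold_rate": planted_above / n_seeds,
        "reverse_below_threshold_rate": reverse_below / n_seeds,
        "time_reversal_flip_rate": flips / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Morphometry calibration and power
# ---------------------------------------------------------------------------


def _chain_adjacency(n_regions: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"region_a": np.arange(n_regions - 1), "region_b": np.arange(1, n_regions)}
    )


def morphometry_fwe_rate(
    n_reps: int = 200,
    n_perm: int = 500,
    n_subjects: int = 92,
    n_regions: int = 68,
    seed: int | None = 0,
) -> dict[str, float]:
    """Family-wise error of the cluster permutation under a fully null cohort."""
    adjacency = _chain_adjacency(n_regions)
    seeds = _child_seeds(seed, 2 * n_reps)
    false_pos = 0
    for k in range(n_reps):
        ds = simulate.gen_thickness_cohort(
            n_subjects, n_regions, planted_region=0, r_pop=0.0, seed=seeds[2 * k]
        )
        atrophy = morphometry.compute_atrophy(ds)
        stats = morphometry.adjusted_correlation(atrophy, ds)
        corrected = morphometry.permutation_correct(
            stats, atrophy, ds, adjacency=adjacency, n_perm=n_perm, seed=seeds[2 * k + 1]
        )
        sig = corrected[(corrected["cluster_id"] >= 0) & (corrected["p_corrected"] < 0.05)]
        false_pos += len(sig) > 0
    return {"fwe_rate": false_pos / n_reps, "n_reps": n_reps}


def atrophy_detection_rate(
    n_reps: int = 50,
    r_pop: float = 0.3,
    n_subjects: int = 92,
    n_regions: int = 68,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> dict[str, float]:
    """How often the planted symptom-coupled region enters the seed mask."""
    planted = 10
    adjacency = _chain_adjacency(n_regions)
    seeds = _child_seeds(seed, 2 * n_reps)
    detected = uncorrected = 0
    for k in range(n_reps):
        ds = simulate.gen_thickness_cohort(
            n_subjects, n_regions, planted_region=planted, r_pop=r_pop, seed=seeds[2 * k]
        )
        atrophy = morphometry.compute_atrophy(ds)
        stats = morphometry.adjusted_correlation(atrophy, ds)
        corrected = morphometry.permutation_correct(
            stats, atrophy, ds, adjacency=adjacency, n_perm=n_perm, seed=seeds[2 * k + 1]
        )
        mask = morphometry.binarize_significant(corrected, alpha=0.05)
        detected += planted in mask.region_ids
        uncorrected += float(
            stats.loc[stats["region"] == planted, "p_uncorrected"].iloc[0]
        ) < 0.05
    return {
        "detection_rate": detected / n_reps,
        "uncorrected_detection_rate": uncorrected / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Atrophy network mapping recovery
# ---------------------------------------------------------------------------


def netmap_recovery_dice(
    n_subjects: int = 50,
    grid: int = 15,
    rho_within: float = 0.4,
    n_frames: int = 124,
    seed: int | None = 0,
) -> dict[str, float]:
    """Dice overlap between the FWE network map and the planted module.

    One cubic module is planted in a ``grid**3`` volume; the seed is a small
    block inside it. The Dice coefficient is computed between the
    suprathreshold binary map and the module, both excluding seed voxels.
    """
    shape = (grid, grid, grid)
    lo, hi = grid // 4, grid // 4 + max(grid // 2, 2)
    module = simulate.block_module_labels(shape, {1: (slice(lo, hi),) * 3})
    seed_mask = np.zeros(shape, dtype=bool)
    seed_mask[lo : lo + 2, lo : lo + 2, lo : lo + 2] = True
    seeds = _child_seeds(seed, n_subjects)
    zmaps = []
    for k in range(n_subjects):
        datasets, _ = simulate.gen_normative_bold(
            1, shape, module, rho_within, n_frames=n_frames, seed=seeds[k]
        )
        zmaps.append(netmap.seed_connectivity(datasets[0], seed_mask))
    gmap = netmap.group_tmap(zmaps, alpha_fwe=0.05)
    target = (module == 1) & ~seed_mask
    recovered = gmap.binary & ~seed_mask
    inter = (recovered & target).sum()
    dice = 2 * inter / max(recovered.sum() + target.sum(), 1)
    return {
        "dice": float(dice),
        "n_recovered_voxels": int(recovered.sum()),
        "n_module_voxels": int(target.sum()),
        "t_cutoff": gmap.t_cutoff,
    }


def fisher_transform_checks() -> dict[str, float]:
    """Exactness of the Fisher transform at the worked values."""
    return {
        "z_half": float(netmap.fisher_z(0.5)),
        "z_half_error": abs(float(netmap.fisher_z(0.5)) - 0.5 * np.log(3.0)),
        "z_zero": float(netmap.fisher_z(0.0)),
    }


# ---------------------------------------------------------------------------
# SEM recovery and calibration
# ---------------------------------------------------------------------------


def sem_benchmark(n_reps: int = 50, n: int = 5000, seed: int | None = 0) -> dict[str, float]:
    """Path-coefficient recovery and RMSEA calibration at n = 5000.

    Generates data from ``HADS ~ 0.6 PFC + 0.4 AMG + 0.2 HIP`` with unit-
    variance independent predictors (standardized = raw coefficients). The
    saturated model (free exogenous covariances, df = 0) checks recovery and
    chi^2 ~ 0; the correctly specified restricted model (covariances fixed
    to zero, df = 3) checks RMSEA < 0.05 calibration.
    """
    saturated = sem.PathModel.from_text("HADS ~ PFC + AMG + HIP")
    restricted = sem.PathModel.from_text(
        "HADS ~ PFC + AMG + HIP\nPFC ~~ 0*AMG\nPFC ~~ 0*HIP\nAMG ~~ 0*HIP"
    )
    true_paths = np.array([0.6, 0.4, 0.2])
    resid = 1.0 - float(true_paths @ true_paths)
    theta_true = np.concatenate([true_paths, [1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [resid]])
    seeds = _child_seeds(seed, n_reps)
    max_err = 0.0
    sat_chi2 = []
    sat_rmsea = []
    rmsea_ok = 0
    import warnings as _warnings

    for k in range(n_reps):
        _, data = simulate.gen_sem_cohort(saturated, theta_true, n, seed=seeds[k])
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit_sat = sem.fit_ml(saturated, data)
            fit_res = sem.fit_ml(restricted, data.aligned(restricted))
        est = np.array([fit_sat.theta[f"HADS~{v}"] for v in ("PFC", "AMG", "HIP")])
        max_err = max(max_err, float(np.abs(est - true_paths).max()))
        sat_chi2.append(fit_sat.chi2)
        sat_rmsea.append(fit_sat.rmsea)
        rmsea_ok += fit_res.rmsea < 0.05
    return {
        "max_path_error": max_err,
        "saturated_chi2_max": float(np.max(sat_chi2)),
        "saturated_rmsea_max": float(np.max(sat_rmsea)),
        "restricted_rmsea_below_05_rate": rmsea_ok / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# EEG cluster statistics
# ---------------------------------------------------------------------------


def _eeg_groups(rng, n_per_group=15, n_ch=32, n_t=100, effect=0.0):
    a = rng.standard_normal((n_per_group, n_ch, n_t))
    b = rng.standard_normal((n_per_group, n_ch, n_t))
    if effect:
        b[:, 5:11, 30:60] += effect
    return a, b


def cluster_test_calibration(
    n_datasets: int = 500,
    n_perm: int = 500,
    seed: int | None = 0,
) -> dict[str, float]:
    """Empirical FWE of the cluster permutation test on null group maps."""
    adjacency = np.column_stack([np.arange(31), np.arange(1, 32)])
    seeds = _child_seeds(seed, 2 * n_datasets)
    false_pos = 0
    for k in range(n_datasets):
        rng = np.random.default_rng(seeds[2 * k])
        a, b = _eeg_groups(rng)
        res = eegtask.cluster_permutation_test(
            a, b, adjacency, n_perm=n_perm, seed=seeds[2 * k + 1]
        )
        false_pos += bool(res.clusters["significant"].any())
    return {"fwe_rate": false_pos / n_datasets, "n_datasets": n_datasets}


def cluster_test_power(
    n_datasets: int = 20,
    n_perm: int = 500,
    effect: float = 1.0,
    seed: int | None = 0,
) -> dict[str, float]:
    """Detection of a planted channel x time mean shift (pilot-calibrated SNR).

    The effect is a +1 SD mean shift on 6 channels x 30 time points; a hit
    requires a significant cluster overlapping the planted block.
    """
    adjacency = np.column_stack([np.arange(31), np.arange(1, 32)])
    planted = np.zeros((32, 100), dtype=bool)
    planted[5:11, 30:60] = True
    seeds = _child_seeds(seed, 2 * n_datasets)
    hits = 0
    for k in range(n_datasets):
        rng = np.random.default_rng(seeds[2 * k])
        a, b = _eeg_groups(rng, effect=effect)
        res = eegtask.cluster_permutation_test(
            a, b, adjacency, n_perm=n_perm, seed=seeds[2 * k + 1]
        )
        sig_ids = res.clusters.loc[res.clusters["significant"], "cluster_id"].to_numpy()
        hit = any(np.any((res.labels == cid) & planted) for cid in sig_ids)
        hits += hit
    return {"detection_rate": hits / n_datasets, "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# DICS localization
# ---------------------------------------------------------------------------


def dics_localization_rate(n_seeds: int = 20, seed: int | None = 0) -> dict[str, float]:
    """Argmax DICS power vs the true oscillatory source among 3 candidates."""
    fs = 250.0
    n_samples = int(10 * fs)
    t = np.arange(n_samples) / fs
    seeds = _child_seeds(seed, n_seeds)
    correct = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seeds[k])
        lf = simulate.gen_leadfield(64, 3, seed=seeds[k])
        true_src = k % 3
        src = 2.0 * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        sensors = np.outer(lf.gain[:, true_src], src) + rng.standard_normal((64, n_samples))
        sig = effconn.MultichannelSignal(sensors, fs)
        csd = effconn.cross_spectral_density(sig, band=(8.0, 12.0))
        power, _ = effconn.dics_power(csd, lf, reg_lambda=0.05)
        correct += int(np.argmax(power)) == true_src
    return {"localization_rate": correct / n_seeds, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# Deterministic EEG plumbing
# ---------------------------------------------------------------------------


def eeg_plumbing_checks(seed: int | None = 0) -> dict[str, float]:
    """Epoch length, TMS excision span and re-reference residual at 250 Hz."""
    cont, _ = simulate.gen_task_eeg(
        n_trials=6, n_channels=8, fs_hz=250.0, seed=seed, trial_spacing_s=(8.0, 9.0)
    )
    ep = eegtask.epoch(cont, tmin=-2.0, tmax=5.0)
    n_before = ep.data.shape[2]
    excised = eegtask.excise_tms(ep, pre_s=0.005, post_s=0.02, mode="remove")
    n_excised = n_before - excised.data.shape[2]
    reref = eegtask.rereference_average(excised)
    residual = float(np.abs(reref.data.mean(axis=1)).max())
    return {
        "epoch_samples": float(n_before),
        "excised_samples": float(n_excised),
        "excised_seconds": n_excised / 250.0,
        "reref_max_abs_channel_mean": residual,
    }
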