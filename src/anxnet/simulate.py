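"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed, and
plants an effect that the matching estimator is expected to recover:

* :func:`gen_thickness_cohort` — a two-timepoint cortical-thickness cohort in
  which annualized thinning in one planted region correlates with an anxiety
  score (HADS-A-like, 0-21) at a chosen population ``r_pop``.
* :func:`gen_normative_bold` — many-subject 4D BOLD with modular correlation
  structure standing in for a large normative resting-state dataset; module
  membership is the ground truth for network-recovery tests.
* :func:`gen_mvar_signals` — forward simulation of a stable MVAR model with
  known directed couplings.
* :func:`gen_sem_cohort` — draws from the multivariate normal implied by a
  linear path model.
* :func:`gen_task_eeg` — a continuous instructed-threat EEG record: cue
  events in two conditions, a TMS-like transient one second after each cue,
  probabilistic shock flags on threat trials, and per-condition band-power
  effects on chosen channels and windows.
* :func:`gen_leadfield` — a full-rank unit-column-norm gain matrix standing
  in for a forward model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .effconn import LeadField, MultichannelSignal, MVARModel
from .exceptions import PreconditionError
from .netmap import BoldDataset
from .sem import PathModel, SEMData, implied_covariance

__all__ = [
    "SimulationSpec",
    "gen_thickness_cohort",
    "gen_normative_bold",
    "block_module_labels",
    "gen_mvar_signals",
    "oscillatory_mvar_model",
    "gen_sem_cohort",
    "gen_task_eeg",
    "ConditionEffect",
    "gen_leadfield",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Bundle of generator settings used by the end-to-end pipeline.

    Defaults follow the study conditions being emulated: a 92-subject
    thickness cohort over 68 cortical regions scanned ~2 years apart, a
    many-subject normative BOLD sample at TR = 3 s with 124 frames, 250-Hz
    task EEG with 90 trials, and theta/gamma analysis bands.
    """

    seed: int = 0
    n_subjects: int = 92
    n_regions: int = 68
    grid_shape: tuple[int, int, int] = (15, 15, 15)
    n_bold_subjects: int = 20
    tr_seconds: float = 3.0
    n_frames: int = 124
    fs_hz: float = 250.0
    r_pop: float = 0.3
    rho_within: float = 0.4
    n_trials: int = 90
    shock_trial_fraction: float = 0.33


# ---------------------------------------------------------------------------
# Thickness cohort
# ---------------------------------------------------------------------------


def gen_thickness_cohort(
    n_subjects: int = 92,
    n_regions: int = 68,
    planted_region: int = 0,
    r_pop: float = 0.3,
    dt_range_years: tuple[float, float] = (1.0, 3.8),
    seed: int | None = None,
    rate_mean: float = -0.01,
    rate_sd: float = 0.02,
    symptom_mean: float = 5.5,
    symptom_sd: float = 4.1,
) -> pd.DataFrame:
    """Two-timepoint thickness cohort with one symptom-coupled region.

    Annualized thickness change in ``planted_region`` correlates with the
    pre-rounding symptom score at population ``r_pop``; all other regions are
    independent of the score. Scores are rounded and clipped to the 0-21
    integer range (HADS-A), which attenuates the realized correlation by a
    few percent. Returns a tidy table with one row per subject x region and
    columns ``subject, region, ct_baseline, ct_followup, delta_years, age,
    sex, symptom``.
    """
    if n_subjects < 4:
        raise PreconditionError("need at least 4 subjects")
    if n_regions <= 0:
        raise PreconditionError("n_regions must be positive")
    if not -1 < r_pop < 1:
        raise PreconditionError("r_pop must lie in (-1, 1)")
    if not 0 <= planted_region < n_regions:
        raise PreconditionError("planted_region out of range")
    lo, hi = dt_range_years
    if lo <= 0 or hi < lo:
        raise PreconditionError("dt_range_years must be positive and ordered")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_subjects)
    symptom = np.clip(np.rint(symptom_mean + symptom_sd * latent), 0, 21).astype(int)
    age = np.clip(rng.normal(34.4, 9.5, n_subjects), 18, 65)
    sex = rng.binomial(1, 1 / 3, n_subjects)  # 1 = male, ~1/3 of the cohort
    dt = rng.uniform(lo, hi, n_subjects)
    z = rng.standard_normal((n_subjects, n_regions))
    z[:, planted_region] = r_pop * latent + np.sqrt(1 - r_pop**2) * z[:, planted_region]
    rates = rate_mean + rate_sd * z
    ct_baseline = np.clip(rng.normal(2.5, 0.3, (n_subjects, n_regions)), 0.8, None)
    ct_followup = ct_baseline + rates * dt[:, None]
    rows = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subjects), n_regions),
            "region": np.tile(np.arange(n_regions), n_subjects),
            "ct_baseline": ct_baseline.ravel(),
            "ct_followup": ct_followup.ravel(),
            "delta_years": np.repeat(dt, n_regions),
            "age": np.repeat(age, n_regions),
            "sex": np.repeat(sex, n_regions),
            "symptom": np.repeat(symptom, n_regions),
        }
    )
    return rows


# ---------------------------------------------------------------------------
# Normative BOLD
# ---------------------------------------------------------------------------


def block_module_labels(
    grid_shape: tuple[int, int, int],
    blocks: Mapping[int, tuple[slice, slice, slice]],
) -> np.ndarray:
    """Integer module map: 0 = background, each block id > 0 a module."""
    labels = np.zeros(grid_shape, dtype=int)
    for module_id, sl in blocks.items():
        if module_id <= 0:
            raise PreconditionError("module ids must be positive")
        labels[sl] = module_id
    return labels


def gen_normative_bold(
    n_subjects: int,
    grid_shape: tuple[int, int, int],
    module_labels: np.ndarray,
    rho_within: float,
    tr_seconds: float = 3.0,
    n_frames: int = 124,
    seed: int | None = None,
    ar_coeff: float = 0.0,
) -> tuple[list[BoldDataset], np.ndarray]:
    """Many-subject 4D BOLD with a planted modular correlation structure.

    Voxels sharing a module label load on a common latent signal with weight
    ``sqrt(rho_within)``, giving pairwise within-module correlation
    ``rho_within``; background voxels (label 0) and voxels of different
    modules are independent. Optional AR(1) temporal smoothness is applied
    and re-standardized so the correlation target is unchanged.
    """
    module_labels = np.asarray(module_labels)
    if module_labels.shape != tuple(grid_shape):
        raise PreconditionError("module_labels shape must equal grid_shape")
    if not 0 <= rho_within < 1:
        raise PreconditionError("rho_within must lie in [0, 1)")
    if n_frames < 3:
        raise PreconditionError("need at least 3 frames")
    if np.prod(grid_shape) < 2:
        raise PreconditionError("degenerate single-voxel grid")
    rng = np.random.default_rng(seed)
    flat = module_labels.ravel()
    modules = [m for m in np.unique(flat) if m > 0]
    w = np.sqrt(rho_within)
    datasets = []
    for s in range(n_subjects):
        noise = rng.standard_normal((flat.size, n_frames))
        data = np.sqrt(1 - rho_within) * noise if rho_within > 0 else noise
        if rho_within > 0:
            for m in modules:
                g = rng.standard_normal(n_frames)
                data[flat == m] += w * g
        if ar_coeff:
            data = spsig.lfilter([1.0], [1.0, -ar_coeff], data, axis=1)
            data *= np.sqrt(1 - ar_coeff**2)
        vol = data.reshape(*grid_shape, n_frames)
        datasets.append(
            BoldDataset(
                data=vol,
                tr_seconds=tr_seconds,
                mask=np.ones(grid_shape, dtype=bool),
                subject_id=f"sub-{s:04d}",
            )
        )
    return datasets, module_labels


# ---------------------------------------------------------------------------
# MVAR signals
# ---------------------------------------------------------------------------


def oscillatory_mvar_model(
    fs_hz: float,
    n_channels: int = 3,
    peak_hz: float = 5.5,
    pole_radius: float = 0.8,
    couplings: Sequence[tuple[int, int, float]] = (),
    noise_sd: float = 1.0,
) -> MVARModel:
    """MVAR(2) model of damped oscillators with lag-1 directed couplings.

    Each channel is an AR(2) resonator peaking at ``peak_hz``; each coupling
    ``(target, source, weight)`` adds ``weight * x_source[t-1]`` to the
    target. The returned model is checked for stability.
    """
    omega = 2 * np.pi * peak_hz / fs_hz
    a1 = 2 * pole_radius * np.cos(omega)
    a2 = -(pole_radius**2)
    A = np.zeros((2, n_channels, n_channels))
    A[0] += a1 * np.eye(n_channels)
    A[1] += a2 * np.eye(n_channels)
    for tgt, src, wgt in couplings:
        A[0, tgt, src] += wgt
    model = MVARModel(A, noise_sd**2 * np.eye(n_channels), fs_hz)
    if not model.is_stable:
        raise PreconditionError(
            f"requested model is unstable (spectral radius {model.spectral_radius():.3f})"
        )
    return model


def gen_mvar_signals(
    model: MVARModel,
    n_samples: int,
    seed: int | None = None,
    burn_in: int = 500,
) -> MultichannelSignal:
    """Forward-simulate a stable MVAR model, discarding a burn-in segment."""
    if n_samples <= 10 * model.order:
        raise PreconditionError("n_samples must exceed 10x the model order")
    rho = model.spectral_radius()
    if rho >= 1:
        raise PreconditionError(f"unstable MVAR model (spectral radius {rho:.3f})")
    rng = np.random.default_rng(seed)
    c, p = model.n_channels, model.order
    chol = np.linalg.cholesky(model.resid_cov + 1e-15 * np.eye(c))
    total = n_samples + burn_in
    noise = rng.standard_normal((total, c)) @ chol.T
    x = np.zeros((total, c))
    A = model.coeffs
    for t in range(p, total):
        acc = noise[t].copy()
        for k in range(p):
            acc += A[k] @ x[t - 1 - k]
        x[t] = acc
    return MultichannelSignal(x[burn_in:].T.copy(), model.fs_hz)


# ---------------------------------------------------------------------------
# SEM cohort
# ---------------------------------------------------------------------------


def gen_sem_cohort(
    path_model: PathModel,
    true_theta: np.ndarray | Sequence[float],
    n: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SEMData]:
    """Draw ``n`` observations from the covariance implied by a path model."""
    if n < len(path_model.variables) + 2:
        raise PreconditionError("n too small for a usable sample covariance")
    path_model.topological_order()  # rejects cyclic models
    sigma = implied_covariance(path_model, np.asarray(true_theta, dtype=float))
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise PreconditionError("implied covariance is not positive definite")
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        rng.multivariate_normal(np.zeros(len(path_model.variables)), sigma, size=n,
                                method="cholesky"),
        columns=list(path_model.variables),
    )
    return table, SEMData.from_table(table, path_model.variables)


# ---------------------------------------------------------------------------
# Task EEG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionEffect:
    """Band-power multiplier applied on chosen channels in a cue-locked window."""

    condition: str
    band: tuple[float, float]
    channels: tuple[int, ...]
    window_s: tuple[float, float]  # relative to cue onset
    multiplier: float = 1.0


def _band_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                band: tuple[float, float], fs: float) -> np.ndarray:
    sos = spsig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = spsig.sosfiltfilt(sos, rng.standard_normal((n_channels, n_samples)), axis=1)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_task_eeg(
    n_trials: int = 90,
    n_channels: int = 32,
    fs_hz: float = 250.0,
    condition_effects: Sequence[ConditionEffect] = (),
    tms_offset_s: float = 1.0,
    shock_trial_fraction: float = 0.33,
    seed: int | None = None,
    trial_spacing_s: tuple[float, float] = (10.0, 11.0),
    tms_amplitude: float = 80.0,
    pre_record_s: float = 3.0,
):
    """Continuous instructed-threat EEG with events, TMS transients and effects.

    Returns ``(ContinuousEEG, events)`` from :mod:`anxnet.eegtask`. Trials
    alternate threat/safe in a seeded random order; threat trials carry a
    shock flag with probability ``shock_trial_fraction``; a decaying-
    exponential TMS-like burst is injected ``tms_offset_s`` after every cue.
    Condition effects multiply the amplitude of a band-limited signal
    component on the given channels inside the given cue-locked window.
    """
    from .eegtask import ContinuousEEG

    for eff in condition_effects:
        if fs_hz <= 2 * eff.band[1]:
            raise PreconditionError(
                f"fs={fs_hz} too low for band {eff.band} (need > 2x high edge)"
            )
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(*trial_spacing_s, n_trials)
    cues = (pre_record_s + np.concatenate([[0.0], np.cumsum(gaps[:-1])])) * fs_hz
    cues = cues.astype(int)
    n_samples = int(cues[-1] + (trial_spacing_s[1] + pre_record_s) * fs_hz)
    conditions = np.array(["threat", "safe"])[rng.integers(0, 2, n_trials)]
    shock = (conditions == "threat") & (rng.random(n_trials) < shock_trial_fraction)
    tms_samples = cues + int(round(tms_offset_s * fs_hz))

    data = rng.standard_normal((n_channels, n_samples))
    theta = _band_noise(rng, n_channels, n_samples, (4.0, 7.0), fs_hz)
    bands = {(4.0, 7.0): theta}
    if fs_hz > 140:
        bands[(30.0, 70.0)] = _band_noise(rng, n_channels, n_samples, (30.0, 70.0), fs_hz)
    for band, comp in bands.items():
        data += comp
    for eff in condition_effects:
        comp = bands.get(eff.band)
        if comp is None:
            comp = _band_noise(rng, n_channels, n_samples, eff.band, fs_hz)
            bands[eff.band] = comp
            data += comp
        extra = eff.multiplier - 1.0
        if extra == 0.0:
            continue
        for tr in np.flatnonzero(conditions == eff.condition):
            s0 = cues[tr] + int(round(eff.window_s[0] * fs_hz))
            s1 = cues[tr] + int(round(eff.window_s[1] * fs_hz))
            s0, s1 = max(s0, 0), min(s1, n_samples)
            for ch in eff.channels:
                data[ch, s0:s1] += extra * comp[ch, s0:s1]
    # TMS-like transient: sharp decaying-exponential burst (shape irrelevant
    # downstream; the pipeline excises it)
    burst_len = int(round(0.015 * fs_hz)) + 1
    t = np.arange(burst_len) / fs_hz
    burst = tms_amplitude * np.exp(-t / 0.004) * np.cos(2 * np.pi * 300 * t)
    for ts in tms_samples:
        seg = slice(ts, min(ts + burst_len, n_samples))
        data[:, seg] += burst[: seg.stop - seg.start]
    events = pd.DataFrame(
        {
            "sample": cues,
            "condition": conditions,
            "shock": shock,
            "tms_sample": tms_samples,
        }
    )
    return ContinuousEEG(data=data, fs_hz=fs_hz, events=events), events


# ---------------------------------------------------------------------------
# Lead fields
# ---------------------------------------------------------------------------


def gen_leadfield(n_channels: int, n_sources: int, seed: int | None = None) -> LeadField:
    """Random full-rank gain matrix with unit-norm columns."""
    if n_channels <= n_sources:
        raise PreconditionError("need more channels than sources")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        g = rng.standard_normal((n_channels, n_sources))
        g /= np.linalg.norm(g, axis=0, keepdims=True)
        if np.linalg.matrix_rank(g) == n_sources:
            return LeadField(g)
    raise PreconditionError("failed to generate a full-rank lead field")
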