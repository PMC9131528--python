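"""End-to-end ``simulate -> analyze`` orchestration.

A single validated configuration drives the full synthetic workflow: a
thickness cohort is analyzed for symptom-correlated atrophy; the surviving
regions become a volumetric seed for network mapping on synthetic normative
BOLD; an MVAR simulation is pushed through the TPDC / bootstrap /
time-reversal chain; a task-EEG record is epoched, cleaned and tested with
cluster permutations; and a path model is fitted to a simulated volume
cohort. One global seed fans out deterministically to per-stage seeds, and a
manifest records configuration, seeds and SHA-256 hashes of every output so
a run can be reproduced exactly.

The synthetic atlas ties stages together: the voxel grid is partitioned
into cubic parcels, thickness "regions" are parcels, and the BOLD module is
planted at the parcel corresponding to the planted thickness region, so a
correct morphometry stage seeds the network-mapping stage at the right
location.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import eegtask, effconn, io, morphometry, netmap, sem, simulate
from ._seeds import child_seeds
from .exceptions import PreconditionError

__all__ = [
    "PipelineConfig",
    "MorphometryConfig",
    "NetmapConfig",
    "EffconnConfig",
    "EEGConfig",
    "SEMConfig",
    "run_pipeline",
    "parcel_atlas",
]

logger = logging.getLogger(__name__)


class MorphometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = 40
    r_pop: float = 0.6
    n_perm: int = 1000
    cluster_forming_p: float = 0.05
    alpha: float = 0.05


class NetmapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int = 20
    grid: int = 15
    n_frames: int = 124
    tr_seconds: float = 3.0
    rho_within: float = 0.4
    fwhm_mm: float = 6.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    alpha_fwe: float = 0.05
    preprocess: bool = False


class EffconnConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fs_hz: float = 125.0
    n_samples: int = 20000
    coupling: float = 0.35
    order: int = 3
    window_s: float = 2.0
    step_s: float = 0.5
    n_boot: int = 1000
    shuffle_window_s: float = 1.0
    theta: tuple[float, float] = (4.0, 7.0)
    gamma: tuple[float, float] = (30.0, 70.0)


class EEGConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trials: int = 90
    n_channels: int = 32
    fs_hz: float = 250.0
    tmin: float = -2.0
    tmax: float = 5.0
    tms_pre_s: float = 0.005
    tms_post_s: float = 0.02
    shock_trial_fraction: float = 0.33
    n_perm: int = 1000


class SEMConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 2000
    model_text: str = "HADS ~ PFC + AMG + HIP"
    paths: tuple[float, float, float] = (0.6, 0.4, 0.2)


class PipelineConfig(BaseModel):
    """Validated, schema-checked configuration for the full workflow."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "anxnet_out"
    stages: tuple[str, ...] = ("morphometry", "netmap", "effconn", "eegtask", "sem")
    morphometry: MorphometryConfig = Field(default_factory=MorphometryConfig)
    netmap: NetmapConfig = Field(default_factory=NetmapConfig)
    effconn: EffconnConfig = Field(default_factory=EffconnConfig)
    eegtask: EEGConfig = Field(default_factory=EEGConfig)
    sem: SEMConfig = Field(default_factory=SEMConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def parcel_atlas(grid: int, parcels_per_axis: int = 3) -> np.ndarray:
    """Partition a cubic grid into cubic parcels labelled 1..k**3."""
    edges = np.linspace(0, grid, parcels_per_axis + 1).astype(int)
    atlas = np.zeros((grid, grid, grid), dtype=int)
    label = 1
    for i in range(parcels_per_axis):
        for j in range(parcels_per_axis):
            for k in range(parcels_per_axis):
                atlas[edges[i]:edges[i + 1], edges[j]:edges[j + 1], edges[k]:edges[k + 1]] = label
                label += 1
    return atlas


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ("morphometry", "morph_perm", "netmap", "effconn", "effconn_boot", "eegtask", "sem"),
        child_seeds(config.seed, 7),
    ))
    manifest: dict = {"config": config.model_dump(), "seeds": seeds, "stages": {}, "outputs": {}}
    atlas = parcel_atlas(config.netmap.grid)
    n_regions = int(atlas.max())
    planted_label = (atlas.max() + 1) // 2  # central parcel
    planted_region = int(planted_label - 1)

    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written.append(path)

    seed_mask_regions: tuple[int, ...] = ()

    if "morphometry" in config.stages:
        mc = config.morphometry
        ds = simulate.gen_thickness_cohort(
            mc.n_subjects, n_regions, planted_region=planted_region,
            r_pop=mc.r_pop, seed=seeds["morphometry"],
        )
        atrophy = morphometry.compute_atrophy(ds)
        stats = morphometry.adjusted_correlation(atrophy, ds)
        adjacency = _parcel_adjacency(atlas)
        corrected = morphometry.permutation_correct(
            stats, atrophy, ds, adjacency=adjacency,
            cluster_forming_p=mc.cluster_forming_p, n_perm=mc.n_perm,
            seed=seeds["morph_perm"],
        )
        seed_obj = morphometry.binarize_significant(corrected, alpha=mc.alpha)
        seed_mask_regions = seed_obj.region_ids
        emit("thickness.tsv", lambda p: io.write_table(ds, p))
        emit("region_stats.tsv", lambda p: io.write_table(corrected, p))
        emit("seed_regions.json", lambda p: p.write_text(json.dumps(
            {"region_ids": list(seed_obj.region_ids), "alpha": seed_obj.alpha,
             "method": seed_obj.method}, sort_keys=True)))
        manifest["stages"]["morphometry"] = {
            "n_significant_regions": len(seed_obj.region_ids),
            "planted_region": planted_region,
            "planted_detected": planted_region in seed_obj.region_ids,
        }

    if "netmap" in config.stages:
        nc = config.netmap
        if not seed_mask_regions:
            manifest["stages"]["netmap"] = {"skipped": "empty seed mask from morphometry"}
        else:
            seed_vol = morphometry.seed_mask_to_volume(
                morphometry.SeedMask(tuple(r + 1 for r in seed_mask_regions), 0.05, "atlas"),
                atlas,
            )
            module = simulate.block_module_labels(
                atlas.shape, {1: tuple(slice(a, b + 1) for a, b in _bbox(atlas == planted_label))}
            )
            shape = (nc.grid,) * 3
            zmaps = []
            for s, s_seed in enumerate(child_seeds(seeds["netmap"], nc.n_subjects)):
                datasets, _ = simulate.gen_normative_bold(
                    1, shape, module, nc.rho_within, tr_seconds=nc.tr_seconds,
                    n_frames=nc.n_frames, seed=s_seed,
                )
                bold = datasets[0]
                if nc.preprocess:
                    bold = netmap.preprocess_bold(
                        bold, netmap.PreprocConfig(fwhm_mm=nc.fwhm_mm, band_hz=nc.band_hz)
                    )
                zmaps.append(netmap.seed_connectivity(bold, seed_vol))
            gmap = netmap.group_tmap(zmaps, alpha_fwe=nc.alpha_fwe)
            regions = netmap.extract_network_regions(gmap, atlas)
            emit("group_tmap.nii", lambda p: netmap.write_volume(p, gmap.t))
            emit("network_binary.nii", lambda p: netmap.write_volume(p, gmap.binary))
            emit("network_regions.tsv", lambda p: io.write_table(regions, p))
            manifest["stages"]["netmap"] = {
                "t_cutoff": gmap.t_cutoff,
                "n_suprathreshold_voxels": int(gmap.binary.sum()),
                "top_region": int(regions["region"].iloc[0]) if len(regions) else None,
            }

    if "effconn" in config.stages:
        ec = config.effconn
        model = simulate.oscillatory_mvar_model(
            ec.fs_hz, n_channels=3, couplings=[(1, 0, ec.coupling)]
        )
        sig = simulate.gen_mvar_signals(model, ec.n_samples, seed=seeds["effconn"])
        bands = {"theta": ec.theta}
        if ec.gamma[1] < ec.fs_hz / 2:
            bands["gamma"] = ec.gamma
        params = dict(window_s=ec.window_s, step_s=ec.step_s, order=ec.order, bands=bands)
        null = effconn.bootstrap_threshold(
            sig, n_boot=ec.n_boot, shuffle_window_s=ec.shuffle_window_s,
            seed=seeds["effconn_boot"], **params,
        )
        decisions = effconn.time_reversal_test(sig, null, **params)
        emit("effconn_decisions.tsv", lambda p: io.write_table(decisions, p))
        planted = decisions[(decisions["band"] == "theta")
                            & (decisions["target"] == "ch1") & (decisions["source"] == "ch0")]
        manifest["stages"]["effconn"] = {
            "n_boot": ec.n_boot,
            "planted_passes": bool(planted["passes"].iloc[0]),
            "n_passing_connections": int(decisions["passes"].sum()),
        }

    if "eegtask" in config.stages:
        gc = config.eegtask
        effects = [simulate.ConditionEffect(
            condition="threat", band=(4.0, 7.0),
            channels=tuple(range(6)), window_s=(1.0, 2.0), multiplier=2.0,
        )]
        cont, events = simulate.gen_task_eeg(
            n_trials=gc.n_trials, n_channels=gc.n_channels, fs_hz=gc.fs_hz,
            condition_effects=effects, shock_trial_fraction=gc.shock_trial_fraction,
            seed=seeds["eegtask"],
        )
        ep = eegtask.epoch(cont, tmin=gc.tmin, tmax=gc.tmax)
        ep = eegtask.excise_tms(ep, pre_s=gc.tms_pre_s, post_s=gc.tms_post_s)
        ep = eegtask.drop_shock_trials(ep)
        ep = eegtask.rereference_average(ep)
        pmap = eegtask.band_power(ep, band=(4.0, 7.0))
        emit("events.tsv", lambda p: io.write_table(events, p))
        emit("theta_power_threat.npy", lambda p: np.save(p, pmap.power.get("threat")))
        manifest["stages"]["eegtask"] = {
            "n_trials_kept": ep.n_trials,
            "n_trials_total": gc.n_trials,
            "log": ep.log,
        }

    if "sem" in config.stages:
        sc = config.sem
        model = sem.PathModel.from_text(sc.model_text)
        paths = np.asarray(sc.paths, dtype=float)
        resid = max(1.0 - float(paths @ paths), 0.05)
        theta = np.concatenate([
            paths, np.ones(len(model.exogenous)),
            np.zeros(len(model.free_exo_covs())), [resid],
        ])
        _, data = simulate.gen_sem_cohort(model, theta, sc.n, seed=seeds["sem"])
        fit = sem.fit_ml(model, data)
        emit("sem_fit.json", lambda p: p.write_text(json.dumps({
            "theta": fit.theta, "standardized": fit.standardized,
            "chi2": fit.chi2, "df": fit.df, "rmsea": fit.rmsea, "aic": fit.aic,
        }, sort_keys=True)))
        manifest["stages"]["sem"] = {
            "chi2": fit.chi2, "df": fit.df, "rmsea": fit.rmsea, "converged": fit.converged,
        }

    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2, default=str))
    return manifest


def _bbox(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.argwhere(mask)
    return [(int(idx[:, d].min()), int(idx[:, d].max())) for d in range(mask.ndim)]


def _parcel_adjacency(atlas: np.ndarray) -> pd.DataFrame:
    """Face-neighbour adjacency between parcel labels, as 0-based region ids."""
    pairs = set()
    for axis in range(3):
        a = np.moveaxis(atlas, axis, 0)
        diff = a[:-1] != a[1:]
        lo, hi = a[:-1][diff], a[1:][diff]
        for x, y in zip(lo.ravel(), hi.ravel()):
            pairs.add((int(min(x, y)) - 1, int(max(x, y)) - 1))
    arr = sorted(pairs)
    return pd.DataFrame(arr, columns=["region_a", "region_b"])
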