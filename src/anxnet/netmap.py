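"""Atrophy network mapping against a normative functional connectome.

A binarized seed (the symptom-correlated atrophy cluster) is projected into
a large normative resting-state BOLD sample: for each subject, the mean BOLD
time course within the seed is correlated with every other in-brain voxel,
the correlations are Fisher-transformed (z = atanh r), and a one-sample
group t map of z against zero is thresholded at a voxel-wise FWE-corrected
level (Bonferroni across in-brain voxels by default). The surviving binary
map is the functional network of the seed; an atlas summary ranks regions by
their suprathreshold fraction.

Minimal BOLD preprocessing is provided in the conventional order: spatial
Gaussian smoothing (FWHM -> sigma = FWHM / (2 sqrt(2 ln 2))), nuisance
regression (confounds + intercept) and zero-phase Butterworth bandpass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, signal as spsig, stats as sps

from .exceptions import PreconditionError

__all__ = [
    "BoldDataset",
    "PreprocConfig",
    "SubjectZMap",
    "GroupNetworkMap",
    "fisher_z",
    "preprocess_bold",
    "seed_timecourse",
    "seed_connectivity",
    "group_tmap",
    "extract_network_regions",
    "read_bold",
    "write_volume",
]

logger = logging.getLogger(__name__)

#: clamp applied to |r| before atanh, avoiding infinite z at r = +-1
R_CLAMP = 1.0 - 1e-7


@dataclass
class BoldDataset:
    """4D BOLD intensities (x, y, z, t) with TR and an in-brain mask."""

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray | None = None
    subject_id: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise PreconditionError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[-1] < 3:
            raise PreconditionError("need at least 3 frames")
        if self.tr_seconds <= 0:
            raise PreconditionError("TR must be positive")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise PreconditionError("mask shape must match the spatial grid")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise PreconditionError("non-finite values inside the brain mask")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


@dataclass(frozen=True)
class PreprocConfig:
    """Smoothing kernel, passband and confound settings.

    ``fwhm_mm`` of 0 disables smoothing; ``band_hz`` of None disables the
    bandpass. ``voxel_size_mm`` converts the kernel to voxel units.
    """

    fwhm_mm: float = 6.0
    band_hz: tuple[float, float] | None = (0.01, 0.08)
    voxel_size_mm: float = 3.0
    confounds: np.ndarray | None = None

    def validate(self, tr_seconds: float) -> None:
        if self.fwhm_mm < 0 or self.voxel_size_mm <= 0:
            raise PreconditionError("non-positive smoothing geometry")
        if self.band_hz is not None:
            lo, hi = self.band_hz
            nyq = 1.0 / (2.0 * tr_seconds)
            if not 0 <= lo < hi < nyq:
                raise PreconditionError(
                    f"passband ({lo}, {hi}) must satisfy 0 <= low < high < Nyquist={nyq:.4g}"
                )


@dataclass
class SubjectZMap:
    """Per-voxel Fisher z of the seed correlation, with a validity mask."""

    z: np.ndarray
    valid: np.ndarray
    subject_id: str = ""


@dataclass
class GroupNetworkMap:
    """Group t map of z against zero, its FWE cutoff and binary survivors."""

    t: np.ndarray
    df: int
    t_cutoff: float
    binary: np.ndarray
    alpha_fwe: float
    n_tests: int
    two_sided: bool = True


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher transform z = atanh(r), with |r| clamped at 1 - 1e-7."""
    r_arr = np.clip(np.asarray(r, dtype=float), -R_CLAMP, R_CLAMP)
    z = np.arctanh(r_arr)
    return float(z) if np.isscalar(r) else z


def preprocess_bold(bold: BoldDataset, config: PreprocConfig) -> BoldDataset:
    """Smooth, regress confounds (plus intercept) and bandpass a BOLD run."""
    config.validate(bold.tr_seconds)
    data = bold.data
    if config.fwhm_mm > 0:
        sigma_vox = config.fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / config.voxel_size_mm
        data = ndimage.gaussian_filter(data, sigma=(sigma_vox,) * 3 + (0,))
    flat = data.reshape(-1, bold.n_frames)
    conf = config.confounds
    if conf is not None:
        conf = np.asarray(conf, dtype=float)
        if conf.ndim == 1:
            conf = conf[:, None]
        if conf.shape[0] != bold.n_frames:
            raise PreconditionError("confound table must have one row per frame")
        X = np.column_stack([np.ones(bold.n_frames), conf])
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * np.abs(r).max()
        if not keep.all():
            logger.warning("dropping %d collinear confound columns", int((~keep).sum()))
            q = q[:, keep]
    else:
        X = np.ones((bold.n_frames, 1))
        q, _ = np.linalg.qr(X)
    flat = flat - (flat @ q) @ q.T
    if config.band_hz is not None:
        fs = 1.0 / bold.tr_seconds
        sos = spsig.butter(4, config.band_hz, btype="bandpass", fs=fs, output="sos")
        flat = spsig.sosfiltfilt(sos, flat, axis=1)
    return BoldDataset(
        data=flat.reshape(bold.data.shape),
        tr_seconds=bold.tr_seconds,
        mask=bold.mask,
        subject_id=bold.subject_id,
        affine=bold.affine,
    )


def seed_timecourse(bold: BoldDataset, seed_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean BOLD time course over seed voxels inside the brain."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != bold.data.shape[:3]:
        raise PreconditionError("seed mask shape must match the spatial grid")
    overlap = seed_mask & bold.mask
    if not overlap.any():
        raise PreconditionError("seed does not overlap the in-brain mask")
    return bold.data[overlap].mean(axis=0)


def seed_connectivity(bold: BoldDataset, seed_mask: np.ndarray) -> SubjectZMap:
    """Fisher-z map of the Pearson correlation with the seed time course."""
    tc = seed_timecourse(bold, seed_mask)
    tc_c = tc - tc.mean()
    tc_norm = np.linalg.norm(tc_c)
    if tc_norm == 0:
        raise PreconditionError("seed time course has zero variance")
    flat = bold.data.reshape(-1, bold.n_frames)
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat_c, axis=1)
    valid_flat = (norms > 0) & bold.mask.ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (flat_c @ tc_c) / (norms * tc_norm)
    z = np.full(flat.shape[0], np.nan)
    z[valid_flat] = fisher_z(r[valid_flat])
    shape = bold.data.shape[:3]
    return SubjectZMap(
        z=z.reshape(shape), valid=valid_flat.reshape(shape), subject_id=bold.subject_id
    )


def group_tmap(
    zmaps: list[SubjectZMap],
    alpha_fwe: float = 0.05,
    n_in_brain_voxels: int | None = None,
    two_sided: bool = True,
) -> GroupNetworkMap:
    """One-sample t of Fisher z against 0 per voxel, Bonferroni-FWE threshold.

    Voxel-wise listwise deletion of missing z; voxels with fewer than two
    valid subjects are excluded. A voxel where all subjects agree exactly
    (zero variance, non-zero mean) is assigned t = +-inf and survives.
    """
    if len(zmaps) < 2:
        raise PreconditionError("need at least 2 subjects")
    z = np.stack([m.z for m in zmaps])
    valid = np.stack([m.valid for m in zmaps])
    z = np.where(valid, z, np.nan)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(np.where(valid, z, np.nan), axis=0)
        sd = np.nanstd(np.where(valid, z, np.nan), axis=0, ddof=1)
        t = mean / (sd / np.sqrt(n_valid))
    degenerate = (sd == 0) & (n_valid >= 2)
    t[degenerate] = np.sign(mean[degenerate]) * np.inf
    t[n_valid < 2] = np.nan
    df = len(zmaps) - 1
    usable = n_valid >= 2
    n_tests = int(n_in_brain_voxels) if n_in_brain_voxels else int(usable.sum())
    p_vox = alpha_fwe / n_tests
    t_cutoff = float(sps.t.isf(p_vox / 2 if two_sided else p_vox, df))
    with np.errstate(invalid="ignore"):
        binary = (np.abs(t) if two_sided else t) > t_cutoff
    binary &= usable
    return GroupNetworkMap(
        t=t, df=df, t_cutoff=t_cutoff, binary=binary,
        alpha_fwe=alpha_fwe, n_tests=n_tests, two_sided=two_sided,
    )


def extract_network_regions(
    gmap: GroupNetworkMap,
    atlas: np.ndarray,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Rank atlas regions by their suprathreshold voxel fraction.

    Returns one row per atlas region overlapping the binary map, with the
    suprathreshold fraction and peak |t|, sorted by fraction then peak.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != gmap.t.shape:
        raise PreconditionError("atlas shape must match the statistical map")
    rows = []
    for region in np.unique(atlas):
        if region == 0:
            continue
        sel = atlas == region
        hits = gmap.binary & sel
        if not hits.any():
            continue
        with np.errstate(invalid="ignore"):
            peak = float(np.nanmax(np.abs(gmap.t[hits])))
        rows.append(
            {
                "region": int(region),
                "name": (label_names or {}).get(int(region), str(int(region))),
                "n_voxels": int(sel.sum()),
                "n_suprathreshold": int(hits.sum()),
                "fraction": float(hits.sum() / sel.sum()),
                "peak_abs_t": peak,
            }
        )
    out = pd.DataFrame(
        rows, columns=["region", "name", "n_voxels", "n_suprathreshold", "fraction", "peak_abs_t"]
    )
    return out.sort_values(["fraction", "peak_abs_t"], ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_bold(path, tr_seconds: float | None = None, mask: np.ndarray | None = None) -> BoldDataset:
    """Load a 4D NIfTI as a :class:`BoldDataset` (TR from the header zooms)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldDataset(data=data, tr_seconds=tr_seconds, mask=mask, affine=img.affine)


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a 3D/4D array as NIfTI (bools as uint8)."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine if affine is not None else np.eye(4)), str(path))
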