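"""Longitudinal atrophy and its covariate-adjusted correlation with symptoms.

Annualized atrophy per subject and region is

    atrophy_rate = (ct_followup - ct_baseline) / delta_years   [mm / year]

(negative values = thinning). The region-wise association with the symptom
score is the partial correlation of atrophy rate with the score given age
and sex: both variables are residualized on [1, age, sex] and the residuals
correlated; t = r sqrt((n - k - 2) / (1 - r^2)) with k = 2 covariates.

Family-wise error across regions is controlled with a max-statistic
permutation procedure: symptom scores are permuted across subjects, each
permutation re-runs the adjusted correlation, suprathreshold regions
(p < cluster_forming_p) are grouped into connected clusters under a supplied
region adjacency, and the observed cluster mass (sum of |t|) is referred to
the permutation null of the maximum cluster mass. Without adjacency every
region is its own cluster, i.e. max-|t| correction.

Sign convention: the generator and analysis treat the atrophy rate as signed
change per year, so "more thinning with higher symptom" appears as a
negative correlation on the rate. Detection is two-sided by default; no sign
convention is hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._clustering import cluster_labels, max_cluster_mass
from .exceptions import PreconditionError

__all__ = [
    "SeedMask",
    "compute_atrophy",
    "adjusted_correlation",
    "permutation_correct",
    "binarize_significant",
    "seed_mask_to_volume",
    "load_thickness_table",
    "adjacency_edges",
]

logger = logging.getLogger(__name__)

THICKNESS_COLUMNS = (
    "subject",
    "region",
    "ct_baseline",
    "ct_followup",
    "delta_years",
    "age",
    "sex",
    "symptom",
)


@dataclass(frozen=True)
class SeedMask:
    """Regions surviving the corrected threshold, for use as a seed."""

    region_ids: tuple[int, ...]
    alpha: float
    method: str

    @property
    def is_empty(self) -> bool:
        return len(self.region_ids) == 0


def load_thickness_table(path) -> pd.DataFrame:
    """Read a delimited thickness table (TSV/CSV inferred from extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(THICKNESS_COLUMNS) - set(df.columns)
    if missing:
        raise PreconditionError(f"thickness table lacks columns: {sorted(missing)}")
    return df


def compute_atrophy(ds: pd.DataFrame) -> pd.DataFrame:
    """Annualized thickness change per subject x region.

    Rows with a missing timepoint or non-positive inter-scan interval are
    rejected with a logged warning.
    """
    ds = ds.copy()
    bad = ds["ct_baseline"].isna() | ds["ct_followup"].isna() | ds["delta_years"].isna()
    nonpos = (~bad) & (ds["delta_years"] <= 0)
    if nonpos.any():
        raise PreconditionError("delta_years must be positive for all rows")
    if bad.any():
        logger.warning("dropping %d rows with missing timepoints", int(bad.sum()))
        ds = ds[~bad]
    out = ds[["subject", "region"]].copy()
    out["atrophy_rate"] = (ds["ct_followup"] - ds["ct_baseline"]) / ds["delta_years"]
    return out.reset_index(drop=True)


def _design(ds_subj: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(ds_subj))]
    for cv in covariates:
        v = ds_subj[cv].to_numpy(dtype=float)
        cols.append(v - v.mean())  # centering: numerical hygiene, r unchanged
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PreconditionError("covariates are collinear")
    return X


def _prepare(atrophy: pd.DataFrame, ds: pd.DataFrame, covariates: tuple[str, ...]):
    """Wide atrophy matrix, residualizer Q, and subject-level table."""
    wide = atrophy.pivot(index="subject", columns="region", values="atrophy_rate")
    subj_cols = ["symptom", *covariates]
    subj = ds.drop_duplicates("subject").set_index("subject")[subj_cols]
    merged = wide.join(subj, how="inner").dropna()
    if len(merged) < 4:
        raise PreconditionError("need >= 4 subjects after listwise deletion")
    if merged["symptom"].nunique() < 2:
        raise PreconditionError("zero-variance symptom score")
    regions = np.array(wide.columns)
    A = merged[regions].to_numpy(dtype=float)
    X = _design(merged, covariates)
    Q, _ = np.linalg.qr(X)
    return A, merged, Q, regions


def _partial_r(A: np.ndarray, s: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Partial correlations of each column of A with s given span(Q)."""
    Ra = A - Q @ (Q.T @ A)
    rs = s - Q @ (Q.T @ s)
    na = np.linalg.norm(Ra, axis=0)
    ns = np.linalg.norm(rs)
    if ns == 0:
        raise PreconditionError("zero-variance symptom after residualization")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ra.T @ rs) / (na * ns)
    r[na == 0] = np.nan  # zero-variance region: undefined, flagged
    return np.clip(r, -1.0, 1.0, out=r)


def _r_to_t(r: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return t


def adjusted_correlation(
    atrophy: pd.DataFrame,
    ds: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Per-region partial correlation of atrophy rate with the symptom score.

    Returns a table with ``region, n, r, t_stat, p_uncorrected``; regions
    with zero residual variance get ``r = NaN`` and ``p = 1``.
    """
    A, merged, Q, regions = _prepare(atrophy, ds, covariates)
    n, k = len(merged), len(covariates)
    df = n - k - 2
    if df < 1:
        raise PreconditionError("not enough subjects for the partial correlation")
    r = _partial_r(A, merged["symptom"].to_numpy(dtype=float), Q)
    t = _r_to_t(r, df)
    p = 2 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isnan(r), 1.0, p)
    return pd.DataFrame(
        {"region": regions, "n": n, "r": r, "t_stat": t, "p_uncorrected": p}
    )


def adjacency_edges(adjacency: pd.DataFrame | None, regions: np.ndarray) -> np.ndarray:
    """Region-pair adjacency table -> edge index array over ``regions``."""
    if adjacency is None or len(adjacency) == 0:
        return np.empty((0, 2), dtype=np.int64)
    pos = {reg: i for i, reg in enumerate(regions)}
    cols = list(adjacency.columns[:2])
    edges = [
        (pos[a], pos[b])
        for a, b in adjacency[cols].itertuples(index=False)
        if a in pos and b in pos and a != b
    ]
    return np.asarray(edges, dtype=np.int64).reshape(-1, 2)


def permutation_correct(
    stats: pd.DataFrame,
    atrophy: pd.DataFrame,
    ds: pd.DataFrame,
    adjacency: pd.DataFrame | None = None,
    cluster_forming_p: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Max-cluster-mass permutation correction of the region statistics.

    Symptom scores are permuted across subjects (covariates stay with their
    subjects); each permutation recomputes the adjusted correlations.
    Observed suprathreshold regions are clustered by sign under the region
    adjacency (each region its own cluster when no adjacency is given,
    equivalent to max-|t| correction) and each cluster mass is referred to
    the null distribution of the maximum cluster mass:
    p_corrected = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise PreconditionError("n_perm must be >= 1")
    if not 0 < cluster_forming_p < 1:
        raise PreconditionError("cluster_forming_p must lie in (0, 1)")
    A, merged, Q, regions = _prepare(atrophy, ds, covariates)
    n, k = len(merged), len(covariates)
    df = n - k - 2
    t_crit = sps.t.isf(cluster_forming_p / 2, df)
    if adjacency is None:
        logger.info("no adjacency supplied: treating regions independently (max-|t|)")
    edges = adjacency_edges(adjacency, regions)
    m = len(regions)

    stats = stats.set_index("region").loc[regions].reset_index()
    t_obs = stats["t_stat"].to_numpy(dtype=float)
    t_for_mass = np.nan_to_num(t_obs, nan=0.0, posinf=0.0, neginf=0.0)

    # observed clusters, split by sign
    cluster_id = np.full(m, -1, dtype=int)
    masses: list[float] = []
    next_id = 0
    for sign in (+1, -1):
        mask = (sign * t_for_mass) > t_crit
        labels, n_cl = cluster_labels(mask, edges, m)
        for c in range(n_cl):
            members = labels == c
            cluster_id[members] = next_id
            masses.append(float(np.abs(t_for_mass[members]).sum()))
            next_id += 1

    # permutation null of the maximum cluster mass (vectorized correlations)
    rng = np.random.default_rng(seed)
    symptom = merged["symptom"].to_numpy(dtype=float)
    Ra = A - Q @ (Q.T @ A)
    na = np.linalg.norm(Ra, axis=0)
    valid = na > 0
    Ra_n = np.where(valid, Ra / np.where(na == 0, 1.0, na), 0.0)
    batch = 200
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = np.stack([rng.permutation(n) for _ in range(b)])
        S = symptom[perms].T  # (n, b)
        Rs = S - Q @ (Q.T @ S)
        ns = np.linalg.norm(Rs, axis=0)
        Rs_n = Rs / np.where(ns == 0, 1.0, ns)
        r_null = np.clip(Ra_n.T @ Rs_n, -1.0, 1.0)  # (m, b)
        t_null = _r_to_t(r_null, df)
        t_null[~valid] = 0.0
        abs_t = np.abs(t_null)
        for j in range(b):
            best = 0.0
            for sign in (+1, -1):
                mask = (sign * t_null[:, j]) > t_crit
                if mask.any():
                    best = max(best, max_cluster_mass(abs_t[:, j], mask, edges))
            null_max[done + j] = best
        done += b

    p_cluster = np.array(
        [(1 + np.sum(null_max >= mass)) / (1 + n_perm) for mass in masses]
    )
    out = stats.copy()
    out["cluster_id"] = cluster_id
    out["cluster_mass"] = [masses[c] if c >= 0 else 0.0 for c in cluster_id]
    out["p_corrected"] = [p_cluster[c] if c >= 0 else 1.0 for c in cluster_id]
    return out


def binarize_significant(stats: pd.DataFrame, alpha: float = 0.05) -> SeedMask:
    """Binary seed mask of regions in clusters with corrected p < alpha."""
    if "p_corrected" not in stats.columns:
        raise PreconditionError("run permutation_correct first (no p_corrected)")
    sig = stats[(stats["cluster_id"] >= 0) & (stats["p_corrected"] < alpha)]
    ids = tuple(sorted(int(r) for r in sig["region"]))
    if not ids:
        logger.info("no region survives corrected alpha=%g: empty seed mask", alpha)
    return SeedMask(region_ids=ids, alpha=alpha, method="max cluster mass permutation")


def seed_mask_to_volume(seed: SeedMask, atlas: np.ndarray) -> np.ndarray:
    """Render a region-id seed mask into a binary volume via a label atlas."""
    atlas = np.asarray(atlas)
    return np.isin(atlas, np.asarray(seed.region_ids))
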