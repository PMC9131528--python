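"""Effective connectivity: MVAR models, (temporal) partial directed coherence,
surrogate significance, time-reversal testing and DICS source extraction.

The directed-connectivity chain mirrors standard practice in EEG effective
connectivity: source-space signals are modelled with a multivariate
autoregressive (MVAR) model

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + e_t,

whose coefficients define the frequency-domain transfer structure

    Abar(f) = I - sum_k A_k exp(-i 2 pi f k / fs).

Partial directed coherence (PDC) from channel j to channel i is the
column-normalized magnitude

    pdc[i <- j](f) = |Abar_ij(f)| / sqrt(sum_m |Abar_mj(f)|^2),

so that sum_i pdc[i<-j](f)^2 == 1 for every source column j. The "temporal"
variant (TPDC) evaluates PDC in sliding windows and averages across time.
Significance is assessed with a window-shuffle bootstrap (the average null
TPDC serves as a global threshold, with per-connection percentiles as a
stricter alternative) and a time-reversal check: a genuine directed coupling
must flip its net direction when the signal is reversed in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import NumericalError, PreconditionError

__all__ = [
    "MultichannelSignal",
    "MVARModel",
    "TPDCResult",
    "BootstrapNull",
    "LeadField",
    "DEFAULT_BANDS",
    "fit_mvar",
    "select_order",
    "pdc_spectrum",
    "tpdc",
    "bootstrap_threshold",
    "time_reversal_test",
    "cross_spectral_density",
    "dics_power",
    "extract_source_timecourses",
    "compare_groups",
]

#: Canonical analysis bands (Hz): theta 4-7, gamma 30-70.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {"theta": (4.0, 7.0), "gamma": (30.0, 70.0)}


@dataclass
class MultichannelSignal:
    """Equal-length multichannel time series at a fixed sampling rate."""

    data: np.ndarray  # (n_channels, n_samples)
    fs_hz: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreconditionError("signal data must be 2-D (channels x samples)")
        if self.fs_hz <= 0:
            raise PreconditionError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise PreconditionError("signal contains non-finite values")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.data.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def reversed(self) -> "MultichannelSignal":
        return MultichannelSignal(self.data[:, ::-1].copy(), self.fs_hz, self.labels)


@dataclass
class MVARModel:
    """MVAR(p) coefficients ``coeffs[k-1] == A_k`` plus residual covariance."""

    coeffs: np.ndarray  # (p, c, c)
    resid_cov: np.ndarray  # (c, c)
    fs_hz: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise PreconditionError("coeffs must have shape (order, c, c)")
        self.resid_cov = np.asarray(self.resid_cov, dtype=float)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        p, c = self.order, self.n_channels
        comp = np.zeros((p * c, p * c))
        comp[:c] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[c:, : (p - 1) * c] = np.eye((p - 1) * c)
        return comp

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass
class TPDCResult:
    """Sliding-window PDC values and their time/band averages.

    ``values[w, f, i, j]`` is pdc[i <- j] at frequency ``freqs[f]`` in window
    ``w``; ``time_avg`` averages across windows; ``band_avg[name][i, j]``
    additionally averages across the in-band frequency grid points.
    """

    values: np.ndarray  # (n_windows, n_freqs, c, c)
    freqs: np.ndarray
    window_s: float
    step_s: float
    fs_hz: float
    window_starts: np.ndarray
    time_avg: np.ndarray = field(init=False)
    band_avg: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_avg = self.values.mean(axis=0)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


@dataclass
class BootstrapNull:
    """Window-shuffle surrogate distribution of band-averaged TPDC."""

    null_values: np.ndarray  # (n_boot, n_bands, c, c)
    bands: tuple[str, ...]
    threshold_global: dict[str, float]
    threshold_per_connection: dict[str, np.ndarray]  # (c, c) 95th percentile
    shuffle_window_s: float
    n_boot: int
    seed: int | None


@dataclass
class LeadField:
    """Sensor gain matrix (channels x sources), full column rank."""

    gain: np.ndarray
    source_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise PreconditionError("lead field must be 2-D")
        if np.linalg.matrix_rank(self.gain) < self.gain.shape[1]:
            raise PreconditionError("lead field is rank deficient")
        if not self.source_labels:
            self.source_labels = tuple(f"src{i}" for i in range(self.gain.shape[1]))


# ---------------------------------------------------------------------------
# MVAR estimation
# ---------------------------------------------------------------------------


def _ols_mvar(data: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares MVAR fit on demeaned ``data`` (c, n). Returns (A, resid_cov)."""
    c, n = data.shape
    p = order
    x = data - data.mean(axis=1, keepdims=True)
    # design row t: [x_{t-1}, ..., x_{t-p}] flattened channel blocks
    cols = [x[:, p - k : n - k].T for k in range(1, p + 1)]
    Z = np.concatenate(cols, axis=1)  # (n-p, c*p)
    Y = x[:, p:].T  # (n-p, c)
    G = Z.T @ Z
    try:
        B = np.linalg.solve(G, Z.T @ Y)  # (c*p, c)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise NumericalError(
            f"singular MVAR design (cond={np.linalg.cond(Z):.3g})"
        ) from exc
    E = Y - Z @ B
    dof = max(Y.shape[0] - c * p, 1)
    resid_cov = E.T @ E / dof
    A = np.stack([B[k * c : (k + 1) * c].T for k in range(p)])
    return A, resid_cov


def fit_mvar(signal: MultichannelSignal, order: int) -> MVARModel:
    """Fit an MVAR(p) model by multivariate least squares.

    The stacked regression of ``x_t`` on its ``p`` lags is solved by normal
    equations; the residual covariance uses the degrees-of-freedom corrected
    denominator ``n_eff - c*p``.
    """
    if order < 1:
        raise PreconditionError("order must be >= 1")
    c, n = signal.data.shape
    if n <= 10 * order:
        raise PreconditionError(
            f"signal too short for order {order}: {n} samples (< {10 * order + 1})"
        )
    A, resid_cov = _ols_mvar(signal.data, order)
    return MVARModel(A, resid_cov, signal.fs_hz)


def select_order(signal: MultichannelSignal, max_order: int) -> tuple[int, pd.DataFrame]:
    """Select the MVAR order minimizing Schwarz's Bayesian criterion.

    All candidate orders are fitted on the common effective sample (the last
    ``n - max_order`` points) so their criteria are comparable. Returns the
    chosen order and the criterion trace.
    """
    if max_order < 1:
        raise PreconditionError("max_order must be >= 1")
    c, n = signal.data.shape
    feasible = max_order
    while feasible > 1 and n - feasible <= 10 * feasible:
        feasible -= 1
    if feasible < max_order:
        warnings.warn(
            f"series too short for max_order={max_order}; searching up to {feasible}",
            stacklevel=2,
        )
    x = signal.data - signal.data.mean(axis=1, keepdims=True)
    n_eff = n - feasible
    rows = []
    for p in range(1, feasible + 1):
        cols = [x[:, feasible - k : n - k].T for k in range(1, p + 1)]
        Z = np.concatenate(cols, axis=1)
        Y = x[:, feasible:].T
        B = np.linalg.solve(Z.T @ Z, Z.T @ Y)
        E = Y - Z @ B
        sigma = E.T @ E / n_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf
        sbc = logdet + (c * c * p) * np.log(n_eff) / n_eff
        rows.append({"order": p, "sbc": sbc})
    trace = pd.DataFrame(rows)
    best = int(trace.loc[trace["sbc"].idxmin(), "order"])
    return best, trace


# ---------------------------------------------------------------------------
# PDC / TPDC
# ---------------------------------------------------------------------------


def pdc_spectrum(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    """Partial directed coherence ``out[f, i, j] = pdc[i <- j](freqs[f])``."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs < 0) or np.any(freqs > model.fs_hz / 2):
        raise PreconditionError("frequencies must lie in [0, fs/2]")
    p, c = model.order, model.n_channels
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / model.fs_hz)  # (F, p)
    abar = np.eye(c)[None] - np.einsum("fk,kij->fij", phase, model.coeffs)
    mag = np.abs(abar)
    denom = np.sqrt((mag**2).sum(axis=1, keepdims=True))
    return mag / denom


def default_freq_grid(fs_hz: float, fmin: float = 1.0, fmax: float = 90.0) -> np.ndarray:
    """1-Hz grid from ``fmin`` up to min(fmax, just below Nyquist)."""
    top = min(fmax, fs_hz / 2 - 1e-9)
    return np.arange(fmin, top + 1e-9, 1.0)


def _band_average(time_avg: np.ndarray, freqs: np.ndarray, bands: Mapping[str, tuple[float, float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise PreconditionError(f"band {name}=({lo},{hi}) has no grid points")
        out[name] = time_avg[sel].mean(axis=0)
    return out


def tpdc(
    signal: MultichannelSignal,
    window_s: float = 2.0,
    step_s: float = 0.5,
    order: int = 5,
    freqs: np.ndarray | None = None,
    bands: Mapping[str, tuple[float, float]] | None = None,
) -> TPDCResult:
    """Temporal PDC: sliding-window MVAR fits, PDC per window, time average."""
    fs = signal.fs_hz
    if freqs is None:
        freqs = default_freq_grid(fs)
    freqs = np.asarray(freqs, dtype=float)
    bands = dict(bands) if bands is not None else {
        k: v for k, v in DEFAULT_BANDS.items() if v[1] < fs / 2
    }
    win = int(round(window_s * fs))
    step = max(int(round(step_s * fs)), 1)
    if win <= 10 * order:
        raise PreconditionError("window too short for the requested MVAR order")
    n = signal.n_samples
    if n < win:
        raise PreconditionError("signal shorter than one window")
    starts = np.arange(0, n - win + 1, step)
    c = signal.n_channels
    p = order
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)  # (F, p)
    eye = np.eye(c)[None]
    values = np.empty((len(starts), len(freqs), c, c))
    for w, s0 in enumerate(starts):
        A, _ = _ols_mvar(signal.data[:, s0 : s0 + win], p)
        abar = eye - np.einsum("fk,kij->fij", phase, A)
        mag = np.abs(abar)
        values[w] = mag / np.sqrt((mag**2).sum(axis=1, keepdims=True))
    res = TPDCResult(values, freqs, window_s, step_s, fs, starts)
    res.band_avg = _band_average(res.time_avg, freqs, bands)
    return res


# ---------------------------------------------------------------------------
# Significance: window-shuffle bootstrap and time reversal
# ---------------------------------------------------------------------------


def _offdiag_mask(c: int) -> np.ndarray:
    return ~np.eye(c, dtype=bool)


def bootstrap_threshold(
    signal: MultichannelSignal,
    n_boot: int = 1000,
    shuffle_window_s: float = 1.0,
    seed: int | None = None,
    **tpdc_params,
) -> BootstrapNull:
    """Window-shuffle surrogate threshold for TPDC values.

    The record is cut into non-overlapping windows of ``shuffle_window_s``;
    each replicate permutes the window order (one permutation applied to all
    channels), refits the sliding-window MVAR chain and recomputes
    band-averaged TPDC. The default decision threshold per band is the mean
    of all off-diagonal null values (one global threshold for every
    connection); 95th-percentile per-connection thresholds are returned as a
    stricter alternative.
    """
    if n_boot < 1:
        raise PreconditionError("n_boot must be >= 1")
    fs = signal.fs_hz
    shuf_len = int(round(shuffle_window_s * fs))
    order = tpdc_params.get("order", 5)
    if shuf_len < 3 * order:
        raise PreconditionError("shuffle window shorter than 3x the MVAR order")
    n_win = signal.n_samples // shuf_len
    if n_win < 10:
        raise PreconditionError("need at least 10 shuffle windows")
    rng = np.random.default_rng(seed)
    usable = signal.data[:, : n_win * shuf_len]
    blocks = usable.reshape(signal.n_channels, n_win, shuf_len)
    null_vals: list[np.ndarray] = []
    band_names: tuple[str, ...] = ()
    for _ in range(n_boot):
        perm = rng.permutation(n_win)
        shuffled = blocks[:, perm].reshape(signal.n_channels, -1)
        res = tpdc(MultichannelSignal(shuffled, fs, signal.labels), **tpdc_params)
        band_names = tuple(res.band_avg)
        null_vals.append(np.stack([res.band_avg[b] for b in band_names]))
    null = np.stack(null_vals)  # (n_boot, n_bands, c, c)
    c = signal.n_channels
    off = _offdiag_mask(c)
    thr_global = {
        b: float(null[:, i][:, off].mean()) for i, b in enumerate(band_names)
    }
    thr_conn = {
        b: np.percentile(null[:, i], 95, axis=0) for i, b in enumerate(band_names)
    }
    return BootstrapNull(
        null_values=null,
        bands=band_names,
        threshold_global=thr_global,
        threshold_per_connection=thr_conn,
        shuffle_window_s=shuffle_window_s,
        n_boot=n_boot,
        seed=seed,
    )


def time_reversal_test(
    signal: MultichannelSignal,
    null: BootstrapNull | None = None,
    threshold_mode: str = "global",
    **tpdc_params,
) -> pd.DataFrame:
    """Two-stage significance decision per directed connection and band.

    A connection j -> i passes when (a) its forward band-averaged TPDC
    exceeds the bootstrap threshold and (b) the net direction
    ``pdc[i<-j] - pdc[j<-i]`` flips sign when the series is reversed in time.
    Symmetric couplings with no net direction abstain (``direction_flips``
    False, decision driven by the threshold only is not granted).
    """
    fwd = tpdc(signal, **tpdc_params)
    rev = tpdc(signal.reversed(), **tpdc_params)
    c = signal.n_channels
    rows = []
    for band in fwd.band_avg:
        f = fwd.band_avg[band]
        r = rev.band_avg[band]
        if null is not None and band in null.threshold_global:
            if threshold_mode == "global":
                thr = np.full((c, c), null.threshold_global[band])
            elif threshold_mode == "per_connection":
                thr = null.threshold_per_connection[band]
            else:
                raise PreconditionError(f"unknown threshold_mode {threshold_mode!r}")
        else:
            thr = np.full((c, c), np.nan)
        for i in range(c):
            for j in range(c):
                if i == j:
                    continue
                net_f = f[i, j] - f[j, i]
                net_r = r[i, j] - r[j, i]
                above = bool(f[i, j] > thr[i, j]) if np.isfinite(thr[i, j]) else False
                flips = bool(net_f * net_r < 0)
                rows.append(
                    {
                        "band": band,
                        "target": signal.labels[i],
                        "source": signal.labels[j],
                        "forward": float(f[i, j]),
                        "reversed": float(r[i, j]),
                        "net_forward": float(net_f),
                        "net_reversed": float(net_r),
                        "threshold": float(thr[i, j]),
                        "above_threshold": above,
                        "direction_flips": flips,
                        "passes": above and flips,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DICS source power / time courses
# ---------------------------------------------------------------------------


def cross_spectral_density(
    signal: MultichannelSignal,
    band: tuple[float, float],
    nperseg: int = 256,
) -> np.ndarray:
    """Welch-averaged sensor cross-spectral density, averaged over ``band``.

    Hann-windowed 50%-overlapping segments; the returned (c, c) matrix is
    Hermitian positive semidefinite.
    """
    x = signal.data
    c, n = x.shape
    nperseg = min(nperseg, n)
    step = nperseg // 2
    win = np.hanning(nperseg)
    freqs = np.fft.rfftfreq(nperseg, 1 / signal.fs_hz)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise PreconditionError("band contains no FFT bins; increase nperseg")
    acc = np.zeros((c, c), dtype=complex)
    count = 0
    for s0 in range(0, n - nperseg + 1, step):
        seg = (x[:, s0 : s0 + nperseg] - x[:, s0 : s0 + nperseg].mean(axis=1, keepdims=True)) * win
        spec = np.fft.rfft(seg, axis=1)[:, sel]  # (c, nb)
        acc += spec @ spec.conj().T
        count += sel.sum()
    if count == 0:
        raise PreconditionError("signal too short for one CSD segment")
    return acc / count


def dics_power(
    csd: np.ndarray,
    leadfield: LeadField,
    reg_lambda: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """DICS beamformer power per candidate source, plus the spatial filters.

    The sensor CSD ``C`` is regularized as ``C + lambda * mean(diag C) * I``;
    for each lead-field column ``l`` the unit-gain filter is
    ``w = C_r^-1 l / (l^H C_r^-1 l)`` and source power is ``Re(w^H C w)``.
    Filters are returned (sources x channels) and can be applied to raw data
    to extract source time courses.
    """
    C = np.asarray(csd)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise PreconditionError("CSD must be square")
    if not np.allclose(C, C.conj().T, atol=1e-8 * max(1.0, np.abs(C).max())):
        raise PreconditionError("CSD must be Hermitian")
    if reg_lambda < 0:
        raise PreconditionError("reg_lambda must be >= 0")
    c = C.shape[0]
    Cr = C + reg_lambda * np.real(np.trace(C)) / c * np.eye(c)
    try:
        Cr_inv = np.linalg.inv(Cr)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular CSD; increase reg_lambda above zero"
        ) from exc
    G = leadfield.gain
    filters = np.empty((G.shape[1], c), dtype=complex)
    power = np.empty(G.shape[1])
    for s in range(G.shape[1]):
        l = G[:, s]
        ci_l = Cr_inv @ l
        denom = l.conj() @ ci_l
        if np.abs(denom) < 1e-300:
            raise NumericalError("degenerate lead-field column in DICS filter")
        w = ci_l / denom
        filters[s] = w.conj()
        power[s] = float(np.real(w.conj() @ C @ w))
    return power, filters


def extract_source_timecourses(data: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Apply DICS spatial filters (sources x channels) to sensor data."""
    return np.real(filters) @ np.asarray(data)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_groups(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-factor fixed-effects ANOVA (group, connection) plus post-hoc t tests.

    ``values`` is long-format with columns ``group``, ``connection``,
    ``value``. Returns the type-II ANOVA table and a per-connection two-sided
    Welch-free (pooled variance) t-test table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"group", "connection", "value"}
    if not required.issubset(values.columns):
        raise PreconditionError(f"values must have columns {sorted(required)}")
    groups = values["group"].unique()
    conns = values["connection"].unique()
    if len(groups) < 2 or len(conns) < 2:
        raise PreconditionError("need >= 2 groups and >= 2 connections")
    counts = values.groupby(["group", "connection"], observed=True).size()
    full = pd.MultiIndex.from_product([groups, conns], names=["group", "connection"])
    missing = full.difference(counts.index)
    if len(missing) or (counts < 2).any():
        bad = list(missing) + list(counts[counts < 2].index)
        raise PreconditionError(f"cells with < 2 observations: {bad}")
    model = smf.ols("value ~ C(group) + C(connection)", data=values).fit()
    anova = anova_lm(model, typ=2)
    rows = []
    for conn in conns:
        sub = values[values["connection"] == conn]
        a = sub.loc[sub["group"] == groups[0], "value"]
        b = sub.loc[sub["group"] == groups[1], "value"]
        t, p = sps.ttest_ind(a, b)
        rows.append({"connection": conn, "t": float(t), "p": float(p),
                     "mean_" + str(groups[0]): a.mean(), "mean_" + str(groups[1]): b.mean()})
    return anova, pd.DataFrame(rows)
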