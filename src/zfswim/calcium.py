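"""Voxelwise calcium-imaging regression against fictive swim signals.

The chain: motion-correct the T×Z×Y×X movie against a reference volume
(integer-voxel cross-correlation shifts), extract ROI fluorescence and
ΔF/F against a bottom-20th-percentile baseline, build regressors by
convolving each fictive motor signal with a GCaMP6s impulse response
(0.5 s rise, 2 s decay) and z-scoring at the volume times, fit every
voxel's time course with ordinary least squares (Y = Xβ + ε, intercept
included), convert coefficients to t values, and threshold the maps at a
Benjamini–Hochberg false discovery rate of q = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats

__all__ = [
    "CalciumMovie",
    "RoiTrace",
    "RegressorSet",
    "ActivationMap",
    "gcamp_kernel",
    "kernel_peak_time",
    "motion_correct",
    "extract_dff",
    "event_triggered_average",
    "build_regressor",
    "voxel_glm",
    "fdr_threshold",
    "apply_fdr",
]


@dataclass
class CalciumMovie:
    """T×Z×Y×X fluorescence movie at a fixed volume rate."""

    data: np.ndarray
    volume_rate: float = 2.0
    voxel_size_um: tuple[float, float, float] = (7.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[0] < 2:
            raise ValueError("movie must be T×Z×Y×X with T ≥ 2")
        if not self.volume_rate > 0:
            raise ValueError("volume rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) / self.volume_rate


@dataclass
class RoiTrace:
    F: np.ndarray
    F0: float
    dff: np.ndarray

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if not self.F0 > 0:
            raise ValueError("baseline F0 must be positive")
        if not np.allclose(self.dff, (self.F - self.F0) / self.F0):
            raise ValueError("dff must equal (F − F0)/F0")


@dataclass
class RegressorSet:
    """Standardised design matrix with per-column source labels."""

    X: np.ndarray
    labels: list[str]
    tau_rise_s: float = 0.5
    tau_decay_s: float = 2.0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.labels):
            raise ValueError("X must be T×p with one label per column")
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0)
        if np.any(np.abs(mu) > 1e-9) or np.any(np.abs(sd - 1) > 1e-9):
            raise ValueError("regressor columns must be standardized (mean 0, SD 1)")


@dataclass
class ActivationMap:
    """Per-voxel β, t and p for each regressor, plus the FDR mask."""

    beta: np.ndarray  # V×p
    t: np.ndarray  # V×p
    p: np.ndarray  # V×p
    mask: np.ndarray | None = None  # V×p boolean, set by fdr_threshold
    p_adjusted: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)
    q: float = 0.05


def gcamp_kernel(
    t: np.ndarray,
    tau_rise_s: float = 0.5,
    tau_decay_s: float = 2.0,
    form: str = "product",
) -> np.ndarray:
    """GCaMP6s impulse response, normalised to unit peak.

    ``product``: h(t) = (1 − e^(−t/τr)) e^(−t/τd) (saturating rise ×
    exponential decay); ``difference``: h(t) = e^(−t/τd) − e^(−t/τr).
    Both reproduce the stated 0.5 s rise / 2 s decay time constants.
    """
    t = np.asarray(t, dtype=float)
    if form == "product":
        h = (1.0 - np.exp(-t / tau_rise_s)) * np.exp(-t / tau_decay_s)
    elif form == "difference":
        h = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    else:
        raise ValueError("form must be 'product' or 'difference'")
    h[t < 0] = 0.0
    peak = h.max()
    return h / peak if peak > 0 else h


def kernel_peak_time(tau_rise_s: float = 0.5, tau_decay_s: float = 2.0) -> float:
    """Closed-form peak time of the product-form kernel:
    t* = τr · ln(1 + τd/τr)."""
    return tau_rise_s * np.log(1.0 + tau_decay_s / tau_rise_s)


def motion_correct(
    movie: CalciumMovie,
    reference: np.ndarray,
    *,
    max_shift: int = 10,
) -> tuple[CalciumMovie, np.ndarray, np.ndarray]:
    """Integer-voxel rigid correction by cross-correlation to a reference.

    Returns the shifted movie, the applied per-volume shifts (T×3,
    z/y/x) and a boolean flag per volume marking shifts that hit the
    ``max_shift`` search bound.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != movie.data.shape[1:]:
        raise ValueError("reference must match the movie's spatial shape")
    ref0 = ref - ref.mean()
    F_ref = np.fft.fftn(ref0)
    T = movie.data.shape[0]
    shifts = np.zeros((T, 3), dtype=int)
    flagged = np.zeros(T, dtype=bool)
    corrected = np.empty_like(movie.data)
    dims = np.array(ref.shape)
    for i in range(T):
        vol = movie.data[i]
        xc = np.fft.ifftn(F_ref * np.conj(np.fft.fftn(vol - vol.mean()))).real
        # displacement of the volume relative to the reference, with wraparound
        peak = np.array(np.unravel_index(np.argmax(xc), xc.shape))
        disp = np.where(peak > dims // 2, peak - dims, peak)
        applied = disp  # shifting by `disp` moves the volume back onto the reference
        if np.any(np.abs(applied) > max_shift):
            flagged[i] = True
            applied = np.clip(applied, -max_shift, max_shift)
        shifts[i] = applied
        corrected[i] = ndimage.shift(vol, applied, order=0, mode="nearest")
    return (
        CalciumMovie(corrected, movie.volume_rate, movie.voxel_size_um),
        shifts,
        flagged,
    )


def extract_dff(movie: CalciumMovie, roi_mask: np.ndarray, percentile: float = 20.0) -> RoiTrace:
    """ROI-mean fluorescence and ΔF/F against a bottom-percentile baseline."""
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != movie.data.shape[1:]:
        raise ValueError("roi mask must match the movie's spatial shape")
    if not mask.any():
        raise ValueError("roi mask is empty")
    F = movie.data[:, mask].mean(axis=1)
    F0 = float(np.percentile(F, percentile))
    if F0 <= 0:
        raise ValueError("baseline F0 must be positive")
    return RoiTrace(F=F, F0=F0, dff=(F - F0) / F0)


def event_triggered_average(
    dff: np.ndarray,
    fs: float,
    event_onsets_s: np.ndarray,
    window_s: tuple[float, float] = (1.0, 5.0),
) -> dict:
    """Event-aligned mean ΔF/F with SE across events and the peak of the mean.

    Events whose window exceeds the record are dropped (the count is
    reported).  Returns a dict with ``t`` (s, relative to onset),
    ``mean``, ``se``, ``peak``, ``peak_time_s``, ``n_events`` and
    ``n_dropped``.
    """
    x = np.asarray(dff, dtype=float)
    pre, post = window_s
    i_pre = int(round(pre * fs))
    i_post = int(round(post * fs))
    segs = []
    dropped = 0
    for ev in np.atleast_1d(event_onsets_s):
        c = int(round(ev * fs))
        if c - i_pre < 0 or c + i_post > len(x):
            dropped += 1
            continue
        segs.append(x[c - i_pre : c + i_post])
    if not segs:
        raise ValueError("no event window fits inside the recording")
    seg = np.vstack(segs)
    mean = seg.mean(axis=0)
    se = seg.std(axis=0, ddof=1) / np.sqrt(len(segs)) if len(segs) > 1 else np.zeros_like(mean)
    t_rel = (np.arange(-i_pre, i_post)) / fs
    post_mask = t_rel >= 0
    peak_idx = np.argmax(mean[post_mask])
    return {
        "t": t_rel,
        "mean": mean,
        "se": se,
        "peak": float(mean[post_mask][peak_idx]),
        "peak_time_s": float(t_rel[post_mask][peak_idx]),
        "n_events": len(segs),
        "n_dropped": dropped,
    }


def build_regressor(
    fictive_signal: np.ndarray,
    trace_fs: float,
    volume_times_s: np.ndarray,
    tau_rise_s: float = 0.5,
    tau_decay_s: float = 2.0,
    form: str = "product",
    *,
    standardize: bool = True,
) -> np.ndarray:
    """Convolve a fictive motor signal with the GCaMP6s kernel and z-score.

    The convolution runs at the trace resolution, is sampled at the
    volume acquisition times, and the result is standardised (mean 0,
    SD 1).  A zero-variance result (no events) raises.
    """
    x = np.asarray(fictive_signal, dtype=float)
    t_vol = np.asarray(volume_times_s, dtype=float)
    t_trace = np.arange(len(x)) / trace_fs
    if t_vol.min() < 0 or t_vol.max() > t_trace[-1]:
        raise ValueError("volume times must lie within the trace span")
    t_kernel = np.arange(0, 4.0 * tau_decay_s, 1.0 / trace_fs)
    h = gcamp_kernel(t_kernel, tau_rise_s, tau_decay_s, form)
    # edge-pad with the initial value so a constant signal convolves to
    # an exact constant (steady state) rather than an onset ramp
    pad = len(h)
    xp = np.concatenate([np.full(pad, x[0]), x])
    conv = np.convolve(xp, h)[pad : pad + len(x)]
    sampled = np.interp(t_vol, t_trace, conv)
    if not standardize:
        return sampled
    sd = sampled.std()
    if sd <= 1e-10 * (np.abs(sampled).max() + 1.0):  # constant up to float error
        raise ValueError("zero-variance regressor: the signal contains no events")
    return (sampled - sampled.mean()) / sd


def voxel_glm(Y: np.ndarray, X: RegressorSet | np.ndarray) -> ActivationMap:
    """Per-voxel OLS of Y (T×V) on the standardised regressors.

    An intercept is always included.  t = β̂/SE(β̂) with T − p − 1
    residual degrees of freedom and two-sided p values.
    """
    if isinstance(X, RegressorSet):
        labels = list(X.labels)
        Xmat = X.X
    else:
        Xmat = np.asarray(X, dtype=float)
        labels = [f"x{j}" for j in range(Xmat.shape[1])]
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    T, p = Xmat.shape
    if Y.shape[0] != T:
        raise ValueError("Y and X must share the time dimension")
    if T <= p + 1:
        raise ValueError("need T > p + 1 time points")
    design = np.column_stack([np.ones(T), Xmat])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("rank-deficient design matrix")
    XtX_inv = np.linalg.inv(design.T @ design)
    beta_full = XtX_inv @ design.T @ Y  # (p+1)×V
    resid = Y - design @ beta_full
    dof = T - p - 1
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # (p+1)×V
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta_full / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    return ActivationMap(
        beta=beta_full[1:].T, t=tval[1:].T, p=pval[1:].T, labels=labels
    )


def fdr_threshold(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up over all tests jointly.

    Returns (mask, adjusted p) with ``mask = p_adjusted < q``; shapes
    follow the input.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    flat = p.ravel()
    if np.any((flat < 0) | (flat > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(flat, alpha=q, method="fdr_bh")
    mask = p_adj < q
    return mask.reshape(p.shape), p_adj.reshape(p.shape)


def apply_fdr(amap: ActivationMap, q: float = 0.05) -> ActivationMap:
    """Attach the joint BH-FDR mask (over all voxels and regressors)."""
    mask, p_adj = fdr_threshold(amap.p, q)
    amap.mask = mask
    amap.p_adjusted = p_adj
    amap.q = q
    return amap
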