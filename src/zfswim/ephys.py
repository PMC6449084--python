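"""Fictive ventral-root burst analysis and whole-cell cycle recruitment.

Extracellular ventral-root signals (two channels, 6 kHz) are transformed
with a 10 ms windowed standard deviation, which converts multi-spike
burst packets into smooth amplitude envelopes.  Fictive swim episodes
are runs where either side's envelope exceeds a threshold; each episode
carries the per-side maximum burst amplitude.  Episodes split into weak
spontaneous swims and strong stimulus-driven swims by fitting a
two-component Gaussian mixture to the log maximum burst amplitudes and
cutting at the value whose probability under the weak component is less
than 0.1% (the one-sided 0.999 normal quantile in log space).

Whole-cell sweeps are summarised cycle by cycle: spikes are threshold
crossings (upward, 1 ms refractory), subthreshold depolarisation is the
peak of the 60 Hz low-passed trace relative to the minimum voltage in
the 200 ms before swim onset, and each cycle is classed fast (>35 Hz) or
slow (<35 Hz).  Input resistance comes from averaged hyperpolarising
current steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.stats import norm

__all__ = [
    "FictiveTrace",
    "FictiveEpisode",
    "VmSweep",
    "CycleRecruitment",
    "windowed_sd",
    "default_fictive_threshold",
    "detect_fictive_episodes",
    "classify_fictive_strength",
    "cycle_frequencies",
    "cycle_recruitment",
    "input_resistance",
]


@dataclass
class FictiveTrace:
    """Two-channel ventral-root voltage record."""

    left: np.ndarray
    right: np.ndarray
    fs: float = 6000.0

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right channels must have equal length")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class FictiveEpisode:
    onset_s: float
    offset_s: float
    max_burst_L: float
    max_burst_R: float
    label: str = "unlabeled"
    burst_peak_times_L: np.ndarray = field(default_factory=lambda: np.array([]))
    burst_peak_times_R: np.ndarray = field(default_factory=lambda: np.array([]))
    stimulus_time_s: float | None = None

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise ValueError("episode offset must follow onset")
        if self.max_burst_L < 0 or self.max_burst_R < 0:
            raise ValueError("max burst amplitudes must be non-negative")

    @property
    def max_burst(self) -> float:
        return max(self.max_burst_L, self.max_burst_R)

    @property
    def dominant_side(self) -> str:
        return "left" if self.max_burst_L >= self.max_burst_R else "right"

    @property
    def cycle_freqs(self) -> np.ndarray:
        times = (
            self.burst_peak_times_L
            if self.dominant_side == "left"
            else self.burst_peak_times_R
        )
        if len(times) < 2:
            return np.array([])
        return cycle_frequencies(times)


@dataclass
class VmSweep:
    """Membrane-potential sweep with current-step metadata.

    ``current_steps`` is a list of (amplitude_pA, onset_s, duration_s).
    """

    vm: np.ndarray
    fs: float
    spike_threshold: float
    current_steps: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.vm = np.asarray(self.vm, dtype=float)
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        dur = len(self.vm) / self.fs
        for amp, onset, width in self.current_steps:
            if onset < 0 or onset + width > dur:
                raise ValueError("current step outside sweep")


@dataclass
class CycleRecruitment:
    frequency_hz: float
    speed_class: str  # "fast" (>35 Hz) or "slow" (<35 Hz)
    n_spikes: int
    max_depolarization_mv: float

    def __post_init__(self):
        if self.speed_class not in ("fast", "slow"):
            raise ValueError("speed_class must be 'fast' or 'slow'")
        if self.n_spikes < 0:
            raise ValueError("spike count must be non-negative")


SPEED_BOUNDARY_HZ = 35.0


def windowed_sd(trace: np.ndarray, fs: float, window_s: float = 0.010) -> np.ndarray:
    """Centered moving-window sample SD, same length as the input.

    Edge positions use whatever samples fall inside the (clipped)
    window; a single-sample window yields 0.
    """
    x = np.asarray(trace, dtype=float)
    n = len(x)
    w = int(round(window_s * fs))
    if w < 2:
        raise ValueError("window must cover at least 2 samples")
    if w > n:
        raise ValueError("window longer than trace")
    left = w // 2
    out = np.empty(n)
    # interior: full windows, position i covers x[i-left : i-left+w]
    full = sliding_window_view(x, w)
    out[left : left + full.shape[0]] = np.std(full, axis=-1, ddof=1)
    # edges: clipped windows
    for i in list(range(left)) + list(range(left + full.shape[0], n)):
        seg = x[max(0, i - left) : min(n, i - left + w)]
        out[i] = np.std(seg, ddof=1) if len(seg) > 1 else 0.0
    return out


def default_fictive_threshold(processed: np.ndarray, n_sds: float = 4.5) -> float:
    """Reproducible stand-in for a hand-picked swim threshold.

    The quiescent noise floor is estimated from the lower half of the
    processed-signal distribution (location = 25th percentile, scale
    from the interquartile distance q50 − q25 of a Gaussian), so the
    estimate stays valid as long as swimming occupies less than half the
    record; the threshold sits ``n_sds`` noise SDs above the floor.
    """
    p = np.asarray(processed, dtype=float)
    q25, q50 = np.percentile(p, [25, 50])
    noise_sd = (q50 - q25) / 0.6745
    return float(q25 + n_sds * noise_sd)


def detect_fictive_episodes(
    left_processed: np.ndarray,
    right_processed: np.ndarray,
    fs: float,
    threshold: float | None = None,
    *,
    merge_gap_s: float = 0.05,
    min_duration_s: float = 0.02,
    min_burst_sep_s: float = 0.008,
    burst_smooth_s: float = 0.003,
) -> list[FictiveEpisode]:
    """Fictive swim episodes where either side exceeds the threshold.

    Supra-threshold runs separated by less than ``merge_gap_s`` merge
    into one episode; merged episodes shorter than ``min_duration_s``
    (isolated noise blips) are discarded.  Burst peak times per side are local maxima of the
    processed signal within the episode, at least ``min_burst_sep_s``
    apart (beat frequencies stay below ~100 Hz); a light Gaussian
    smoothing (``burst_smooth_s``) is applied first because the
    windowed-SD envelope of a short burst is double-humped (the SD is
    larger when the window straddles the burst edge than when it covers
    the whole packet).
    """
    L = np.asarray(left_processed, dtype=float)
    R = np.asarray(right_processed, dtype=float)
    combined = np.maximum(L, R)
    if threshold is None:
        threshold = default_fictive_threshold(combined)
    if not threshold > 0:
        raise ValueError("threshold must be positive")

    above = combined > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    gaps = np.diff(idx)
    breaks = np.flatnonzero(gaps > merge_gap_s * fs)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    long_enough = (stops - starts) >= min_duration_s * fs
    starts, stops = starts[long_enough], stops[long_enough]

    sep = max(int(round(min_burst_sep_s * fs)), 1)
    from scipy.ndimage import gaussian_filter1d

    L_sm = gaussian_filter1d(L, burst_smooth_s * fs) if burst_smooth_s > 0 else L
    R_sm = gaussian_filter1d(R, burst_smooth_s * fs) if burst_smooth_s > 0 else R
    episodes = []
    for a, b in zip(starts, stops):
        peaks = {}
        for side, sig_side in (("L", L_sm), ("R", R_sm)):
            pk, _ = signal.find_peaks(sig_side[a:b], height=threshold, distance=sep)
            peaks[side] = (pk + a) / fs
        episodes.append(
            FictiveEpisode(
                onset_s=a / fs,
                offset_s=b / fs,
                max_burst_L=float(L[a:b].max()),
                max_burst_R=float(R[a:b].max()),
                burst_peak_times_L=peaks["L"],
                burst_peak_times_R=peaks["R"],
            )
        )
    return episodes


def classify_fictive_strength(
    max_amplitudes: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Label episodes weak/strong from their maximum burst amplitudes.

    The log amplitudes are fit with a two-component Gaussian mixture;
    the lower-mean component is the weak spontaneous regime and the
    cutoff is the amplitude whose probability of belonging to it is
    below 0.1% (weak mean + 3.0902 weak SD, in log space).  When the
    two fitted components overlap so much that the data are effectively
    unimodal (no strong swims in the session), the pooled mean/SD define
    the weak regime instead — a forced two-component fit of a single
    Gaussian would otherwise split it arbitrarily and place the cutoff
    inside the bulk of the data.  Returns an array of
    ``"weak_spontaneous"``/``"strong"`` labels and the cutoff on the
    original amplitude scale.
    """
    from sklearn.mixture import GaussianMixture

    amps = np.asarray(max_amplitudes, dtype=float)
    if len(amps) < 20:
        raise ValueError("need at least 20 episodes to fit the mixture")
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive for the log transform")
    log_a = np.log(amps).reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=2, n_init=10, init_params="k-means++", random_state=seed,
        covariance_type="full",
    ).fit(log_a)
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    order = np.argsort(means)
    mu_lo, mu_hi = means[order]
    sd_lo, sd_hi = sds[order]
    z = norm.ppf(0.999)
    if mu_hi - mu_lo < 1.5 * (sd_lo + sd_hi):  # effectively unimodal
        cutoff = float(np.exp(log_a.mean() + z * log_a.std(ddof=1)))
    else:
        cutoff = float(np.exp(mu_lo + z * sd_lo))
    labels = np.where(amps > cutoff, "strong", "weak_spontaneous")
    return labels, cutoff


def cycle_frequencies(burst_peak_times: np.ndarray) -> np.ndarray:
    """Reciprocals of the intervals between successive bursts, in Hz."""
    t = np.asarray(burst_peak_times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 bursts")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("burst times must be strictly increasing")
    return 1.0 / dt


def cycle_recruitment(
    sweep: VmSweep,
    cycles: list[tuple[float, float, float]],
    episode_onset_s: float,
    *,
    baseline_window_s: float = 0.2,
    lowpass_hz: float = 60.0,
    refractory_s: float = 0.001,
) -> list[CycleRecruitment]:
    """Per-cycle spike counts and subthreshold depolarisation.

    ``cycles`` is a list of (start_s, end_s, frequency_hz).  Spikes are
    upward crossings of the sweep's spike threshold with a 1 ms
    refractory window; depolarisation is measured on the 60 Hz
    low-passed trace against the minimum voltage in the 200 ms before
    ``episode_onset_s``.
    """
    fs = sweep.fs
    vm = sweep.vm
    n = len(vm)
    for start, end, _ in cycles:
        if start < 0 or end > n / fs or not end > start:
            raise ValueError("cycles must lie within the sweep")

    sos = signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
    vm_low = signal.sosfiltfilt(sos, vm)

    b0 = int(round((episode_onset_s - baseline_window_s) * fs))
    b1 = int(round(episode_onset_s * fs))
    if b0 < 0:
        warnings.warn("baseline window truncated: onset earlier than 200 ms into sweep")
        b0 = 0
    if b1 <= b0:
        raise ValueError("no samples available for the baseline window")
    baseline = float(vm_low[b0:b1].min())

    crossings = np.flatnonzero((vm[1:] > sweep.spike_threshold) & (vm[:-1] <= sweep.spike_threshold)) + 1
    if len(crossings):
        keep = [crossings[0]]
        for c in crossings[1:]:
            if c - keep[-1] >= refractory_s * fs:
                keep.append(c)
        crossings = np.asarray(keep)
    spike_t = crossings / fs

    out = []
    for start, end, freq in cycles:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        n_spk = int(np.sum((spike_t >= start) & (spike_t < end)))
        depol = float(vm_low[i0:i1].max() - baseline)
        out.append(
            CycleRecruitment(
                frequency_hz=float(freq),
                speed_class="fast" if freq > SPEED_BOUNDARY_HZ else "slow",
                n_spikes=n_spk,
                max_depolarization_mv=depol,
            )
        )
    return out


def input_resistance(
    sweep: VmSweep,
    *,
    steady_state_frac: float = 0.2,
    baseline_s: float = 0.05,
) -> float:
    """Input resistance (MΩ) from averaged hyperpolarising current steps.

    For each step, ΔV is the mean of the last ``steady_state_frac`` of
    the step minus the mean over ``baseline_s`` just before its onset;
    R = ΔV/I averaged over pulses (mV/pA → GΩ, returned in MΩ).
    """
    steps = sweep.current_steps
    if any(amp > 0 for amp, _, _ in steps):
        raise ValueError("depolarizing steps supplied; need hyperpolarizing pulses")
    hyper = [s for s in steps if s[0] < 0]
    if len(hyper) < 5:
        raise ValueError("need at least 5 hyperpolarizing steps")
    fs = sweep.fs
    rs = []
    for amp, onset, width in hyper:
        i_on = int(round(onset * fs))
        i_off = int(round((onset + width) * fs))
        i_ss = int(round((onset + (1 - steady_state_frac) * width) * fs))
        i_b0 = max(int(round((onset - baseline_s) * fs)), 0)
        if i_b0 >= i_on:
            i_b0 = max(i_on - 1, 0)
        dv = sweep.vm[i_ss:i_off].mean() - sweep.vm[i_b0:i_on].mean()
        rs.append(1000.0 * dv / amp)  # mV/pA → MΩ
    return float(np.mean(rs))
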