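"""Swim-episode detection and bend-by-bend kinematics from K(t).

Episodes are found on a smoothed envelope of the curvature signal: K(t)
is low-pass filtered at 70 Hz, its absolute value is convolved with a
200 ms Gaussian kernel to give S(t), and an episode begins where S(t)
crosses and stays above 4° for at least 50 ms (the offset is where it
returns and stays below for 50 ms).  Because the smoothing blurs the
onset, each onset is refined to the nearest preceding local maximum of
d²S/dt² — the point where the envelope starts accelerating upward.

Within an episode, bends are the alternating-sign extrema of the
filtered curvature; bend n has amplitude A(n) (curvature change from the
previous peak, or from onset for n = 1) and period P(n) (time from the
previous peak, or from onset).  Global per-episode parameters (distance,
velocities, bend count, angular velocity, escape latency) are computed
from the body-point trajectory and K(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "Bend",
    "SwimEpisode",
    "GlobalParams",
    "lowpass_curvature",
    "smooth_envelope",
    "detect_episodes",
    "detect_bends",
    "bend_metrics",
    "episode_global_params",
]


@dataclass
class Bend:
    """One body bend: 1-based index, peak time, amplitude and period."""

    n: int
    t_peak: float
    amplitude: float
    period: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("bend amplitude must be non-negative")
        if not self.period > 0:
            raise ValueError("bend period must be positive")


@dataclass
class SwimEpisode:
    onset_s: float
    offset_s: float
    bends: list[Bend]
    category: str = "unassigned"
    stimulus_time_s: float | None = None

    def __post_init__(self):
        if not self.offset_s > self.onset_s:
            raise ValueError("episode offset must follow onset")
        for i, b in enumerate(self.bends, start=1):
            if b.n != i:
                raise ValueError("bend indices must be contiguous from 1")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def first_bend_amplitude(self) -> float | None:
        return self.bends[0].amplitude if self.bends else None


@dataclass
class GlobalParams:
    """Whole-episode swim parameters."""

    total_distance_mm: float
    duration_s: float
    mean_velocity_mm_s: float
    max_velocity_mm_s: float
    n_bends: int
    max_angular_velocity_deg_s: float
    max_bend_amplitude_deg: float
    onset_latency_s: float | None = None


def lowpass_curvature(K: np.ndarray, fs: float, fc: float = 70.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass of the curvature series (DC gain 1)."""
    if not fs > 2 * fc:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the cutoff {fc} Hz")
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(K, dtype=float))


def gaussian_kernel(fs: float, fwhm_s: float = 0.2, truncate_sigmas: float = 3.0) -> np.ndarray:
    """Unit-area Gaussian kernel with the given FWHM, truncated at ±3σ."""
    sigma_s = fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = max(int(round(truncate_sigmas * sigma_s * fs)), 1)
    x = np.arange(-half, half + 1) / fs
    g = np.exp(-0.5 * (x / sigma_s) ** 2)
    return g / g.sum()


def smooth_envelope(K_filtered: np.ndarray, fs: float, fwhm_s: float = 0.2) -> np.ndarray:
    """S(t): |K(t)| convolved with a unit-area Gaussian (same length)."""
    g = gaussian_kernel(fs, fwhm_s)
    return np.convolve(np.abs(np.asarray(K_filtered, dtype=float)), g, mode="same")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        stops = np.concatenate([stops, [len(m)]])
    return list(zip(starts, stops))


def detect_episodes(
    S: np.ndarray,
    fs: float,
    threshold_deg: float = 4.0,
    min_hold_s: float = 0.05,
    *,
    onset_refinement: str = "curvature",
    K_filtered: np.ndarray | None = None,
    refine_lookback_s: float = 0.25,
    envelope_fwhm_s: float = 0.2,
    curvature_floor_deg: float = 1.0,
    curvature_floor_frac: float = 0.05,
    curvature_hold_s: float = 0.008,
) -> list[tuple[float, float]]:
    """Episode (onset, offset) times from the smoothed envelope.

    Step 1: a candidate onset is the first sample of each run that stays
    above ``threshold_deg`` for at least ``min_hold_s``; its offset is
    the first sample of the next run that stays below the threshold for
    at least ``min_hold_s`` (or the end of the record).

    Step 2 sharpens each onset, undoing the temporal blur of the
    envelope smoothing, with one of four ``onset_refinement`` modes:

    ``curvature`` (default)
        the onset moves to the first sustained curvature activity
        within ``refine_lookback_s`` around the step-1 onset: |K| above
        a floor (the larger of ``curvature_floor_deg`` and
        ``curvature_floor_frac`` × the episode's peak curvature, which
        keeps the zero-phase filter's pre-ringing below the floor for
        large episodes) for ``curvature_hold_s``.  The smoothed
        envelope cannot localise the onset below its own kernel width,
        but the filtered curvature can; requires ``K_filtered``.
    ``d2``
        the nearest preceding local maximum of d²S/dt² (the foot of the
        envelope rise).  For an onset that is abrupt at the kernel's
        timescale this foot leads the true onset by about one kernel σ.
    ``d2_corrected``
        as ``d2`` plus one kernel σ (from ``envelope_fwhm_s``), which
        compensates that lead with an amplitude-independent constant.
    ``none``
        keep the step-1 threshold crossings.
    """
    S = np.asarray(S, dtype=float)
    hold = max(int(round(min_hold_s * fs)), 1)
    above = S > threshold_deg
    up_runs = [(a, b) for a, b in _runs(above) if b - a >= hold]
    down_runs = [(a, b) for a, b in _runs(~above) if b - a >= hold]

    episodes: list[tuple[int, int]] = []
    last_end = -1
    for a, b in up_runs:
        if a < last_end:
            continue  # merged into the previous episode (no long gap between)
        off = next((da for da, _ in down_runs if da >= b), len(S) - 1)
        episodes.append((a, off))
        last_end = off

    if onset_refinement not in ("none", "d2", "d2_corrected", "curvature"):
        raise ValueError(f"unknown onset_refinement mode {onset_refinement!r}")
    look = max(int(round(refine_lookback_s * fs)), 2)

    if onset_refinement in ("d2", "d2_corrected") and episodes:
        d2 = np.gradient(np.gradient(S)) * fs * fs
        sigma_samp = (
            int(round(envelope_fwhm_s / (2 * np.sqrt(2 * np.log(2))) * fs))
            if onset_refinement == "d2_corrected"
            else 0
        )
        refined = []
        for a, off in episodes:
            lo = max(a - look, 1)
            seg = d2[lo : a + 1]
            # local maxima of the second derivative inside the lookback
            cand = [
                i
                for i in range(1, len(seg) - 1)
                if seg[i] >= seg[i - 1] and seg[i] > seg[i + 1]
            ]
            new_a = min(lo + cand[-1] + sigma_samp, off - 1) if cand else a
            refined.append((new_a, off))
        episodes = refined
    elif onset_refinement == "curvature" and episodes:
        if K_filtered is None:
            raise ValueError("onset_refinement='curvature' requires K_filtered")
        absK = np.abs(np.asarray(K_filtered, dtype=float))
        hold_c = max(int(round(curvature_hold_s * fs)), 1)
        refined = []
        prev_off = 0
        for a, off in episodes:
            lo = max(a - look, prev_off)
            seg = absK[lo:off]
            floor = max(curvature_floor_deg, curvature_floor_frac * seg.max())
            active = seg > floor
            # first sample from which activity is sustained for hold_c samples
            new_a = a
            if active.any():
                run = np.convolve(active.astype(int), np.ones(hold_c, dtype=int))[
                    hold_c - 1 : len(active)
                ]
                idx = np.flatnonzero(run == hold_c)
                if idx.size:
                    new_a = lo + int(idx[0])
            refined.append((new_a, off))
            prev_off = off
        episodes = refined

    return [(a / fs, b / fs) for a, b in episodes]


def detect_bends(
    K_filtered: np.ndarray,
    fs: float,
    episode: tuple[float, float],
    prominence_deg: float = 2.0,
) -> np.ndarray:
    """Peak times of the alternating-sign curvature extrema in an episode.

    Maxima of K and of −K above a prominence floor are pooled and
    time-ordered.  Returns peak times in seconds; raises if the episode
    contains no peak (degenerate episode).
    """
    K = np.asarray(K_filtered, dtype=float)
    i0 = max(int(np.floor(episode[0] * fs)), 0)
    i1 = min(int(np.ceil(episode[1] * fs)) + 1, len(K))
    if i1 <= i0:
        raise ValueError("invalid episode bounds")
    seg = K[i0:i1]
    pk_pos, _ = signal.find_peaks(seg, prominence=prominence_deg)
    pk_neg, _ = signal.find_peaks(-seg, prominence=prominence_deg)
    peaks = np.sort(np.concatenate([pk_pos, pk_neg]))
    if peaks.size == 0:
        raise ValueError("degenerate episode: no curvature peaks")
    return (peaks + i0) / fs


def bend_metrics(
    K_filtered: np.ndarray,
    fs: float,
    t_on: float,
    peak_times: np.ndarray,
    *,
    indexing: str = "contiguous",
) -> list[Bend]:
    """Per-bend amplitudes and periods from curvature peaks.

    A(1) = |K(t₁) − K(t_on)| and P(1) = t₁ − t_on.  For n > 1 the default
    ``contiguous`` convention uses the interval ending at peak n,
    A(n) = |K(tₙ) − K(tₙ₋₁)| and P(n) = tₙ − tₙ₋₁, so that bends tile the
    episode without gaps.  ``indexing='printed'`` instead associates bend
    n with the following interval, A(n) = |K(tₙ₊₁) − K(tₙ)| and
    P(n) = tₙ₊₁ − tₙ (the last bend then has no entry).
    """
    if indexing not in ("contiguous", "printed"):
        raise ValueError("indexing must be 'contiguous' or 'printed'")
    K = np.asarray(K_filtered, dtype=float)
    pt = np.asarray(peak_times, dtype=float)
    if pt.size == 0:
        raise ValueError("at least one peak required")
    if np.any(pt < t_on):
        raise ValueError("peaks before episode onset")

    def k_at(ts: float) -> float:
        return float(np.interp(ts, np.arange(len(K)) / fs, K))

    bends = [Bend(1, float(pt[0]), abs(k_at(pt[0]) - k_at(t_on)), float(pt[0] - t_on))]
    if indexing == "contiguous":
        for n in range(1, len(pt)):
            bends.append(
                Bend(n + 1, float(pt[n]), abs(k_at(pt[n]) - k_at(pt[n - 1])), float(pt[n] - pt[n - 1]))
            )
    else:
        for n in range(1, len(pt) - 1):
            bends.append(
                Bend(n + 1, float(pt[n]), abs(k_at(pt[n + 1]) - k_at(pt[n])), float(pt[n + 1] - pt[n]))
            )
    return bends


def episode_global_params(
    episode: SwimEpisode,
    t: np.ndarray,
    body_xy: np.ndarray,
    K: np.ndarray,
    *,
    stimulus_time_s: float | None = None,
) -> GlobalParams:
    """Whole-episode swim parameters from the body-point trajectory.

    Distance is the summed frame-to-frame displacement of the tracked
    body point (just caudal to the swim bladder); velocities come from
    central differences of position at the native frame rate; the
    maximum angular velocity is the in-episode peak of |dK/dt|.
    """
    t = np.asarray(t, dtype=float)
    xy = np.asarray(body_xy, dtype=float)
    K = np.asarray(K, dtype=float)
    stim = stimulus_time_s if stimulus_time_s is not None else episode.stimulus_time_s
    sel = (t >= episode.onset_s) & (t <= episode.offset_s)
    if sel.sum() < 2:
        raise ValueError("traces do not cover the episode")
    pos = xy[sel]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    distance = float(steps.sum())
    duration = episode.duration_s
    dt = float(np.median(np.diff(t)))
    vel = np.gradient(xy, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    omega = np.gradient(K, dt)
    latency = None
    if stim is not None:
        latency = episode.onset_s - stim
        if latency < 0:
            raise ValueError("stimulus occurs after the episode onset")
    amps = [b.amplitude for b in episode.bends]
    return GlobalParams(
        total_distance_mm=distance,
        duration_s=duration,
        mean_velocity_mm_s=distance / duration,
        max_velocity_mm_s=float(speed[sel].max()),
        n_bends=len(episode.bends),
        max_angular_velocity_deg_s=float(np.abs(omega[sel]).max()),
        max_bend_amplitude_deg=float(max(amps)) if amps else 0.0,
        onset_latency_s=latency,
    )
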