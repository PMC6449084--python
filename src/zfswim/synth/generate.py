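"""Ground-truth-labelled synthetic swim kinematics.

An episode is a train of alternating-sign half-beats of the total body
curvature K(t): half-sine lobes whose first peak reaches the drawn
first-bend amplitude and whose successive peaks decay by a per-beat
damping factor.  Lobe boundaries and peaks are snapped to the sampling
grid so every recorded bend-peak time and amplitude is exact by
construction.  Between episodes K(t) is identically zero.  The head
translates forward at a speed proportional to the instantaneous beat
amplitude × frequency and the heading ramps during turns, so position
and orientation traces carry category-appropriate structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from zfswim.synth.config import CATEGORIES, SynthConfig
from zfswim.tracking import KinematicsSeries

__all__ = [
    "EpisodeTruth",
    "SwimGroundTruth",
    "draw_first_bend_amplitudes",
    "make_kinematics",
    "posture_from_state",
]

# mm/s of forward speed per (degree × Hz) of instantaneous bend drive
_SPEED_GAIN = 0.01
# degrees of heading change per degree of first-bend amplitude, by category
_TURN_GAIN = {"scoot": 0.1, "routine_turn": 0.8, "high_angle_turn": 1.0, "escape": 1.2}


@dataclass
class EpisodeTruth:
    onset_s: float
    offset_s: float
    category: str
    first_bend_amplitude_deg: float
    bend_peak_times_s: np.ndarray
    bend_amplitudes_deg: np.ndarray
    beat_freq_hz: float
    sign: int
    stimulus_time_s: float | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.first_bend_amplitude_deg > 0:
            raise ValueError("first bend amplitude must be positive")
        self.bend_peak_times_s = np.asarray(self.bend_peak_times_s, dtype=float)
        self.bend_amplitudes_deg = np.asarray(self.bend_amplitudes_deg, dtype=float)


@dataclass
class SwimGroundTruth:
    """Exact episode labels and bend-by-bend structure of a synthetic record."""

    episodes: list[EpisodeTruth] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        prev_off = -np.inf
        for ep in self.episodes:
            if ep.onset_s < prev_off:
                raise ValueError("episodes must be non-overlapping and time-ordered")
            if not ep.offset_s > ep.onset_s:
                raise ValueError("episode offset must follow onset")
            prev_off = ep.offset_s

    @property
    def onsets(self) -> np.ndarray:
        return np.array([ep.onset_s for ep in self.episodes])

    @property
    def categories(self) -> list[str]:
        return [ep.category for ep in self.episodes]


def _draw_amplitude(rng, mean, sd) -> float:
    """Truncated-normal (>0) first-bend amplitude via rejection."""
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if a > 0:
            return float(a)
    raise RuntimeError("could not draw a positive amplitude")


def draw_first_bend_amplitudes(
    config: SynthConfig, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n spontaneous first-bend amplitudes (deg) with category labels.

    Categories follow the configured mixture weights; amplitudes are
    truncated-normal (>0) draws from the per-category components.
    """
    rng = np.random.default_rng(seed)
    cats = config.spontaneous_categories
    w = np.asarray(config.spontaneous_weights, dtype=float)
    idx = rng.choice(len(cats), size=n, p=w / w.sum())
    amps = np.empty(n)
    for i, c in enumerate(idx):
        p = config.categories[cats[c]]
        amps[i] = _draw_amplitude(rng, p.amp_mean_deg, p.amp_sd_deg)
    return amps, np.array([cats[c] for c in idx])


def _episode_lobes(fs, onset_idx, amplitude, freq, n_half_beats, damping, sign):
    """Sample indices/values of one episode's curvature lobes.

    The half-beat length is snapped to an even number of samples so each
    lobe's peak falls exactly on the grid; the realised beat frequency is
    returned alongside the exact peak times and amplitudes.
    """
    h = 2 * max(1, int(round(fs / (4.0 * freq))))  # samples per half-beat
    f_actual = fs / (2.0 * h)
    n_samp = n_half_beats * h
    k = np.arange(n_samp)
    lobe = k // h  # which half-beat each sample belongs to
    amps = amplitude * damping ** lobe
    signs = sign * (-1.0) ** lobe
    phase = np.pi * (k - lobe * h) / h
    values = amps * signs * np.sin(phase)
    peak_idx = onset_idx + np.arange(n_half_beats) * h + h // 2
    peak_amps = amplitude * damping ** np.arange(n_half_beats)
    return values, n_samp, peak_idx, peak_amps, f_actual


def make_kinematics(
    config: SynthConfig,
    duration_s: float,
    seed: int,
    *,
    stimulus_times_s: list[float] | None = None,
    episodes: list[dict] | None = None,
) -> tuple[KinematicsSeries, SwimGroundTruth]:
    """Generate a curvature/orientation/position record with exact truth.

    Spontaneous episodes arrive as a Poisson-like process at
    ``config.episode_rate_hz`` (with an enforced quiet gap so episodes
    never overlap) and draw their category from the configured mixture.
    Each ``stimulus_times_s`` entry triggers an escape after a short
    latency.  ``episodes`` overrides the random schedule entirely: each
    dict may fix ``onset_s``, ``category``, ``amplitude_deg``,
    ``beat_freq_hz``, ``n_half_beats`` and ``sign``.
    """
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    fs = config.frame_rate_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    K = np.zeros(n)

    def _materialise(spec: dict) -> EpisodeTruth | None:
        cat = spec["category"]
        p = config.categories[cat]
        amp = spec.get("amplitude_deg") or _draw_amplitude(rng, p.amp_mean_deg, p.amp_sd_deg)
        freq = spec.get("beat_freq_hz") or rng.uniform(*p.beat_freq_hz)
        nhb = spec.get("n_half_beats") or int(rng.integers(p.n_half_beats[0], p.n_half_beats[1] + 1))
        sign = spec.get("sign") or int(rng.choice([-1, 1]))
        onset_idx = int(round(spec["onset_s"] * fs))
        values, n_samp, peak_idx, peak_amps, f_actual = _episode_lobes(
            fs, onset_idx, amp, freq, nhb, config.damping_per_beat, sign
        )
        if onset_idx < 0 or onset_idx + n_samp >= n:
            return None
        K[onset_idx : onset_idx + n_samp] += values
        return EpisodeTruth(
            onset_s=onset_idx / fs,
            offset_s=(onset_idx + n_samp) / fs,
            category=cat,
            first_bend_amplitude_deg=amp,
            bend_peak_times_s=peak_idx / fs,
            bend_amplitudes_deg=peak_amps,
            beat_freq_hz=f_actual,
            sign=sign,
            stimulus_time_s=spec.get("stimulus_time_s"),
        )

    specs: list[dict] = []
    if episodes is not None:
        specs = [dict(e) for e in episodes]
    else:
        cats = config.spontaneous_categories
        weights = np.asarray(config.spontaneous_weights)
        if config.episode_rate_hz > 0:
            clock = 0.0
            while True:
                gap = rng.exponential(1.0 / config.episode_rate_hz)
                onset = clock + config.min_gap_s + gap
                if onset >= duration_s - 0.1:
                    break
                cat = str(rng.choice(cats, p=weights / weights.sum()))
                specs.append({"onset_s": onset, "category": cat})
                # longest plausible episode for this category bounds the clock
                p = config.categories[cat]
                clock = onset + p.n_half_beats[1] / (2.0 * p.beat_freq_hz[0])
        for st in stimulus_times_s or []:
            latency = max(float(rng.normal(0.012, 0.002)), 0.004)
            specs.append({"onset_s": st + latency, "category": "escape", "stimulus_time_s": st})
    specs.sort(key=lambda s: s["onset_s"])

    truth_eps: list[EpisodeTruth] = []
    for spec in specs:
        ep = _materialise(spec)
        if ep is not None and (not truth_eps or ep.onset_s >= truth_eps[-1].offset_s):
            truth_eps.append(ep)

    # Heading and position: forward speed ∝ instantaneous drive, heading
    # ramps by a category-dependent multiple of the first-bend amplitude.
    phi = np.zeros(n)
    speed = np.zeros(n)
    heading = rng.uniform(0, 360) if episodes is None else 0.0
    phi[:] = heading
    for ep in truth_eps:
        i0, i1 = int(round(ep.onset_s * fs)), int(round(ep.offset_s * fs))
        d_heading = _TURN_GAIN[ep.category] * ep.first_bend_amplitude_deg * ep.sign
        ramp = np.linspace(0.0, d_heading, i1 - i0)
        phi[i0:i1] = heading + ramp
        heading += d_heading
        phi[i1:] = heading
        env = np.abs(K[i0:i1])
        speed[i0:i1] = _SPEED_GAIN * env * ep.beat_freq_hz

    head = np.zeros((n, 2))
    head[0] = (6.0, 6.0)  # start near the arena centre, mm
    step = np.column_stack([np.cos(np.radians(phi)), np.sin(np.radians(phi))])
    head[1:] = head[0] + np.cumsum((speed[:-1] / fs)[:, None] * step[:-1], axis=0)
    tailward = -step
    body = head + 0.35 * config.fish_length_mm * tailward

    kin = KinematicsSeries(t=t, K=K, phi_H=phi, head_xy=head, body_xy=body, frame_rate=fs)
    return kin, SwimGroundTruth(episodes=truth_eps, seed=seed)


def posture_from_state(
    head_xy, phi_deg: float, K_deg: float, length_mm: float, n_points: int = 50
) -> np.ndarray:
    """Midline points (head → tail, mm) for a given kinematic state.

    The body leaves the head along the direction opposite φ_H and the
    total curvature K is distributed over the caudal 80% of the body with
    a smoothstep weight, so the curve's summed tangent rotation equals K
    exactly and the rostral 20% stays straight (stiff head).
    """
    s = np.linspace(0.0, 1.0, n_points)
    u = np.clip((s - 0.2) / 0.8, 0.0, 1.0)
    w = u * u * (3.0 - 2.0 * u)
    theta = np.radians(phi_deg + 180.0) + np.radians(K_deg) * w
    ds = length_mm / (n_points - 1)
    pts = np.zeros((n_points, 2))
    pts[0] = head_xy
    # integrate with the mean tangent of each segment (midpoint rule)
    seg_theta = 0.5 * (theta[:-1] + theta[1:])
    pts[1:] = pts[0] + np.cumsum(
        ds * np.column_stack([np.cos(seg_theta), np.sin(seg_theta)]), axis=0
    )
    return pts
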