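"""Synthetic two-channel ventral-root traces with labelled episodes.

Bursts are rectified 300 Hz tone packets of ~5 ms (matching the
100–1000 Hz band-pass character of the recordings) placed at the beat
interval; left and right channels burst in anti-phase by default.  Burst
waveforms are scaled so that the downstream 10 ms windowed-SD transform
of a noiseless burst peaks at the scheduled amplitude, which makes the
weak/strong amplitude regimes directly comparable with the analysis
side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from zfswim.ephys import FictiveTrace, windowed_sd
from zfswim.synth.config import SynthConfig

__all__ = ["FictiveEpisodeSpec", "make_fictive_trace", "make_fictive_schedule"]

_BURST_FREQ_HZ = 300.0
_BURST_WIDTH_S = 0.005


@dataclass
class FictiveEpisodeSpec:
    onset_s: float
    duration_s: float
    beat_freq_hz: float
    amplitude_L: float
    amplitude_R: float
    label: str  # "weak" | "strong"

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


def _unit_burst(fs: float) -> np.ndarray:
    """Rectified tone burst whose max 10 ms windowed SD equals 1."""
    n = int(round(_BURST_WIDTH_S * fs))
    t = np.arange(n) / fs
    w = np.hanning(n)
    b = w * np.abs(np.sin(2 * np.pi * _BURST_FREQ_HZ * t))
    pad = np.zeros(int(round(0.02 * fs)))
    probe = np.concatenate([pad, b, pad])
    scale = windowed_sd(probe, fs, 0.010).max()
    return b / scale


def make_fictive_trace(
    schedule: list[FictiveEpisodeSpec],
    fs: float,
    noise_sd: float,
    seed: int,
    *,
    duration_s: float | None = None,
    antiphase: bool = True,
) -> tuple[FictiveTrace, list[str]]:
    """Build a two-channel trace from a burst schedule.

    Each episode places bursts at 1/beat_freq intervals on the left
    channel and (by default) anti-phase on the right; burst envelope
    amplitudes follow the per-side scheduled values.  Additive Gaussian
    noise is applied to both channels.  Returns the trace and the
    per-episode labels.
    """
    for spec in schedule:
        if not fs >= 20.0 * spec.beat_freq_hz:
            raise ValueError("sampling rate too low for the burst structure")
    ordered = sorted(schedule, key=lambda s: s.onset_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset_s < a.offset_s:
            raise ValueError("overlapping scheduled episodes")

    if duration_s is None:
        duration_s = (ordered[-1].offset_s + 0.2) if ordered else 1.0
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    left = np.zeros(n)
    right = np.zeros(n)
    burst = _unit_burst(fs)
    nb = len(burst)

    for spec in ordered:
        period = 1.0 / spec.beat_freq_hz
        t = spec.onset_s
        phase = 0
        while t + _BURST_WIDTH_S <= spec.offset_s:
            i0 = int(round(t * fs))
            if i0 + nb > n:
                break
            on_left = (phase % 2 == 0) if antiphase else True
            if antiphase:
                target, amp = (left, spec.amplitude_L) if on_left else (right, spec.amplitude_R)
                target[i0 : i0 + nb] += amp * burst
                t += period / 2.0
            else:
                left[i0 : i0 + nb] += spec.amplitude_L * burst
                right[i0 : i0 + nb] += spec.amplitude_R * burst
                t += period
            phase += 1
    if noise_sd > 0:
        left += rng.normal(0, noise_sd, n)
        right += rng.normal(0, noise_sd, n)
    return FictiveTrace(left, right, fs), [s.label for s in ordered]


def make_fictive_schedule(
    config: SynthConfig,
    n_episodes: int,
    seed: int,
    *,
    strong_fraction: float = 0.3,
    gap_s: tuple[float, float] = (0.5, 2.0),
    duration_s: tuple[float, float] = (0.3, 0.8),
) -> list[FictiveEpisodeSpec]:
    """Random weak/strong episode schedule from the configured regimes.

    Weak spontaneous episodes beat slowly (15–30 Hz) with amplitudes
    from the weak regime; strong stimulus-like episodes beat fast
    (40–60 Hz) with amplitudes from the strong regime — beat frequencies
    deliberately straddle the 35 Hz fast/slow boundary.  Amplitude
    draws are truncated at ±2.5 SD so that each episode's nominal label
    remains its Bayes-optimal label (an untruncated >3σ weak draw would
    be indistinguishable from a strong swim and its ground-truth label
    operationally meaningless).
    """
    rng = np.random.default_rng(seed)

    def draw(mu, sd):
        x = rng.normal(mu, sd)
        return float(np.clip(x, mu - 2.5 * sd, mu + 2.5 * sd))

    t = rng.uniform(*gap_s)
    out = []
    for _ in range(n_episodes):
        strong = rng.random() < strong_fraction
        if strong:
            amp_mu, amp_sd = config.strong_burst_mean, config.strong_burst_sd
            freq = rng.uniform(40.0, 60.0)
        else:
            amp_mu, amp_sd = config.weak_burst_mean, config.weak_burst_sd
            freq = rng.uniform(15.0, 30.0)
        aL = max(draw(amp_mu, amp_sd), 0.05 * amp_mu)
        aR = max(draw(amp_mu, amp_sd), 0.05 * amp_mu)
        dur = rng.uniform(*duration_s)
        out.append(
            FictiveEpisodeSpec(
                onset_s=t,
                duration_s=dur,
                beat_freq_hz=freq,
                amplitude_L=aL,
                amplitude_R=aR,
                label="strong" if strong else "weak",
            )
        )
        t += dur + rng.uniform(*gap_s)
    return out
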