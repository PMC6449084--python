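"""Configuration for the synthetic-data generators.

The defaults define the study conditions emulated throughout the test
suite: spontaneous swims drawn from a three-component first-bend
amplitude mixture (scoot < routine turn < high-angle turn) plus a
separate stimulus-evoked escape cluster, ventral-root burst trains with
distinct weak/strong amplitude regimes and beat frequencies straddling
35 Hz, and GCaMP6s calcium responses with a 0.5 s rise / 2 s decay
kernel.  Mixture weights default to the relative category frequencies
observed in real spontaneous swimming (≈67% scoots, 26% routine turns,
6% high-angle turns); the per-category amplitude means/SDs are free
parameters chosen once for the canonical amplitude ordering with
component overlap small enough that the categories remain separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["CategoryParams", "SynthConfig"]

CATEGORIES = ("scoot", "routine_turn", "high_angle_turn", "escape")


@dataclass
class CategoryParams:
    """Per-category swim-episode statistics.

    ``amp_mean_deg``/``amp_sd_deg`` parameterise the Gaussian first-bend
    amplitude distribution (truncated at 0), ``beat_freq_hz`` the uniform
    tail-beat frequency range and ``n_half_beats`` the inclusive range of
    half-beats (bends) per episode.
    """

    weight: float
    amp_mean_deg: float
    amp_sd_deg: float
    beat_freq_hz: tuple[float, float]
    n_half_beats: tuple[int, int]

    def __post_init__(self):
        if self.amp_sd_deg <= 0:
            raise ValueError("amplitude SD must be positive")
        if self.weight < 0:
            raise ValueError("mixture weight must be non-negative")


def _default_categories() -> dict[str, CategoryParams]:
    return {
        # Spontaneous weights follow the observed category frequencies
        # 3969 : 1565 : 376; escapes occur only in response to a stimulus.
        "scoot": CategoryParams(0.6716, 20.0, 4.5, (26.0, 34.0), (16, 24)),
        "routine_turn": CategoryParams(0.2648, 50.0, 8.0, (30.0, 40.0), (10, 14)),
        "high_angle_turn": CategoryParams(0.0636, 95.0, 11.0, (34.0, 46.0), (8, 12)),
        "escape": CategoryParams(0.0, 155.0, 20.0, (55.0, 70.0), (10, 14)),
    }


@dataclass
class SynthConfig:
    """Defaults for every synthetic generator; see module docstring."""

    categories: dict[str, CategoryParams] = field(default_factory=_default_categories)
    damping_per_beat: float = 0.95  # amplitude decay factor per half-beat
    episode_rate_hz: float = 0.5  # spontaneous episode rate
    min_gap_s: float = 0.4  # enforced quiet time between episodes

    # Video rendering
    pixel_size_mm: float = 0.057
    frame_rate_hz: float = 500.0
    sensor_noise_sd: float = 8.0  # additive i.i.d. noise, intensity units
    background_level: float = 220.0
    fish_length_mm: float = 4.0

    # Fictive ventral-root bursts (windowed-SD amplitude regimes, a.u.)
    weak_burst_mean: float = 1.0
    weak_burst_sd: float = 0.2
    strong_burst_mean: float = 8.0
    strong_burst_sd: float = 1.6
    fictive_noise_sd: float = 0.05
    fictive_fs_hz: float = 6000.0

    # Calcium imaging
    tau_rise_s: float = 0.5
    tau_decay_s: float = 2.0
    cell_snr: float = 5.0  # peak response / voxel noise SD
    volume_rate_hz: float = 2.0
    baseline_f0: float = 100.0

    def __post_init__(self):
        spont = [c for name, c in self.categories.items() if name != "escape"]
        wsum = sum(c.weight for c in spont)
        if abs(wsum - 1.0) > 1e-6:
            raise ValueError(f"spontaneous mixture weights must sum to 1 (got {wsum})")
        if self.weak_burst_mean >= self.strong_burst_mean:
            raise ValueError("weak burst mean must be below strong burst mean")
        if not self.tau_rise_s < self.tau_decay_s:
            raise ValueError("calcium kernel requires tau_rise < tau_decay")
        if not 0 <= self.damping_per_beat <= 1:
            raise ValueError("damping factor must be in [0, 1]")

    @property
    def spontaneous_categories(self) -> list[str]:
        return [name for name in self.categories if name != "escape"]

    @property
    def spontaneous_weights(self) -> list[float]:
        return [self.categories[n].weight for n in self.spontaneous_categories]

    # -- plain-text round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k != "categories"
        }
        data["categories"] = {
            name: {
                "weight": c.weight,
                "amp_mean_deg": c.amp_mean_deg,
                "amp_sd_deg": c.amp_sd_deg,
                "beat_freq_hz": list(c.beat_freq_hz),
                "n_half_beats": list(c.n_half_beats),
            }
            for name, c in self.categories.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cats = {
            name: CategoryParams(
                weight=d["weight"],
                amp_mean_deg=d["amp_mean_deg"],
                amp_sd_deg=d["amp_sd_deg"],
                beat_freq_hz=tuple(d["beat_freq_hz"]),
                n_half_beats=tuple(d["n_half_beats"]),
            )
            for name, d in data.pop("categories").items()
        }
        return cls(categories=cats, **data)
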