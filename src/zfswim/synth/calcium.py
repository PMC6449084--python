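"""Synthetic volumetric calcium movies with known responding voxels.

Responding voxels carry baseline + amplitude × (fictive signal ⊛ GCaMP6s
kernel, unit-peak normalised) sampled at the volume times, plus i.i.d.
Gaussian noise; all other voxels are baseline + noise.  The truth mask
marks responding voxels exactly.  The peak ΔF of a cell equals its
amplitude, so the configured cell SNR (peak response / noise SD) sets
the voxel noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from zfswim.calcium import CalciumMovie, build_regressor
from zfswim.synth.config import SynthConfig

__all__ = ["CellSpec", "make_calcium_movie"]


@dataclass
class CellSpec:
    position: tuple[int, int, int]  # (z, y, x) voxel
    responds_to: str  # key into fictive_signals
    amplitude: float  # peak fluorescence response, intensity units


def make_calcium_movie(
    cell_specs: list[CellSpec],
    fictive_signals: dict[str, tuple[np.ndarray, float]],
    config: SynthConfig,
    seed: int,
    *,
    shape_zyx: tuple[int, int, int] = (4, 50, 50),
    n_volumes: int | None = None,
    noise_sd: float | None = None,
) -> tuple[CalciumMovie, np.ndarray]:
    """Build a T×Z×Y×X movie plus the boolean truth mask of responders.

    ``fictive_signals`` maps a regressor id to (signal, fs).  When
    ``noise_sd`` is None it is set from the mean cell amplitude and the
    configured SNR (noise = amplitude / cell_snr).
    """
    rng = np.random.default_rng(seed)
    vr = config.volume_rate_hz
    sig_len_s = min(len(s) / fs for s, fs in fictive_signals.values()) if fictive_signals else 0.0
    if n_volumes is None:
        n_volumes = int(np.floor(sig_len_s * vr))
    t_vol = np.arange(n_volumes) / vr

    responses = {}
    for key, (sig, fs) in fictive_signals.items():
        conv = build_regressor(
            sig, fs, t_vol, config.tau_rise_s, config.tau_decay_s, standardize=False
        )
        peak = np.abs(conv).max()
        responses[key] = conv / peak if peak > 0 else conv

    Z, Y, X = shape_zyx
    if noise_sd is None:
        amps = [abs(c.amplitude) for c in cell_specs if c.amplitude != 0]
        noise_sd = (np.mean(amps) / config.cell_snr) if amps else 1.0

    data = np.full((n_volumes, Z, Y, X), config.baseline_f0, dtype=float)
    truth = np.zeros((Z, Y, X), dtype=bool)
    for cell in cell_specs:
        z, y, x = cell.position
        if not (0 <= z < Z and 0 <= y < Y and 0 <= x < X):
            raise ValueError(f"cell position {cell.position} outside volume {shape_zyx}")
        if cell.responds_to not in responses:
            raise KeyError(f"unknown fictive signal id {cell.responds_to!r}")
        if cell.amplitude != 0:
            data[:, z, y, x] += cell.amplitude * responses[cell.responds_to]
            truth[z, y, x] = True
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, data.shape)
    return CalciumMovie(data, volume_rate=vr), truth
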