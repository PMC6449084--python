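"""Readers and writers for the pipeline's on-disk formats.

Behaviour movies travel as multi-page TIFF, kinematics and episode/bend
tables as tidy CSV, midlines and ventral-root traces as HDF5
(``/left``, ``/right``, ``/fs`` plus an episode truth table), calcium
movies as 4-D TIFF or HDF5, and configuration/mixture models as YAML.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from zfswim.ephys import FictiveTrace
from zfswim.kinematics import Bend, SwimEpisode
from zfswim.tracking import FrameStack, KinematicsSeries

__all__ = [
    "write_tiff_stack",
    "read_tiff_stack",
    "write_kinematics_csv",
    "read_kinematics_csv",
    "write_midlines_h5",
    "read_midlines_h5",
    "write_episode_tables",
    "read_episode_tables",
    "write_fictive_h5",
    "read_fictive_h5",
    "write_calcium_h5",
    "read_calcium_h5",
    "write_activation_h5",
    "write_mixture_json",
    "read_mixture_json",
]


# -- movies ------------------------------------------------------------------

def write_tiff_stack(path, stack: FrameStack, dtype=np.float32) -> None:
    """Multi-page TIFF; pass ``dtype=np.uint8`` for camera-like 8-bit
    output (values are clipped to [0, 255] and rounded)."""
    frames = stack.frames
    if np.dtype(dtype) == np.uint8:
        frames = np.clip(np.round(frames), 0, 255)
    tifffile.imwrite(path, frames.astype(dtype), photometric="minisblack", metadata={
        "frame_rate_hz": stack.frame_rate, "pixel_size_mm": stack.pixel_size_mm,
    })


def read_tiff_stack(path, frame_rate: float, pixel_size_mm: float) -> FrameStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames, frame_rate=frame_rate, pixel_size_mm=pixel_size_mm)


# -- kinematics --------------------------------------------------------------

def write_kinematics_csv(path, kin: KinematicsSeries) -> None:
    pd.DataFrame({
        "t_s": kin.t,
        "head_x_mm": kin.head_xy[:, 0],
        "head_y_mm": kin.head_xy[:, 1],
        "body_x_mm": kin.body_xy[:, 0],
        "body_y_mm": kin.body_xy[:, 1],
        "phi_H_deg": kin.phi_H,
        "K_deg": kin.K,
    }).to_csv(path, index=False)


def read_kinematics_csv(path) -> KinematicsSeries:
    df = pd.read_csv(path)
    return KinematicsSeries(
        t=df["t_s"].to_numpy(),
        K=df["K_deg"].to_numpy(),
        phi_H=df["phi_H_deg"].to_numpy(),
        head_xy=df[["head_x_mm", "head_y_mm"]].to_numpy(),
        body_xy=df[["body_x_mm", "body_y_mm"]].to_numpy(),
    )


def write_midlines_h5(path, midlines: np.ndarray) -> None:
    """T×50×2 midline array (mm) under ``/midlines``."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("midlines", data=np.asarray(midlines, dtype=float))


def read_midlines_h5(path) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh["midlines"][()]


# -- episodes ----------------------------------------------------------------

def write_episode_tables(path_episodes, path_bends, episodes: list[SwimEpisode]) -> None:
    """One row per episode and one row per bend (keyed by episode id)."""
    ep_rows, bend_rows = [], []
    for i, ep in enumerate(episodes):
        ep_rows.append({
            "episode_id": i,
            "onset_s": ep.onset_s,
            "offset_s": ep.offset_s,
            "category": ep.category,
            "n_bends": len(ep.bends),
            "stimulus_time_s": ep.stimulus_time_s,
        })
        for b in ep.bends:
            bend_rows.append({
                "episode_id": i, "n": b.n, "t_peak_s": b.t_peak,
                "amplitude_deg": b.amplitude, "period_s": b.period,
            })
    pd.DataFrame(ep_rows).to_csv(path_episodes, index=False)
    pd.DataFrame(bend_rows).to_csv(path_bends, index=False)


def read_episode_tables(path_episodes, path_bends) -> list[SwimEpisode]:
    eps = pd.read_csv(path_episodes)
    bends = pd.read_csv(path_bends)
    out = []
    for _, row in eps.iterrows():
        sub = bends[bends["episode_id"] == row["episode_id"]].sort_values("n")
        blist = [
            Bend(int(r["n"]), float(r["t_peak_s"]), float(r["amplitude_deg"]), float(r["period_s"]))
            for _, r in sub.iterrows()
        ]
        stim = row["stimulus_time_s"]
        out.append(SwimEpisode(
            onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
            bends=blist, category=str(row["category"]),
            stimulus_time_s=None if pd.isna(stim) else float(stim),
        ))
    return out


# -- fictive traces ----------------------------------------------------------

def write_fictive_h5(path, trace: FictiveTrace, truth: list[dict] | None = None) -> None:
    """Datasets /left, /right, /fs; optional JSON-encoded /truth."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("left", data=trace.left)
        fh.create_dataset("right", data=trace.right)
        fh.create_dataset("fs", data=trace.fs)
        if truth is not None:
            fh.create_dataset("truth", data=json.dumps(truth))


def read_fictive_h5(path) -> tuple[FictiveTrace, list[dict] | None]:
    with h5py.File(path, "r") as fh:
        trace = FictiveTrace(fh["left"][()], fh["right"][()], float(fh["fs"][()]))
        truth = json.loads(fh["truth"][()]) if "truth" in fh else None
    return trace, truth


def read_fictive_csv(path) -> FictiveTrace:
    """Two-column CSV (left, right); sampling rate from a ``# fs=`` header
    line or the default 6 kHz."""
    fs = 6000.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1])
    df = pd.read_csv(path, comment="#")
    return FictiveTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), fs)


# -- calcium -----------------------------------------------------------------

def write_calcium_h5(path, movie) -> None:
    """4-D movie under ``/data`` with volume-rate and voxel-size attrs."""
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("data", data=movie.data.astype(np.float32))
        d.attrs["volume_rate_hz"] = movie.volume_rate
        d.attrs["voxel_size_um"] = movie.voxel_size_um


def read_calcium_h5(path):
    from zfswim.calcium import CalciumMovie

    with h5py.File(path, "r") as fh:
        d = fh["data"]
        return CalciumMovie(d[()], float(d.attrs["volume_rate_hz"]),
                            tuple(d.attrs["voxel_size_um"]))


def write_activation_h5(path, amap, shape_zyx) -> None:
    """Per-regressor β/t/p volumes plus the FDR mask, one group per label."""
    with h5py.File(path, "w") as fh:
        fh.attrs["q"] = amap.q
        for j, label in enumerate(amap.labels):
            g = fh.create_group(label)
            g.create_dataset("beta", data=amap.beta[:, j].reshape(shape_zyx))
            g.create_dataset("t", data=amap.t[:, j].reshape(shape_zyx))
            g.create_dataset("p", data=amap.p[:, j].reshape(shape_zyx))
            if amap.mask is not None:
                g.create_dataset("mask", data=amap.mask[:, j].reshape(shape_zyx))


# -- models ------------------------------------------------------------------

def write_mixture_json(path, model) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def read_mixture_json(path):
    from zfswim.classification import MixtureModel

    with open(path) as fh:
        return MixtureModel.from_dict(json.load(fh))
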