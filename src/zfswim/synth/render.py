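"""Render synthetic fish silhouettes over a noisy background.

Each frame is a flat background plus a fish silhouette darker than the
background (as in transmitted-light behaviour rigs): the head region
(eyes + swim bladder) is darkest and the body brightens toward the tail,
with a body width profile widest near the swim bladder and tapering
caudally.  Independent Gaussian sensor noise is added per pixel and per
frame.  The true 50-point midline of every frame is kept as ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from zfswim.synth.config import SynthConfig
from zfswim.synth.generate import posture_from_state
from zfswim.tracking import FrameStack, KinematicsSeries

__all__ = ["BodyModel", "render_frames", "render_silhouette"]


@dataclass
class BodyModel:
    """Parametric body shape: half-width and intensity vs. arc position.

    ``width_knots``/``intensity_knots`` map normalised arc position
    s ∈ [0, 1] (head → tail) to full body width in mm (for a 4 mm fish;
    widths scale with length) and to fish surface intensity.  The head
    is darkest and widest near the swim bladder (s ≈ 0.15).
    """

    length_mm: float = 4.0
    width_s: tuple = (0.0, 0.10, 0.20, 0.40, 0.70, 1.0)
    width_mm: tuple = (0.45, 0.80, 0.60, 0.35, 0.20, 0.14)
    intensity_s: tuple = (0.0, 0.22, 0.40, 1.0)
    intensity: tuple = (40.0, 45.0, 95.0, 140.0)

    def half_width(self, s: np.ndarray) -> np.ndarray:
        scale = self.length_mm / 4.0
        return 0.5 * scale * np.interp(s, self.width_s, self.width_mm)

    def surface_intensity(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.intensity_s, self.intensity)


def render_silhouette(
    midline_mm: np.ndarray,
    shape: tuple[int, int],
    pixel_size_mm: float,
    body: BodyModel,
    background_level: float,
) -> np.ndarray:
    """Noise-free frame for one posture (H×W, intensity units).

    A pixel belongs to the fish when its distance to the midline
    polyline is below the local body half-width; its intensity is the
    body surface intensity at the nearest arc position.  Edges are
    anti-aliased over one pixel (linear coverage blend), emulating the
    optical blur that real imaging applies at the body outline.
    """
    H, W = shape
    frame = np.full((H, W), background_level, dtype=float)
    pts = np.asarray(midline_mm, dtype=float) / pixel_size_mm  # px, (x, y)
    n = len(pts)
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    s_of_point = arc / arc[-1]
    max_hw = body.half_width(np.linspace(0, 1, 50)).max() / pixel_size_mm

    x0 = int(np.floor(pts[:, 0].min() - max_hw - 2))
    x1 = int(np.ceil(pts[:, 0].max() + max_hw + 3))
    y0 = int(np.floor(pts[:, 1].min() - max_hw - 2))
    y1 = int(np.ceil(pts[:, 1].max() + max_hw + 3))
    if x0 < 0 or y0 < 0 or x1 > W or y1 > H:
        raise ValueError("fish body exits frame bounds")

    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    P = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)  # (M, 2)

    best_d2 = np.full(len(P), np.inf)
    best_s = np.zeros(len(P))
    for i in range(n - 1):
        a, b = pts[i], pts[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        tproj = np.clip(((P - a) @ ab) / denom, 0.0, 1.0)
        closest = a + tproj[:, None] * ab
        d2 = ((P - closest) ** 2).sum(axis=1)
        upd = d2 < best_d2
        best_d2[upd] = d2[upd]
        best_s[upd] = s_of_point[i] + tproj[upd] * (s_of_point[i + 1] - s_of_point[i])

    hw_px = body.half_width(best_s) / pixel_size_mm
    # coverage fraction: 1 well inside, 0 outside, linear over 1 px
    alpha = np.clip(hw_px - np.sqrt(best_d2) + 0.5, 0.0, 1.0)
    vals = frame[y0:y1, x0:x1].ravel()
    fish_val = body.surface_intensity(best_s)
    vals = (1.0 - alpha) * vals + alpha * fish_val
    frame[y0:y1, x0:x1] = vals.reshape(y1 - y0, x1 - x0)
    return frame


def render_frames(
    kin: KinematicsSeries,
    body: BodyModel | None,
    config: SynthConfig,
    seed: int,
    *,
    frame_shape: tuple[int, int] | None = None,
) -> tuple[FrameStack, np.ndarray]:
    """Render a kinematics record into a noisy grayscale movie.

    Returns the :class:`~zfswim.tracking.FrameStack` and the T×50×2
    ground-truth midlines (mm).  Identical consecutive postures reuse
    the cached silhouette, so long stationary recordings render fast.
    """
    rng = np.random.default_rng(seed)
    if body is None:
        body = BodyModel(length_mm=config.fish_length_mm)
    px = config.pixel_size_mm
    T = len(kin.t)
    if frame_shape is None:
        side = int(np.ceil(12.0 / px))
        frame_shape = (side, side)

    frames = np.empty((T,) + frame_shape, dtype=float)
    midlines = np.empty((T, 50, 2))
    cache_key = None
    cached = None
    for i in range(T):
        pose = posture_from_state(kin.head_xy[i], kin.phi_H[i], kin.K[i], body.length_mm)
        midlines[i] = pose
        key = (round(kin.head_xy[i][0], 9), round(kin.head_xy[i][1], 9),
               round(float(kin.phi_H[i]), 9), round(float(kin.K[i]), 9))
        if key != cache_key:
            cached = render_silhouette(pose, frame_shape, px, body, config.background_level)
            cache_key = key
        frames[i] = cached
    if config.sensor_noise_sd > 0:
        frames += rng.normal(0.0, config.sensor_noise_sd, frames.shape)
    stack = FrameStack(frames, frame_rate=config.frame_rate_hz, pixel_size_mm=px)
    return stack, midlines
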