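"""Head, midline and body-curvature tracking from behaviour video.

The pipeline mirrors standard free-swimming assays for larval zebrafish:
a static background is estimated and subtracted, the (dark) fish is
sign-inverted so that the eyes and swim bladder become the brightest
structures, the head is located as the centroid of the brightest blob
after 1 mm Gaussian smoothing, the body is segmented with an iterative
two-class threshold, thinned to a skeleton, refined by intensity-weighted
averaging and resampled with a cubic spline to a 50-point midline.  From
the midline we compute per-point tangent angles, the total body curvature
K (sum of local tangent-angle differences, signed, in degrees) and the
head orientation φ_H (angle of a line fit to the 10 midline points
nearest the head).

Coordinates are (x, y) in mm with the origin at the top-left image corner
and y increasing downward; angles are measured from +x and stored in
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

__all__ = [
    "FrameStack",
    "Midline",
    "KinematicsSeries",
    "FishNotFoundError",
    "BranchingSkeletonError",
    "estimate_background",
    "detect_head",
    "segment_fish",
    "extract_midline",
    "compute_body_angles",
    "compute_head_orientation",
    "track_stack",
]

N_MIDLINE_POINTS = 50


class FishNotFoundError(RuntimeError):
    """No fish-like blob above the automatic threshold in this frame."""


class BranchingSkeletonError(RuntimeError):
    """Skeleton has more than two endpoints after pruning."""

    def __init__(self, n_branches: int):
        self.n_branches = int(n_branches)
        super().__init__(f"branching skeleton: {n_branches} extra branches after pruning")


@dataclass
class FrameStack:
    """A T×H×W grayscale movie with its temporal and spatial calibration."""

    frames: np.ndarray
    frame_rate: float
    pixel_size_mm: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty T×H×W array")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Midline:
    """Exactly 50 ordered midline points in mm, head first."""

    points: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_MIDLINE_POINTS, 2):
            raise ValueError(f"midline must have exactly {N_MIDLINE_POINTS} (x, y) points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("cumulative arc length must be strictly increasing")

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length from the head, in mm (length 50)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class KinematicsSeries:
    """Per-frame kinematic summary of a tracked recording.

    ``K`` is the total body curvature in degrees, ``phi_H`` the head
    orientation in degrees, ``head_xy``/``body_xy`` positions in mm (the
    body point sits just caudal to the swim bladder) and ``local_angles``
    the per-frame 50-vector of cumulative tangent angles along the
    midline (degrees, zero at the head).
    """

    t: np.ndarray
    K: np.ndarray
    phi_H: np.ndarray
    head_xy: np.ndarray
    body_xy: np.ndarray
    local_angles: np.ndarray | None = None
    frame_rate: float = field(default=0.0)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.phi_H = np.asarray(self.phi_H, dtype=float)
        self.head_xy = np.asarray(self.head_xy, dtype=float)
        self.body_xy = np.asarray(self.body_xy, dtype=float)
        n = len(self.t)
        if not (len(self.K) == len(self.phi_H) == len(self.head_xy) == len(self.body_xy) == n):
            raise ValueError("all kinematics arrays must share length T")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.local_angles is not None:
            self.local_angles = np.asarray(self.local_angles, dtype=float)
            if self.local_angles.shape != (n, N_MIDLINE_POINTS):
                raise ValueError("local_angles must be T×50")
        if not self.frame_rate and n > 1:
            self.frame_rate = 1.0 / float(np.median(np.diff(self.t)))


def estimate_background(stack: FrameStack, n_samples: int = 1000) -> np.ndarray:
    """Pixelwise mean of ``n_samples`` temporally uniformly spaced frames."""
    T = stack.n_frames
    if T == 0:
        raise ValueError("empty stack")
    n = min(int(n_samples), T)
    idx = np.unique(np.round(np.linspace(0, T - 1, n)).astype(int))
    return stack.frames[idx].mean(axis=0)


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_head(
    frame: np.ndarray,
    background: np.ndarray,
    pixel_size_mm: float,
    *,
    kernel_width_mm: float = 1.0,
    min_contrast_sd: float = 8.0,
) -> tuple[float, float]:
    """Locate the fish head as the centroid of the brightest blob.

    The background-subtracted frame is sign-inverted (the fish is darker
    than the background, so its eyes and swim bladder become the
    brightest pixels), smoothed with a 2-D Gaussian whose full width is
    ``kernel_width_mm`` (σ = width/2), auto-thresholded with a two-level
    Otsu split keeping the top class, and the connected blob with the
    highest mean intensity is reduced to its pixel centroid.

    Returns (x, y) in mm.  Raises :class:`FishNotFoundError` when no blob
    stands out from the noise floor (e.g. the frame equals the
    background).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != np.shape(background):
        raise ValueError("frame and background must share shape")
    inv = np.asarray(background, dtype=float) - frame
    sigma_px = (kernel_width_mm / 2.0) / pixel_size_mm
    sm = ndimage.gaussian_filter(inv, sigma_px)

    noise = _robust_sd(sm)
    contrast = float(sm.max() - np.median(sm))
    if contrast <= 0 or (noise > 0 and contrast < min_contrast_sd * noise) or (
        noise == 0 and contrast < 1e-12
    ):
        raise FishNotFoundError("no blob above the automatic threshold")
    try:
        thr = threshold_multiotsu(sm, classes=3)[-1]
    except ValueError as err:  # image with too few distinct values
        raise FishNotFoundError("no blob above the automatic threshold") from err
    mask = sm > thr
    if not mask.any():
        raise FishNotFoundError("no blob above the automatic threshold")
    lab = label(mask)
    props = regionprops(lab, intensity_image=sm)
    best = max(props, key=lambda p: p.intensity_mean)
    cy, cx = best.centroid
    return (cx * pixel_size_mm, cy * pixel_size_mm)


def segment_fish(
    frame: np.ndarray,
    background: np.ndarray,
    *,
    max_iter: int = 50,
    tol: float = 0.01,
    min_area_px: int = 30,
    max_area_frac: float = 0.25,
    denoise_sigma_px: float = 0.0,
) -> np.ndarray:
    """Binary fish mask from an iterative two-class intensity split.

    Otsu's threshold on the inverted background-subtracted image (after
    a light Gaussian denoising that stabilises the body outline against
    sensor noise) seeds a Ridler–Calvard style iteration (threshold =
    midpoint of the two class means) that stops once the foreground
    pixel count changes by less than ``tol``; the largest connected
    component is returned.  The goal is to keep as many genuine fish
    pixels as possible while excluding the noise floor.
    """
    work = np.asarray(background, dtype=float) - np.asarray(frame, dtype=float)
    if denoise_sigma_px > 0:
        work = ndimage.gaussian_filter(work, denoise_sigma_px)
    if np.ptp(work) <= 0:
        raise FishNotFoundError("flat image; cannot segment")
    thr = threshold_otsu(work)
    count = int((work > thr).sum())
    for _ in range(max_iter):
        fg = work > thr
        if not fg.any() or fg.all():
            break
        new_thr = 0.5 * (work[fg].mean() + work[~fg].mean())
        new_count = int((work > new_thr).sum())
        if count > 0 and abs(new_count - count) / count < tol:
            thr, count = new_thr, new_count
            break
        thr, count = new_thr, new_count
    mask = work > thr
    lab = label(mask)
    if lab.max() == 0:
        raise FishNotFoundError("no foreground after thresholding")
    sizes = np.bincount(lab.ravel())[1:]
    mask = lab == (np.argmax(sizes) + 1)
    area = int(mask.sum())
    if area < min_area_px or area > max_area_frac * mask.size:
        raise FishNotFoundError(f"segmented area {area} px outside sanity bounds")
    return mask


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    adj: list[list[int]] = [[] for _ in coords]
    for (r, c), i in index.items():
        for dr, dc in _NEIGHBOURS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)
    return coords, adj


def _bfs_farthest(adj, start):
    """Return (farthest node, parent map) for a BFS from ``start``."""
    from collections import deque

    parent = {start: None}
    q = deque([start])
    last = start
    while q:
        u = q.popleft()
        last = u
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                q.append(v)
    return last, parent


def _longest_path(coords, adj):
    """Approximate longest path via double BFS (exact on trees)."""
    a, _ = _bfs_farthest(adj, 0)
    b, parent = _bfs_farthest(adj, a)
    path = [b]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path


def _extend_to_boundary(chain: np.ndarray, mask: np.ndarray, max_px: int = 20) -> np.ndarray:
    """Prolong both chain ends along their local tangents to the mask edge."""
    H, W = mask.shape

    def extension(pts):  # pts ordered outward: pts[0] is the end
        n = min(7, len(pts))
        idx = np.arange(n, dtype=float)
        cr = np.polyfit(idx, pts[:n, 0], 1)
        cc = np.polyfit(idx, pts[:n, 1], 1)
        t = -np.array([cr[0], cc[0]])  # outward direction
        norm = np.linalg.norm(t)
        if norm == 0:
            return np.empty((0, 2))
        t /= norm
        out = []
        p = pts[0].astype(float)
        for _ in range(max_px):
            p = p + t
            r, c = int(round(p[0])), int(round(p[1]))
            if not (0 <= r < H and 0 <= c < W) or not mask[r, c]:
                break
            out.append(p.copy())
        return np.asarray(out)

    head_ext = extension(chain)
    tail_ext = extension(chain[::-1])
    parts = [head_ext[::-1], chain] if len(head_ext) else [chain]
    if len(tail_ext):
        parts.append(tail_ext)
    return np.vstack(parts)


def extract_midline(
    frame: np.ndarray,
    fish_mask: np.ndarray,
    *,
    background: np.ndarray | None = None,
    pixel_size_mm: float = 1.0,
    frame_index: int = 0,
    head_centroid_mm: tuple[float, float] | None = None,
    weight_halfwidth_px: int | None = None,
    weight_halfwidth_mm: float = 0.35,
    prune_px: int = 12,
    tip_trim_px: int = 4,
    knot_spacing_mm: float = 0.9,
    n_points: int = N_MIDLINE_POINTS,
) -> Midline:
    """Thin the fish mask to an ordered, spline-smoothed 50-point midline.

    The binary mask is skeletonised, the skeleton's main chain is taken
    as the longest path between endpoints (side branches shorter than
    ``prune_px`` are ignored; longer ones raise
    :class:`BranchingSkeletonError`), each chain pixel is replaced by the
    intensity-weighted mean of its neighbourhood in the inverted image
    (half-width ``weight_halfwidth_mm``, wide enough to span the body so
    the point recentres on the true cross-section), and a least-squares
    cubic spline (interior knots every ``knot_spacing_mm`` of arc, which
    averages sub-pixel jitter without distorting the bend) is resampled
    at 50 points equally spaced in arc length.  Point 1 is the end
    nearest the head centroid (or the intrinsically brighter end when no
    centroid is supplied).
    """
    from scipy.interpolate import LSQUnivariateSpline, interp1d

    mask = np.asarray(fish_mask, dtype=bool)
    if label(mask).max() != 1:
        raise ValueError("fish_mask must be a single connected component")
    inv = (
        np.asarray(background, dtype=float) - np.asarray(frame, dtype=float)
        if background is not None
        else np.asarray(frame, dtype=float).max() - np.asarray(frame, dtype=float)
    )
    inv = np.clip(inv, 0.0, None)

    skel = skeletonize(mask)
    coords, adj = _skeleton_graph(skel)
    if len(coords) < 4:
        raise ValueError("skeleton too short")
    path = _longest_path(coords, adj)
    n_off = len(coords) - len(path)
    if n_off > prune_px:
        degrees = np.array([len(a) for a in adj])
        n_ends = int((degrees == 1).sum())
        raise BranchingSkeletonError(max(n_ends - 2, 1))
    chain = coords[path].astype(float)  # (m, 2) row, col
    # skeleton tips hook toward mask corners (medial-axis boundary
    # artifact) and stop short of the body ends; drop a few pixels at
    # each end, then extend straight along the end tangents until the
    # mask boundary so the midline spans the body reproducibly
    if tip_trim_px > 0 and len(chain) > 2 * tip_trim_px + 8:
        chain = chain[tip_trim_px:-tip_trim_px]
    chain = _extend_to_boundary(chain, mask)

    # Intensity-weighted sub-pixel refinement: recentre each chain pixel
    # along its local normal using the 1-D intensity centroid across the
    # body.  Restricting the pull to the normal keeps bends and chain
    # ends unbiased (a full 2-D window drags end points into the body).
    w = (
        int(weight_halfwidth_px)
        if weight_halfwidth_px is not None
        else max(int(round(weight_halfwidth_mm / pixel_size_mm)), 1)
    )
    H, W = inv.shape
    chain_f = ndimage.uniform_filter1d(chain.astype(float), size=7, axis=0, mode="nearest")
    tang = np.gradient(chain_f, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(-w, w + 1, dtype=float)
    refined = np.empty((len(chain), 2), dtype=float)
    for i, (r, c) in enumerate(chain):
        samples = np.array([r, c], dtype=float)[:, None] + normal[i][:, None] * offsets
        vals = ndimage.map_coordinates(inv, samples, order=1, mode="constant")
        tot = vals.sum()
        shift = float((vals * offsets).sum() / tot) if tot > 0 else 0.0
        refined[i] = np.array([r, c], dtype=float) + shift * normal[i]

    # Head end: nearest the supplied head centroid, else the brighter end.
    if head_centroid_mm is not None:
        head_rc = np.array([head_centroid_mm[1], head_centroid_mm[0]]) / pixel_size_mm
        if np.linalg.norm(refined[-1] - head_rc) < np.linalg.norm(refined[0] - head_rc):
            refined = refined[::-1]
    else:
        k = max(len(refined) // 5, 1)
        ends = [refined[:k], refined[-k:]]
        bright = [
            np.mean([inv[int(round(r)), int(round(c))] for r, c in e.clip(0, [H - 1, W - 1])])
            for e in ends
        ]
        if bright[1] > bright[0]:
            refined = refined[::-1]

    # Chord-length parameterisation with strictly increasing u.
    u = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(refined, axis=0), axis=1))]
    )
    u, uniq = np.unique(u, return_index=True)
    refined = refined[uniq]
    if len(refined) < 8:
        raise ValueError("too few distinct midline pixels")

    knot_px = knot_spacing_mm / pixel_size_mm
    # at least ~4 data points per knot interval (Schoenberg–Whitney)
    n_knots = max(min(int(u[-1] // knot_px) - 1, (len(u) - 4) // 4), 1)
    knots = np.linspace(u[0], u[-1], n_knots + 2)[1:-1]
    sx = LSQUnivariateSpline(u, refined[:, 1], knots, k=3)
    sy = LSQUnivariateSpline(u, refined[:, 0], knots, k=3)
    u_dense = np.linspace(u[0], u[-1], 20 * n_points)
    xd, yd = sx(u_dense), sy(u_dense)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xd), np.diff(yd)))])
    u_equal = interp1d(arc, u_dense)(np.linspace(0, arc[-1], n_points))
    points_mm = np.column_stack([sx(u_equal), sy(u_equal)]) * pixel_size_mm
    return Midline(points_mm, frame_index=frame_index)


def _endpoint_tangent(p: np.ndarray, n_fit: int = 9) -> np.ndarray:
    """Tangent at p[0] from a quadratic LSQ fit of the first n_fit points.

    Exact (to cubic order) on a smooth arc, and averages sub-pixel noise
    that a 3-point one-sided difference would amplify.
    """
    n = min(n_fit, len(p))
    idx = np.arange(n, dtype=float)
    cx = np.polyfit(idx, p[:n, 0], 2)
    cy = np.polyfit(idx, p[:n, 1], 2)
    return np.array([cx[1], cy[1]])  # d/didx at idx = 0


def _tangent_angles(points: np.ndarray) -> np.ndarray:
    """Tangent angle (radians, unwrapped) at every midline point.

    Central differences in the interior; the two endpoint tangents come
    from local quadratic fits, so that the summed local curvature of a
    circular arc recovers the full subtended angle without amplifying
    endpoint noise.
    """
    p = np.asarray(points, dtype=float)
    d = np.empty_like(p)
    d[1:-1] = p[2:] - p[:-2]
    d[0] = _endpoint_tangent(p)
    d[-1] = -_endpoint_tangent(p[::-1])
    return np.unwrap(np.arctan2(d[:, 1], d[:, 0]))


def compute_body_angles(
    midline: Midline, head_centroid_mm: tuple[float, float] | None = None
) -> tuple[np.ndarray, float]:
    """Cumulative tangent angles along the body and total curvature K.

    Local curvature is the angle difference between adjacent tangent
    vectors along the midline; the cumulative sum starts from the point
    closest to the head centroid (point 1 by the midline convention) and
    K is the signed sum of all local curvatures, in degrees.
    """
    pts = midline.points
    if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) <= 0):
        raise ValueError("degenerate midline with repeated points")
    ang = _tangent_angles(pts)
    local = np.diff(ang)  # 49 local curvatures, radians
    cum = np.concatenate([[0.0], np.cumsum(local)])
    local_angles_deg = np.degrees(cum)
    K_deg = float(local_angles_deg[-1])
    return local_angles_deg, K_deg


def compute_head_orientation(midline: Midline) -> float:
    """Head orientation φ_H in degrees ∈ [0, 360).

    A straight line L is fit (total least squares) to the 10 midline
    points closest to the head; φ_H is the absolute angle of the vector
    from the point on L farthest from the head centroid toward the point
    on L closest to it, i.e. the direction the head points.
    """
    pts = midline.points[:10]
    head = midline.points[0]
    centred = pts - pts.mean(axis=0)
    if np.allclose(centred, 0):
        raise ValueError("first 10 midline points are coincident")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    u = vt[0]
    proj = centred @ u
    on_line = pts.mean(axis=0) + np.outer(proj, u)
    d = np.linalg.norm(on_line - head, axis=1)
    v = on_line[np.argmin(d)] - on_line[np.argmax(d)]
    return float(np.degrees(np.arctan2(v[1], v[0])) % 360.0)


def track_stack(
    stack: FrameStack,
    *,
    background: np.ndarray | None = None,
    body_point_frac: float = 0.35,
    n_background_samples: int = 1000,
) -> tuple[KinematicsSeries, list[Midline | None]]:
    """Run the full per-frame tracking chain over a movie.

    Frames where the fish cannot be found or the skeleton is unusable
    yield NaN rows and a ``None`` midline.  The body point used for
    translation measures sits at ``body_point_frac`` of the midline arc
    length from the head (just caudal to the swim bladder).
    """
    if background is None:
        background = estimate_background(stack, n_background_samples)
    T = stack.n_frames
    px = stack.pixel_size_mm
    K = np.full(T, np.nan)
    phi = np.full(T, np.nan)
    head = np.full((T, 2), np.nan)
    body = np.full((T, 2), np.nan)
    angles = np.full((T, N_MIDLINE_POINTS), np.nan)
    midlines: list[Midline | None] = [None] * T
    body_idx = int(round(body_point_frac * (N_MIDLINE_POINTS - 1)))
    for i in range(T):
        frame = stack.frames[i]
        try:
            hx, hy = detect_head(frame, background, px)
            mask = segment_fish(frame, background)
            ml = extract_midline(
                frame,
                mask,
                background=background,
                pixel_size_mm=px,
                frame_index=i,
                head_centroid_mm=(hx, hy),
            )
        except (FishNotFoundError, BranchingSkeletonError, ValueError):
            continue
        head[i] = (hx, hy)
        body[i] = ml.points[body_idx]
        local, K[i] = compute_body_angles(ml, (hx, hy))
        angles[i] = local
        phi[i] = compute_head_orientation(ml)
        midlines[i] = ml
    t = np.arange(T) / stack.frame_rate
    kin = KinematicsSeries(
        t=t, K=K, phi_H=phi, head_xy=head, body_xy=body, local_angles=angles,
        frame_rate=stack.frame_rate,
    )
    return kin, midlines
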