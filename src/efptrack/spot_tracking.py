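"""Raw-movie front end: rendering, localization and trajectory linking.

Implements the classic sparse single-molecule pipeline: smooth and
zero-base each frame, find local intensity maxima above a user-set
threshold, localize each spot as the intensity-weighted centroid of a
7x7 pixel window (robust to the asymmetric motion blur of a diffusing
emitter, unlike Gaussian fitting), and connect localizations across frames
by nearest-neighbour assignment in the Crocker-Grier spirit.

A synthetic movie renderer (Gaussian PSFs accumulated over substep
positions, Poisson noise, uniform background) makes the front end fully
testable without microscope data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Movie",
    "Localization",
    "LinkConfig",
    "preprocess_frame",
    "detect_peaks",
    "centroid_localize",
    "localize_movie",
    "link_localizations",
    "render_movie",
]


@dataclass
class Movie:
    """Stack of 2D intensity frames with camera geometry metadata."""

    frames: np.ndarray  # (n_frames, ny, nx), non-negative
    pixel_size_nm: float = 160.0
    frame_interval_ms: float = 2.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (n, ny, nx) stack")
        if np.any(f < 0):
            raise ValueError("intensities must be non-negative")
        self.frames = f

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.frames.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, pixel_size_nm: float = 160.0, frame_interval_ms: float = 2.0):
        import tifffile

        return cls(
            frames=tifffile.imread(path),
            pixel_size_nm=pixel_size_nm,
            frame_interval_ms=frame_interval_ms,
        )


@dataclass(frozen=True)
class Localization:
    """One localized spot: frame index, position in µm, summed intensity."""

    frame: int
    x_um: float
    y_um: float
    intensity: float


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters: search radius (µm) and gap memory (frames)."""

    max_displacement: float
    memory: int = 0

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be positive")
        if self.memory != 0:
            raise NotImplementedError("gap closing (memory > 0) is not implemented")


def preprocess_frame(image: np.ndarray, smooth_size: int = 3) -> np.ndarray:
    """Boxcar-smooth and zero-base one frame.

    The image is smoothed with a ``smooth_size`` x ``smooth_size`` boxcar,
    the frame median is subtracted as the background estimate, and negative
    values are clamped to zero.
    """
    img = np.asarray(image, dtype=float)
    sm = ndimage.uniform_filter(img, size=smooth_size, mode="constant")
    out = sm - np.median(sm)
    np.maximum(out, 0.0, out=out)
    return out


def detect_peaks(
    image: np.ndarray, threshold: float, merge_radius: float = 4.0
) -> np.ndarray:
    """Pixel-level peak candidates in a preprocessed frame.

    A peak is a pixel strictly greater than its 8 neighbours with value
    >= threshold.  Peaks closer than ``merge_radius`` pixels are merged,
    keeping the brighter one.  Returns an (n, 2) array of (row, col).
    """
    img = np.asarray(image, dtype=float)
    mx = ndimage.maximum_filter(img, size=3, mode="constant", cval=-np.inf)
    cand = np.argwhere((img >= mx) & (img >= threshold))
    # require a strict maximum: a plateau (equal-valued neighbour) is not a peak
    keep = []
    for r, c in cand:
        window = img[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2]
        if np.sum(window == img[r, c]) == 1:
            keep.append((r, c))
    if not keep:
        return np.empty((0, 2), dtype=int)
    peaks = np.array(keep)
    vals = img[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-vals, kind="stable")
    selected: List[np.ndarray] = []
    for idx in order:
        p = peaks[idx]
        if all(np.hypot(*(p - q)) >= merge_radius for q in selected):
            selected.append(p)
    return np.array(sorted(map(tuple, selected)))


def centroid_localize(
    image: np.ndarray,
    peak: Sequence[int],
    frame: int = 0,
    window: int = 7,
    pixel_size_nm: float = 160.0,
) -> Optional[Localization]:
    """Intensity-weighted centroid over a ``window`` x ``window`` square.

    Operates on the zero-based image; pixel centres sit at integer indices,
    converted to µm at the output.  Returns ``None`` (caller warns) for
    peaks too close to the frame edge; raises if the window has zero total
    intensity.
    """
    img = np.asarray(image, dtype=float)
    h = window // 2
    r, c = int(peak[0]), int(peak[1])
    if r - h < 0 or c - h < 0 or r + h >= img.shape[0] or c + h >= img.shape[1]:
        return None
    win = img[r - h : r + h + 1, c - h : c + h + 1]
    total = win.sum()
    if total <= 0:
        raise ValueError("zero total intensity in centroid window")
    rows, cols = np.mgrid[r - h : r + h + 1, c - h : c + h + 1]
    cy = float((rows * win).sum() / total)
    cx = float((cols * win).sum() / total)
    scale = pixel_size_nm * 1e-3
    return Localization(frame=frame, x_um=cx * scale, y_um=cy * scale, intensity=float(total))


def localize_movie(
    movie: Movie, threshold: float, window: int = 7, smooth_size: int = 3
) -> List[Localization]:
    """Preprocess, detect and localize every frame of a movie."""
    out: List[Localization] = []
    for k, frame in enumerate(movie.frames):
        img = preprocess_frame(frame, smooth_size=smooth_size)
        for peak in detect_peaks(img, threshold):
            loc = centroid_localize(
                img, peak, frame=k, window=window, pixel_size_nm=movie.pixel_size_nm
            )
            if loc is not None:
                out.append(loc)
    return out


def _assign_frame_pair(
    prev: np.ndarray, curr: np.ndarray, max_disp: float
) -> List[tuple[int, int]]:
    """Minimum-cost assignment between two localization sets.

    Solves the optimal one-to-one matching that maximizes the number of
    pairs within ``max_disp`` and, among those, minimizes the total squared
    displacement (the Crocker-Grier objective).  Implemented as a Hungarian
    assignment on an augmented matrix where leaving a point unmatched costs
    ``max_disp**2``.
    """
    from scipy.optimize import linear_sum_assignment

    n, m = len(prev), len(curr)
    if n == 0 or m == 0:
        return []
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
    u = max_disp**2
    big = 1e6 * max(u, d2.max())
    cost = np.full((n + m, n + m), 0.0)
    cost[:n, :m] = np.where(d2 <= u, d2, big)
    cost[:n, m:] = big
    cost[np.arange(n), m + np.arange(n)] = u  # prev i unmatched
    cost[n:, :m] = big
    cost[n + np.arange(m), np.arange(m)] = u  # curr j unmatched
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n and j < m and d2[i, j] <= u
    ]


def link_localizations(
    locs: Sequence[Localization], cfg: LinkConfig, frame_interval: float = 2.0
):
    """Frame-to-frame minimum-cost linking into a TrajectorySet.

    Localizations are grouped by frame; successive frames are matched by
    optimal assignment of squared displacements within
    ``cfg.max_displacement``.  Unmatched localizations start new
    trajectories; with memory 0 a missed frame ends a trajectory.
    """
    import pandas as pd

    from efptrack.traj_stats import TrajectorySet

    if not locs:
        raise ValueError("no localizations to link")
    locs = sorted(locs, key=lambda l: l.frame)
    frames = sorted({l.frame for l in locs})
    by_frame = {f: [l for l in locs if l.frame == f] for f in frames}

    next_id = 0
    rows = []
    active: dict[int, int] = {}  # index within previous frame -> traj_id
    prev_frame = None
    prev_xy = None
    for f in frames:
        cur = by_frame[f]
        cur_xy = np.array([[l.x_um, l.y_um] for l in cur])
        assigned: dict[int, int] = {}
        if prev_frame is not None and f == prev_frame + 1:
            for i, j in _assign_frame_pair(prev_xy, cur_xy, cfg.max_displacement):
                if i in active:
                    assigned[j] = active[i]
        cur_ids = []
        for j, loc in enumerate(cur):
            tid = assigned.get(j)
            if tid is None:
                tid = next_id
                next_id += 1
            cur_ids.append(tid)
            rows.append((tid, f, loc.x_um, loc.y_um))
        active = dict(enumerate(cur_ids))
        prev_frame = f
        prev_xy = cur_xy

    df = pd.DataFrame(rows, columns=["traj_id", "frame", "x_um", "y_um"])
    df.insert(0, "cell_id", "movie")
    # renumber frames per trajectory are already consecutive by construction
    return TrajectorySet(df, frame_interval=frame_interval)


def render_movie(
    positions: np.ndarray,
    shape: tuple[int, int] = (128, 128),
    pixel_size_nm: float = 160.0,
    psf_sigma_nm: float = 130.0,
    photons_per_frame: float = 1000.0,
    background: float = 0.0,
    seed: Optional[int] = 0,
    frame_interval_ms: float = 2.0,
) -> Movie:
    """Render emitter positions into a synthetic camera movie.

    ``positions`` is (n_frames, n_emitters, n_sub, 2) or
    (n_frames, n_emitters, 2) in µm: per-frame substep positions of each
    emitter.  Photons are split equally across substeps (motion blur) and
    rendered as integrated 2D Gaussian PSFs; a uniform background is added
    and Poisson noise applied unless ``seed`` is None.  NaN positions mean
    "emitter dark this frame".
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 3:
        pos = pos[:, :, None, :]
    n_frames, n_emit, n_sub, _ = pos.shape
    ny, nx = shape
    px_um = pixel_size_nm * 1e-3
    sigma_px = psf_sigma_nm / pixel_size_nm
    frames = np.full((n_frames, ny, nx), float(background))
    half = int(np.ceil(4 * sigma_px)) + 1
    from scipy.special import erf

    def _pixel_gauss(center_px: float, n_pix: int, lo: int, hi: int) -> np.ndarray:
        edges = np.arange(lo, hi + 1) - 0.5
        cdf = 0.5 * (1 + erf((edges - center_px) / (np.sqrt(2) * sigma_px)))
        return np.diff(cdf)

    for k in range(n_frames):
        for e in range(n_emit):
            for s in range(n_sub):
                x_um, y_um = pos[k, e, s]
                if np.isnan(x_um):
                    continue
                cx, cy = x_um / px_um, y_um / px_um
                c0, r0 = int(round(cx)), int(round(cy))
                c_lo, c_hi = max(0, c0 - half), min(nx, c0 + half + 1)
                r_lo, r_hi = max(0, r0 - half), min(ny, r0 + half + 1)
                if c_lo >= c_hi or r_lo >= r_hi:
                    continue
                gx = _pixel_gauss(cx, nx, c_lo, c_hi)
                gy = _pixel_gauss(cy, ny, r_lo, r_hi)
                frames[k, r_lo:r_hi, c_lo:c_hi] += (
                    photons_per_frame / n_sub
                ) * np.outer(gy, gx)
    if seed is not None:
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(float)
    return Movie(
        frames=frames, pixel_size_nm=pixel_size_nm, frame_interval_ms=frame_interval_ms
    )
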