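"""Spherocylindrical cell geometry.

An *E. coli* cell is idealized as a spherocylinder: a cylinder of diameter
``d`` capped by two hemispheres, with tip-to-tip length ``L``.  The long
(x) axis is the cell axis with the origin at the cell centre; callers are
expected to supply coordinates already rotated into this frame.

The module provides containment tests, rejection-based confinement of
diffusive steps, uniform volume sampling, and the closed-form axial profile
of a uniformly filled spherocylinder.  The uniform profile is the
"no binding" null against which measured axial distributions are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Spherocylinder",
    "AxialProfile",
    "contains",
    "confine_step",
    "sample_uniform",
    "uniform_axial_profile",
    "scale_axial",
    "read_cell_table",
    "write_axial_profile",
]


class ResamplingLimitError(RuntimeError):
    """Raised when confinement rejection sampling exceeds its draw cap."""


class OutOfCellError(ValueError):
    """Raised when an axial position lies outside the nominal cell."""


@dataclass(frozen=True)
class Spherocylinder:
    """Cylinder of diameter ``diameter`` capped by hemispheres.

    Parameters
    ----------
    total_length : float
        Tip-to-tip length L in µm.
    diameter : float
        Cell diameter d in µm.
    """

    total_length: float
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.total_length < self.diameter:
            raise ValueError("total_length must be >= diameter")

    @property
    def radius(self) -> float:
        """Cylinder/cap radius r_c = d/2 (µm)."""
        return self.diameter / 2.0

    @property
    def cylinder_half_length(self) -> float:
        """Half-length a = (L - d)/2 of the cylindrical section (µm)."""
        return (self.total_length - self.diameter) / 2.0

    @property
    def volume(self) -> float:
        """Total volume (µm^3): cylinder + sphere."""
        a = self.cylinder_half_length
        r = self.radius
        return np.pi * r * r * (2.0 * a) + 4.0 / 3.0 * np.pi * r**3


def contains(cell: Spherocylinder, points: np.ndarray) -> np.ndarray:
    """Inclusive containment test for points of shape (..., 3).

    A point (x, y, z) is inside iff it is within the central cylinder
    (|x| <= a and y^2+z^2 <= r_c^2) or within one of the hemispherical caps
    ((|x|-a)^2 + y^2 + z^2 <= r_c^2 for |x| > a).  Surface points count as
    inside so that confinement resampling cannot loop at machine precision.
    """
    p = np.asarray(points, dtype=float)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    a = cell.cylinder_half_length
    r2 = cell.radius**2
    ax = np.abs(p[..., 0])
    rad2 = p[..., 1] ** 2 + p[..., 2] ** 2
    in_cyl = (ax <= a) & (rad2 <= r2)
    in_cap = (ax > a) & ((ax - a) ** 2 + rad2 <= r2)
    out = in_cyl | in_cap
    return bool(out[0]) if scalar else out


def confine_step(
    cell: Spherocylinder,
    current: np.ndarray,
    step_sampler: Callable[[], np.ndarray],
    max_draws: int = 1000,
) -> np.ndarray:
    """Advance ``current`` by a displacement drawn from ``step_sampler``.

    The whole displacement is redrawn until ``current + delta`` lies inside
    the cell (rejection resampling, which preserves the uniform equilibrium
    distribution).  Raises :class:`ResamplingLimitError` after ``max_draws``
    failed draws — a sign that the step size is incompatible with the
    geometry.
    """
    cur = np.asarray(current, dtype=float)
    for _ in range(max_draws):
        cand = cur + np.asarray(step_sampler(), dtype=float)
        if contains(cell, cand):
            return cand
    raise ResamplingLimitError(
        f"no in-cell step found after {max_draws} draws from {cur}"
    )


def confine_steps_vectorized(
    cell: Spherocylinder,
    current: np.ndarray,
    scale: np.ndarray,
    rng: np.random.Generator,
    max_draws: int = 1000,
) -> np.ndarray:
    """Vectorized confined Gaussian substep for an ensemble.

    ``current`` has shape (n, 3); ``scale`` is the per-walker per-axis
    Gaussian s.d. (shape (n,) or scalar).  Each walker's full 3D step is
    redrawn until it lands inside the cell.
    """
    cur = np.asarray(current, dtype=float)
    n = cur.shape[0]
    scale = np.broadcast_to(np.asarray(scale, dtype=float), (n,))
    out = cur.copy()
    pending = np.ones(n, dtype=bool)
    for _ in range(max_draws):
        idx = np.nonzero(pending)[0]
        if idx.size == 0:
            return out
        delta = rng.normal(0.0, 1.0, size=(idx.size, 3)) * scale[idx, None]
        cand = cur[idx] + delta
        ok = contains(cell, cand)
        out[idx[ok]] = cand[ok]
        pending[idx[ok]] = False
    raise ResamplingLimitError(
        f"{int(pending.sum())} walkers found no in-cell step in {max_draws} draws"
    )


def sample_uniform(cell: Spherocylinder, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. points uniform over the spherocylinder volume.

    Rejection sampling from the bounding box; deterministic given ``seed``.
    Returns an array of shape (n, 3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    half_l = cell.total_length / 2.0
    r = cell.radius
    pts = np.empty((0, 3))
    # bounding-box acceptance is volume / (2L * 4r^2) >= pi/6 ~ 0.52
    while pts.shape[0] < n:
        m = max(int(2.2 * (n - pts.shape[0])) + 16, 32)
        cand = rng.uniform(-1.0, 1.0, size=(m, 3)) * np.array([half_l, r, r])
        pts = np.vstack([pts, cand[contains(cell, cand)]])
    return pts[:n]


@dataclass(frozen=True)
class AxialProfile:
    """Binned axial probability profile on the scaled [-0.5, 0.5] axis.

    ``counts`` is present for measured profiles (None for closed-form ones)
    so that goodness-of-fit statistics can use Poisson errors.
    """

    bin_edges: np.ndarray
    probability: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probability, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges)
        return 0.5 * (e[:-1] + e[1:])


def axial_uniformity_chi2(profile: AxialProfile, cell: Spherocylinder) -> float:
    """Pearson reduced chi-square of a measured profile against the
    uniformly-filled-spherocylinder null (nu = n_bins - 1).

    Requires ``profile.counts``; a homogeneous (non-binding) species should
    give values near 1 while a ribosome-like three-peaked profile gives
    values far above it.
    """
    if profile.counts is None:
        raise ValueError("profile must carry counts")
    c = np.asarray(profile.counts, dtype=float)
    n = c.sum()
    expected = uniform_axial_profile(cell, len(c)).probability * n
    chi2 = float(np.sum((c - expected) ** 2 / expected))
    return chi2 / (len(c) - 1)


def _cap_cdf_segment(cell: Spherocylinder, x0: float, x1: float) -> float:
    """Integral of the cross-section area A(x) over [x0, x1] (unnormalized).

    A(x) = pi r^2 for |x| <= a and pi (r^2 - (|x|-a)^2) in the caps.
    Integrated piecewise in closed form.
    """
    a = cell.cylinder_half_length
    r = cell.radius
    half_l = cell.total_length / 2.0

    def antideriv(x: float) -> float:
        # antiderivative of A, valid piecewise; assembled by splitting at +-a
        x = np.clip(x, -half_l, half_l)
        total = 0.0
        # contribution from [-half_l, x]
        # left cap [-half_l, min(x, -a)]
        xl = min(x, -a)
        if xl > -half_l:
            # substitute u = x + a in (-half_l, -a): A = pi (r^2 - u^2), u in (-r, 0)
            u0, u1 = -half_l + a, xl + a
            total += np.pi * (r * r * (u1 - u0) - (u1**3 - u0**3) / 3.0)
        # cylinder (-a, min(x, a)]
        if x > -a:
            xc = min(x, a)
            total += np.pi * r * r * (xc + a)
        # right cap (a, x]
        if x > a:
            u0, u1 = 0.0, x - a
            total += np.pi * (r * r * (u1 - u0) - (u1**3 - u0**3) / 3.0)
        return total

    return antideriv(x1) - antideriv(x0)


def uniform_axial_profile(cell: Spherocylinder, n_bins: int) -> AxialProfile:
    """Closed-form axial profile of a uniformly filled spherocylinder.

    The axial density is the cross-section area A(x) normalized by the cell
    volume, integrated over ``n_bins`` equal bins of the scaled axis
    x/L in [-0.5, 0.5].
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges_scaled = np.linspace(-0.5, 0.5, n_bins + 1)
    edges_um = edges_scaled * cell.total_length
    mass = np.array(
        [_cap_cdf_segment(cell, edges_um[i], edges_um[i + 1]) for i in range(n_bins)]
    )
    prob = mass / mass.sum()
    return AxialProfile(bin_edges=edges_scaled, probability=prob)


def scale_axial(
    x_positions: Sequence[float] | np.ndarray, cell_length: float
) -> np.ndarray:
    """Scale cell-frame axial positions (µm) to the relative [-0.5, 0.5] axis.

    Positions must already be centred on the cell midpoint.  Values outside
    +-L/2 raise :class:`OutOfCellError` rather than being clipped.
    """
    x = np.asarray(x_positions, dtype=float)
    if np.any(np.abs(x) > cell_length / 2.0):
        raise OutOfCellError("axial position outside +-L/2; not clipping")
    return x / cell_length


def scale_axial_filtered(
    x_positions: np.ndarray, cell_length: float
) -> tuple[np.ndarray, int]:
    """Like :func:`scale_axial` but drops out-of-cell positions with a warning.

    Experimental localizations can fall nominally outside the cell due to
    localization error; they are rejected (not projected) and counted.
    Returns (scaled_positions, n_rejected).
    """
    x = np.asarray(x_positions, dtype=float)
    keep = np.abs(x) <= cell_length / 2.0
    n_rej = int((~keep).sum())
    if n_rej:
        warnings.warn(
            f"dropped {n_rej} localization(s) outside the nominal cell",
            stacklevel=2,
        )
    return x[keep] / cell_length, n_rej


def read_cell_table(path) -> "pd.DataFrame":
    """Read a cell geometry CSV with columns cell_id, length_um, diameter_um."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"cell_id", "length_um", "diameter_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return df


def write_axial_profile(profile: AxialProfile, path) -> None:
    """Write a profile as TSV: scaled_x_bin_center, probability."""
    import pandas as pd

    pd.DataFrame(
        {
            "scaled_x_bin_center": profile.bin_centers,
            "probability": profile.probability,
        }
    ).to_csv(path, sep="\t", index=False)
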