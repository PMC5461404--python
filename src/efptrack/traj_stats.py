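"""Summary statistics of single-particle trajectories.

Turns trajectory tables (experimental or simulated) into the quantities the
two-state analysis fits: the single-step displacement distribution P(r),
the six-step mean distribution P(<r>_6), MSD(tau) curves with diffusion
coefficient and localization-error estimates, per-trajectory diffusion
estimates, and pooled scaled axial distributions.

All displacements are 2D (x, y) over consecutive camera frames; trajectories
with detection gaps must be split upstream so that no gap displacement ever
enters P(r).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from efptrack.cellgeom import AxialProfile, scale_axial_filtered

__all__ = [
    "TrajectorySet",
    "DisplacementDistribution",
    "MSDCurve",
    "filter_by_length",
    "single_step_displacements",
    "mean_six_step",
    "displacement_pdf",
    "msd_curve",
    "d_sigma_from_msd",
    "stepwise_d_selection",
    "pooled_axial_distribution",
]

log = logging.getLogger(__name__)

#: default histogram binning: 25 nm bins; P(r) on [0, 1.2] µm, P(<r>_6) on [0, 0.8]
DEFAULT_BIN_WIDTH = 0.025
DEFAULT_RMAX_SINGLE = 1.2
DEFAULT_RMAX_SIX = 0.8


@dataclass
class TrajectorySet:
    """Trajectory table with columns cell_id, traj_id, frame, x_um, y_um.

    Frames within a trajectory must be strictly increasing and consecutive.
    An optional ``state`` column carries the hidden state of simulated data.
    """

    records: pd.DataFrame
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        required = {"cell_id", "traj_id", "frame", "x_um", "y_um"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        df = self.records.sort_values(["cell_id", "traj_id", "frame"], kind="stable")
        self.records = df.reset_index(drop=True)
        key = self._group_key()
        same = key[1:] == key[:-1]
        dframe = np.diff(self.records["frame"].to_numpy())
        if np.any(same & (dframe != 1)):
            raise ValueError(
                "frames within a trajectory must be consecutive; split gapped "
                "trajectories upstream"
            )

    def _group_key(self) -> np.ndarray:
        df = self.records
        return (
            df["cell_id"].astype(str) + "\x00" + df["traj_id"].astype(str)
        ).to_numpy()

    @property
    def n_trajectories(self) -> int:
        return len(np.unique(self._group_key()))

    def trajectory_lengths(self) -> pd.Series:
        return self.records.groupby(["cell_id", "traj_id"], sort=False).size()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval: float = 2.0) -> "TrajectorySet":
        return cls(pd.read_csv(path), frame_interval=frame_interval)


@dataclass(frozen=True)
class DisplacementDistribution:
    """Binned, normalized displacement histogram with raw counts.

    ``kind`` distinguishes single-step P(r) from six-step-mean P(<r>_6)
    distributions.  Counts are retained so Poisson errors propagate into the
    reduced-chi-square fit statistic.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    kind: str = "single_step"

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")
        if self.kind not in ("single_step", "six_step_mean"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def probability(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_total

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges)
        return 0.5 * (e[:-1] + e[1:])

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "r_bin_center_um": self.bin_centers,
                "count": self.counts,
                "probability": self.probability,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MSDCurve:
    """Mean square displacement versus lag time (lags in ms, MSD in µm²)."""

    lag: np.ndarray
    msd: np.ndarray
    sem: np.ndarray
    n_pairs: np.ndarray


def filter_by_length(trajs: TrajectorySet, min_frames: int = 7) -> TrajectorySet:
    """Keep trajectories with at least ``min_frames`` localizations.

    Seven frames yield the six steps used throughout the analysis; shorter
    trajectories are dropped (count logged).
    """
    sizes = trajs.records.groupby(["cell_id", "traj_id"], sort=False)["frame"].transform(
        "size"
    )
    kept = trajs.records[sizes >= min_frames]
    n_dropped = trajs.n_trajectories - len(
        kept.groupby(["cell_id", "traj_id"], sort=False)
    )
    if n_dropped:
        log.info("filter_by_length dropped %d trajectories (< %d frames)", n_dropped, min_frames)
    return TrajectorySet(kept.reset_index(drop=True), frame_interval=trajs.frame_interval)


def _step_arrays(trajs: TrajectorySet) -> tuple[np.ndarray, np.ndarray]:
    """(step lengths r, trajectory group index per step) for consecutive frames."""
    df = trajs.records
    key = trajs._group_key()
    _, gidx = np.unique(key, return_inverse=True)
    same = gidx[1:] == gidx[:-1]
    dx = np.diff(df["x_um"].to_numpy())
    dy = np.diff(df["y_um"].to_numpy())
    r = np.hypot(dx, dy)[same]
    return r, gidx[1:][same]


def single_step_displacements(trajs: TrajectorySet) -> np.ndarray:
    """All consecutive-frame 2D displacement magnitudes r (µm), pooled."""
    r, _ = _step_arrays(trajs)
    return r


def mean_six_step(trajs: TrajectorySet) -> np.ndarray:
    """Per-trajectory mean of the first six single-step displacements.

    Longer trajectories are truncated to their first six steps; trajectories
    with fewer than six steps are skipped with a warning.
    """
    r, gidx = _step_arrays(trajs)
    out = []
    n_skipped = 0
    for g in np.unique(gidx):
        steps = r[gidx == g]
        if steps.size < 6:
            n_skipped += 1
            continue
        out.append(steps[:6].mean())
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} trajectories with fewer than six steps",
            stacklevel=2,
        )
    return np.asarray(out)


def displacement_pdf(
    values: Sequence[float] | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float = DEFAULT_RMAX_SINGLE,
    kind: str = "single_step",
) -> DisplacementDistribution:
    """Histogram displacement magnitudes into fixed-width bins on [0, r_max).

    Values at or beyond ``r_max`` accumulate in the last bin so that counts
    are conserved and probabilities sum to one.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(v < 0):
        raise ValueError("displacement magnitudes must be non-negative")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    clipped = np.minimum(v, edges[-1] - bin_width * 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    return DisplacementDistribution(
        bin_edges=edges, counts=counts, n_total=int(v.size), kind=kind
    )


def msd_curve(
    trajs: TrajectorySet, max_lag: int = 6, max_frames: Optional[int] = 7
) -> MSDCurve:
    """MSD(tau) over all within-trajectory frame pairs up to ``max_lag``.

    Trajectories are truncated to ``max_frames`` localizations first (the
    analysis convention is six steps; pass None to use full trajectories).
    The error estimate is the standard error of the mean of the squared
    displacements contributing to each lag.
    """
    df = trajs.records
    key = trajs._group_key()
    _, gidx = np.unique(key, return_inverse=True)
    order = np.arange(len(df))
    first = pd.Series(order).groupby(gidx, sort=False).transform("min").to_numpy()
    within = order - first
    keep = (
        within < max_frames if max_frames is not None else np.ones_like(within, bool)
    )
    x = df["x_um"].to_numpy()[keep]
    y = df["y_um"].to_numpy()[keep]
    g = gidx[keep]

    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    sem = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for i, k in enumerate(lags):
        same = g[k:] == g[:-k]
        sq = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2
        sq = sq[same]
        n_pairs[i] = sq.size
        msd[i] = sq.mean() if sq.size else np.nan
        sem[i] = sq.std(ddof=1) / np.sqrt(sq.size) if sq.size > 1 else np.nan
    return MSDCurve(lag=lags * trajs.frame_interval, msd=msd, sem=sem, n_pairs=n_pairs)


def d_sigma_from_msd(curve: MSDCurve) -> tuple[float, float, bool]:
    """Estimate (D, sigma) from the first two MSD points.

    The line through (tau_1, MSD_1) and (tau_2, MSD_2) gives
    D = slope / 4 (µm²/s, with tau in ms a factor 1000 applies) and
    sigma = sqrt(intercept / 4) in nm.  A negative intercept is reported as
    sigma = 0 with the returned flag set.
    """
    if len(curve.lag) < 2:
        raise ValueError("need at least two lags")
    t1, t2 = curve.lag[0], curve.lag[1]
    m1, m2 = curve.msd[0], curve.msd[1]
    slope = (m2 - m1) / (t2 - t1)  # µm² per ms
    intercept = m1 - slope * t1
    D = slope / 4.0 * 1e3  # µm²/s
    clamped = intercept < 0
    sigma_nm = float(np.sqrt(max(intercept, 0.0) / 4.0) * 1e3)
    return float(D), sigma_nm, bool(clamped)


def stepwise_d_selection(
    trajs: TrajectorySet, quantile: float = 0.10
) -> tuple[TrajectorySet, TrajectorySet, tuple[float, float]]:
    """Select the slowest and fastest trajectory subsets by <D>_6.

    Each six-step trajectory gets <D>_6, the mean over its six steps of the
    one-step estimator r_i^2 / (4 dt).  Returns the slowest-``quantile`` and
    fastest-``quantile`` subsets plus the (slow_cutoff, fast_cutoff) values.
    Ties are broken by trajectory order, so the subsets have deterministic
    sizes.
    """
    r, gidx = _step_arrays(trajs)
    dt_s = trajs.frame_interval * 1e-3
    groups = np.unique(gidx)
    d6 = np.full(groups.size, np.nan)
    for j, g in enumerate(groups):
        steps = r[gidx == g][:6]
        if steps.size == 6:
            d6[j] = (steps**2 / (4.0 * dt_s)).mean()
    valid = ~np.isnan(d6)
    groups, d6 = groups[valid], d6[valid]
    n_sel = max(1, int(round(quantile * groups.size)))
    order = np.argsort(d6, kind="stable")
    slow_groups = set(groups[order[:n_sel]])
    fast_groups = set(groups[order[-n_sel:]])
    slow_cut = float(d6[order[n_sel - 1]])
    fast_cut = float(d6[order[-n_sel]])

    key = trajs._group_key()
    _, all_gidx = np.unique(key, return_inverse=True)
    slow_mask = np.isin(all_gidx, list(slow_groups))
    fast_mask = np.isin(all_gidx, list(fast_groups))
    slow = TrajectorySet(
        trajs.records[slow_mask].reset_index(drop=True), trajs.frame_interval
    )
    fast = TrajectorySet(
        trajs.records[fast_mask].reset_index(drop=True), trajs.frame_interval
    )
    return slow, fast, (slow_cut, fast_cut)


def pooled_axial_distribution(
    trajs: TrajectorySet,
    cells: pd.DataFrame,
    length_range: tuple[float, float] = (3.5, 4.5),
    n_bins: int = 40,
    per_molecule: bool = False,
) -> tuple[AxialProfile, int]:
    """Pool scaled axial localizations from cells within a length window.

    ``cells`` is a cell table with cell_id and length_um; x positions are
    assumed centred on each cell's midpoint.  Cells are selected by length
    (the analysis bins cells into 1-µm windows before pooling), each cell's
    axial positions are scaled by its own length to [-0.5, 0.5], and
    localizations nominally outside the cell are dropped with a warning
    count.  Returns (profile, n_rejected).

    With ``per_molecule=True`` only each trajectory's first localization is
    pooled.  Successive localizations of one molecule are strongly
    correlated, so Poisson-error statistics on the all-localization profile
    overstate significance; the per-molecule profile has independent counts
    and is the right input for goodness-of-fit tests against the uniform
    null.
    """
    lengths = cells.set_index("cell_id")["length_um"]
    lo, hi = length_range
    chosen = lengths[(lengths >= lo) & (lengths <= hi)]
    records = trajs.records
    if per_molecule:
        records = records.loc[
            records.groupby(["cell_id", "traj_id"], sort=False)["frame"].idxmin()
        ]
    pooled = []
    n_rej = 0
    for cell_id, L in chosen.items():
        x = records.loc[records["cell_id"] == cell_id, "x_um"].to_numpy()
        if x.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled, rej = scale_axial_filtered(x, L)
        pooled.append(scaled)
        n_rej += rej
    if not pooled:
        raise ValueError("no localizations in the selected length range")
    allx = np.concatenate(pooled)
    edges = np.linspace(-0.5, 0.5, n_bins + 1)
    counts, _ = np.histogram(np.clip(allx, -0.5, 0.5 - 1e-12), bins=edges)
    prob = counts / counts.sum()
    return AxialProfile(bin_edges=edges, probability=prob, counts=counts), n_rej
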