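"""Forward simulator of confined two-state diffusion.

A molecule switches between a ribosome-bound state (diffusion coefficient
``D_slow``) and a free state (``D_fast``) with exponential dwell times
``tau_bound`` and ``tau_free`` (ms).  It diffuses inside a spherocylindrical
cell and is observed every ``frame_interval`` ms as a 2D (x, y) centroid
with motion blur over the exposure and state-dependent dynamic localization
error sigma (nm, per coordinate).

This module is both the synthetic-data generator of the pipeline and the
model generator for the histogram-fitting engine: the fitted model
distributions P_model(r; D) are themselves simulated from here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from efptrack.cellgeom import (
    Spherocylinder,
    confine_steps_vectorized,
    contains,
    sample_uniform,
)

__all__ = [
    "STATE_BOUND",
    "STATE_FREE",
    "TwoStateModel",
    "SimConfig",
    "StatePath",
    "sample_state_path",
    "simulate_trajectory",
    "simulate_ensemble",
    "EnsembleResult",
]

STATE_BOUND = 1
STATE_FREE = 0


def stationary_bound_fraction(tau_free: float, tau_bound: float) -> float:
    """Stationary probability of the bound state, tau_b / (tau_b + tau_f)."""
    return tau_bound / (tau_bound + tau_free)


@dataclass(frozen=True)
class TwoStateModel:
    """Complete kinetic-diffusion parameterization of the two-state scheme.

    Parameters
    ----------
    D_slow, D_fast : float
        Diffusion coefficients (µm²/s) of the bound and free states.
    f_slow : float
        Stationary bound fraction.  When exchange is enabled it must equal
        tau_bound / (tau_bound + tau_free); use :meth:`with_lifetimes` to
        construct consistently.
    tau_free, tau_bound : float or None
        Mean dwell times (ms) of the free and bound states.  ``None`` for a
        static (non-exchanging) model.
    sigma_slow, sigma_fast : float
        Dynamic localization error (nm, per coordinate) applied to observed
        positions in the bound and free states.
    """

    D_slow: float
    D_fast: float
    f_slow: float
    tau_free: Optional[float] = None
    tau_bound: Optional[float] = None
    sigma_slow: float = 50.0
    sigma_fast: float = 75.0

    def __post_init__(self) -> None:
        if not (self.D_fast >= self.D_slow >= 0):
            raise ValueError("require D_fast >= D_slow >= 0")
        if not (0.0 <= self.f_slow <= 1.0):
            raise ValueError("f_slow must lie in [0, 1]")
        if (self.tau_free is None) != (self.tau_bound is None):
            raise ValueError("tau_free and tau_bound must be set together")
        if self.exchange:
            if self.tau_free <= 0 or self.tau_bound <= 0:
                raise ValueError("dwell times must be positive")
            implied = stationary_bound_fraction(self.tau_free, self.tau_bound)
            if abs(self.f_slow - implied) > 1e-9:
                raise ValueError(
                    f"f_slow={self.f_slow} inconsistent with lifetimes "
                    f"(implied {implied}); use TwoStateModel.with_lifetimes"
                )

    @property
    def exchange(self) -> bool:
        return self.tau_free is not None

    @property
    def f_fast(self) -> float:
        return 1.0 - self.f_slow

    @classmethod
    def with_lifetimes(
        cls,
        D_slow: float,
        D_fast: float,
        tau_free: float,
        tau_bound: float,
        sigma_slow: float = 50.0,
        sigma_fast: float = 75.0,
    ) -> "TwoStateModel":
        """Build an exchanging model; f_slow derived from the lifetimes."""
        return cls(
            D_slow=D_slow,
            D_fast=D_fast,
            f_slow=stationary_bound_fraction(tau_free, tau_bound),
            tau_free=tau_free,
            tau_bound=tau_bound,
            sigma_slow=sigma_slow,
            sigma_fast=sigma_fast,
        )

    def static_copy(self) -> "TwoStateModel":
        """Same diffusion/fraction parameters with exchange disabled."""
        return replace(self, tau_free=None, tau_bound=None)


@dataclass(frozen=True)
class SimConfig:
    """Imaging/simulation configuration.

    ``frame_interval`` and ``exposure`` are in ms (continuous illumination:
    exposure equals the frame interval by default).  ``substeps_per_frame``
    sets the Brownian substep grid.

    ``motion_blur`` selects the observation convention.  Off (default), the
    observed position is the instantaneous position at frame start and the
    per-state sigma is a *dynamic* localization error that already folds in
    both photon noise and diffusion blur during the exposure — the
    convention under which the per-condition sigma values (50-90 nm) are
    quoted, and under which free diffusion obeys the exact Rayleigh /
    MSD closed forms.  On, the observed position is the exposure-averaged
    substep mean and sigma should then contain photon noise only (used by
    the photon-level movie renderer, where blur arises physically).
    """

    n_frames: int
    cell: Spherocylinder = field(
        default_factory=lambda: Spherocylinder(total_length=4.0, diameter=0.9)
    )
    frame_interval: float = 2.0
    exposure: float = 2.0
    substeps_per_frame: int = 20
    motion_blur: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.exposure > self.frame_interval + 1e-12:
            raise ValueError("exposure cannot exceed frame_interval")
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")

    @property
    def dt_substep(self) -> float:
        """Substep duration in ms."""
        return self.frame_interval / self.substeps_per_frame

    @property
    def duration(self) -> float:
        """Total simulated time in ms."""
        return (self.n_frames - 1) * self.frame_interval + self.exposure


@dataclass(frozen=True)
class StatePath:
    """Piecewise-constant state history on [0, duration] (times in ms)."""

    start: np.ndarray
    end: np.ndarray
    state: np.ndarray

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """State at times ``t`` (right-open intervals)."""
        idx = np.clip(
            np.searchsorted(self.end, np.asarray(t), side="right"),
            0,
            len(self.state) - 1,
        )
        return self.state[idx]

    @property
    def duration(self) -> float:
        return float(self.end[-1])


def sample_state_path(
    tau_free: float,
    tau_bound: float,
    duration: float,
    seed,
) -> StatePath:
    """Sample one two-state history by exact exponential dwell sampling.

    The initial state is drawn from the stationary distribution
    P(bound) = tau_bound / (tau_bound + tau_free); successive dwell times
    are independent exponentials with the current state's mean.  ``seed``
    may be an int or a numpy Generator.
    """
    if tau_free <= 0 or tau_bound <= 0:
        raise ValueError("dwell times must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_bound = stationary_bound_fraction(tau_free, tau_bound)
    state = STATE_BOUND if rng.random() < p_bound else STATE_FREE
    starts, ends, states = [], [], []
    t = 0.0
    while t < duration:
        mean = tau_bound if state == STATE_BOUND else tau_free
        dwell = rng.exponential(mean)
        starts.append(t)
        ends.append(min(t + dwell, duration))
        states.append(state)
        t += dwell
        state = STATE_FREE if state == STATE_BOUND else STATE_BOUND
    return StatePath(
        start=np.array(starts), end=np.array(ends), state=np.array(states, dtype=np.int8)
    )


def _sample_states_vectorized(
    model: TwoStateModel,
    n_traj: int,
    t_query: np.ndarray,
    duration: float,
    rng: np.random.Generator,
    s0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """States of ``n_traj`` independent walkers at each time in ``t_query``.

    Alternating exponential dwells are drawn in blocks; the state at time t
    is s0 XOR (number of switches before t).  Returns int8 (n_traj, n_query).
    """
    tf, tb = model.tau_free, model.tau_bound
    if s0 is None:
        s0 = (rng.random(n_traj) < model.f_slow).astype(np.int8)  # 1 = bound
    else:
        s0 = np.asarray(s0, dtype=np.int8)
    rate = 1.0 / tf + 1.0 / tb
    k = max(8, int(duration * rate * 0.75) + int(6 * np.sqrt(duration * rate) + 9))
    # mean of dwell j depends on parity relative to s0
    cum = None
    while True:
        parity = (np.arange(k)[None, :] + 0) % 2  # 0 => initial state's dwell
        means = np.where(
            (parity == 0) == (s0[:, None] == STATE_BOUND), tb, tf
        )
        dwells = rng.exponential(1.0, size=(n_traj, k)) * means
        cum = np.cumsum(dwells, axis=1)
        if np.all(cum[:, -1] >= duration):
            break
        k *= 2  # rare: redraw with a longer block
    # global searchsorted trick: offset each row into its own segment
    span = duration + 1.0
    offsets = np.arange(n_traj)[:, None] * (cum[:, -1:].max() + span)
    flat_cum = (cum + offsets).ravel()
    flat_q = (np.asarray(t_query)[None, :] + offsets).ravel()
    n_events = (
        np.searchsorted(flat_cum, flat_q, side="right").reshape(n_traj, -1)
        - np.arange(n_traj)[:, None] * k
    )
    return ((s0[:, None].astype(np.int64) + n_events) % 2).astype(np.int8)


@dataclass
class EnsembleResult:
    """Simulated ensemble: observed 2D positions plus hidden ground truth.

    ``x_obs``/``y_obs`` are (n_traj, n_frames) observed coordinates in µm;
    ``frame_state`` is the majority-occupancy state of each frame
    (1 = bound); ``true_positions`` are the noise-free 3D positions at the
    frame sampling instants; ``bound_occupancy`` is each trajectory's
    fraction of simulated time spent bound (substep resolution).
    """

    x_obs: np.ndarray
    y_obs: np.ndarray
    frame_state: np.ndarray
    true_positions: np.ndarray
    bound_occupancy: np.ndarray
    model: TwoStateModel
    config: SimConfig

    @property
    def n_traj(self) -> int:
        return self.x_obs.shape[0]

    def step_lengths(self) -> np.ndarray:
        """2D single-step displacement magnitudes, shape (n_traj, n_frames-1)."""
        dx = np.diff(self.x_obs, axis=1)
        dy = np.diff(self.y_obs, axis=1)
        return np.hypot(dx, dy)

    def mean_six_step(self) -> np.ndarray:
        """Per-trajectory mean of the first six step lengths (needs >= 7 frames)."""
        r = self.step_lengths()
        if r.shape[1] < 6:
            raise ValueError("need at least 7 frames for six-step means")
        return r[:, :6].mean(axis=1)

    def to_trajectory_set(self, cell_id: str = "sim", traj_id_offset: int = 0):
        """Export as a :class:`efptrack.traj_stats.TrajectorySet`."""
        import pandas as pd

        from efptrack.traj_stats import TrajectorySet

        n_t, n_f = self.x_obs.shape
        df = pd.DataFrame(
            {
                "cell_id": cell_id,
                "traj_id": np.repeat(np.arange(n_t) + traj_id_offset, n_f),
                "frame": np.tile(np.arange(n_f), n_t),
                "x_um": self.x_obs.ravel(),
                "y_um": self.y_obs.ravel(),
                "state": self.frame_state.ravel(),
            }
        )
        return TrajectorySet(df, frame_interval=self.config.frame_interval)


def simulate_ensemble(
    model: TwoStateModel,
    config: SimConfig,
    n_traj: int,
    seed,
    static: bool = False,
    initial_positions: Optional[np.ndarray] = None,
    initial_states: Optional[np.ndarray] = None,
) -> EnsembleResult:
    """Simulate ``n_traj`` independent confined two-state trajectories.

    With ``static=True`` (or a model without lifetimes) each trajectory
    keeps a single state drawn Bernoulli(f_slow).  Brownian substeps with
    per-axis variance 2 D dt are confined to the cell by rejection
    resampling; the observed frame position is the exposure-averaged
    (motion-blurred) substep mean, projected to (x, y), plus Gaussian noise
    with the per-coordinate sigma of the frame's majority state.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; results are
    deterministic given the seed.  ``initial_positions`` (n_traj, 3)
    overrides the default uniform in-cell start (used for spatially
    structured fixtures).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    cell = config.cell
    n_f = config.n_frames
    sub = config.substeps_per_frame
    dt_sub = config.dt_substep
    n_sub_total = (n_f - 1) * sub + max(1, int(round(config.exposure / dt_sub)))
    sub_exposure = max(1, int(round(config.exposure / dt_sub)))

    # --- state per substep interval ---------------------------------------
    if initial_states is not None:
        s0 = np.asarray(initial_states, dtype=np.int8)
        if s0.shape != (n_traj,):
            raise ValueError("initial_states must have shape (n_traj,)")
    else:
        s0 = None
    if static or not model.exchange:
        if s0 is None:
            s0 = (rng.random(n_traj) < model.f_slow).astype(np.int8)
        states = np.repeat(s0[:, None], n_sub_total, axis=1)
    else:
        t_mid = (np.arange(n_sub_total) + 0.5) * dt_sub
        states = _sample_states_vectorized(
            model, n_traj, t_mid, config.duration, rng, s0=s0
        )

    # --- positions ---------------------------------------------------------
    if initial_positions is None:
        pos = sample_uniform(cell, n_traj, seed=ss.spawn(1)[0])
    else:
        pos = np.array(initial_positions, dtype=float)
        if pos.shape != (n_traj, 3):
            raise ValueError("initial_positions must have shape (n_traj, 3)")
        if not np.all(contains(cell, pos)):
            raise ValueError("initial_positions must lie inside the cell")

    scale_by_state = np.array(
        [
            np.sqrt(2.0 * model.D_fast * dt_sub * 1e-3),  # STATE_FREE = 0
            np.sqrt(2.0 * model.D_slow * dt_sub * 1e-3),  # STATE_BOUND = 1
        ]
    )

    # propagate and keep every substep position (n_sub_total + 1 time points)
    path = np.empty((n_traj, n_sub_total + 1, 3))
    path[:, 0] = pos
    for i in range(n_sub_total):
        scale = scale_by_state[states[:, i]]
        pos = confine_steps_vectorized(cell, pos, scale, rng)
        path[:, i + 1] = pos

    frame_starts = np.arange(n_f) * sub
    true_positions = path[:, frame_starts, :].copy()
    frame_state = np.empty((n_traj, n_f), dtype=np.int8)
    x_obs = np.empty((n_traj, n_f))
    y_obs = np.empty((n_traj, n_f))
    for k in range(n_f):
        lo = k * sub
        hi = lo + sub_exposure
        if config.motion_blur:
            x_obs[:, k] = path[:, lo : hi + 1, 0].mean(axis=1)
            y_obs[:, k] = path[:, lo : hi + 1, 1].mean(axis=1)
        else:
            x_obs[:, k] = path[:, lo, 0]
            y_obs[:, k] = path[:, lo, 1]
        frame_state[:, k] = (states[:, lo:hi].mean(axis=1) >= 0.5).astype(np.int8)

    # --- localization noise -------------------------------------------------
    sigma_um = np.where(
        frame_state == STATE_BOUND, model.sigma_slow, model.sigma_fast
    ) * 1e-3
    x_obs = x_obs + rng.normal(0.0, 1.0, size=x_obs.shape) * sigma_um
    y_obs = y_obs + rng.normal(0.0, 1.0, size=y_obs.shape) * sigma_um

    return EnsembleResult(
        x_obs=x_obs,
        y_obs=y_obs,
        frame_state=frame_state,
        true_positions=true_positions,
        bound_occupancy=states.mean(axis=1),
        model=model,
        config=config,
    )


def simulate_trajectory(
    model: TwoStateModel, config: SimConfig, traj_seed: int
) -> EnsembleResult:
    """Simulate a single trajectory (an ensemble of one)."""
    return simulate_ensemble(model, config, n_traj=1, seed=traj_seed)
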