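"""Histogram-based inference of two-state diffusion parameters.

The measured displacement distributions have no closed form because of
confinement, motion blur and state-dependent localization error, so fitting
works against *simulated* model distributions: a library of single-state
P_model(r; D, sigma) histograms built by the forward simulator with the same
binning as the data.  One- and two-state static mixtures are fitted by
exhaustive reduced-chi-square grid search; parameter uncertainties come from
the region of the grid with chi2_nu below a threshold (1.5 by default); and
exchange lifetimes are fitted to P(<r>_6) by scanning tau_free with the
tau_free/tau_bound ratio pinned to the static-fit fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from efptrack.kinetic_sim import SimConfig, TwoStateModel, simulate_ensemble
from efptrack.traj_stats import DisplacementDistribution, displacement_pdf

__all__ = [
    "ModelLibrary",
    "StaticFit",
    "KineticFit",
    "ChiSqGrid",
    "build_model_library",
    "reduced_chi_square",
    "fit_static",
    "confidence_region",
    "predict_six_step_static",
    "fit_lifetimes",
    "default_d_grid",
]


def default_d_grid(
    d_min: float = 0.05, d_max: float = 20.0, points_per_decade: int = 25
) -> np.ndarray:
    """Log-spaced diffusion-coefficient search grid (µm²/s)."""
    n = int(np.ceil(np.log10(d_max / d_min) * points_per_decade)) + 1
    return np.logspace(np.log10(d_min), np.log10(d_max), n)


@dataclass
class ModelLibrary:
    """Simulated single-state displacement histograms keyed by (D, sigma).

    All entries share bin edges with the experimental target and carry their
    own counting noise, which enters the chi-square error model.
    """

    entries: Dict[Tuple[float, float], DisplacementDistribution]
    config: SimConfig
    n_traj: int
    seed: int
    kind: str = "single_step"

    def __post_init__(self) -> None:
        edges = None
        for key, dist in self.entries.items():
            if edges is None:
                edges = dist.bin_edges
            elif not np.array_equal(dist.bin_edges, edges):
                raise ValueError(f"entry {key} has mismatched bin edges")

    @property
    def d_values(self) -> np.ndarray:
        return np.unique([d for d, _ in self.entries])

    def sigma_values(self) -> np.ndarray:
        return np.unique([s for _, s in self.entries])

    def get(self, D: float, sigma: float) -> DisplacementDistribution:
        key = min(self.entries, key=lambda k: (abs(k[0] - D), abs(k[1] - sigma)))
        if not (np.isclose(key[0], D) and np.isclose(key[1], sigma)):
            raise KeyError(f"no library entry near (D={D}, sigma={sigma})")
        return self.entries[key]


def build_model_library(
    D_grid: Sequence[float],
    sigma_grid: Sequence[float],
    config: SimConfig,
    n_traj: int,
    seed: int,
    kind: str = "single_step",
    bin_width: float = 0.025,
    r_max: float = 1.2,
) -> ModelLibrary:
    """Simulate a static single-state ensemble for every (D, sigma) pair.

    Each entry is built from at least 10,000 displacement values; ``n_traj``
    is raised if necessary.  Entries are reproducible bit-for-bit given
    ``seed`` (every entry uses its own deterministic child stream, so the
    library does not depend on grid order).
    """
    if len(D_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("grids must be non-empty")
    n_steps_per_traj = 6 if kind == "single_step" else 1
    n_needed = int(np.ceil(10_000 / n_steps_per_traj))
    n_traj = max(n_traj, n_needed)
    entries = {}
    for i, D in enumerate(D_grid):
        for j, sigma in enumerate(sigma_grid):
            model = TwoStateModel(
                D_slow=D, D_fast=D, f_slow=1.0, sigma_slow=sigma, sigma_fast=sigma
            )
            ens = simulate_ensemble(
                model,
                config,
                n_traj=n_traj,
                seed=np.random.SeedSequence([seed, i, j]),
                static=True,
            )
            if kind == "single_step":
                values = ens.step_lengths().ravel()
            else:
                values = ens.mean_six_step()
            entries[(float(D), float(sigma))] = displacement_pdf(
                values, bin_width=bin_width, r_max=r_max, kind=kind
            )
    return ModelLibrary(entries=entries, config=config, n_traj=n_traj, seed=seed, kind=kind)


def _merge_low_count_bins(
    p_exp: np.ndarray,
    p_model: np.ndarray,
    c_exp: np.ndarray,
    c_model: np.ndarray,
    var_model: np.ndarray,
    n_exp: int,
    min_count: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge adjacent bins until each group holds >= min_count counts in the
    experimental histogram and in the model histogram; a deficient tail
    merges into the previous group.  Requiring adequate counts on *both*
    sides keeps the observed-count error model finite in tail bins (an
    observed zero against a well-populated model bin would otherwise get a
    vanishing variance).  Returns (p_exp, p_model, var) per merged group,
    where var is the Poisson variance of the group probability difference.
    """
    groups = []
    acc = None
    for i in range(len(p_exp)):
        row = np.array([p_exp[i], p_model[i], c_exp[i], c_model[i], var_model[i]])
        acc = row if acc is None else acc + row
        if acc[2] >= min_count and acc[3] >= min_count:
            groups.append(acc)
            acc = None
    if acc is not None:
        if groups:
            groups[-1] = groups[-1] + acc
        else:
            groups.append(acc)
    g = np.array(groups)
    var = g[:, 0] / n_exp + g[:, 4]
    return g[:, 0], g[:, 1], var


def reduced_chi_square(
    experimental: DisplacementDistribution,
    model: DisplacementDistribution,
    n_free_params: int,
    model_probability: Optional[np.ndarray] = None,
    model_prob_variance: Optional[np.ndarray] = None,
    model_counts: Optional[np.ndarray] = None,
) -> float:
    """Reduced chi-square between two normalized histograms.

    chi2 = sum_i (p_exp,i - p_model,i)^2 / var_i with
    var_i = p_exp,i / n_exp + p_model,i / n_model, the Poisson errors of
    both normalized histograms; bins where both expected counts are below 5
    are merged into neighbours before summing.  nu = n_groups -
    n_free_params - 1 (the -1 accounts for normalization).

    The ``model_*`` overrides let a caller supply a mixture probability with
    its exactly propagated variance while ``model`` provides the binning and
    approximate counts used for the merge rule.
    """
    if not np.array_equal(experimental.bin_edges, model.bin_edges):
        raise ValueError("experimental and model histograms must share bin edges")
    p_exp = experimental.probability
    c_exp = np.asarray(experimental.counts, dtype=float)
    if model_probability is None:
        p_model = model.probability
        var_model = p_model / model.n_total
        c_model = np.asarray(model.counts, dtype=float)
    else:
        p_model = np.asarray(model_probability, dtype=float)
        var_model = np.asarray(model_prob_variance, dtype=float)
        c_model = np.asarray(model_counts, dtype=float)
    pe, pm, var = _merge_low_count_bins(
        p_exp, p_model, c_exp, c_model, var_model, experimental.n_total
    )
    nu = len(pe) - n_free_params - 1
    if nu <= 0:
        raise ValueError(f"non-positive degrees of freedom (nu={nu})")
    ok = var > 0
    chi2 = float(np.sum((pe[ok] - pm[ok]) ** 2 / var[ok]))
    return chi2 / nu


@dataclass
class ChiSqGrid:
    """Reduced-chi-square values over a labelled parameter grid.

    ``axes`` maps parameter names to 1D grids; ``chi2_nu`` has one dimension
    per axis in insertion order.  Grid cells excluded by constraints (e.g.
    D_slow > D_fast) hold +inf.
    """

    axes: Dict[str, np.ndarray]
    chi2_nu: np.ndarray

    def min_index(self) -> tuple[int, ...]:
        return np.unravel_index(np.argmin(self.chi2_nu), self.chi2_nu.shape)

    def to_tsv(self, path) -> None:
        import pandas as pd

        names = list(self.axes)
        mesh = np.meshgrid(*self.axes.values(), indexing="ij")
        df = pd.DataFrame({n: m.ravel() for n, m in zip(names, mesh)})
        df["chi2_nu"] = self.chi2_nu.ravel()
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class StaticFit:
    """Best-fit static (non-exchanging) one- or two-state mixture."""

    n_states: int
    D_slow: float
    D_fast: float
    f_slow: float
    sigma_slow: float
    sigma_fast: float
    chi2_nu: float
    constrained: Dict[str, float] = field(default_factory=dict)
    on_boundary: bool = False

    @property
    def f_fast(self) -> float:
        return 1.0 - self.f_slow

    def to_model(self) -> TwoStateModel:
        return TwoStateModel(
            D_slow=self.D_slow,
            D_fast=self.D_fast,
            f_slow=self.f_slow,
            sigma_slow=self.sigma_slow,
            sigma_fast=self.sigma_fast,
        )


def _mixture(slow: DisplacementDistribution, fast: DisplacementDistribution, f: float):
    """Mixture probability, its Poisson variance, and effective counts."""
    p = f * slow.probability + (1 - f) * fast.probability
    var = (f**2) * slow.probability / slow.n_total + ((1 - f) ** 2) * (
        fast.probability / fast.n_total
    )
    c = f * np.asarray(slow.counts, float) + (1 - f) * np.asarray(fast.counts, float)
    return p, var, c


def fit_static(
    experimental: DisplacementDistribution,
    library: ModelLibrary,
    n_states: int = 2,
    D_slow_fixed: Optional[float] = None,
    sigma_slow: Optional[float] = None,
    sigma_fast: Optional[float] = None,
    f_step: float = 0.05,
) -> tuple[StaticFit, ChiSqGrid]:
    """Exhaustive grid-search fit of a static one- or two-state mixture.

    The candidate D values are the library's grid (at ``sigma_slow`` for the
    slow component, ``sigma_fast`` for the fast one); f_slow runs over
    multiples of ``f_step``; D_slow <= D_fast is enforced.  Ties are broken
    toward smaller D_fast, then smaller f_slow.  A minimizer on any grid
    boundary is flagged in the result.
    """
    sigmas = library.sigma_values()
    if sigma_slow is None:
        sigma_slow = float(sigmas[0])
    if sigma_fast is None:
        sigma_fast = float(sigmas[-1])
    d_slow_grid = np.array(
        sorted({d for d, s in library.entries if np.isclose(s, sigma_slow)})
    )
    d_fast_grid = np.array(
        sorted({d for d, s in library.entries if np.isclose(s, sigma_fast)})
    )

    if n_states == 1:
        chi2 = np.full(d_fast_grid.size, np.inf)
        for i, d in enumerate(d_fast_grid):
            chi2[i] = reduced_chi_square(
                experimental, library.get(d, sigma_fast), n_free_params=1
            )
        grid = ChiSqGrid(axes={"D": d_fast_grid}, chi2_nu=chi2)
        i = int(np.argmin(chi2))
        fit = StaticFit(
            n_states=1,
            D_slow=float(d_fast_grid[i]),
            D_fast=float(d_fast_grid[i]),
            f_slow=1.0,
            sigma_slow=sigma_fast,
            sigma_fast=sigma_fast,
            chi2_nu=float(chi2[i]),
            on_boundary=i in (0, d_fast_grid.size - 1),
        )
        return fit, grid

    if n_states != 2:
        raise ValueError("n_states must be 1 or 2")

    constrained = {}
    if D_slow_fixed is not None:
        # snap to nearest available grid value
        d_slow_grid = np.array(
            [d_slow_grid[np.argmin(np.abs(d_slow_grid - D_slow_fixed))]]
        )
        constrained["D_slow"] = float(d_slow_grid[0])

    f_grid = np.round(np.arange(0.0, 1.0 + 1e-9, f_step), 10)
    n_free = 2 if D_slow_fixed is not None else 3

    shape = (d_slow_grid.size, d_fast_grid.size, f_grid.size)
    chi2 = np.full(shape, np.inf)
    slow_dists = {d: library.get(d, sigma_slow) for d in d_slow_grid}
    fast_dists = {d: library.get(d, sigma_fast) for d in d_fast_grid}

    best = None  # (chi2, j_fast, k_f, i_slow) in tie-break precedence order
    for j, df_ in enumerate(d_fast_grid):
        for k, f in enumerate(f_grid):
            for i, ds in enumerate(d_slow_grid):
                if ds > df_:
                    continue
                p, var, c = _mixture(slow_dists[ds], fast_dists[df_], f)
                val = reduced_chi_square(
                    experimental,
                    fast_dists[df_],
                    n_free_params=n_free,
                    model_probability=p,
                    model_prob_variance=var,
                    model_counts=c,
                )
                chi2[i, j, k] = val
                if best is None or val < best[0]:
                    best = (val, j, k, i)

    val, j, k, i = best
    on_boundary = (
        (d_slow_grid.size > 1 and i in (0, d_slow_grid.size - 1))
        or j in (0, d_fast_grid.size - 1)
        or k in (0, f_grid.size - 1)
    )
    fit = StaticFit(
        n_states=2,
        D_slow=float(d_slow_grid[i]),
        D_fast=float(d_fast_grid[j]),
        f_slow=float(f_grid[k]),
        sigma_slow=float(sigma_slow),
        sigma_fast=float(sigma_fast),
        chi2_nu=float(val),
        constrained=constrained,
        on_boundary=bool(on_boundary),
    )
    grid = ChiSqGrid(
        axes={"D_slow": d_slow_grid, "D_fast": d_fast_grid, "f_slow": f_grid},
        chi2_nu=chi2,
    )
    return fit, grid


def confidence_region(
    grid: ChiSqGrid, threshold: float = 1.5
) -> Dict[str, tuple[float, float]]:
    """Per-parameter min/max over grid points with chi2_nu <= threshold.

    Mirrors the goodness-of-fit-region method for error bars; raises if no
    grid point is below the threshold (the fit is then inadequate).
    """
    mask = grid.chi2_nu <= threshold
    if not mask.any():
        raise ValueError(
            f"no grid point with chi2_nu <= {threshold}; fit inadequate"
        )
    out = {}
    idx = np.nonzero(mask)
    for axis, (name, values) in enumerate(grid.axes.items()):
        sel = values[idx[axis]]
        out[name] = (float(sel.min()), float(sel.max()))
    return out


def predict_six_step_static(
    fit: StaticFit,
    config: SimConfig,
    n_traj: int,
    seed,
    bin_width: float = 0.025,
    r_max: float = 0.8,
) -> DisplacementDistribution:
    """Simulated P(<r>_6) of the fitted static two-state mixture.

    Delegates to the forward simulator with the static flag, so the result
    is bit-for-bit the ensemble the simulator would produce at these
    parameters and seed.
    """
    if fit.n_states != 2:
        raise ValueError("six-step prediction requires a two-state fit")
    ens = simulate_ensemble(fit.to_model(), config, n_traj=n_traj, seed=seed, static=True)
    return displacement_pdf(
        ens.mean_six_step(), bin_width=bin_width, r_max=r_max, kind="six_step_mean"
    )


@dataclass(frozen=True)
class KineticFit:
    """Best-fit exchange lifetimes at a fixed tau_free/tau_bound ratio."""

    tau_free: float
    tau_bound: float
    chi2_nu: float
    fixed_ratio: float


def default_tau_grid(n_points: int = 12) -> np.ndarray:
    """Log-spaced tau_free grid over 0.1-100 ms."""
    return np.logspace(np.log10(0.1), np.log10(100.0), n_points)


def fit_lifetimes(
    experimental_r6: DisplacementDistribution,
    base: StaticFit,
    tau_grid: Sequence[float],
    config: SimConfig,
    n_traj: int = 15_000,
    seed: int = 0,
    refine: bool = False,
) -> tuple[KineticFit, ChiSqGrid]:
    """Scan tau_free against the six-step-mean distribution.

    The ratio tau_free/tau_bound = f_fast/f_slow is fixed by the static
    fit's fractions (so the stationary bound fraction is preserved at every
    grid point).  For each tau_free an exchange ensemble of ``n_traj``
    trajectories is simulated with common random numbers across grid points
    and compared to ``experimental_r6`` by reduced chi-square with one free
    parameter.  ``refine=True`` adds a x2-resolution pass around the coarse
    minimum.
    """
    if not (0 < base.f_slow < 1):
        raise ValueError("base fit must have an interior f_slow")
    ratio = base.f_fast / base.f_slow
    edges = np.asarray(experimental_r6.bin_edges)
    bin_width = float(edges[1] - edges[0])
    r_max = float(edges[-1])

    def chi2_at(tau_free: float) -> float:
        model = TwoStateModel.with_lifetimes(
            D_slow=base.D_slow,
            D_fast=base.D_fast,
            tau_free=tau_free,
            tau_bound=tau_free / ratio,
            sigma_slow=base.sigma_slow,
            sigma_fast=base.sigma_fast,
        )
        ens = simulate_ensemble(model, config, n_traj=n_traj, seed=seed)
        dist = displacement_pdf(
            ens.mean_six_step(), bin_width=bin_width, r_max=r_max, kind="six_step_mean"
        )
        return reduced_chi_square(experimental_r6, dist, n_free_params=1)

    taus = np.sort(np.asarray(tau_grid, dtype=float))
    chi2 = np.array([chi2_at(t) for t in taus])
    if refine:
        i = int(np.argmin(chi2))
        extra = []
        if i > 0:
            extra.append(np.sqrt(taus[i - 1] * taus[i]))
        if i < taus.size - 1:
            extra.append(np.sqrt(taus[i] * taus[i + 1]))
        if extra:
            extra = np.asarray(extra)
            chi2 = np.concatenate([chi2, [chi2_at(t) for t in extra]])
            taus = np.concatenate([taus, extra])
            order = np.argsort(taus)
            taus, chi2 = taus[order], chi2[order]
    i = int(np.argmin(chi2))
    fit = KineticFit(
        tau_free=float(taus[i]),
        tau_bound=float(taus[i] / ratio),
        chi2_nu=float(chi2[i]),
        fixed_ratio=float(ratio),
    )
    return fit, ChiSqGrid(axes={"tau_free": taus}, chi2_nu=chi2)
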