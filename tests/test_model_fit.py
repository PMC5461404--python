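"""Fitting engine: library building, chi-square, static and lifetime fits."""

import numpy as np
import pytest
from scipy import stats

from efptrack.kinetic_sim import SimConfig, TwoStateModel, simulate_ensemble
from efptrack.model_fit import (
    ChiSqGrid,
    StaticFit,
    build_model_library,
    confidence_region,
    default_tau_grid,
    fit_lifetimes,
    fit_static,
    predict_six_step_static,
    reduced_chi_square,
)
from efptrack.traj_stats import displacement_pdf


@pytest.fixture(scope="module")
def small_library(seven_frame_config):
    """Compact two-sigma library around the wild-type parameter region."""
    d_grid = np.unique(
        np.concatenate(
            [[0.2], np.logspace(np.log10(0.5), np.log10(12.0), 15)]
        )
    )
    return build_model_library(
        d_grid, [50.0, 75.0], seven_frame_config, n_traj=1700, seed=42
    )


def _target_from(model, config, n_traj, seed, static=True):
    ens = simulate_ensemble(model, config, n_traj=n_traj, seed=seed, static=static)
    return displacement_pdf(ens.step_lengths().ravel())


class TestModelLibrary:
    def test_entries_reproducible(self, seven_frame_config):
        kw = dict(config=seven_frame_config, n_traj=1700, seed=1)
        a = build_model_library([1.0], [50.0], **kw)
        b = build_model_library([1.0], [50.0], **kw)
        assert np.array_equal(
            a.entries[(1.0, 50.0)].counts, b.entries[(1.0, 50.0)].counts
        )

    def test_mean_displacement_monotone_in_d(self, small_library):
        slow = small_library.get(0.2, 50.0)
        fast = small_library.get(small_library.d_values[-1], 75.0)
        mean = lambda d: np.sum(d.bin_centers * d.probability)
        assert mean(slow) < mean(fast)

    def test_noise_only_entry_is_rayleigh(self, giant_cell):
        """D = 0 with sigma = 50 nm: displacements are pure localization
        noise, Rayleigh with scale sqrt(2) sigma (unconfined)."""
        cfg = SimConfig(n_frames=7, cell=giant_cell, motion_blur=False)
        lib = build_model_library([0.0], [50.0], cfg, n_traj=1700, seed=2)
        dist = lib.entries[(0.0, 50.0)]
        scale = np.sqrt(2) * 0.050
        edges = np.asarray(dist.bin_edges)
        p_exp = np.diff(stats.rayleigh(scale=scale).cdf(edges))
        p_exp[-1] += 1 - stats.rayleigh(scale=scale).cdf(edges[-1])
        expected = p_exp * dist.n_total
        mask = expected > 5
        chi2_nu = float(
            np.sum((dist.counts[mask] - expected[mask]) ** 2 / expected[mask])
            / (mask.sum() - 1)
        )
        assert chi2_nu < 2.0


class TestReducedChiSquare:
    def test_identical_histograms_give_zero(self):
        rng = np.random.default_rng(3)
        d = displacement_pdf(rng.rayleigh(0.2, 2000))
        assert reduced_chi_square(d, d, 1) == 0.0

    def test_null_distribution_near_one(self, seven_frame_config):
        """Two independent simulations of the same model: chi2_nu in 0.5-1.5."""
        m = TwoStateModel(1.0, 1.0, 1.0, sigma_slow=60.0, sigma_fast=60.0)
        vals = []
        for sa, sb in [(1, 2), (3, 4), (5, 6)]:
            a = _target_from(m, seven_frame_config, 8400, sa)
            b = _target_from(m, seven_frame_config, 8400, sb)
            vals.append(reduced_chi_square(a, b, 1))
        assert all(0.5 < v < 1.5 for v in vals)

    def test_wrong_model_rejected(self, seven_frame_config, efp_static_model):
        """An EF-P-like two-state target against a pure fast one-state model
        gives chi2_nu far above 1 (single-population fits are poor)."""
        target = _target_from(efp_static_model, seven_frame_config, 867, 7)
        wrong = _target_from(
            TwoStateModel(4.3, 4.3, 1.0, sigma_slow=75.0, sigma_fast=75.0),
            seven_frame_config,
            8400,
            8,
        )
        assert reduced_chi_square(target, wrong, 1) > 5.0

    def test_mismatched_binning_raises(self):
        rng = np.random.default_rng(9)
        a = displacement_pdf(rng.rayleigh(0.2, 500), bin_width=0.025)
        b = displacement_pdf(rng.rayleigh(0.2, 500), bin_width=0.05)
        with pytest.raises(ValueError, match="bin edges"):
            reduced_chi_square(a, b, 1)


class TestFitStatic:
    def test_one_state_self_fit(self, small_library, seven_frame_config):
        """A target generated at a library D is recovered by the 1-state fit."""
        d_true = small_library.d_values[6]
        m = TwoStateModel(d_true, d_true, 1.0, sigma_slow=75.0, sigma_fast=75.0)
        target = _target_from(m, seven_frame_config, 3000, 10)
        fit, grid = fit_static(target, small_library, n_states=1, sigma_fast=75.0)
        d_grid = grid.axes["D"]
        i_true = int(np.argmin(np.abs(d_grid - d_true)))
        i_fit = int(np.argmin(np.abs(d_grid - fit.D_fast)))
        assert abs(i_fit - i_true) <= 1

    def test_constrained_efp_recovery(
        self, small_library, seven_frame_config, efp_static_model
    ):
        """With D_slow constrained to 0.2, the fit recovers f_slow within
        0.10 and D_fast within 1.0 µm²/s of (0.30, 4.3)."""
        target = _target_from(efp_static_model, seven_frame_config, 867, 11)
        fit, grid = fit_static(
            target,
            small_library,
            n_states=2,
            D_slow_fixed=0.2,
            sigma_slow=50.0,
            sigma_fast=75.0,
        )
        assert fit.D_slow == pytest.approx(0.2, abs=0.05)
        assert abs(fit.f_slow - 0.30) <= 0.10
        assert abs(fit.D_fast - 4.3) <= 1.0
        region = confidence_region(grid, threshold=1.5)
        lo, hi = region["f_slow"]
        assert lo <= fit.f_slow <= hi

    def test_ribosome_like_unconstrained_recovery(self, seven_frame_config):
        """Unconstrained two-state fit of a ribosome-like target (0.2 / 0.8,
        f_slow 0.65) recovers all three parameters within one grid step."""
        d_grid = np.logspace(np.log10(0.05), np.log10(3.0), 20)
        lib = build_model_library(
            d_grid, [40.0, 75.0], seven_frame_config, n_traj=1700, seed=12
        )
        m = TwoStateModel(0.2, 0.8, 0.65, sigma_slow=40.0, sigma_fast=75.0)
        target = _target_from(m, seven_frame_config, 2634, 13)  # ~15,800 steps
        fit, _ = fit_static(
            target, lib, n_states=2, sigma_slow=40.0, sigma_fast=75.0
        )
        step = np.log10(d_grid[1] / d_grid[0])
        assert abs(np.log10(fit.D_slow / 0.2)) <= 2 * step
        assert abs(np.log10(fit.D_fast / 0.8)) <= 2 * step
        assert abs(fit.f_slow - 0.65) <= 0.10

    def test_mixture_identity_f_zero(self, small_library):
        """f_slow = 0 mixture equals the pure fast library entry exactly."""
        from efptrack.model_fit import _mixture

        slow = small_library.get(0.2, 50.0)
        fast = small_library.get(small_library.d_values[-1], 75.0)
        p, var, c = _mixture(slow, fast, 0.0)
        assert np.array_equal(p, fast.probability)
        assert np.array_equal(c, np.asarray(fast.counts, float))


class TestConfidenceRegion:
    def test_single_point_region(self):
        grid = ChiSqGrid(
            axes={"a": np.array([1.0, 2.0, 3.0])},
            chi2_nu=np.array([5.0, 1.2, 8.0]),
        )
        region = confidence_region(grid, threshold=1.5)
        assert region["a"] == (2.0, 2.0)

    def test_no_subthreshold_point_raises(self):
        grid = ChiSqGrid(axes={"a": np.array([1.0])}, chi2_nu=np.array([9.0]))
        with pytest.raises(ValueError, match="inadequate"):
            confidence_region(grid, threshold=1.5)


class TestSixStepPrediction:
    def test_delegation_matches_simulator(self, seven_frame_config):
        fit = StaticFit(
            n_states=2, D_slow=0.2, D_fast=4.3, f_slow=0.3,
            sigma_slow=50.0, sigma_fast=75.0, chi2_nu=1.0,
        )
        pred = predict_six_step_static(fit, seven_frame_config, 2000, seed=14)
        ens = simulate_ensemble(
            fit.to_model(), seven_frame_config, 2000, seed=14, static=True
        )
        direct = displacement_pdf(
            ens.mean_six_step(), bin_width=0.025, r_max=0.8, kind="six_step_mean"
        )
        assert np.array_equal(pred.counts, direct.counts)

    def test_static_mixture_is_bimodal(self, seven_frame_config):
        """The static 0.3/0.7 mixture of D 0.2 and 4.3 shows two partially
        resolved peaks: the antimode density is well below the lower peak."""
        fit = StaticFit(
            n_states=2, D_slow=0.2, D_fast=4.3, f_slow=0.3,
            sigma_slow=50.0, sigma_fast=75.0, chi2_nu=1.0,
        )
        pred = predict_six_step_static(fit, seven_frame_config, 15_000, seed=15)
        p = pred.probability
        c = pred.bin_centers
        slow_peak = p[(c > 0.02) & (c < 0.11)].max()
        fast_peak = p[(c > 0.15) & (c < 0.35)].max()
        antimode = p[(c > 0.11) & (c < 0.16)].min()
        # partial resolution: a clear dip between the two population modes
        assert antimode < 0.75 * min(slow_peak, fast_peak)

    def test_pure_slow_population_unimodal(self, seven_frame_config):
        fit = StaticFit(
            n_states=2, D_slow=0.2, D_fast=4.3, f_slow=1.0,
            sigma_slow=50.0, sigma_fast=75.0, chi2_nu=1.0,
        )
        pred = predict_six_step_static(fit, seven_frame_config, 5000, seed=16)
        p = pred.probability
        peak = int(np.argmax(p))
        after = p[peak:]
        # monotone decay after the single mode, up to counting noise
        rises = np.diff(after) > 0.01
        assert not rises.any()


@pytest.fixture(scope="module")
def base_fit():
    return StaticFit(
        n_states=2, D_slow=0.2, D_fast=4.3, f_slow=0.30,
        sigma_slow=50.0, sigma_fast=75.0, chi2_nu=1.0,
    )


class TestFitLifetimes:
    def test_recovers_exchange_lifetime(
        self, base_fit, seven_frame_config, efp_model
    ):
        """A tau_free = 16 ms target of the experiment's size lands in the
        11-20 ms bracket."""
        ens = simulate_ensemble(efp_model, seven_frame_config, 859, seed=100)
        target = displacement_pdf(
            ens.mean_six_step(), r_max=0.8, kind="six_step_mean"
        )
        fit, grid = fit_lifetimes(
            target, base_fit, default_tau_grid(12), seven_frame_config,
            n_traj=6000, seed=5,
        )
        assert 11.0 <= fit.tau_free <= 20.0
        assert fit.tau_free / fit.tau_bound == pytest.approx(fit.fixed_ratio)

    def test_static_target_prefers_slow_exchange_limit(
        self, base_fit, seven_frame_config, efp_static_model
    ):
        """A no-exchange target is best fit at the slow-exchange end of the
        grid, and the fast-exchange end fits it worst."""
        ens = simulate_ensemble(
            efp_static_model, seven_frame_config, 859, seed=101, static=True
        )
        target = displacement_pdf(
            ens.mean_six_step(), r_max=0.8, kind="six_step_mean"
        )
        taus = np.array([0.1, 1.0, 10.0, 100.0])
        fit, grid = fit_lifetimes(
            target, base_fit, taus, seven_frame_config, n_traj=6000, seed=6
        )
        assert fit.tau_free == pytest.approx(100.0)
        assert grid.chi2_nu[0] > grid.chi2_nu[-1]

    def test_occupancy_preserved_along_grid(self, base_fit, seven_frame_config):
        """Fixing the lifetime ratio preserves the stationary bound fraction
        at every tau_free."""
        ratio = base_fit.f_fast / base_fit.f_slow
        for tau in [0.5, 5.0, 50.0]:
            m = TwoStateModel.with_lifetimes(
                0.2, 4.3, tau_free=tau, tau_bound=tau / ratio,
                sigma_slow=50.0, sigma_fast=75.0,
            )
            ens = simulate_ensemble(m, seven_frame_config, 4000, seed=17)
            assert abs(ens.bound_occupancy.mean() - base_fit.f_slow) < 0.02
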