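"""Trajectory summary statistics: P(r), P(<r>_6), MSD, selections, axial."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from efptrack.kinetic_sim import SimConfig, TwoStateModel, simulate_ensemble
from efptrack.traj_stats import (
    DisplacementDistribution,
    TrajectorySet,
    d_sigma_from_msd,
    displacement_pdf,
    filter_by_length,
    mean_six_step,
    msd_curve,
    single_step_displacements,
    stepwise_d_selection,
)


def make_trajs(segments, frame_interval=2.0):
    """Build a TrajectorySet from {traj_id: [(x, y), ...]}."""
    rows = []
    for tid, pts in segments.items():
        for k, (x, y) in enumerate(pts):
            rows.append(("c0", tid, k, x, y))
    df = pd.DataFrame(rows, columns=["cell_id", "traj_id", "frame", "x_um", "y_um"])
    return TrajectorySet(df, frame_interval=frame_interval)


class TestTrajectorySet:
    def test_gapped_trajectory_rejected(self):
        df = pd.DataFrame(
            {
                "cell_id": ["c"] * 3,
                "traj_id": [0, 0, 0],
                "frame": [0, 1, 3],
                "x_um": [0.0] * 3,
                "y_um": [0.0] * 3,
            }
        )
        with pytest.raises(ValueError, match="consecutive"):
            TrajectorySet(df)

    def test_roundtrip_csv(self, tmp_path):
        ts = make_trajs({0: [(0, 0), (0.1, 0.1), (0.2, 0.0)]})
        p = tmp_path / "t.csv"
        ts.to_csv(p)
        back = TrajectorySet.from_csv(p)
        pd.testing.assert_frame_equal(
            back.records[["traj_id", "frame", "x_um", "y_um"]],
            ts.records[["traj_id", "frame", "x_um", "y_um"]],
        )


class TestFilterByLength:
    def test_boundary_and_enumeration(self):
        segments = {
            i: [(0.01 * k, 0.0) for k in range(length)]
            for i, length in enumerate(range(3, 13))
        }
        trajs = make_trajs(segments)
        kept = filter_by_length(trajs, min_frames=7)
        lengths = kept.trajectory_lengths()
        assert sorted(lengths) == [7, 8, 9, 10, 11, 12]

    def test_six_frame_dropped_seven_kept(self):
        trajs = make_trajs(
            {
                "six": [(0.0, 0.0)] * 6,
                "seven": [(0.0, 0.0)] * 7,
            }
        )
        kept = filter_by_length(trajs)
        ids = set(kept.records["traj_id"])
        assert ids == {"seven"}


class TestDisplacements:
    def test_static_trajectory_zero_steps(self):
        trajs = make_trajs({0: [(1.0, 1.0)] * 7})
        assert np.allclose(single_step_displacements(trajs), 0.0)

    def test_three_four_five_triangle(self):
        trajs = make_trajs({0: [(0.0, 0.0), (0.3, 0.4)]})
        assert single_step_displacements(trajs)[0] == pytest.approx(0.5)

    def test_step_count_six_per_seven_frame_trajectory(self):
        """859 seven-frame trajectories yield 859 x 6 = 5,154 steps."""
        n = 859
        rng = np.random.default_rng(0)
        segments = {
            i: [tuple(xy) for xy in rng.normal(size=(7, 2)).cumsum(axis=0)]
            for i in range(n)
        }
        trajs = make_trajs(segments)
        assert single_step_displacements(trajs).size == n * 6

    def test_mean_six_step_hand_values(self):
        # steps 0.1..0.6 along x
        xs = np.concatenate([[0.0], np.cumsum([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])])
        trajs = make_trajs({0: [(x, 0.0) for x in xs]})
        assert mean_six_step(trajs)[0] == pytest.approx(0.35)

    def test_truncation_ignores_later_steps(self):
        xs = np.concatenate([[0.0], np.cumsum([0.2] * 12)])
        base = make_trajs({0: [(x, 0.0) for x in xs]})
        perturbed_xs = xs.copy()
        perturbed_xs[8:] += 5.0  # change steps 8+ only
        pert = make_trajs({0: [(x, 0.0) for x in perturbed_xs]})
        assert mean_six_step(base)[0] == pytest.approx(0.2)
        # perturbing beyond the first six steps leaves <r>_6 unchanged except
        # for the single boundary step it touches
        assert mean_six_step(pert)[0] == pytest.approx(mean_six_step(base)[0])

    def test_short_trajectory_skipped_with_warning(self):
        trajs = make_trajs({0: [(0.0, 0.0), (0.1, 0.0), (0.2, 0.0)]})
        with pytest.warns(UserWarning, match="fewer than six"):
            out = mean_six_step(trajs)
        assert out.size == 0


class TestDisplacementPdf:
    def test_single_value_lands_in_its_bin(self):
        dist = displacement_pdf([0.05], bin_width=0.025, r_max=0.2)
        idx = np.nonzero(dist.counts)[0]
        assert len(idx) == 1
        lo, hi = dist.bin_edges[idx[0]], dist.bin_edges[idx[0] + 1]
        assert lo <= 0.05 < hi

    def test_normalization_and_count_conservation(self):
        rng = np.random.default_rng(1)
        v = rng.rayleigh(0.2, size=5000)
        dist = displacement_pdf(v, bin_width=0.025, r_max=0.5)  # forces overflow
        assert dist.counts.sum() == v.size
        assert dist.probability.sum() == pytest.approx(1.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            displacement_pdf([])

    def test_rayleigh_sample_matches_analytic_integral(self):
        """Histogram of a Rayleigh sample matches the per-bin integral of the
        analytic pdf with chi2_nu near 1."""
        scale = 0.1687
        rng = np.random.default_rng(2)
        v = rng.rayleigh(scale, size=100_000)
        dist = displacement_pdf(v, bin_width=0.025, r_max=1.2)
        cdf = stats.rayleigh(scale=scale).cdf
        edges = np.asarray(dist.bin_edges)
        p_exp = np.diff(cdf(edges))
        p_exp[-1] += 1.0 - cdf(edges[-1])
        expected = p_exp * v.size
        mask = expected > 5
        chi2 = np.sum((dist.counts[mask] - expected[mask]) ** 2 / expected[mask])
        chi2_nu = chi2 / (mask.sum() - 1)
        assert 0.5 < chi2_nu < 1.6


class TestMSD:
    def test_frozen_particle_msd_zero(self):
        trajs = make_trajs({0: [(1.0, 2.0)] * 7})
        curve = msd_curve(trajs)
        assert np.allclose(curve.msd, 0.0)

    def test_hand_line_fit(self):
        """MSD {2 ms: 0.018, 4 ms: 0.034} gives D = 2 µm²/s, sigma = 22.4 nm."""
        from efptrack.traj_stats import MSDCurve

        curve = MSDCurve(
            lag=np.array([2.0, 4.0]),
            msd=np.array([0.018, 0.034]),
            sem=np.zeros(2),
            n_pairs=np.array([10, 10]),
        )
        D, sigma_nm, clamped = d_sigma_from_msd(curve)
        assert D == pytest.approx(2.0)
        assert sigma_nm == pytest.approx(np.sqrt(0.002 / 4) * 1e3, rel=1e-6)
        assert not clamped

    def test_pure_noise_curve(self):
        from efptrack.traj_stats import MSDCurve

        sigma_um = 0.05
        curve = MSDCurve(
            lag=np.array([2.0, 4.0]),
            msd=np.full(2, 4 * sigma_um**2),
            sem=np.zeros(2),
            n_pairs=np.array([10, 10]),
        )
        D, sigma_nm, clamped = d_sigma_from_msd(curve)
        assert D == pytest.approx(0.0, abs=1e-12)
        assert sigma_nm == pytest.approx(50.0)

    def test_noise_offset_lifts_curve_by_4_sigma_sq(self, giant_cell):
        cfg = SimConfig(n_frames=7, cell=giant_cell, motion_blur=False)
        quiet = TwoStateModel(1.0, 1.0, 1.0, sigma_slow=0.0, sigma_fast=0.0)
        noisy = TwoStateModel(1.0, 1.0, 1.0, sigma_slow=50.0, sigma_fast=50.0)
        a = msd_curve(
            simulate_ensemble(quiet, cfg, 8000, seed=3, static=True).to_trajectory_set()
        )
        b = msd_curve(
            simulate_ensemble(noisy, cfg, 8000, seed=3, static=True).to_trajectory_set()
        )
        offset = b.msd - a.msd
        assert np.all(np.abs(offset - 0.01) < 0.002)

    def test_concatenation_is_pair_weighted_mean(self):
        rng = np.random.default_rng(4)
        seg_a = {i: [tuple(x) for x in rng.normal(size=(7, 2)).cumsum(0)] for i in range(5)}
        seg_b = {
            i + 10: [tuple(x) for x in (0.2 * rng.normal(size=(7, 2))).cumsum(0)]
            for i in range(3)
        }
        ta, tb = make_trajs(seg_a), make_trajs(seg_b)
        tall = make_trajs({**seg_a, **seg_b})
        ca, cb, call_ = msd_curve(ta), msd_curve(tb), msd_curve(tall)
        weighted = (ca.msd * ca.n_pairs + cb.msd * cb.n_pairs) / (
            ca.n_pairs + cb.n_pairs
        )
        assert np.allclose(call_.msd, weighted)


class TestAveragingNarrows:
    def test_six_step_mean_narrower_than_single_steps(
        self, efp_static_model, seven_frame_config
    ):
        """P(<r>_6) is narrower than P(r): averaging six successive
        displacements shrinks the variance of any population."""
        ens = simulate_ensemble(
            efp_static_model, seven_frame_config, 4000, seed=5, static=True
        )
        r = ens.step_lengths().ravel()
        r6 = ens.mean_six_step()
        assert r6.var() < r.var()


class TestStepwiseSelection:
    def test_counting_with_distinct_values(self):
        rng = np.random.default_rng(6)
        segments = {}
        for i in range(10):
            step = 0.05 * (i + 1)
            xs = np.concatenate([[0.0], np.cumsum([step] * 6)])
            segments[i] = [(x, 0.0) for x in xs]
        trajs = make_trajs(segments)
        slow, fast, (slow_cut, fast_cut) = stepwise_d_selection(trajs, quantile=0.10)
        assert slow.n_trajectories == 1 and fast.n_trajectories == 1
        assert set(slow.records["traj_id"]) == {0}
        assert set(fast.records["traj_id"]) == {9}
        assert slow_cut < fast_cut

    def test_degenerate_identical_trajectories(self):
        xs = np.concatenate([[0.0], np.cumsum([0.1] * 6)])
        segments = {i: [(x, 0.0) for x in xs] for i in range(10)}
        slow, fast, (slow_cut, fast_cut) = stepwise_d_selection(
            make_trajs(segments), quantile=0.10
        )
        assert slow_cut == pytest.approx(fast_cut)
        assert slow.n_trajectories == 1 and fast.n_trajectories == 1

    def test_two_state_ensemble_orders_subsets(
        self, efp_static_model, seven_frame_config
    ):
        """Slowest-decile trajectories have far smaller MSD-derived D than
        the fastest decile in a two-state population."""
        ens = simulate_ensemble(
            efp_static_model, seven_frame_config, 3000, seed=7, static=True
        )
        trajs = ens.to_trajectory_set()
        slow, fast, _ = stepwise_d_selection(trajs, quantile=0.10)
        d_slow, *_ = d_sigma_from_msd(msd_curve(slow))
        d_fast, *_ = d_sigma_from_msd(msd_curve(fast))
        assert d_slow < d_fast / 5
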