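"""Flip-flop nanometry: linking, intervals, tether inference, model fits."""

import numpy as np
import pandas as pd
import pytest

from kinetomech import flipflop, simgen
from kinetomech.simgen import TOWARD_MINUS, TOWARD_PLUS


def _symmetric(d=37.0, noise=10.0, n_cycles=6, seed=0, **kw):
    cfg = simgen.FlipFlopConfig(
        displacement_by_direction=((TOWARD_PLUS, d), (TOWARD_MINUS, d)),
        loc_noise_sd=noise, n_cycles=n_cycles, seed=seed, **kw,
    )
    return simgen.make_flipflop_trajectory(cfg), cfg


class TestLinkTrajectory:
    def test_single_persistent_spot_links_completely(self):
        spots = pd.DataFrame({"frame": range(10), "x_nm": np.arange(10.0), "y_nm": 0.0})
        traj = flipflop.link_trajectory(spots, max_jump=5.0)
        assert len(traj) == 10 and traj.x_nm.notna().all()

    def test_vanishing_spot_leaves_gap_without_false_link(self):
        frames = [0, 1, 2, 6, 7]
        spots = pd.DataFrame({"frame": frames, "x_nm": [0, 1, 2, 6, 7.0], "y_nm": 0.0})
        traj = flipflop.link_trajectory(spots, max_jump=5.0)
        assert traj.x_nm.isna().sum() == 3
        assert traj.set_index("frame").loc[6, "x_nm"] == 6.0

    def test_jump_beyond_max_is_rejected(self):
        spots = pd.DataFrame({"frame": [0, 1], "x_nm": [0.0, 100.0], "y_nm": 0.0})
        traj = flipflop.link_trajectory(spots, max_jump=5.0)
        assert np.isnan(traj.x_nm.iloc[1])

    def test_tracks_simulated_flipflop_within_noise(self):
        (traj_true, sched, truth), cfg = _symmetric(seed=3)
        spots = traj_true.reset_index().rename(columns={"index": "frame"})
        spots["frame"] = np.arange(len(spots))
        linked = flipflop.link_trajectory(
            spots[["frame", "x_nm", "y_nm"]], max_jump=200.0
        )
        assert np.allclose(linked.x_nm, traj_true.x_nm)

    def test_empty_input_gives_empty_trajectory(self):
        out = flipflop.link_trajectory(pd.DataFrame(columns=["frame", "x_nm", "y_nm"]), 5.0)
        assert len(out) == 0


class TestSegmentIntervals:
    def test_noiseless_means_exact(self):
        (traj, sched, truth), cfg = _symmetric(noise=0.0, seed=0)
        ivs = flipflop.segment_intervals(traj, sched)
        u = np.array(sched.flow_axis)
        t = truth.values["tether_xy"]
        for iv in ivs:
            assert (np.asarray(iv.mean_xy) - t) @ u == pytest.approx(iv.sign * 37.0)
            assert iv.n_frames == 60

    def test_interval_sd_matches_noise_within_chisq_bounds(self):
        (traj, sched, _), cfg = _symmetric(seed=8)
        ivs = flipflop.segment_intervals(traj, sched)
        from scipy import stats
        lo = 10.0 * np.sqrt(stats.chi2.ppf(0.0005, 59) / 59)
        hi = 10.0 * np.sqrt(stats.chi2.ppf(0.9995, 59) / 59)
        for iv in ivs:
            assert lo < iv.sd_proj < hi

    def test_zero_exclusion_biases_means_toward_tether(self):
        (traj, sched, truth), cfg = _symmetric(noise=0.0, seed=0)
        with_excl = flipflop.segment_intervals(traj, sched)
        no_excl = flipflop.segment_intervals(traj, sched, exclusion_s=0.0)
        u = np.array(sched.flow_axis)
        t = truth.values["tether_xy"]
        # skip the first epoch (no preceding transit)
        for a, b in zip(with_excl[1:], no_excl[1:]):
            d_a = abs((np.asarray(a.mean_xy) - t) @ u)
            d_b = abs((np.asarray(b.mean_xy) - t) @ u)
            assert d_b < d_a  # transit frames pull the mean toward the tether
            assert d_a == pytest.approx(37.0)

    def test_no_usable_intervals_errors(self):
        (traj, sched, _), cfg = _symmetric(seed=0)
        with pytest.raises(ValueError):
            flipflop.segment_intervals(traj, sched, min_frames=10_000)


class TestTetherInference:
    def test_noiseless_symmetric_exact(self):
        (traj, sched, truth), _ = _symmetric(noise=0.0, seed=0)
        ivs = flipflop.segment_intervals(traj, sched)
        tether, disp = flipflop.infer_tether_and_displacements(ivs, sched.flow_axis)
        assert np.allclose(tether, truth.values["tether_xy"], atol=1e-9)
        assert np.allclose(disp.displacement_nm, 37.0, atol=1e-9)

    def test_asymmetric_noiseless_midpoint_bias_and_exact_sum(self):
        # midpoint tether is biased by (d1-d2)/2 along the flow axis, but
        # the displacement SUM over a flip pair is recovered exactly
        d1, d2 = 39.0, 14.0
        cfg = simgen.FlipFlopConfig(
            displacement_by_direction=((TOWARD_PLUS, d1), (TOWARD_MINUS, d2)),
            loc_noise_sd=0.0, n_cycles=4, seed=0,
        )
        traj, sched, truth = simgen.make_flipflop_trajectory(cfg)
        ivs = flipflop.segment_intervals(traj, sched)
        tether, disp = flipflop.infer_tether_and_displacements(ivs, sched.flow_axis)
        u = np.array(sched.flow_axis)
        bias = (tether - truth.values["tether_xy"]) @ u
        assert bias == pytest.approx((d1 - d2) / 2, abs=1e-9)
        pair_sums = (
            disp.displacement_nm.iloc[::2].to_numpy()
            + disp.displacement_nm.iloc[1::2].to_numpy()
        )
        assert np.allclose(pair_sums, d1 + d2, atol=1e-9)

    def test_external_dna_tether_removes_asymmetry_bias(self):
        d1, d2 = 39.0, 14.0
        cfg = simgen.FlipFlopConfig(
            displacement_by_direction=((TOWARD_PLUS, d1), (TOWARD_MINUS, d2)),
            loc_noise_sd=0.0, n_cycles=4, seed=0,
        )
        traj, sched, truth = simgen.make_flipflop_trajectory(cfg)
        ivs = flipflop.segment_intervals(traj, sched)
        disp = flipflop.displacements_from_tether(
            ivs, truth.values["tether_xy"], sched.flow_axis
        )
        plus = disp[disp.direction == TOWARD_PLUS].displacement_nm
        minus = disp[disp.direction == TOWARD_MINUS].displacement_nm
        assert np.allclose(plus, d1) and np.allclose(minus, d2)

    def test_single_sign_errors(self):
        (traj, sched, _), _ = _symmetric(seed=0)
        ivs = [iv for iv in flipflop.segment_intervals(traj, sched) if iv.sign > 0]
        with pytest.raises(ValueError):
            flipflop.infer_tether_and_displacements(ivs, sched.flow_axis)

    def test_pooled_estimate_within_two_sem(self):
        # 116 intervals at d=37, 10 nm noise: fitted mean within 2 SEM of 37
        (traj, sched, _), _ = _symmetric(n_cycles=58, seed=21)
        ivs = flipflop.segment_intervals(traj, sched)
        _, disp = flipflop.infer_tether_and_displacements(ivs, sched.flow_axis)
        fit = flipflop.fit_displacement_model(disp.displacement_nm.to_numpy(), k=1, seed=0)
        assert abs(fit.means[0] - 37.0) < 2 * fit.sem_means[0] + 0.05


class TestFitDisplacementModel:
    def test_unimodal_sample_selects_single_gaussian(self):
        rng = np.random.default_rng(5)
        x = rng.normal(16, 8, 74)
        fit = flipflop.fit_displacement_model(x, seed=0)
        assert fit.k == 1
        assert abs(fit.means[0] - 16) < 2 * fit.sem_means[0] + 0.5

    def test_mixture_means_recovered_with_k2(self):
        # the Fig-4E-like mixture: recovery within 2 nm when k=2 is fitted
        rng = np.random.default_rng(1)
        n1 = rng.binomial(87, 0.6)
        x = np.concatenate([rng.normal(39, 8, n1), rng.normal(18, 6, 87 - n1)])
        fit = flipflop.fit_displacement_model(x, k=2, seed=0)
        assert fit.k == 2
        assert abs(fit.means[0] - 18) < 2.0
        assert abs(fit.means[1] - 39) < 2.0

    def test_bic_selects_k2_for_well_separated_mixture(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(39, 6, 50), rng.normal(14, 5, 40)])
        fit = flipflop.fit_displacement_model(x, seed=0, n_boot=0)
        assert fit.k == 2 and fit.selected

    def test_identical_components_prefer_k1(self):
        rng = np.random.default_rng(3)
        x = rng.normal(25, 6, 80)
        f1 = flipflop.fit_displacement_model(x, k=1, n_boot=0, seed=0)
        auto = flipflop.fit_displacement_model(x, n_boot=0, seed=0)
        assert auto.k == 1
        assert auto.log_likelihood == pytest.approx(f1.log_likelihood)

    def test_em_likelihood_not_worse_than_sklearn(self):
        # independent cross-check of the in-package EM against sklearn
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(39, 8, 52), rng.normal(18, 6, 35)])
        fit = flipflop.fit_displacement_model(x, k=2, n_boot=0, seed=0)
        gm = sklearn.GaussianMixture(2, n_init=10, random_state=0).fit(x[:, None])
        assert fit.log_likelihood >= gm.score(x[:, None]) * len(x) - 0.5

    def test_minimum_sample_sizes_enforced(self):
        with pytest.raises(ValueError):
            flipflop.fit_displacement_model(np.arange(5.0), k=1)
        with pytest.raises(ValueError):
            flipflop.fit_displacement_model(np.arange(15.0), k=2)


class TestCompareDisplacements:
    def test_delegates_to_ks(self):
        res = flipflop.compare_displacements([1.0, 2, 3], [1.0, 2, 3])
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            flipflop.compare_displacements([1.0], [1.0, 2.0])
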