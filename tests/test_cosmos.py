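"""Spot detection, registration, colocalization, and capture polarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from kinetomech import cosmos, simgen
from kinetomech.simgen import _render


def _camera(rate, background=20.0, read_sd=2.0, seed=0):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate + background).astype(float)
    return counts + rng.normal(0, read_sd, rate.shape)


class TestDetectSpots:
    def test_constant_image_yields_empty_table(self):
        out = cosmos.detect_spots(np.full((64, 64), 7.0))
        assert len(out) == 0

    def test_nonfinite_pixels_rejected(self):
        img = np.zeros((32, 32))
        img[5, 5] = np.nan
        with pytest.raises(ValueError):
            cosmos.detect_spots(img)

    def test_single_spot_localized_to_subpixel(self):
        img = _camera(_render((64, 64), [(10.30, 22.70)], [5000.0], 1.1), seed=1)
        out = cosmos.detect_spots(img, cosmos.DetectionConfig(threshold=50))
        assert len(out) == 1
        assert abs(out.x[0] - 10.30) < 0.2
        assert abs(out.y[0] - 22.70) < 0.2

    def test_two_spots_ten_px_apart_both_found(self):
        img = _camera(
            _render((64, 64), [(20.0, 30.0), (30.0, 30.0)], [5000.0, 5000.0], 1.1),
            seed=2,
        )
        out = cosmos.detect_spots(img, cosmos.DetectionConfig(threshold=50))
        assert len(out) == 2

    def test_recall_and_false_positive_rate_at_high_snr(self):
        # detection on a simulated field: recall >= 0.95, FP <= 0.01/spot
        cfg = simgen.CosmosFieldConfig(field_size=512, n_sites=300, p_coloc=0.0,
                                       false_spot_density=0.0, seed=6)
        (dna, _), truth = simgen.make_cosmos_field(cfg)
        out = cosmos.detect_spots(dna, cosmos.DetectionConfig(threshold=50))
        sites = truth.values["site_xy"]
        d, _ = cKDTree(out[["x", "y"]].to_numpy()).query(sites)
        recall = np.mean(d < 1.0)
        d2, _ = cKDTree(sites).query(out[["x", "y"]].to_numpy())
        false_pos = np.sum(d2 > 2.0)
        assert recall >= 0.95
        assert false_pos / len(sites) <= 0.01


class TestRegistration:
    def test_identity_on_identical_point_sets(self):
        pts = np.random.default_rng(0).uniform(0, 100, (12, 2))
        m = cosmos.fit_registration(pts, pts)
        assert np.allclose(m.matrix(), [[1, 0, 0], [0, 1, 0]], atol=1e-10)
        assert m.residual_rms < 1e-10

    def test_pure_shift_recovered(self):
        pts = np.random.default_rng(1).uniform(0, 100, (20, 2))
        m = cosmos.fit_registration(pts, pts - [2.5, -1.0])
        assert np.allclose(m.matrix()[:, 2], [2.5, -1.0], atol=1e-6)

    def test_noisy_affine_recovered_within_standard_errors(self):
        rng = np.random.default_rng(2)
        A = np.array([[1.002, 0.003, 1.4], [-0.002, 0.998, -0.7]])
        mov = rng.uniform(0, 400, (20, 2))
        ref = mov @ A[:, :2].T + A[:, 2] + rng.normal(0, 0.05, (20, 2))
        m = cosmos.fit_registration(ref, mov)
        # linear-model oracle: coefficient SEs from the design matrix
        X = np.column_stack([mov, np.ones(20)])
        cov = np.linalg.inv(X.T @ X) * 0.05**2
        se = np.sqrt(np.diag(cov))  # per output coordinate
        est = m.matrix()
        for r in range(2):
            assert np.all(np.abs(est[r] - A[r]) < 3 * se[[0, 1, 2]] + 1e-12)

    def test_too_few_or_collinear_fiducials_error(self):
        with pytest.raises(ValueError):
            cosmos.fit_registration([[0, 0], [1, 1]], [[0, 0], [1, 1]])
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            cosmos.fit_registration(line, line)

    def test_round_trip_identity(self):
        m = cosmos.fit_registration(
            np.array([[0.0, 0], [10, 0], [0, 10], [7, 3]]),
            np.array([[1.0, -2], [11.2, -1.8], [0.8, 8.4], [8.1, 1.1]]),
        )
        pts = np.array([[3.3, 4.4], [50.0, -20.0]])
        back = cosmos.apply_registration(m.inverse(), cosmos.apply_registration(m, pts))
        assert np.allclose(back, pts, atol=1e-9)


class TestColocalization:
    def _tables(self, ref_xy, tgt_xy, fov=0):
        ref = pd.DataFrame(ref_xy, columns=["x", "y"]).assign(fov=fov)
        tgt = pd.DataFrame(tgt_xy, columns=["x", "y"]).assign(fov=fov)
        return ref, tgt

    def test_empty_target_gives_zero_fraction(self):
        ref, tgt = self._tables([[10, 10], [20, 20]], np.empty((0, 2)))
        res = cosmos.colocalization_fraction(ref, tgt, radius=1.5)
        assert res.mean_fraction == 0.0

    def test_radius_must_be_positive(self):
        ref, tgt = self._tables([[10, 10]], [[10, 10]])
        with pytest.raises(ValueError):
            cosmos.colocalization_fraction(ref, tgt, radius=0.0)

    def test_one_target_can_satisfy_multiple_references(self):
        ref, tgt = self._tables([[10, 10], [11, 10]], [[10.5, 10]])
        res = cosmos.colocalization_fraction(ref, tgt, radius=1.5)
        assert res.per_fov.n_colocalized[0] == 2

    def test_simulated_fields_within_binomial_interval(self):
        # 9 fields at p=0.40: estimate inside the 95% binomial CI
        det = cosmos.DetectionConfig(threshold=50)
        refs, tgts = [], []
        n_sites = 120
        for fov in range(9):
            cfg = simgen.CosmosFieldConfig(
                field_size=256, n_sites=n_sites, p_coloc=0.40,
                misregistration=((1, 0, 0), (0, 1, 0)), seed=30 + fov,
            )
            (dna, gfp), _ = simgen.make_cosmos_field(cfg)
            refs.append(cosmos.detect_spots(dna, det).assign(fov=fov))
            tgts.append(cosmos.detect_spots(gfp, det).assign(fov=fov))
        res = cosmos.colocalization_fraction(
            pd.concat(refs), pd.concat(tgts), radius=1.5
        )
        n = 9 * n_sites
        half = 1.96 * np.sqrt(0.4 * 0.6 / n)
        assert abs(res.mean_fraction - 0.40) < half + 0.01  # +1% chance-coloc allowance


class TestCapturePolarity:
    def test_dim_attached_end_is_plus(self):
        p = cosmos.FilamentProfile(
            cosmos.EndSegment("dim", 5.0), cosmos.EndSegment("bright", 2.0), "a"
        )
        assert cosmos.classify_capture_polarity(p) == "plus"

    def test_bright_attached_end_is_minus(self):
        p = cosmos.FilamentProfile(
            cosmos.EndSegment("bright", 2.0), cosmos.EndSegment("dim", 5.0), "a"
        )
        assert cosmos.classify_capture_polarity(p) == "minus"

    def test_length_rule_breaks_brightness_tie(self):
        p = cosmos.FilamentProfile(
            cosmos.EndSegment("dim", 6.0), cosmos.EndSegment("dim", 2.0), "a"
        )
        assert cosmos.classify_capture_polarity(p) == "plus"

    def test_fully_ambiguous_is_undetermined(self):
        p = cosmos.FilamentProfile(
            cosmos.EndSegment("dim", 3.0), cosmos.EndSegment("dim", 3.0), "a"
        )
        assert cosmos.classify_capture_polarity(p) == "undetermined"

    def test_summarize_all_plus(self):
        calls = pd.DataFrame({"experiment": [0, 0, 1], "call": ["plus"] * 3})
        s = cosmos.summarize_capture(calls)
        assert s["mean_pct_plus"] == 100.0 and s["sd_pct_plus"] == 0.0

    def test_pooled_percentage_from_counts(self):
        # 162 plus of 196 determined calls -> 82.65% pooled
        calls = pd.DataFrame(
            {"experiment": 0, "call": ["plus"] * 162 + ["minus"] * 34}
        )
        s = cosmos.summarize_capture(calls)
        assert s["pooled_pct_plus"] == pytest.approx(82.6530612, abs=1e-5)

    def test_simulated_experiments_recover_true_rate(self):
        rng = np.random.default_rng(13)
        rows = []
        for e in range(8):
            for _ in range(25):
                rows.append({"experiment": e,
                             "call": "plus" if rng.random() < 0.83 else "minus"})
        s = cosmos.summarize_capture(pd.DataFrame(rows))
        assert abs(s["mean_pct_plus"] - 83.0) < 2 * s["sd_pct_plus"]

    def test_no_determined_calls_errors(self):
        calls = pd.DataFrame({"experiment": [0], "call": ["undetermined"]})
        with pytest.raises(ValueError):
            cosmos.summarize_capture(calls)
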