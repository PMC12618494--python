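"""Segmentation, region linking, blob colocalization and area statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from chromoscope.errors import ConfigurationError, DomainError
from chromoscope.nucleoid import (
    colocalize,
    compare_groups,
    count_clusters,
    detect_blobs,
    dose_response,
    link_regions,
    segment_chromosomes,
    summed_area_series,
)
from chromoscope.simulate import render_nucleoid_stack, simulate_nucleoid_population
from chromoscope.stack import CameraModel

PX = 0.16


def _scene_image(seed, n_chromosomes=1, area=20.0, n_blobs=(4, 4), camera=None):
    camera = camera or CameraModel()
    scenes, truth = simulate_nucleoid_population(
        n_chromosomes, area, 0.0, n_blobs, (0, 0), 0.0, seed=seed
    )
    stack = render_nucleoid_stack(
        scenes, camera, seed=seed + 1000, fov_um=(truth.params["fov_um"],) * 2
    )
    return stack.channel("dna")[0], truth


class TestSegmentation:
    def test_blank_frame_no_regions(self, rng):
        frame = rng.normal(150.0, 12.0, (128, 128))
        regions, labels = segment_chromosomes(frame, PX)
        assert regions == []
        assert labels.max() == 0

    def test_single_chromosome_area_recovery(self):
        """A rendered ~20 um^2 nucleoid segments back within 10% of truth."""
        img, truth = _scene_image(seed=31)
        regions, _ = segment_chromosomes(img, PX)
        assert len(regions) == 1
        assert regions[0].area_um2 == pytest.approx(
            truth.regions["true_area_um2"].iloc[0], rel=0.10
        )

    def test_well_separated_chromosomes_counted(self):
        img, truth = _scene_image(seed=32, n_chromosomes=2)
        regions, _ = segment_chromosomes(img, PX)
        assert len(regions) == 2

    def test_area_recovery_across_compaction_states(self):
        """Open (~20), active-TxTl (~4.8) and compact (~3 um^2) areas recover <10%."""
        for area in (3.0, 4.8, 20.0):
            rel_errors = []
            for seed in range(3):
                img, truth = _scene_image(
                    seed=40 + seed, area=area, n_blobs=(2, 3)
                )
                regions, _ = segment_chromosomes(img, PX, min_area_um2=0.5)
                assert len(regions) == 1
                rel_errors.append(
                    regions[0].area_um2 / truth.regions["true_area_um2"].iloc[0] - 1
                )
            assert abs(np.mean(rel_errors)) < 0.10

    def test_area_invariant_under_translation_and_rotation(self):
        img, _ = _scene_image(seed=33)
        base, _ = segment_chromosomes(img, PX)
        shifted = np.roll(img, (7, -11), axis=(0, 1))
        rot = np.rot90(img)
        area0 = base[0].area_um2
        for variant in (shifted, rot):
            regions, _ = segment_chromosomes(variant, PX)
            assert len(regions) == 1
            # allow one pixel-row of boundary discretization
            perimeter_row_um2 = 2 * np.sqrt(area0 * np.pi) * PX
            assert abs(regions[0].area_um2 - area0) < perimeter_row_um2

    def test_missing_pixel_size_rejected(self):
        with pytest.raises(ConfigurationError):
            segment_chromosomes(np.zeros((16, 16)), pixel_size_um=0.0)

    def test_constant_threshold_mode(self):
        img, _ = _scene_image(seed=34)
        regions, _ = segment_chromosomes(
            img, PX, threshold_method="constant", threshold_value=np.median(img) + 200
        )
        assert len(regions) >= 1
        with pytest.raises(ConfigurationError):
            segment_chromosomes(img, PX, threshold_method="constant")


class TestRegionLinking:
    @staticmethod
    def _disk_stack(centers_per_frame, radius_px=8, shape=(64, 64)):
        stack = np.zeros((len(centers_per_frame), *shape), dtype=int)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        for f, centers in enumerate(centers_per_frame):
            for label, (r, c) in enumerate(centers, start=1):
                stack[f][np.hypot(yy - r, xx - c) <= radius_px] = label
        return stack

    def test_stationary_region_single_series(self):
        stack = self._disk_stack([[(30, 30)]] * 5)
        series = link_regions(stack, PX)
        assert series["series_id"].nunique() == 1
        assert len(series) == 5

    def test_one_frame_disappearance_starts_new_series(self):
        stack = self._disk_stack([[(30, 30)], [], [(30, 30)]])
        series = link_regions(stack, PX)
        assert series["series_id"].nunique() == 2

    def test_drifting_regions_keep_identity(self):
        """Slowly moving, slowly deforming disks keep one series each."""
        frames = []
        for f in range(50):
            frames.append([(20 + f // 5, 20), (45, 40 - f // 5)])
        stack = self._disk_stack(frames, radius_px=6)
        series = link_regions(stack, PX)
        assert series["series_id"].nunique() == 2

    def test_largest_overlap_wins(self):
        # one big region in frame 0; two in frame 1, one overlapping more
        stack = self._disk_stack([[(30, 30)], [(30, 28), (30, 52)]], radius_px=10)
        series = link_regions(stack, PX)
        f1 = series[series["frame"] == 1].sort_values("label")
        parent = series[series["frame"] == 0]["series_id"].iloc[0]
        assert f1.iloc[0]["series_id"] == parent
        assert f1.iloc[1]["series_id"] != parent


class TestSummedAreaSeries:
    def test_constant_area_stays_one(self):
        series = pd.DataFrame(
            {"series_id": 0, "frame": range(10), "label": 1, "area_um2": 20.0}
        )
        out = summed_area_series(series, frame_interval_s=2.0)
        assert np.allclose(out["area_norm"], 1.0)

    def test_linear_doubling_endpoint(self):
        areas = np.linspace(10.0, 20.0, 50)
        series = pd.DataFrame(
            {"series_id": 0, "frame": range(50), "label": 1, "area_um2": areas}
        )
        out = summed_area_series(series, 1.0, smoothing_sigma_s=2.0)
        assert out["area_norm_smooth"].iloc[-1] == pytest.approx(2.0, rel=0.02)

    def test_smoothing_preserves_mean(self, rng):
        areas = 20.0 + rng.normal(0, 2.0, 200)
        series = pd.DataFrame(
            {"series_id": 0, "frame": range(200), "label": 1, "area_um2": areas}
        )
        out = summed_area_series(series, 1.0, smoothing_sigma_s=5.0)
        assert out["area_norm_smooth"].mean() == pytest.approx(
            out["area_norm"].mean(), rel=0.01
        )

    def test_zero_initial_area_rejected(self):
        series = pd.DataFrame(
            {"series_id": 0, "frame": [0, 1], "label": 1, "area_um2": [0.0, 5.0]}
        )
        with pytest.raises(DomainError):
            summed_area_series(series, 1.0)


class TestBlobsAndColocalization:
    def test_uniform_region_no_blobs(self, rng):
        img = rng.normal(1000.0, 5.0, (64, 64))
        labels = np.zeros((64, 64), dtype=int)
        labels[16:48, 16:48] = 1
        blobs = detect_blobs(img, labels, PX)
        assert len(blobs) <= 1  # noise maxima stay below any real prominence

    def test_subblob_positions_recovered(self):
        camera = CameraModel()
        scenes, truth = simulate_nucleoid_population(
            1, 20.0, 0.0, (5, 5), (0, 0), 0.0, seed=51
        )
        stack = render_nucleoid_stack(
            scenes, camera, seed=52, fov_um=(truth.params["fov_um"],) * 2
        )
        img = stack.channel("dna")[0]
        _, labels = segment_chromosomes(img, PX)
        blobs = detect_blobs(img, labels, PX)
        assert len(blobs) == 5
        for _, b in truth.blobs.iterrows():
            d = np.hypot(blobs["x_um"] - b["x_um"], blobs["y_um"] - b["y_um"]).min()
            assert d < 0.2

    def test_blob_count_monotone_in_prominence(self):
        img, _ = _scene_image(seed=53, n_blobs=(5, 5))
        _, labels = segment_chromosomes(img, PX)
        counts = [
            len(detect_blobs(img, labels, PX, prominence=p))
            for p in (0.1, 0.3, 0.6, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_identical_positions_fully_colocalized(self, rng):
        pts = rng.uniform(0, 10, (8, 2))
        res = colocalize(pts, pts.copy())
        assert res.fraction_colocalized == 1.0
        assert res.n_matched == 8

    def test_strict_threshold_semantics(self):
        blobs = np.array([[0.0, 0.0], [5.0, 0.0]])
        spots = blobs + np.array([0.33, 0.0])
        assert colocalize(blobs, spots, radius_um=0.32).fraction_colocalized == 0.0
        just_in = blobs + np.array([0.31, 0.0])
        assert colocalize(blobs, just_in, radius_um=0.32).fraction_colocalized == 1.0

    def test_matching_is_one_to_one(self):
        blobs = np.array([[0.0, 0.0], [0.1, 0.0]])
        spots = np.array([[0.05, 0.0]])
        res = colocalize(blobs, spots)
        assert res.n_matched == 1
        assert res.pairs["distance_um"].iloc[0] == pytest.approx(0.05)

    def test_fraction_monotone_in_radius(self, rng):
        blobs = rng.uniform(0, 10, (20, 2))
        spots = blobs + rng.normal(0, 0.2, (20, 2))
        fracs = [
            colocalize(blobs, spots, radius_um=r).fraction_colocalized
            for r in (0.05, 0.16, 0.32, 0.64, 1.28)
        ]
        assert fracs == sorted(fracs)

    def test_cluster_count_containment(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[8:24, 8:24] = 1
        labels[40:56, 40:56] = 2
        spots = np.array([[2.0, 2.0], [2.2, 2.4], [7.5, 7.5], [0.1, 9.9]])
        counts = count_clusters(spots, labels, PX)
        assert counts.set_index("label")["n_clusters"].to_dict() == {1: 2, 2: 1}

    def test_median_count_recovery_from_uniform_truth(self):
        """Counts drawn uniformly on {2..9} recover the sample median."""
        camera = CameraModel()
        scenes, truth = simulate_nucleoid_population(
            12, 20.0, 0.1, (5, 5), (2, 9), 1.0, seed=54
        )
        stack = render_nucleoid_stack(
            scenes, camera, seed=55, fov_um=(truth.params["fov_um"],) * 2
        )
        from chromoscope.spots import detect_spots

        img = stack.channel("dna")[0]
        _, labels = segment_chromosomes(img, PX)
        det = detect_spots(stack, channel="condensin", snr_min=5)
        counts = count_clusters(det[["x_um", "y_um"]].to_numpy(), labels, PX)
        true_median = truth.spots.groupby("chromosome").size().median()
        assert abs(counts.attrs["median"] - true_median) <= 1


class TestDoseResponse:
    def test_single_value_group(self):
        out = dose_response({2.0: np.array([7.5])})
        row = out.iloc[0]
        assert row["mean_area_um2"] == row["q15_9"] == row["q84_1"] == 7.5

    def test_normal_band_matches_one_sd(self, rng):
        values = rng.normal(20.0, 3.0, 300)
        out = dose_response({1.0: values})
        assert out["q84_1"].iloc[0] - out["q15_9"].iloc[0] == pytest.approx(
            2 * values.std(), rel=0.10
        )

    def test_sigmoidal_midpoint_recovery(self, rng):
        """Recovered per-condition means trace the underlying compaction curve."""

        def sigmoid(x, lo, hi, mid, slope):
            return lo + (hi - lo) / (1 + np.exp((x - mid) / slope))

        pegs = np.arange(1.0, 10.5, 0.5)
        truth_mid = 6.0
        groups = {
            p: sigmoid(p, 3.0, 20.0, truth_mid, 0.6) + rng.normal(0, 0.4, 80)
            for p in pegs
        }
        out = dose_response(groups)
        popt, _ = curve_fit(
            sigmoid, out["peg_percent"], out["mean_area_um2"],
            p0=[3.0, 20.0, 5.0, 1.0],
        )
        assert popt[2] == pytest.approx(truth_mid, abs=0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError, match="7.0"):
            dose_response({7.0: np.array([])})


class TestGroupComparison:
    def test_identical_groups_not_significant(self, rng):
        a = rng.normal(10.0, 2.0, 30)
        res = compare_groups(a, a.copy())
        assert res.p_value > 0.9

    def test_exact_u_matches_enumeration_oracle(self):
        """U statistic equals brute-force enumeration over all 4-vs-4 splits."""
        a = np.array([1.3, 2.9, 4.1, 6.0])
        b = np.array([2.0, 3.5, 5.2, 7.7])
        res = compare_groups(a, b)
        # oracle: U_a = number of (a, b) pairs with a > b (no ties here)
        u_a = sum(x > y for x in a for y in b)
        u_b = sum(y > x for x in a for y in b)
        assert res.u_statistic in (u_a, u_b)
        # exact p-value: share of all 70 rank splits at least as extreme
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        observed = ranks[:4].sum()
        sums = [
            sum(combo) for combo in itertools.combinations(ranks, 4)
        ]
        mean_sum = np.mean(sums)
        p_exact = np.mean(
            [abs(s - mean_sum) >= abs(observed - mean_sum) - 1e-9 for s in sums]
        )
        assert res.p_value == pytest.approx(p_exact, abs=1e-9)
        assert res.method == "exact"

    def test_shifted_distributions_detected(self):
        """Power: a 2-sd shift at n=50 is significant in >= 95% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.normal(10.0, 2.0, 50)
            b = rng.normal(14.0, 2.0, 50)
            hits += compare_groups(a, b).p_value < 0.001
        assert hits >= 0.95 * n_seeds

    def test_degenerate_input_flagged(self):
        res = compare_groups(np.full(5, 3.0), np.full(4, 3.0))
        assert res.degenerate
        assert res.p_value == 1.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(DomainError):
            compare_groups(np.array([1.0]), np.array([2.0, 3.0]))
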