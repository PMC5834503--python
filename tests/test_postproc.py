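import numpy as np
import pytest

from smlmq import postproc, synth
from smlmq.core_io import LocalizationTable, Polyline
from smlmq.postproc import (
    BlinkMerger,
    DriftCorrector,
    DriftCurve,
    EstimationError,
    NoFiducialError,
    estimate_nena,
    fire_resolution,
    merge_blinks,
    reconstruct_image,
)
from smlmq.synth import BlinkModel


@pytest.fixture(scope="module")
def drifted_field(filament_table):
    table, _ = filament_table
    return synth.sim_fiducials_with_drift(
        3, {"kind": "random_walk", "step_sd_nm": 1.0}, table, seed=21
    )


class TestFiducialDetection:
    def test_finds_exactly_planted_beads(self, drifted_field):
        table, _ = drifted_field
        tracks, mask = postproc.detect_fiducials(table)
        assert len(tracks) == 3
        # detected bead localizations are exactly the truth-labeled ones
        truth_beads = (table.df["truth_kind"] == "bead").to_numpy()
        assert (mask & truth_beads).sum() >= 0.99 * truth_beads.sum()

    def test_blinking_emitters_are_not_beads(self, filament_table):
        table, _ = filament_table
        with pytest.raises(NoFiducialError):
            postproc.detect_fiducials(table)

    def test_gappy_bead_still_detected_and_interpolated(self, filament_table):
        table, _ = filament_table
        out, _ = synth.sim_fiducials_with_drift(
            1, {"kind": "none"}, table, seed=5, bead_presence=0.95
        )
        tracks, _ = postproc.detect_fiducials(out, min_presence=0.9)
        assert len(tracks) == 1
        assert np.isfinite(tracks[0]).all()
        assert len(tracks[0]) == table.n_frames


class TestDriftEstimation:
    def test_noise_floor_single_stationary_bead(self, filament_table):
        table, _ = filament_table
        sigma_bead = 2.0
        out, _ = synth.sim_fiducials_with_drift(
            1, {"kind": "none"}, table, seed=6, bead_sigma_loc_nm=sigma_bead
        )
        tracks, _ = postproc.detect_fiducials(out)
        curve = postproc.estimate_drift(tracks, smooth_window=10)
        rms = np.sqrt((curve.dxy**2).sum(axis=1).mean())
        assert rms <= 3.0 * sigma_bead / np.sqrt(10)

    def test_linear_drift_slope_recovered(self, filament_table):
        table, _ = filament_table
        out, truth = synth.sim_fiducials_with_drift(
            2, {"kind": "linear", "velocity_nm_per_frame": (0.08, -0.03)}, table, seed=7
        )
        tracks, _ = postproc.detect_fiducials(out)
        curve = postproc.estimate_drift(tracks)
        t = np.arange(table.n_frames)
        slope_x = np.polyfit(t, curve.dxy[:, 0], 1)[0]
        slope_y = np.polyfit(t, curve.dxy[:, 1], 1)[0]
        assert slope_x == pytest.approx(0.08, rel=0.01)
        assert slope_y == pytest.approx(-0.03, rel=0.01)

    def test_two_identical_beads_give_their_track(self):
        rng = np.random.default_rng(0)
        n_frames = 200
        walk = np.cumsum(rng.normal(0, 1, (n_frames, 2)), axis=0)
        walk -= walk[0]
        tracks = [walk + 100.0, walk + 900.0]
        curve = postproc.estimate_drift(tracks, smooth_window=1)
        np.testing.assert_allclose(curve.dxy, walk, atol=1e-9)

    def test_random_walk_recovery_rmse(self, drifted_field):
        table, truth = drifted_field
        corrector = DriftCorrector().fit(table)
        err = corrector.drift_curve_.dxy - truth.drift
        rmse = np.sqrt((err**2).sum(axis=1).mean())
        assert rmse <= 2.0 * 2.0 / np.sqrt(3) + 2.0  # 2 sigma/sqrt(beads) + smoothing bias


class TestCorrectDrift:
    def test_zero_curve_is_identity(self, filament_table):
        table, _ = filament_table
        curve = DriftCurve(np.zeros((table.n_frames, 2)))
        out = postproc.correct_drift(table, curve)
        np.testing.assert_array_equal(out.xy, table.xy)

    def test_involution_and_count_conservation(self, filament_table):
        table, _ = filament_table
        rng = np.random.default_rng(3)
        curve = DriftCurve(np.cumsum(rng.normal(0, 1, (table.n_frames, 2)), axis=0))
        once = postproc.correct_drift(table, curve)
        back = postproc.correct_drift(once, curve.inverse())
        assert len(once) == len(table)
        np.testing.assert_allclose(back.xy, table.xy, atol=1e-9)

    def test_frame_outside_curve_rejected(self, filament_table):
        table, _ = filament_table
        with pytest.raises(ValueError):
            postproc.correct_drift(table, DriftCurve(np.zeros((10, 2))))

    def test_correction_restores_transverse_width(self, drifted_field, filament_table):
        table_drift, _ = drifted_field
        table_clean, _ = filament_table
        corrector = DriftCorrector().fit(table_drift)
        corrected = corrector.transform(table_drift, drop_beads=True)
        sd_clean = table_clean.df["y_nm"].std()
        sd_corr = corrected.df["y_nm"].std()
        assert sd_corr == pytest.approx(sd_clean, rel=0.05)


class TestNena:
    @pytest.mark.parametrize("sigma_true", [5.0, 10.0, 20.0])
    def test_recovers_known_precision(self, sigma_true):
        lines = [
            Polyline(np.array([[1000.0, 5000.0], [19000.0, 5000.0]])),
            Polyline(np.array([[1000.0, 12000.0], [19000.0, 15000.0]])),
        ]
        blink = BlinkModel(mean_blinks_per_fluorophore=3, on_frames=3)
        table, _ = synth.sim_filament_field(
            lines, 75.0, 1.0, 150.0, blink, sigma_true, seed=42, n_frames=5000
        )
        est = estimate_nena(table)
        assert est.n_pairs >= 5000
        assert est.sigma_loc_nm == pytest.approx(sigma_true, rel=0.10)
        assert est.reliable

    def test_zero_precision_limit(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 10_000, (400, 2))
        # each emitter localized identically on 5 consecutive frames
        x = np.repeat(pos[:, 0], 5)
        y = np.repeat(pos[:, 1], 5)
        frames = (np.tile(np.arange(5), 400) + rng.integers(0, 4000, 400).repeat(5))
        table = LocalizationTable.from_arrays(x, y, frames)
        est = estimate_nena(table, min_pairs=500)
        assert est.sigma_loc_nm < 1.0

    def test_uniform_points_flagged_unreliable(self):
        rng = np.random.default_rng(2)
        table = LocalizationTable.from_arrays(
            rng.uniform(0, 5_000, 20_000),
            rng.uniform(0, 5_000, 20_000),
            rng.integers(0, 200, 20_000),
        )
        est = estimate_nena(table)
        assert not est.reliable

    def test_too_few_pairs_raises(self):
        table = LocalizationTable.from_arrays([0.0, 1.0], [0.0, 1.0], [0, 1])
        with pytest.raises(EstimationError):
            estimate_nena(table)


def brute_force_chain_count(xy, frames, intensity, radius, max_gap=0):
    """Union-find over pairs on nearby frames within radius (well-separated
    chains only: each chain must absorb at most one localization per frame)."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(n):
            if i < j and 1 <= abs(frames[i] - frames[j]) <= 1 + max_gap:
                if np.hypot(*(xy[i] - xy[j])) <= radius:
                    union(i, j)
    return len({find(i) for i in range(n)})


class TestMergeBlinks:
    def test_single_emitter_five_frames_collapses(self):
        table = LocalizationTable.from_arrays(
            np.full(5, 100.0), np.full(5, 200.0), np.arange(5), np.full(5, 10.0)
        )
        merged = merge_blinks(table, radius_nm=20.0)
        assert len(merged) == 1
        assert merged.df.loc[0, "intensity"] == 50.0
        assert merged.df.loc[0, "frame"] == 0
        assert merged.df.loc[0, "x_nm"] == pytest.approx(100.0)

    def test_distant_emitters_stay_separate(self):
        table = LocalizationTable.from_arrays(
            [0.0, 500.0, 0.0, 500.0], [0.0, 0.0, 0.0, 0.0], [0, 0, 1, 1]
        )
        merged = merge_blinks(table, radius_nm=20.0)
        assert len(merged) == 2

    def test_gap_semantics(self):
        table = LocalizationTable.from_arrays([0.0, 0.0], [0.0, 0.0], [0, 2])
        assert len(merge_blinks(table, 20.0, max_gap_frames=0)) == 2
        assert len(merge_blinks(table, 20.0, max_gap_frames=1)) == 1

    def test_matches_union_find_oracle_and_conserves_intensity(self):
        rng = np.random.default_rng(8)
        # well-separated emitters, chains of consecutive re-localizations
        pos = rng.uniform(0, 50_000, (120, 2))
        rows_x, rows_y, rows_f, rows_i = [], [], [], []
        for p in pos:
            start = rng.integers(0, 500)
            length = rng.integers(1, 6)
            for k in range(length):
                jitter = rng.normal(0, 3.0, 2)
                rows_x.append(p[0] + jitter[0])
                rows_y.append(p[1] + jitter[1])
                rows_f.append(start + k)
                rows_i.append(rng.uniform(50, 150))
        table = LocalizationTable.from_arrays(rows_x, rows_y, rows_f, rows_i)
        merged = merge_blinks(table, radius_nm=25.0)
        oracle = brute_force_chain_count(
            table.xy, table.frames, table.intensity, 25.0
        )
        assert len(merged) == oracle
        assert merged.intensity.sum() == pytest.approx(table.intensity.sum(), rel=1e-12)

    def test_estimator_facade(self, filament_table):
        table, _ = filament_table
        out = BlinkMerger(radius_nm=30.0).fit().transform(table)
        assert len(out) < len(table)
        assert out.intensity.sum() == pytest.approx(table.intensity.sum(), rel=1e-12)


class TestReconstruction:
    def test_single_localization_single_pixel(self):
        table = LocalizationTable.from_arrays([105.0], [42.0], [0])
        img = reconstruct_image(table, pixel_nm=10.0)
        assert img.values.sum() == 1.0
        assert img.values.max() == 1.0

    def test_half_open_binning_convention(self):
        # x exactly on a pixel edge belongs to the right-hand pixel
        table = LocalizationTable.from_arrays([10.0, 19.999, 0.0], [0.0, 0.0, 0.0], [0, 0, 0])
        img = reconstruct_image(table, pixel_nm=10.0)
        assert img.values[0, 0] == 1.0   # [0, 10)
        assert img.values[0, 1] == 2.0   # [10, 20)

    def test_blur_conserves_mass(self, filament_table):
        table, _ = filament_table
        img = reconstruct_image(table, 10.0, blur_sigma_nm=12.0)
        assert img.values.sum() == pytest.approx(len(table), rel=1e-6)

    def test_column_sums_match_direct_binning(self, filament_table):
        table, _ = filament_table
        img = reconstruct_image(table, 10.0)
        x = table.df["x_nm"].to_numpy()
        lo = img.origin_nm[0]
        counts, _ = np.histogram(
            x, bins=np.arange(lo, lo + (img.shape[1] + 1) * 10.0, 10.0)
        )
        np.testing.assert_array_equal(img.values.sum(axis=0), counts)


class TestFire:
    def test_identical_halves_never_cross(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 5_000, (4_000, 2))
        # duplicate every localization into both parity halves
        table = LocalizationTable.from_arrays(
            np.r_[pos[:, 0], pos[:, 0]],
            np.r_[pos[:, 1], pos[:, 1]],
            np.r_[np.zeros(4_000, int), np.ones(4_000, int)],
        )
        res = fire_resolution(table, image_scale=256)
        assert not res.resolved
        assert np.all(res.frc[1 : len(res.frc) // 2] > 0.9)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(4)
        table = LocalizationTable.from_arrays(
            rng.uniform(0, 5_000, 40_000),
            rng.uniform(0, 5_000, 40_000),
            rng.integers(0, 100, 40_000),
        )
        res = fire_resolution(table, image_scale=256)
        # skip the first few rings, which average only a handful of pixels
        assert np.abs(res.frc[5:]).mean() < 0.05

    def test_resolution_tracks_precision_and_translation_invariance(self):
        lines = [
            Polyline(np.array([[500.0, 2500.0], [9500.0, 2500.0]])),
            Polyline(np.array([[500.0, 5000.0], [9500.0, 6500.0]])),
            Polyline(np.array([[2500.0, 500.0], [2500.0, 9500.0]])),
        ]
        blink = BlinkModel(on_frames=2)
        results = {}
        for sigma in (5.0, 10.0, 20.0):
            table, _ = synth.sim_filament_field(
                lines, 50.0, 1.0, 400.0, blink, sigma, seed=3, n_frames=4000
            )
            results[sigma] = fire_resolution(table, image_scale=1024)
        assert 20.0 <= results[10.0].resolution_nm <= 60.0
        assert results[5.0].resolution_nm < results[10.0].resolution_nm
        assert results[10.0].resolution_nm < results[20.0].resolution_nm

        # global translation leaves the FRC curve unchanged
        table, _ = synth.sim_filament_field(
            lines, 50.0, 1.0, 400.0, blink, 10.0, seed=3, n_frames=4000
        )
        shifted_df = table.df.copy()
        shifted_df["x_nm"] += 12_345.6
        shifted_df["y_nm"] -= 987.3
        shifted = table.with_df(shifted_df)
        r1 = fire_resolution(table, image_scale=1024)
        r2 = fire_resolution(shifted, image_scale=1024)
        assert r1.resolution_nm == pytest.approx(r2.resolution_nm, rel=1e-9)
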