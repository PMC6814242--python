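import numpy as np
import pandas as pd
import pytest

from colonywave.geometry import make_mask
from colonywave.quantify import (
    ProfileSeries,
    QuantifyError,
    RadialProfile,
    average_profiles,
    nonmembrane_profile,
    nuclear_radial_profile,
    similarity_index,
    track_stats,
    track_wave,
)
from colonywave.synth import (
    ChannelRecipe,
    ColonyImageSpec,
    WaveSpec,
    gen_colony_images,
    gen_tracks,
    gen_wave_series,
)


@pytest.fixture(scope="module")
def mask():
    return make_mask("circle", 700.0, 64, 14.0)


@pytest.fixture(scope="module")
def images(mask):
    spec = ColonyImageSpec(
        channels=(ChannelRecipe("flat", lambda d: np.full_like(np.asarray(d, float), 30.0)),),
        seed=1,
    )
    return gen_colony_images(spec, mask)


class TestNuclearRadialProfile:
    def test_flat_marker_gives_flat_ratio(self, mask, images):
        marker = np.where(images.nuclear_mask, 30.0, 0.0)
        dapi = np.where(images.nuclear_mask, 100.0, 0.0)
        prof = nuclear_radial_profile(marker, dapi, images.nuclear_mask, mask)
        vals = prof.mean_intensity[np.isfinite(prof.mean_intensity)]
        assert np.allclose(vals, 0.3, atol=1e-9)

    def test_global_intensity_scaling_cancels(self, mask, images):
        rng = np.random.default_rng(0)
        marker = np.where(images.nuclear_mask, rng.uniform(10, 50, mask.shape), 0.0)
        dapi = np.where(images.nuclear_mask, rng.uniform(80, 120, mask.shape), 0.0)
        a = nuclear_radial_profile(marker, dapi, images.nuclear_mask, mask)
        b = nuclear_radial_profile(7.3 * marker, 7.3 * dapi, images.nuclear_mask, mask)
        assert np.allclose(
            a.mean_intensity, b.mean_intensity, equal_nan=True, rtol=1e-12
        )

    def test_checkerboard_local_average_halves(self, mask, images):
        # marker = c on half the nuclear pixels (checkerboard), 0 on the rest,
        # uniform DAPI: the 120 um local mean sees ~c/2
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        checker = (yy + xx) % 2 == 0
        marker = np.where(images.nuclear_mask & checker, 60.0, 0.0)
        dapi = np.where(images.nuclear_mask, 100.0, 0.0)
        prof = nuclear_radial_profile(marker, dapi, images.nuclear_mask, mask)
        # raw nuclear values alternate 0 / 0.6; the 120 um local mean pulls
        # every well-populated bin to ~0.3 (outer bins hold many nuclei;
        # center bins contain too few nuclei for the parity average)
        vals = prof.mean_intensity[:12]
        vals = vals[np.isfinite(vals)]
        assert len(vals) >= 10
        assert np.allclose(vals, 0.3, atol=0.08)
        assert vals.std() < 0.05

    def test_empty_nuclear_mask_rejected(self, mask):
        z = np.zeros(mask.shape)
        with pytest.raises(QuantifyError, match="empty nuclear"):
            nuclear_radial_profile(z, z, np.zeros(mask.shape, bool), mask)

    def test_planted_ring_peak_recovered(self, mask):
        ring = ChannelRecipe(
            "ring", lambda d: 20.0 + 100.0 * np.exp(-((np.asarray(d) - 140.0) ** 2) / (2 * 25.0**2))
        )
        spec = ColonyImageSpec(channels=(ring,), seed=2)
        imgs = gen_colony_images(spec, mask)
        prof = nuclear_radial_profile(
            imgs.channels["ring"], imgs.dapi, imgs.nuclear_mask, mask,
            local_radius=30.0,
        )
        peak = prof.bin_centers[np.nanargmax(prof.mean_intensity)]
        assert abs(peak - 140.0) <= 20.0  # within two bins of the planted ring


class TestNonMembraneProfile:
    def test_membrane_pixels_excluded_exactly(self, mask, images):
        signal = np.where(mask.grid, 5.0, 0.0)
        signal[images.membrane_mask] = 50.0
        prof = nonmembrane_profile(signal, images.membrane_mask, mask)
        vals = prof.mean_intensity[np.isfinite(prof.mean_intensity)]
        assert np.allclose(vals, 5.0)

    def test_empty_membrane_equals_plain_profile(self, mask):
        rng = np.random.default_rng(1)
        signal = np.where(mask.grid, rng.uniform(1, 2, mask.shape), 0.0)
        a = nonmembrane_profile(signal, np.zeros(mask.shape, bool), mask)
        b = nonmembrane_profile(signal, np.zeros(mask.shape, bool), mask)
        assert np.allclose(a.mean_intensity, b.mean_intensity, equal_nan=True)

    def test_planted_radial_gradient_recovered(self, mask, images):
        from colonywave.geometry import edge_distance

        d = edge_distance(mask).values
        signal = np.where(mask.grid, 10.0 + 0.5 * d, 0.0)
        signal[images.membrane_mask] *= 10  # membrane contamination
        prof = nonmembrane_profile(signal, images.membrane_mask, mask)
        expected = 10.0 + 0.5 * prof.bin_centers
        ok = np.isfinite(prof.mean_intensity)
        rel = np.abs(prof.mean_intensity[ok] - expected[ok]) / expected[ok]
        assert np.nanmax(rel[:-1]) < 0.2  # within binning error

    def test_full_membrane_coverage_rejected(self, mask):
        with pytest.raises(QuantifyError, match="entire colony"):
            nonmembrane_profile(np.ones(mask.shape), mask.grid.copy(), mask)


class TestTrackWave:
    def test_planted_speed_recovered_within_five_percent(self, mask):
        spec = WaveSpec(speed=6.0, noise_sd=0.01, seed=3)
        series, _ = gen_wave_series(spec, mask)
        track = track_wave(series)
        assert track.slope == pytest.approx(6.0, rel=0.05)
        assert track.r_squared > 0.95

    def test_constant_profile_has_zero_slope(self, mask):
        n_bins = 10
        edges = np.arange(n_bins + 1) * 10.0
        profiles = [
            RadialProfile(edges, np.linspace(2, 1, n_bins), np.zeros(n_bins))
            for _ in range(5)
        ]
        track = track_wave(ProfileSeries(np.arange(5.0), profiles))
        assert track.slope == 0.0
        assert track.r_squared == 0.0

    def test_threshold_is_half_spatiotemporal_max(self, mask):
        spec = WaveSpec(speed=6.0, seed=0)
        series, _ = gen_wave_series(spec, mask)
        track = track_wave(series)
        assert track.threshold == pytest.approx(
            0.5 * np.nanmax(series.intensity_matrix())
        )

    def test_intensity_rescaling_preserves_front(self, mask):
        spec = WaveSpec(speed=6.0, seed=0)
        series, _ = gen_wave_series(spec, mask)
        scaled = ProfileSeries(
            times=series.times,
            profiles=[
                RadialProfile(p.bin_edges, 3.0 * p.mean_intensity, p.sem)
                for p in series.profiles
            ],
        )
        a, b = track_wave(series), track_wave(scaled)
        assert np.allclose(a.front_position, b.front_position, equal_nan=True)
        assert b.slope == pytest.approx(a.slope)

    def test_requires_three_time_points(self, mask):
        edges = np.arange(4) * 10.0
        profiles = [RadialProfile(edges, np.ones(3), np.zeros(3))] * 2
        with pytest.raises(QuantifyError):
            track_wave(ProfileSeries(np.arange(2.0), profiles))

    def test_subthreshold_series_yields_empty_track(self, mask):
        # one bin carries the max; all other times stay below half of it
        edges = np.arange(4) * 10.0
        quiet = RadialProfile(edges, np.array([0.1, 0.1, 0.1]), np.zeros(3))
        loud = RadialProfile(edges, np.array([1.0, 0.1, 0.1]), np.zeros(3))
        track = track_wave(ProfileSeries(np.arange(3.0), [quiet, loud, quiet]))
        assert np.isnan(track.front_position[0])
        assert np.isfinite(track.front_position[1])


class TestTrackStats:
    def test_stationary_tracks_have_zero_displacement(self):
        rows = [
            {"track_id": 0, "t": t, "x": 30.0, "y": 40.0, "parent_id": -1}
            for t in range(5)
        ]
        stats = track_stats(pd.DataFrame(rows), colony_center=(0.0, 0.0))
        row = stats.per_cell.iloc[0]
        assert row["displacement_um"] == 0.0
        assert row["radial_displacement_um"] == 0.0
        assert row["arc_displacement_um"] == 0.0
        assert row["progeny"] == 0

    def test_pure_rotation_gives_arc_but_no_radial_motion(self):
        r, dth = 100.0, 0.3
        rows = [
            {"track_id": 0, "t": 0, "x": r, "y": 0.0, "parent_id": -1},
            {"track_id": 0, "t": 1, "x": r * np.cos(dth), "y": r * np.sin(dth),
             "parent_id": -1},
        ]
        stats = track_stats(pd.DataFrame(rows), colony_center=(0.0, 0.0))
        row = stats.per_cell.iloc[0]
        assert row["radial_displacement_um"] == pytest.approx(0.0, abs=1e-9)
        assert row["arc_displacement_um"] == pytest.approx(r * dth, rel=1e-9)

    def test_single_point_tracks_excluded_and_counted(self):
        rows = [
            {"track_id": 0, "t": 0, "x": 1.0, "y": 1.0, "parent_id": -1},
            {"track_id": 1, "t": 0, "x": 0.0, "y": 0.0, "parent_id": -1},
            {"track_id": 1, "t": 1, "x": 3.0, "y": 4.0, "parent_id": -1},
        ]
        stats = track_stats(pd.DataFrame(rows), colony_center=(0.0, 0.0))
        assert stats.n_excluded == 1
        assert stats.excluded_ids == [0]
        assert len(stats.per_cell) == 1

    def test_planted_inward_drift_recovered(self, mask):
        tracks, truth = gen_tracks(
            120, mask, drift_um=-10.0, jitter_um=0.5, seed=9
        )
        stats = track_stats(tracks, colony_center=(0.0, 0.0))
        assert stats.mean_radial_displacement == pytest.approx(-10.0, abs=1.5)

    def test_progeny_codes_recovered(self, mask):
        tracks, truth = gen_tracks(
            60, mask, division_prob=0.5, n_timepoints=20, seed=4
        )
        stats = track_stats(tracks, colony_center=(0.0, 0.0))
        merged = stats.per_cell.merge(truth, on="track_id", suffixes=("", "_true"))
        assert (merged["progeny"] == merged["progeny_true"]).all()
        assert set(merged["progeny"]) <= {0, 2, 3, 4}
        assert (merged["progeny"] >= 2).any()


class TestSimilarityIndex:
    def test_uniform_labels_give_one(self, rng):
        pos = rng.uniform(0, 200, size=(50, 2))
        labels = np.zeros(50, dtype=int)
        assert similarity_index(pos, labels) == 1.0

    def test_segregated_blocks_give_one(self):
        left = np.column_stack([np.random.default_rng(0).uniform(0, 50, 40),
                                np.random.default_rng(1).uniform(0, 50, 40)])
        right = left + np.array([500.0, 0.0])
        pos = np.vstack([left, right])
        labels = np.array([0] * 40 + [1] * 40)
        assert similarity_index(pos, labels) == 1.0

    def test_well_mixed_matches_monte_carlo_oracle(self):
        """On a dense grid with random labels at ratio 3:7, the similarity
        index matches a brute-force Monte-Carlo estimate computed with an
        independent O(n^2) implementation."""
        rng = np.random.default_rng(7)
        xx, yy = np.meshgrid(np.arange(30) * 20.0, np.arange(30) * 20.0)
        pos = np.column_stack([xx.ravel(), yy.ravel()])
        estimates = []
        oracle = []
        for _ in range(5):
            labels = (rng.random(len(pos)) < 0.3).astype(int)
            estimates.append(similarity_index(pos, labels))
            # brute force, no spatial index
            n_sim = n_tot = 0
            for i in range(len(pos)):
                d = np.hypot(*(pos - pos[i]).T)
                neigh = (d <= 62.0) & (d > 0)
                if neigh.sum() == 0:
                    continue
                n_tot += 1
                if (labels[neigh] == labels[i]).mean() > 0.6:
                    n_sim += 1
            oracle.append(n_sim / n_tot)
        assert np.allclose(estimates, oracle)

    def test_invariant_under_permutation_and_rotation(self, rng):
        pos = rng.uniform(0, 300, size=(80, 2))
        labels = rng.integers(0, 2, 80)
        base = similarity_index(pos, labels)
        perm = rng.permutation(80)
        assert similarity_index(pos[perm], labels[perm]) == base
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert similarity_index(pos @ R.T, labels) == pytest.approx(base)

    def test_isolated_cells_undefined(self):
        pos = np.array([[0.0, 0.0], [1000.0, 0.0]])
        assert np.isnan(similarity_index(pos, np.array([0, 1])))


def test_average_profiles_combines_colonies():
    edges = np.arange(4) * 10.0
    p1 = RadialProfile(edges, np.array([1.0, 2.0, 3.0]), np.zeros(3))
    p2 = RadialProfile(edges, np.array([3.0, 4.0, 5.0]), np.zeros(3))
    avg = average_profiles([p1, p2])
    assert np.allclose(avg.mean_intensity, [2.0, 3.0, 4.0])
    assert avg.n_colonies == 2
    assert (avg.sem > 0).all()
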