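import numpy as np
import pytest

import fuccitrack as ft
from fuccitrack.cycle_alignment import WarpingPath
from fuccitrack.errors import UnalignableTrackError
from fuccitrack.signal_processing import IntensityTrack

from oracles import subsequence_dtw_oracle


def _track_from(values_by_channel, track_id=0):
    n = len(next(iter(values_by_channel.values())))
    return IntensityTrack(
        track_id=track_id,
        branch="",
        frames=np.arange(n),
        channel_means={k: np.asarray(v, float) for k, v in values_by_channel.items()},
        interpolated_mask=np.zeros(n, dtype=bool),
    )


class TestBuildReferenceCurve:
    def test_single_track_identity(self, noiseless_model):
        track, _ = ft.simulate_fucci_track(noiseless_model, 0.0, 101)
        curve = ft.build_reference_curve([track])
        np.testing.assert_allclose(curve.percentage, np.linspace(0, 100, 101))
        np.testing.assert_allclose(
            curve.channel_means["cyan"], track.channel_means["cyan"]
        )
        assert curve.n_source_tracks == 1

    def test_mean_of_identical_tracks(self, noiseless_model):
        track, _ = ft.simulate_fucci_track(noiseless_model, 0.0, 101)
        one = ft.build_reference_curve([track])
        four = ft.build_reference_curve([track] * 4)
        np.testing.assert_allclose(
            one.channel_means["magenta"], four.channel_means["magenta"]
        )
        assert four.n_source_tracks == 4

    def test_resampling_matches_shape_across_lengths(self, noiseless_model):
        short, _ = ft.simulate_fucci_track(
            ft.CycleModel(noise_sigma=0.0, bleaching=0.0, cycle_frames=50), 0.0, 51
        )
        long, _ = ft.simulate_fucci_track(noiseless_model, 0.0, 101)
        curve = ft.build_reference_curve([short, long])
        solo = ft.build_reference_curve([long])
        np.testing.assert_allclose(
            curve.channel_means["cyan"], solo.channel_means["cyan"], atol=0.02
        )

    def test_too_short_tracks_rejected(self):
        stub = _track_from({"cyan": np.arange(5.0), "magenta": np.arange(5.0)})
        with pytest.raises(ValueError):
            ft.build_reference_curve([stub])
        with pytest.raises(ValueError):
            ft.build_reference_curve([])

    def test_csv_round_trip(self, reference, tmp_path):
        path = tmp_path / "ref.csv"
        reference.to_csv(path)
        again = ft.ReferenceCurve.from_csv(path)
        np.testing.assert_allclose(again.percentage, reference.percentage)
        for ch in reference.channel_means:
            np.testing.assert_allclose(
                again.channel_means[ch], reference.channel_means[ch]
            )
        assert again.n_source_tracks == reference.n_source_tracks


class TestSubsequenceDtw:
    def test_exact_slice_gives_zero_distance_diagonal_path(self, rng):
        ref = rng.normal(size=40)
        query = ref[12:25]
        path, dist, window = ft.subsequence_dtw(query, ref)
        assert dist == 0.0
        assert window == (12, 24)
        steps = {(b[0] - a[0], b[1] - a[1]) for a, b in zip(path.pairs, path.pairs[1:])}
        assert steps == {(1, 1)}

    def test_single_element_query_matches_nearest(self):
        ref = np.array([0.0, 1.0, 4.0, 2.0])
        path, dist, window = ft.subsequence_dtw(np.array([1.2]), ref)
        assert window == (1, 1)
        assert dist == pytest.approx(0.2)

    def test_distance_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(2, 13))
            q = rng.normal(size=n)
            r = rng.normal(size=m)
            _, dist, _ = ft.subsequence_dtw(q, r)
            assert dist == pytest.approx(subsequence_dtw_oracle(q, r), abs=1e-9)

    def test_multifeature_distance_matches_oracle(self):
        rng = np.random.default_rng(5)
        q = rng.normal(size=(5, 2))
        r = rng.normal(size=(9, 2))
        _, dist, _ = ft.subsequence_dtw(q, r)
        assert dist == pytest.approx(subsequence_dtw_oracle(q, r), abs=1e-9)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ft.subsequence_dtw(np.array([]), np.array([1.0]))

    def test_noise_never_decreases_expected_distance(self, reference):
        """More query noise -> larger expected alignment distance."""
        base = reference.channel_means["magenta"][40:70]
        ref_feats = ft.preprocess_for_dtw(
            _track_from({"m": reference.channel_means["magenta"]}), "m", 5
        ).values
        means = []
        for sigma in (0.0, 0.05, 0.2):
            dists = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                noisy = base + rng.normal(0, sigma, base.shape)
                try:
                    q = ft.preprocess_for_dtw(_track_from({"m": noisy}), "m", 5).values
                except UnalignableTrackError:
                    continue
                dists.append(ft.subsequence_dtw(q, ref_feats)[1])
            means.append(np.mean(dists))
        assert means[0] <= means[1] <= means[2]


class TestTimeDistortion:
    def test_diagonal_path_is_zero(self):
        path = WarpingPath(pairs=((0, 3), (1, 4), (2, 5)))
        assert ft.time_distortion(path) == 0.0

    def test_counts_non_diagonal_steps(self):
        # 2 horizontal + 3 vertical among diagonals -> 5
        pairs = [(0, 0)]
        for step in [(1, 1), (1, 0), (0, 1), (1, 1), (1, 0), (0, 1), (0, 1)]:
            pairs.append((pairs[-1][0] + step[0], pairs[-1][1] + step[1]))
        assert ft.time_distortion(WarpingPath(pairs=tuple(pairs))) == 5.0

    def test_time_dilated_query_distortion_scales(self, rng):
        """A query dilated 2x in time needs about n/2 compressions."""
        ref = rng.normal(size=40)
        query = np.repeat(ref[8:23], 2)
        path, dist, _ = ft.subsequence_dtw(query, ref)
        assert dist == pytest.approx(0.0, abs=1e-12)
        n = len(query)
        assert ft.time_distortion(path) == pytest.approx(n / 2, abs=2)

    def test_relative_distortion_arithmetic(self):
        assert ft.relative_time_distortion(0.0, 7) == 0.0
        assert ft.relative_time_distortion(10.0, 5) == 2.0
        with pytest.raises(ValueError):
            ft.relative_time_distortion(1.0, 0)


class TestAssignPseudotime:
    def test_diagonal_slice_is_exactly_linear(self):
        pct = np.linspace(0, 100, 101)
        # slice covering percentages 25..50: features 25..49
        path = WarpingPath(pairs=tuple((i, 25 + i) for i in range(25)))
        out = ft.assign_pseudotime(path, pct)
        np.testing.assert_allclose(out, np.arange(25, 51.0))

    def test_mean_of_matched_percentages(self):
        pct = np.linspace(0, 100, 101)
        # query frame 1 touches reference points 40 (twice) and 41
        path = WarpingPath(pairs=((0, 39), (1, 40), (1, 41)))
        out = ft.assign_pseudotime(path, pct)
        assert out[1] == pytest.approx((40 + 40 + 41) / 3)
        assert out[2] == pytest.approx(41.5)  # mean of points 41 and 42


class TestArrest:
    def test_threshold_rule(self):
        result = ft.AlignmentResult(
            path=WarpingPath(pairs=((0, 0),)),
            distance=1.0,
            ref_window=(0, 0),
            pseudotime=np.zeros(1),
            time_distortion=12.0,
            relative_time_distortion=6.0,
            arrested=False,
        )
        assert ft.flag_arrest(result, ft.ArrestConfig(threshold=5.0))
        result.relative_time_distortion = 0.0
        assert not ft.flag_arrest(result, ft.ArrestConfig(threshold=5.0))

    def test_default_threshold_is_five(self):
        assert ft.ArrestConfig().threshold == 5.0

    def test_suggest_threshold_splits_bimodal(self):
        values = [0.1, 0.15, 0.2, 0.9, 1.0, 1.1]
        thr = ft.suggest_arrest_threshold(values)
        assert 0.2 < thr < 0.9

    def test_arrested_scores_higher_than_normal(self, reference):
        model = ft.CycleModel(noise_sigma=0.05)
        rng = np.random.default_rng(9)
        normal, _ = ft.simulate_fucci_track(model, 10.0, 80, rng=rng)
        arrested, _ = ft.simulate_fucci_track(model, 10.0, 80, arrested=True, rng=rng)
        r_n = ft.align_track(normal, reference)
        r_a = ft.align_track(arrested, reference)
        assert r_a.relative_time_distortion > r_n.relative_time_distortion
        assert r_a.normalized_distance > r_n.normalized_distance


class TestAlignTrack:
    def test_reference_slice_recovers_exact_pseudotime(self, reference):
        track = _track_from(
            {ch: reference.channel_means[ch][20:50] for ch in reference.channel_means}
        )
        result = ft.align_track(track, reference)
        assert result.distance == pytest.approx(0.0, abs=1e-9)
        assert result.time_distortion == 0.0
        np.testing.assert_allclose(result.pseudotime, np.arange(20.0, 50.0), atol=1e-9)
        assert not result.arrested

    def test_wraparound_query_straddling_mitosis(self, noiseless_model, reference):
        track, pct = ft.simulate_fucci_track(noiseless_model, 85.0, 30)
        result = ft.align_track(track, reference)
        err = np.abs(result.pseudotime - pct)
        err = np.minimum(err, 100 - err)
        assert err.max() < 5.0

    def test_reversed_track_is_heavily_distorted(self, reference):
        forward = _track_from(
            {ch: reference.channel_means[ch][10:60] for ch in reference.channel_means}
        )
        backward = _track_from(
            {
                ch: reference.channel_means[ch][10:60][::-1].copy()
                for ch in reference.channel_means
            }
        )
        r_fwd = ft.align_track(forward, reference)
        r_bwd = ft.align_track(backward, reference)
        assert r_bwd.relative_time_distortion > 5 * max(
            r_fwd.relative_time_distortion, 0.02
        )
        assert r_bwd.normalized_distance > 10 * max(r_fwd.normalized_distance, 1e-9)

    def test_dark_track_unalignable_not_arrested(self, reference):
        track = _track_from({"cyan": np.zeros(30), "magenta": np.zeros(30)})
        with pytest.raises(UnalignableTrackError):
            ft.align_track(track, reference)

    def test_short_track_rejected(self, reference):
        track = _track_from({"cyan": np.arange(5.0), "magenta": np.arange(5.0)})
        with pytest.raises(ValueError):
            ft.align_track(track, reference)

    def test_deterministic(self, reference):
        model = ft.CycleModel(noise_sigma=0.05)
        track, _ = ft.simulate_fucci_track(
            model, 30.0, 40, rng=np.random.default_rng(2)
        )
        a = ft.align_track(track, reference)
        b = ft.align_track(track, reference)
        assert a.distance == b.distance and a.path.pairs == b.path.pairs
        np.testing.assert_array_equal(a.pseudotime, b.pseudotime)

    def test_intensity_scaling_invariance(self, reference):
        model = ft.CycleModel(noise_sigma=0.05)
        track, _ = ft.simulate_fucci_track(model, 30.0, 40, rng=np.random.default_rng(2))
        scaled = _track_from(
            {ch: 7.5 * v for ch, v in track.channel_means.items()}
        )
        a = ft.align_track(track, reference)
        b = ft.align_track(scaled, reference)
        assert a.relative_time_distortion == b.relative_time_distortion
        np.testing.assert_allclose(a.pseudotime, b.pseudotime, atol=1e-9)

    def test_align_tracks_reports_unalignable(self, reference):
        good, _ = ft.simulate_fucci_track(
            ft.CycleModel(noise_sigma=0.05), 10.0, 40, rng=np.random.default_rng(0)
        )
        dark = _track_from({"cyan": np.zeros(30), "magenta": np.zeros(30)})
        dark.track_id = 99
        report = ft.align_tracks([good, dark], reference)
        assert set(report["status"]) == {"ok", "unalignable"}
        assert not report[report["status"] == "unalignable"]["arrested"].any()
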