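import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fuccitrack as ft
from fuccitrack.errors import FormatError, IntegrityError, VocabularyError
from fuccitrack.phases import PhaseLabel
from fuccitrack.signal_processing import IntensityTrack
from fuccitrack.track_io import Spot, Track


XML_TWO_SPOTS = """<?xml version="1.0"?>
<TrackMate><Model>
 <AllSpots>
  <SpotsInFrame frame="0"><Spot ID="1" name="A" FRAME="0" POSITION_X="5.0" POSITION_Y="6.0"/></SpotsInFrame>
  <SpotsInFrame frame="1"><Spot ID="2" name="A" FRAME="1" POSITION_X="6.0" POSITION_Y="7.0"/></SpotsInFrame>
 </AllSpots>
 <AllTracks><Track TRACK_ID="0"><Edge SPOT_SOURCE_ID="1" SPOT_TARGET_ID="2"/></Track></AllTracks>
</Model></TrackMate>
"""

XML_DIVISION = """<?xml version="1.0"?>
<TrackMate><Model>
 <AllSpots>
  <SpotsInFrame frame="0"><Spot ID="1" name="T1" FRAME="0" POSITION_X="5.0" POSITION_Y="6.0"/></SpotsInFrame>
  <SpotsInFrame frame="1">
   <Spot ID="2" name="T1a" FRAME="1" POSITION_X="4.0" POSITION_Y="6.0"/>
   <Spot ID="3" name="T1b" FRAME="1" POSITION_X="7.0" POSITION_Y="6.0"/>
  </SpotsInFrame>
 </AllSpots>
 <AllTracks><Track TRACK_ID="0">
  <Edge SPOT_SOURCE_ID="1" SPOT_TARGET_ID="2"/>
  <Edge SPOT_SOURCE_ID="1" SPOT_TARGET_ID="3"/>
 </Track></AllTracks>
</Model></TrackMate>
"""


class TestReadTrackingXml:
    def test_empty_track_list(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text(
            "<TrackMate><Model><AllSpots/><AllTracks/></Model></TrackMate>"
        )
        assert ft.read_tracking_xml(path) == []

    def test_two_spots_one_edge(self, tmp_path):
        path = tmp_path / "t.xml"
        path.write_text(XML_TWO_SPOTS)
        tracks = ft.read_tracking_xml(path)
        assert len(tracks) == 1
        assert [s.frame for s in tracks[0].spots] == [0, 1]
        assert tracks[0].spots[0].x == 5.0 and tracks[0].spots[0].y == 6.0
        assert tracks[0].spots[0].name == "A"

    def test_division_preserves_branch_names(self, tmp_path):
        path = tmp_path / "d.xml"
        path.write_text(XML_DIVISION)
        tracks = ft.read_tracking_xml(path)
        assert len(tracks) == 1 and len(tracks[0].spots) == 3
        names = {s.name for s in tracks[0].spots if s.frame == 1}
        assert names == {"T1a", "T1b"}

    def test_malformed_xml_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<TrackMate><Model><AllSpots>")
        with pytest.raises(FormatError):
            ft.read_tracking_xml(path)

    def test_edge_to_missing_spot_raises_integrity_error(self, tmp_path):
        path = tmp_path / "m.xml"
        path.write_text(XML_TWO_SPOTS.replace('SPOT_TARGET_ID="2"', 'SPOT_TARGET_ID="99"'))
        with pytest.raises(IntegrityError):
            ft.read_tracking_xml(path)

    def test_xml_round_trip(self, tmp_path):
        path = tmp_path / "d.xml"
        path.write_text(XML_DIVISION)
        tracks = ft.read_tracking_xml(path)
        out = tmp_path / "out.xml"
        ft.write_tracking_xml(tracks, out)
        again = ft.read_tracking_xml(out)
        assert [(s.frame, s.x, s.y, s.name) for s in again[0].spots] == [
            (s.frame, s.x, s.y, s.name) for s in tracks[0].spots
        ]


def _track(frames_xy, name="A", track_id=0):
    spots = tuple(
        Spot(spot_id=i, frame=f, x=x, y=y, name=name)
        for i, (f, x, y) in enumerate(frames_xy)
    )
    return Track(track_id=track_id, spots=spots)


class TestCloseTrackGaps:
    def test_single_gap_linear_midpoint(self):
        closed = ft.close_track_gaps(_track([(1, 0, 0), (3, 2, 2)]))
        inserted = [s for s in closed.spots if s.interpolated]
        assert len(inserted) == 1
        assert inserted[0].frame == 2
        assert (inserted[0].x, inserted[0].y) == (1.0, 1.0)
        assert inserted[0].label_value == 0

    def test_no_gaps_is_identity(self):
        track = _track([(0, 0, 0), (1, 1, 1), (2, 2, 2)])
        assert ft.close_track_gaps(track).spots == track.spots

    def test_three_frame_gap_interpolation(self):
        closed = ft.close_track_gaps(_track([(0, 0, 0), (4, 3, 6)]))
        inserted = sorted(
            (s for s in closed.spots if s.interpolated), key=lambda s: s.frame
        )
        assert [(s.frame, s.x, s.y) for s in inserted] == [
            (1, 0.75, 1.5), (2, 1.5, 3.0), (3, 2.25, 4.5)
        ]

    def test_duplicate_frames_raise(self):
        with pytest.raises(IntegrityError):
            ft.close_track_gaps(_track([(1, 0, 0), (1, 1, 1)]))

    @given(
        frames=st.lists(
            st.integers(min_value=0, max_value=30), min_size=2, max_size=8, unique=True
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_gap_closing_idempotent_and_contiguous(self, frames):
        track = _track([(f, float(f), float(2 * f)) for f in sorted(frames)])
        once = ft.close_track_gaps(track)
        twice = ft.close_track_gaps(once)
        got = sorted(s.frame for s in once.spots)
        assert got == list(range(min(frames), max(frames) + 1))
        assert sorted(s.frame for s in twice.spots) == got
        assert sum(s.interpolated for s in twice.spots) == sum(
            s.interpolated for s in once.spots
        )


class TestSplitLineage:
    def test_linear_track_is_identity(self):
        track = _track([(0, 0, 0), (1, 1, 1)])
        out = ft.split_lineage(track)
        assert len(out) == 1 and out[0].spots == track.spots

    def test_one_division_two_branches_share_root(self):
        spots = (
            Spot(spot_id=1, frame=0, x=0, y=0, name="T"),
            Spot(spot_id=2, frame=1, x=-1, y=0, name="Ta"),
            Spot(spot_id=3, frame=1, x=1, y=0, name="Tb"),
        )
        out = ft.split_lineage(Track(track_id=0, spots=spots))
        assert len(out) == 2
        for branch in out:
            assert branch.spots[0].name == "T"  # shared ancestor duplicated
            assert len(branch.spots) == 2

    def test_two_successive_divisions_give_four_leaves(self):
        spots = [Spot(spot_id=0, frame=0, x=0, y=0, name="T")]
        sid = 1
        for frame, names in ((1, ["Ta", "Tb"]), (2, ["Taa", "Tab", "Tba", "Tbb"])):
            for name in names:
                spots.append(Spot(spot_id=sid, frame=frame, x=sid, y=0, name=name))
                sid += 1
        out = ft.split_lineage(Track(track_id=0, spots=tuple(spots)))
        assert len(out) == 4
        assert sorted(b.spots[-1].name for b in out) == ["Taa", "Tab", "Tba", "Tbb"]

    def test_inconsistent_branch_names_raise(self):
        spots = (
            Spot(spot_id=1, frame=0, x=0, y=0, name="T"),
            Spot(spot_id=2, frame=1, x=0, y=0, name="Xa"),
        )
        with pytest.raises(IntegrityError):
            ft.split_lineage(Track(track_id=0, spots=spots))


class TestStacks:
    def test_image_stack_round_trip(self, tmp_path):
        data = np.random.default_rng(0).uniform(0, 1, (3, 2, 8, 8))
        stack = ft.ImageStack(data=data, channel_names=("cyan", "magenta"),
                              pixel_size=0.335, frame_interval=15.0)
        path = tmp_path / "img.tif"
        ft.write_image_stack(stack, path)
        again = ft.read_image_stack(path)
        np.testing.assert_array_equal(again.data, data)
        assert again.channel_names == ("cyan", "magenta")
        assert again.pixel_size == 0.335
        assert again.frame_interval == 15.0

    def test_label_stack_bit_exact(self, tmp_path):
        data = np.random.default_rng(0).integers(0, 5, (2, 16, 16))
        path = tmp_path / "lab.tif"
        ft.write_label_stack(ft.LabelStack(data=data), path)
        np.testing.assert_array_equal(ft.read_label_stack(path).data, data)

    def test_negative_labels_rejected(self):
        with pytest.raises(FormatError):
            ft.LabelStack(data=np.array([[[-1, 0]]]))

    def test_non_integer_labels_rejected(self):
        with pytest.raises(FormatError):
            ft.LabelStack(data=np.array([[[0.5, 0.0]]]))


class TestIntensityTable:
    def test_round_trip(self, tmp_path):
        tracks = [
            IntensityTrack(
                track_id=i,
                branch=f"T{i}",
                frames=np.arange(4),
                channel_means={
                    "cyan": np.array([0.1, 0.2, 0.3, 0.4]) * (i + 1),
                    "magenta": np.array([1.0, 0.9, 0.8, 0.7]),
                },
                interpolated_mask=np.array([False, True, False, False]),
                x=np.arange(4.0),
                y=np.arange(4.0) + 1,
                labels=np.array([1, 0, 1, 1]),
            )
            for i in range(2)
        ]
        path = tmp_path / "t.csv"
        ft.write_intensity_table(tracks, path)
        again = ft.read_intensity_table(path)
        assert len(again) == 2
        for a, b in zip(tracks, again):
            assert a.track_id == b.track_id and a.branch == b.branch
            np.testing.assert_array_equal(a.frames, b.frames)
            np.testing.assert_array_equal(a.interpolated_mask, b.interpolated_mask)
            for ch in a.channel_means:
                np.testing.assert_allclose(a.channel_means[ch], b.channel_means[ch])


class TestPhaseJson:
    def test_key_convention(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text('{"0_5": "G1", "1_5": "G1/S"}')
        labels = ft.read_phase_json(path)
        assert labels == {(0, 5): PhaseLabel.G1, (1, 5): PhaseLabel.G1S}

    def test_round_trip(self, tmp_path):
        labels = {(0, 1): PhaseLabel.G1, (3, 2): PhaseLabel.DARK}
        path = tmp_path / "p.json"
        ft.write_phase_json(labels, path)
        assert ft.read_phase_json(path) == labels

    def test_unknown_phase_raises_vocabulary_error(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text('{"0_5": "G0"}')
        with pytest.raises(VocabularyError, match="G1"):
            ft.read_phase_json(path)

    def test_custom_key_parser(self, tmp_path):
        path = tmp_path / "p.json"
        path.write_text('{"f0-l5": "S/G2/M"}')
        parser = lambda k: tuple(int(part[1:]) for part in k.split("-"))
        assert ft.read_phase_json(path, key_parser=parser) == {
            (0, 5): PhaseLabel.SG2M
        }
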