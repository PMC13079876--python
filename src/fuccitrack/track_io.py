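"""Readers, writers and track post-processing for the pipeline's artifacts.

Conventions (used everywhere in this package):

* frames are 0-based integers;
* spot positions are pixel coordinates in image convention — x to the
  right, y downwards, origin at the top-left pixel center;
* image stacks are ``(time, channel, y, x)``, label stacks ``(time, y, x)``
  with background 0;
* branch names follow the tracker's auto-naming convention: all spots of a
  track share a root name, and one letter is appended per branch after each
  division (``"1" → "1a", "1b"``), so divisions are recoverable from the
  spot names alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import tifffile
from lxml import etree

from .errors import FormatError, IntegrityError
from .phases import PhaseLabel, parse_phase


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spot:
    """One detection: a nucleus center at one frame.

    ``label_value`` is the id of the mask instance under the spot in that
    frame's label image (0 when unknown). ``interpolated`` marks spots
    inserted by gap closing: their position is interpolated but no mask is
    known for them, so they are excluded from intensity extraction.
    """

    spot_id: int
    frame: int
    x: float
    y: float
    label_value: int = 0
    name: str = ""
    interpolated: bool = False

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        if self.label_value < 0:
            raise ValueError("label_value must be >= 0")


@dataclass(frozen=True)
class Track:
    """A connected set of spots, possibly branching at divisions."""

    track_id: int
    spots: tuple[Spot, ...]
    parent_track: int | None = None

    def __post_init__(self) -> None:
        if not self.spots:
            raise ValueError("track must contain at least one spot")
        object.__setattr__(
            self, "spots", tuple(sorted(self.spots, key=lambda s: (s.frame, s.name)))
        )


@dataclass
class ImageStack:
    """A ``(time, channel, y, x)`` fluorescence stack with named channels."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size: float | None = None  # µm per pixel
    frame_interval: float | None = None  # minutes per frame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(
                f"image stack must be 4-D (time, channel, y, x), got shape "
                f"{self.data.shape}"
            )
        if np.any(self.data < 0):
            raise FormatError("image intensities must be non-negative")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )

    def channel(self, name: str) -> np.ndarray:
        """The ``(time, y, x)`` sub-stack of one named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.data[:, idx]


@dataclass
class LabelStack:
    """A ``(time, y, x)`` integer instance-label stack, background 0.

    Labels need not be consistent across frames — identity over time is
    supplied by tracking, not by the label values.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(
                f"label stack must be 3-D (time, y, x), got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr)):
                arr = arr.astype(np.int64)
            else:
                raise FormatError("label stack must contain integer values")
        if np.any(arr < 0):
            raise FormatError("label values must be >= 0 (background is 0)")
        self.data = arr


# ---------------------------------------------------------------------------
# Tracking XML
# ---------------------------------------------------------------------------

def read_tracking_xml(path: str | Path) -> list[Track]:
    """Read tracks from tracker XML (TrackMate dialect).

    Expects ``Model/AllSpots/SpotsInFrame/Spot`` elements and
    ``Model/AllTracks/Track/Edge`` elements. Spots not referenced by any
    track edge are dropped. Raises :class:`FormatError` on malformed XML and
    :class:`IntegrityError` when an edge references an unknown spot.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed tracking XML {path}: {exc}") from exc
    root = tree.getroot()
    model = root.find("Model") if root.tag != "Model" else root
    if model is None:
        raise FormatError(f"{path}: missing <Model> element")
    all_spots = model.find("AllSpots")
    if all_spots is None:
        raise FormatError(f"{path}: missing <AllSpots> element")

    spots: dict[int, Spot] = {}
    for frame_el in all_spots.findall("SpotsInFrame"):
        frame_attr = frame_el.get("frame")
        for spot_el in frame_el.findall("Spot"):
            try:
                sid = int(spot_el.get("ID"))
                frame = int(float(spot_el.get("FRAME", frame_attr)))
                x = float(spot_el.get("POSITION_X"))
                y = float(spot_el.get("POSITION_Y"))
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: <Spot> element missing/invalid ID, FRAME or "
                    f"POSITION attributes: {exc}"
                ) from exc
            label = int(float(spot_el.get("LABEL", 0)))
            spots[sid] = Spot(
                spot_id=sid,
                frame=frame,
                x=x,
                y=y,
                label_value=label,
                name=spot_el.get("name", ""),
            )

    tracks: list[Track] = []
    all_tracks = model.find("AllTracks")
    if all_tracks is None:
        return tracks
    for track_el in all_tracks.findall("Track"):
        track_id = int(track_el.get("TRACK_ID", len(tracks)))
        member_ids: set[int] = set()
        for edge_el in track_el.findall("Edge"):
            for attr in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID"):
                raw = edge_el.get(attr)
                if raw is None:
                    raise FormatError(
                        f"{path}: <Edge> in track {track_id} missing {attr}"
                    )
                sid = int(raw)
                if sid not in spots:
                    raise IntegrityError(
                        f"{path}: track {track_id} references spot {sid} "
                        f"absent from AllSpots"
                    )
                member_ids.add(sid)
        if member_ids:
            tracks.append(
                Track(track_id=track_id, spots=tuple(spots[i] for i in member_ids))
            )
    return tracks


def write_tracking_xml(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks in the same XML dialect :func:`read_tracking_xml` reads.

    Edges connect frame-consecutive spots within each branch; at a division
    the last pre-division spot is connected to the first spot of each child
    branch.
    """
    root = etree.Element("TrackMate")
    model = etree.SubElement(root, "Model")
    all_spots = etree.SubElement(model, "AllSpots")
    frames: dict[int, list[Spot]] = {}
    for track in tracks:
        for spot in track.spots:
            frames.setdefault(spot.frame, []).append(spot)
    for frame in sorted(frames):
        frame_el = etree.SubElement(all_spots, "SpotsInFrame", frame=str(frame))
        for spot in frames[frame]:
            etree.SubElement(
                frame_el,
                "Spot",
                ID=str(spot.spot_id),
                name=spot.name,
                FRAME=str(spot.frame),
                POSITION_X=repr(float(spot.x)),
                POSITION_Y=repr(float(spot.y)),
                LABEL=str(spot.label_value),
            )
    all_tracks = etree.SubElement(model, "AllTracks")
    for track in tracks:
        track_el = etree.SubElement(all_tracks, "Track", TRACK_ID=str(track.track_id))
        for branch in split_lineage(track):
            prev: Spot | None = None
            for spot in branch.spots:
                if prev is not None and spot.spot_id != prev.spot_id:
                    etree.SubElement(
                        track_el,
                        "Edge",
                        SPOT_SOURCE_ID=str(prev.spot_id),
                        SPOT_TARGET_ID=str(spot.spot_id),
                    )
                prev = spot
    # deduplicate edges shared between branches
    seen: set[tuple[str, str]] = set()
    for track_el in all_tracks.findall("Track"):
        for edge in list(track_el):
            key = (edge.get("SPOT_SOURCE_ID"), edge.get("SPOT_TARGET_ID"))
            if key in seen:
                track_el.remove(edge)
            else:
                seen.add(key)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Track post-processing
# ---------------------------------------------------------------------------

def _branch_groups(track: Track) -> dict[str, list[Spot]]:
    groups: dict[str, list[Spot]] = {}
    for spot in track.spots:
        groups.setdefault(spot.name, []).append(spot)
    for name in groups:
        groups[name].sort(key=lambda s: s.frame)
    return groups


def close_track_gaps(track: Track) -> Track:
    """Fill missing frames within each branch by linear interpolation.

    For every gap between consecutive spots of a branch, new spots are
    inserted at linearly interpolated positions. Inserted spots carry
    ``label_value`` 0 and ``interpolated=True`` — the position can be
    interpolated, but the mask instance at the missing frame is unknown.
    Idempotent. Raises :class:`IntegrityError` on duplicate frames within a
    branch.
    """
    if len(track.spots) < 2:
        return track
    next_id = max(s.spot_id for s in track.spots) + 1
    new_spots: list[Spot] = list(track.spots)
    for name, spots in _branch_groups(track).items():
        frames = [s.frame for s in spots]
        if len(frames) != len(set(frames)):
            raise IntegrityError(
                f"track {track.track_id}: duplicate frames in branch {name!r}"
            )
        for a, b in zip(spots, spots[1:]):
            span = b.frame - a.frame
            for k in range(1, span):
                t = k / span
                new_spots.append(
                    Spot(
                        spot_id=next_id,
                        frame=a.frame + k,
                        x=a.x + t * (b.x - a.x),
                        y=a.y + t * (b.y - a.y),
                        label_value=0,
                        name=name,
                        interpolated=True,
                    )
                )
                next_id += 1
    return replace(track, spots=tuple(new_spots))


def split_lineage(track: Track) -> list[Track]:
    """Split a branching track into one simple root-to-leaf track per leaf.

    Branch membership is read from the spot names (letters appended per
    division): a spot belongs to every leaf whose name it prefixes, so
    spots before a division are duplicated into each daughter branch.
    Raises :class:`IntegrityError` when the names are not prefix-consistent.
    """
    groups = _branch_groups(track)
    names = sorted(groups)
    root = min(names, key=len)
    for name in names:
        if not name.startswith(root):
            raise IntegrityError(
                f"track {track.track_id}: branch name {name!r} does not "
                f"extend root {root!r}"
            )
        if name != root and name[:-1] not in groups:
            raise IntegrityError(
                f"track {track.track_id}: branch {name!r} has no parent "
                f"branch {name[:-1]!r}"
            )
    leaves = [n for n in names if not any(m != n and m.startswith(n) for m in names)]
    out: list[Track] = []
    for leaf in sorted(leaves):
        spots = [s for s in track.spots if leaf.startswith(s.name)]
        frames = [s.frame for s in sorted(spots, key=lambda s: s.frame)]
        if len(frames) != len(set(frames)):
            raise IntegrityError(
                f"track {track.track_id}: duplicate frames on lineage path "
                f"to leaf {leaf!r}"
            )
        out.append(Track(track_id=track.track_id, spots=tuple(spots)))
    return out


def assign_labels_from_stack(tracks: Sequence[Track], labels: LabelStack) -> list[Track]:
    """Fill each spot's ``label_value`` from the label image under it.

    The label is read at the spot's rounded (y, x) position in its frame;
    spots already carrying a label, and interpolated spots, are left
    untouched.
    """
    n_t, n_y, n_x = labels.data.shape
    out = []
    for track in tracks:
        spots = []
        for spot in track.spots:
            if spot.label_value == 0 and not spot.interpolated:
                yi = int(round(spot.y))
                xi = int(round(spot.x))
                if 0 <= spot.frame < n_t and 0 <= yi < n_y and 0 <= xi < n_x:
                    value = int(labels.data[spot.frame, yi, xi])
                    spot = replace(spot, label_value=value)
            spots.append(spot)
        out.append(replace(track, spots=tuple(spots)))
    return out


# ---------------------------------------------------------------------------
# Image / label stacks (TIFF)
# ---------------------------------------------------------------------------

def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a TCYX stack as multi-page TIFF with a JSON metadata description."""
    meta = {
        "axes": "TCYX",
        "channel_names": list(stack.channel_names),
        "pixel_size_um": stack.pixel_size,
        "frame_interval_min": stack.frame_interval,
    }
    tifffile.imwrite(
        str(path), stack.data, description=json.dumps(meta),
        photometric="minisblack",
    )


def read_image_stack(
    path: str | Path, channel_names: Sequence[str] | None = None
) -> ImageStack:
    """Read a TIFF image stack as ``(time, channel, y, x)``.

    3-D input is treated as single-channel. Channel names come from the
    JSON description written by :func:`write_image_stack` when present,
    from ``channel_names`` otherwise, with ``ch0..chN`` as fallback.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    if data.ndim == 3:
        data = data[:, None]
    if data.ndim != 4:
        raise FormatError(f"{path}: cannot interpret shape {data.shape} as TCYX")
    names = channel_names or meta.get("channel_names") or [
        f"ch{i}" for i in range(data.shape[1])
    ]
    return ImageStack(
        data=data,
        channel_names=tuple(names),
        pixel_size=meta.get("pixel_size_um"),
        frame_interval=meta.get("frame_interval_min"),
    )


def write_label_stack(stack: LabelStack, path: str | Path) -> None:
    tifffile.imwrite(
        str(path), stack.data.astype(np.int32), photometric="minisblack"
    )


def read_label_stack(path: str | Path) -> LabelStack:
    """Read a (time, y, x) integer label TIFF; rejects negative/non-integer."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return LabelStack(data=data)


# ---------------------------------------------------------------------------
# Intensity tables (CSV) — schema shared with signal_processing
# ---------------------------------------------------------------------------

#: CSV schema: one row per spot, intensity columns prefixed ``mean_``.
TABLE_BASE_COLUMNS = ("track_id", "branch", "frame", "x", "y", "label", "interpolated")


def write_intensity_table(tracks: Sequence["IntensityTrack"], path: str | Path) -> None:
    """Write intensity tracks as a flat CSV (one row per spot)."""
    import pandas as pd

    rows = []
    for tr in tracks:
        n = len(tr.frames)
        x = tr.x if tr.x is not None else np.full(n, np.nan)
        y = tr.y if tr.y is not None else np.full(n, np.nan)
        lab = tr.labels if tr.labels is not None else np.zeros(n, dtype=int)
        for i in range(n):
            row = {
                "track_id": tr.track_id,
                "branch": tr.branch,
                "frame": int(tr.frames[i]),
                "x": float(x[i]),
                "y": float(y[i]),
                "label": int(lab[i]),
                "interpolated": bool(tr.interpolated_mask[i]),
            }
            for ch, values in tr.channel_means.items():
                row[f"mean_{ch}"] = float(values[i])
            rows.append(row)
    pd.DataFrame(rows, columns=None).to_csv(path, index=False)


def read_intensity_table(path: str | Path) -> list["IntensityTrack"]:
    """Read a CSV written by :func:`write_intensity_table`."""
    import pandas as pd

    from .signal_processing import IntensityTrack

    df = pd.read_csv(path)
    missing = set(TABLE_BASE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    channels = [c[len("mean_"):] for c in df.columns if c.startswith("mean_")]
    tracks = []
    for (track_id, branch), group in df.groupby(["track_id", "branch"], sort=True):
        group = group.sort_values("frame")
        tracks.append(
            IntensityTrack(
                track_id=int(track_id),
                branch=str(branch) if not pd.isna(branch) else "",
                frames=group["frame"].to_numpy(dtype=int),
                channel_means={
                    ch: group[f"mean_{ch}"].to_numpy(dtype=float) for ch in channels
                },
                interpolated_mask=group["interpolated"].to_numpy(dtype=bool),
                x=group["x"].to_numpy(dtype=float),
                y=group["y"].to_numpy(dtype=float),
                labels=group["label"].to_numpy(dtype=int),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Phase-label JSON
# ---------------------------------------------------------------------------

def _default_key_parser(key: str) -> tuple[int, int]:
    """Parse the ``"<frame>_<label>"`` key convention."""
    try:
        frame_str, label_str = key.split("_")
        return int(frame_str), int(label_str)
    except ValueError as exc:
        raise FormatError(
            f"phase-label key {key!r} does not follow the 'frame_label' "
            f"convention"
        ) from exc


def read_phase_json(
    path: str | Path,
    key_parser: Callable[[str], tuple[int, int]] = _default_key_parser,
) -> dict[tuple[int, int], PhaseLabel]:
    """Read per-mask phase annotations from JSON.

    The file maps mask identifiers to phase strings. The default key
    convention is ``"<frame>_<label>"`` (a documented convention of this
    package, since no community schema exists); pass ``key_parser`` to adapt
    other schemas. Unknown phase strings raise a vocabulary error listing
    the allowed values.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: phase JSON must be an object")
    return {key_parser(k): parse_phase(v) for k, v in raw.items()}


def write_phase_json(
    labels: Mapping[tuple[int, int], PhaseLabel], path: str | Path
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {f"{frame}_{label}": phase.value for (frame, label), phase in labels.items()},
            fh,
            indent=1,
        )
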