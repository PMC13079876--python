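"""From masks + images + tracks to per-track FUCCI intensity time series.

The alignment to a reference cycle (see :mod:`fuccitrack.cycle_alignment`)
compares intensity *dynamics*, not absolute intensities, so the extracted
signals are prepared by smoothing, per-track z-scoring (which compensates
for expression-level differences between individual nuclei) and first
differencing, in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .track_io import ImageStack, LabelStack, Track, split_lineage
from .errors import UnalignableTrackError


@dataclass
class IntensityTrack:
    """Per-track time series of mean nuclear intensities per channel."""

    track_id: int
    branch: str
    frames: np.ndarray  # int, strictly increasing
    channel_means: dict[str, np.ndarray]  # arbitrary fluorescence units
    interpolated_mask: np.ndarray  # bool, True where the mask was unknown
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
        n = len(self.frames)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if len(self.interpolated_mask) != n:
            raise ValueError("interpolated_mask length mismatch")
        for ch, values in self.channel_means.items():
            values = np.asarray(values, dtype=float)
            if len(values) != n:
                raise ValueError(f"channel {ch!r} length mismatch")
            self.channel_means[ch] = values

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class FeatureSequence:
    """A prepared signal ready for DTW, with its transform provenance.

    ``values`` has shape (n,) for a single feature or (n, k) for k features;
    ``provenance`` records the source channel(s) and transforms in order.
    """

    values: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_nuclear_intensities(
    labels: LabelStack,
    images: ImageStack,
    tracks: Sequence[Track],
) -> list[IntensityTrack]:
    """Mean nuclear intensity per spot and channel along each lineage branch.

    For every non-interpolated spot, the mean of the image pixels whose
    label equals the spot's ``label_value`` in that frame is taken, per
    channel. Interpolated spots (whose mask is unknown) and spots whose
    label is absent from the frame yield missing values, which are filled
    by linear interpolation over time so that gap-closed tracks produce
    gapless signals.
    """
    if labels.data.shape[0] != images.data.shape[0] or (
        labels.data.shape[1:] != images.data.shape[2:]
    ):
        raise ValueError(
            f"labels {labels.data.shape} and images {images.data.shape} do "
            f"not share (time, y, x) dimensions"
        )
    out: list[IntensityTrack] = []
    for track in tracks:
        for branch in split_lineage(track):
            spots = sorted(branch.spots, key=lambda s: s.frame)
            n = len(spots)
            frames = np.array([s.frame for s in spots])
            means = {ch: np.full(n, np.nan) for ch in images.channel_names}
            for i, spot in enumerate(spots):
                if spot.interpolated:
                    continue
                mask = labels.data[spot.frame] == spot.label_value
                if spot.label_value == 0 or not mask.any():
                    warnings.warn(
                        f"track {track.track_id} frame {spot.frame}: label "
                        f"{spot.label_value} absent from frame; value left "
                        f"missing",
                        stacklevel=2,
                    )
                    continue
                for c, ch in enumerate(images.channel_names):
                    means[ch][i] = float(images.data[spot.frame, c][mask].mean())
            for ch in means:
                means[ch] = _fill_missing(means[ch])
            out.append(
                IntensityTrack(
                    track_id=track.track_id,
                    branch=spots[-1].name,
                    frames=frames,
                    channel_means=means,
                    interpolated_mask=np.array([s.interpolated for s in spots]),
                    x=np.array([s.x for s in spots]),
                    y=np.array([s.y for s in spots]),
                    labels=np.array([s.label_value for s in spots]),
                )
            )
    return out


def _fill_missing(values: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs; edge NaNs take the nearest value."""
    values = np.asarray(values, dtype=float)
    valid = np.isfinite(values)
    if valid.all():
        return values
    if not valid.any():
        return values  # fully missing; downstream validation will reject
    idx = np.arange(len(values))
    return np.interp(idx, idx[valid], values[valid])


# ---------------------------------------------------------------------------
# Frame-wise normalization
# ---------------------------------------------------------------------------

def percentile_normalize_frames(
    images: ImageStack, p_low: float = 1.0, p_high: float = 99.0
) -> ImageStack:
    """Frame-wise percentile normalization (flat-field stand-in).

    Per frame and channel, intensities are mapped affinely so the ``p_low``
    percentile goes to 0 and ``p_high`` to 1, then clipped to [0, 1]. A
    constant frame is mapped to all-zero with a warning.
    """
    if not 0 <= p_low < p_high <= 100:
        raise ValueError("require 0 <= p_low < p_high <= 100")
    data = images.data.astype(float).copy()
    for t in range(data.shape[0]):
        for c in range(data.shape[1]):
            frame = data[t, c]
            lo, hi = np.percentile(frame, [p_low, p_high])
            if hi == lo:
                warnings.warn(
                    f"frame {t} channel {c} is constant at percentile range; "
                    f"mapped to zero",
                    stacklevel=2,
                )
                data[t, c] = 0.0
            else:
                data[t, c] = np.clip((frame - lo) / (hi - lo), 0.0, 1.0)
    return ImageStack(
        data=data,
        channel_names=images.channel_names,
        pixel_size=images.pixel_size,
        frame_interval=images.frame_interval,
    )


# ---------------------------------------------------------------------------
# 1-D signal operators
# ---------------------------------------------------------------------------

def smooth(signal: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with window shrinking at the boundaries.

    Works on a 1-D signal or row-wise on a 2-D array (each row smoothed
    independently with the identical operator — important when query
    windows and reference windows must be transformed bit-identically).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 1")
    signal = np.asarray(signal, dtype=float)
    if window == 1:
        return signal.copy()
    squeeze = signal.ndim == 1
    x = signal[None, :] if squeeze else signal
    n = x.shape[1]
    half = window // 2
    cs = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    out = (cs[:, hi] - cs[:, lo]) / (hi - lo)
    return out[0] if squeeze else out


def zscore(signal: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit standard deviation (per track)."""
    signal = np.asarray(signal, dtype=float)
    std = signal.std()
    if std == 0:
        raise UnalignableTrackError(
            "zero-variance signal cannot be z-scored; DARK or constant tracks "
            "should be excluded from alignment"
        )
    return (signal - signal.mean()) / std


def derivative(signal: np.ndarray) -> np.ndarray:
    """First difference; output is one sample shorter than the input."""
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2:
        raise ValueError("derivative requires at least 2 samples")
    return np.diff(signal)


def preprocess_signal(values: np.ndarray, window: int = 5) -> np.ndarray:
    """The full preparation chain: smooth, then z-score, then differentiate."""
    return derivative(zscore(smooth(values, window)))


def preprocess_for_dtw(
    track: IntensityTrack,
    channel: str | Sequence[str],
    window: int = 5,
) -> FeatureSequence:
    """Prepare one or several channels of a track for DTW.

    Each channel goes through smooth → z-score → derivative; several
    channels are stacked as columns of a multi-feature sequence.
    """
    channels = [channel] if isinstance(channel, str) else list(channel)
    if len(track) < window + 1:
        raise ValueError(
            f"track length {len(track)} too short for window {window}"
        )
    columns = [preprocess_signal(track.channel_means[ch], window) for ch in channels]
    values = columns[0] if len(columns) == 1 else np.column_stack(columns)
    provenance = tuple(
        f"{ch}:smooth(window={window})->zscore->derivative" for ch in channels
    )
    return FeatureSequence(values=values, provenance=provenance)
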