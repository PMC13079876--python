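"""Cell-cycle pseudotime by subsequence dynamic time warping.

The method: average full-cycle FUCCI intensity tracks into a reference
curve indexed by cell-cycle percentage (0–100), then align each query track
— which need not span a whole cycle — to that reference by subsequence DTW.
The alignment is open at both ends on the reference and closed on the
query, so a partial track finds the reference window it came from. The
matched reference percentages give each query frame a pseudotime; the
amount of time-axis stretching and compression the warp needs, divided by
the query length, is the *relative time distortion*, a score that is small
for cells following the reference cycle and large for cells that do not —
notably G1-arrested cells, whose near-constant signal cannot be mapped onto
the moving reference without heavy warping.

Because the alignment runs on smoothed, z-scored signal derivatives, it
carries no information about absolute intensities; the distortion score is
exposed precisely so that such non-conforming alignments can be flagged
instead of being silently trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UnalignableTrackError
from .signal_processing import (
    FeatureSequence,
    IntensityTrack,
    preprocess_signal,
)


# ---------------------------------------------------------------------------
# Reference curve
# ---------------------------------------------------------------------------

@dataclass
class ReferenceCurve:
    """Averaged FUCCI dynamics over one full cycle on a percentage grid."""

    percentage: np.ndarray  # strictly increasing, 0 .. 100
    channel_means: dict[str, np.ndarray]
    n_source_tracks: int = 0
    frame_interval: float | None = None  # minutes, for absolute-time readout

    def __post_init__(self) -> None:
        self.percentage = np.asarray(self.percentage, dtype=float)
        if self.percentage[0] != 0 or self.percentage[-1] != 100:
            raise ValueError("percentage grid must run from 0 to 100")
        if np.any(np.diff(self.percentage) <= 0):
            raise ValueError("percentage grid must be strictly increasing")
        for ch, values in self.channel_means.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(self.percentage):
                raise ValueError(f"channel {ch!r} length mismatch")
            self.channel_means[ch] = values

    def __len__(self) -> int:
        return len(self.percentage)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_source_tracks={self.n_source_tracks}\n")
            if self.frame_interval is not None:
                fh.write(f"# frame_interval_min={self.frame_interval}\n")
            df = pd.DataFrame({"percentage": self.percentage, **self.channel_means})
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceCurve":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("#") and "=" in line:
                key, _, value = line.lstrip("# ").strip().partition("=")
                meta[key] = value
        df = pd.read_csv(path, comment="#")
        if "percentage" not in df.columns:
            raise FormatError(f"{path}: reference CSV must have a 'percentage' column")
        channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "percentage"}
        return cls(
            percentage=df["percentage"].to_numpy(dtype=float),
            channel_means=channels,
            n_source_tracks=int(meta.get("n_source_tracks", 0)),
            frame_interval=(
                float(meta["frame_interval_min"]) if "frame_interval_min" in meta else None
            ),
        )


def build_reference_curve(
    tracks: Sequence[IntensityTrack],
    grid_points: int = 101,
    frame_interval: float | None = None,
) -> ReferenceCurve:
    """Average full-cycle tracks into a reference curve.

    Each track must span exactly one full cycle (mitosis to mitosis). Every
    track is resampled by linear interpolation onto a common percentage
    grid (0..100) and the resampled tracks are averaged point-wise per
    channel. This percentage-grid resampling is how tracks of different
    durations are brought into register before averaging.
    """
    if len(tracks) < 1:
        raise ValueError("at least one full-cycle track is required")
    short = [t.track_id for t in tracks if len(t) < 10]
    if short:
        raise ValueError(f"tracks {short} have fewer than 10 frames")
    channels = list(tracks[0].channel_means)
    grid = np.linspace(0.0, 100.0, grid_points)
    resampled = {ch: [] for ch in channels}
    for track in tracks:
        pct = np.linspace(0.0, 100.0, len(track))
        for ch in channels:
            resampled[ch].append(np.interp(grid, pct, track.channel_means[ch]))
    return ReferenceCurve(
        percentage=grid,
        channel_means={ch: np.mean(resampled[ch], axis=0) for ch in channels},
        n_source_tracks=len(tracks),
        frame_interval=frame_interval,
    )


# ---------------------------------------------------------------------------
# Subsequence DTW
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WarpingPath:
    """Monotone alignment between query and reference feature indices.

    ``pairs`` is a sequence of (query_index, reference_index) with steps in
    {(1,0), (0,1), (1,1)}; it covers the query completely (first pair at
    query index 0, last at the final query index) while the reference
    window is free.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("empty warping path")
        for (qa, ra), (qb, rb) in zip(self.pairs, self.pairs[1:]):
            step = (qb - qa, rb - ra)
            if step not in ((1, 0), (0, 1), (1, 1)):
                raise ValueError(f"invalid warping step {step}")

    def __len__(self) -> int:
        return len(self.pairs)


def _as_2d(values: np.ndarray | FeatureSequence) -> np.ndarray:
    arr = values.values if isinstance(values, FeatureSequence) else np.asarray(values, float)
    return arr[:, None] if arr.ndim == 1 else arr


def subsequence_dtw(
    query: np.ndarray | FeatureSequence,
    reference: np.ndarray | FeatureSequence,
) -> tuple[WarpingPath, float, tuple[int, int]]:
    """Open-begin/open-end DTW of the full query against a reference window.

    Finds, over all reference start and end positions, the monotone warping
    path minimizing the Euclidean distance between the warped sequences:
    the accumulated cost is the sum of *squared* feature differences along
    the path and the returned distance is its square root, with steps
    {(1,0), (0,1), (1,1)} at unit weight. Squared local costs penalize bad
    value matches quadratically, so a query that fits the reference well
    aligns near-diagonally while a non-conforming query is forced into
    visible time-axis warping. Ties are broken deterministically: fewer
    non-diagonal steps first, then the earliest reference start, then the
    earliest reference end.

    Returns the path, its distance, and the matched reference window as
    inclusive indices ``(start, end)``.
    """
    q = _as_2d(query)
    r = _as_2d(reference)
    n, m = len(q), len(r)
    if n == 0 or m == 0:
        raise ValueError("query and reference must be non-empty")
    if q.shape[1] != r.shape[1]:
        raise ValueError("query and reference feature dimensions differ")

    # local cost matrix: squared Euclidean distance over features
    diff = q[:, None, :] - r[None, :, :]
    cost = (diff * diff).sum(axis=2)

    INF = np.inf
    acc = np.full((n, m), INF)  # accumulated cost
    ndg = np.zeros((n, m), dtype=np.int64)  # non-diagonal steps (tie-break 1)
    start = np.zeros((n, m), dtype=np.int64)  # reference start (tie-break 2)
    back = np.zeros((n, m), dtype=np.int8)  # 0 path start, 1 diag, 2 up, 3 left

    acc[0, :] = cost[0, :]
    start[0, :] = np.arange(m)
    for i in range(1, n):
        ci = cost[i]
        for j in range(m):
            best = (acc[i - 1, j], ndg[i - 1, j] + 1, start[i - 1, j], 2)  # (1,0)
            if j >= 1:
                diag = (acc[i - 1, j - 1], ndg[i - 1, j - 1], start[i - 1, j - 1], 1)
                if diag[:3] < best[:3] or (diag[:3] == best[:3]):
                    best = diag
                left = (acc[i, j - 1], ndg[i, j - 1] + 1, start[i, j - 1], 3)
                if left[:3] < best[:3]:
                    best = left
            acc[i, j] = best[0] + ci[j]
            ndg[i, j] = best[1]
            start[i, j] = best[2]
            back[i, j] = best[3]

    last = n - 1
    order = sorted(
        range(m), key=lambda j: (acc[last, j], ndg[last, j], start[last, j], j)
    )
    end = order[0]
    distance = float(np.sqrt(acc[last, end]))

    # traceback
    pairs = []
    i, j = last, end
    while True:
        pairs.append((i, j))
        move = back[i, j]
        if move == 0:
            break
        if move == 1:
            i, j = i - 1, j - 1
        elif move == 2:
            i, j = i - 1, j
        else:
            i, j = i, j - 1
    pairs.reverse()
    path = WarpingPath(pairs=tuple(pairs))
    return path, distance, (int(start[last, end]), int(end))


# ---------------------------------------------------------------------------
# Time distortion
# ---------------------------------------------------------------------------

def time_distortion(path: WarpingPath) -> float:
    """Stretch/compression count of a warping path.

    Counts the non-diagonal steps — expansions (0,1), which stretch the
    query, plus compressions (1,0), which compress it. A purely diagonal
    path (no warping) scores 0.
    """
    steps = 0
    for (qa, ra), (qb, rb) in zip(path.pairs, path.pairs[1:]):
        if (qb - qa, rb - ra) != (1, 1):
            steps += 1
    return float(steps)


def relative_time_distortion(distortion: float, query_len: int) -> float:
    """Time distortion divided by the number of query frames.

    The division makes the score comparable between tracks of different
    lengths, since subsequences of varying length are matched.
    """
    if query_len < 1:
        raise ValueError("query_len must be >= 1")
    return float(distortion) / query_len


def assign_pseudotime(
    path: WarpingPath,
    percentage: np.ndarray | ReferenceCurve,
    n_frames: int | None = None,
) -> np.ndarray:
    """Cell-cycle percentage per query frame from a feature-level path.

    ``percentage`` gives the percentage of each reference *point*; since
    features are first differences, feature index j spans reference points
    j and j+1, and a path pair (i, j) therefore associates query frame i
    with reference point j and frame i+1 with point j+1. Each frame's
    pseudotime is the mean percentage of its associated reference points.
    The output need not be monotone (warping may plateau locally) but stays
    within the matched window's percentage span.
    """
    pct = (
        percentage.percentage
        if isinstance(percentage, ReferenceCurve)
        else np.asarray(percentage, dtype=float)
    )
    if n_frames is None:
        n_frames = path.pairs[-1][0] + 2  # features = frames - 1
    sums = np.zeros(n_frames)
    counts = np.zeros(n_frames)
    for qi, rj in path.pairs:
        sums[qi] += pct[rj]
        counts[qi] += 1
        sums[qi + 1] += pct[rj + 1]
        counts[qi + 1] += 1
    return sums / counts


# ---------------------------------------------------------------------------
# Arrest flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrestConfig:
    """Threshold on the relative time distortion above which a track is
    flagged as cell-cycle arrested.

    The default of 5.0 reproduces the published choice for HT1080 cells,
    but the value is dataset-dependent and was defined manually from the
    distortion histogram; use :func:`suggest_arrest_threshold` to derive a
    threshold from your own population.
    """

    threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("arrest threshold must be positive")


def flag_arrest(result: "AlignmentResult", config: ArrestConfig | None = None) -> bool:
    """True when the relative time distortion exceeds the threshold."""
    config = config or ArrestConfig()
    return bool(result.relative_time_distortion > config.threshold)


def suggest_arrest_threshold(values: Sequence[float]) -> float:
    """Data-driven threshold separating a bimodal score distribution.

    Places the cut at the largest gap between consecutive sorted values —
    multiplicative gap when all scores are positive (distortions and
    alignment distances are scale-like quantities with heavy upper tails),
    additive gap otherwise — an automated stand-in for thresholding the
    histogram by eye. Meant for clearly bimodal populations; with
    overlapping modes no threshold is reliable.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if len(arr) < 2:
        raise ValueError("need at least two values to place a threshold")
    if np.all(arr > 0):
        gaps = np.log(arr[1:]) - np.log(arr[:-1])
        k = int(np.argmax(gaps))
        return float(np.sqrt(arr[k] * arr[k + 1]))  # geometric midpoint
    gaps = np.diff(arr)
    k = int(np.argmax(gaps))
    return float((arr[k] + arr[k + 1]) / 2)


# ---------------------------------------------------------------------------
# Full alignment of a track
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Everything the alignment of one track against the reference yields."""

    path: WarpingPath
    distance: float
    ref_window: tuple[int, int]  # inclusive feature indices into the (tiled) reference
    pseudotime: np.ndarray  # percentage in [0, 100) per query frame
    time_distortion: float
    relative_time_distortion: float
    arrested: bool
    #: alignment distance per query frame — a match-quality score that is
    #: small only when the track genuinely follows the reference dynamics;
    #: in practice the most robust screen for non-conforming (e.g.
    #: arrested) cells on short tracks.
    normalized_distance: float = 0.0


@dataclass(frozen=True)
class AlignmentConfig:
    """Knobs of the track-to-reference alignment.

    window
        Smoothing window (frames) applied before z-scoring/differencing.
    channels
        Channels used as DTW features (None = all reference channels,
        stacked with Euclidean local cost; a single name gives 1-D mode).
    min_length
        Minimum query length in frames.
    tile_reference
        Tile the reference twice end-to-start so queries straddling mitosis
        can match across the 100→0 wrap; pseudotime is reported modulo 100.
    normalization
        How query and reference amplitudes are brought onto a common scale
        before differencing. ``"windowed_pooled"`` (default): channels are
        mean-centered individually but share one scale (RMS of the
        per-channel standard deviations), and the reference is re-normalized
        per candidate window of the query's length with the *identical*
        operator chain — so a query that is an exact reference slice yields
        exactly distance zero, per-nucleus gain cancels, the inter-channel
        amplitude ratio (which carries cycle-stage information) survives,
        and a channel that is quiet over the query's window stays quiet
        instead of being amplified into a spurious full-swing shape.
        ``"windowed"``: like the default but each channel z-scored
        independently per window. ``"pooled"``: pooled scaling with one
        global reference normalization. ``"global"``: plain per-channel
        z-scoring of query and whole reference — the most literal transform
        chain, fragile when a short query covers a low-variance part of the
        cycle, because window-local z-scoring then amplifies faint trends
        into spurious large shapes.
    arrest
        Threshold configuration for arrest flagging.
    """

    window: int = 15
    channels: tuple[str, ...] | None = None
    min_length: int = 10
    tile_reference: bool = True
    normalization: str = "windowed_pooled"
    arrest: ArrestConfig = field(default_factory=ArrestConfig)

    def __post_init__(self) -> None:
        if self.normalization not in (
            "windowed_pooled", "pooled", "windowed", "global"
        ):
            raise ValueError(
                "normalization must be 'windowed_pooled', 'pooled', "
                "'windowed' or 'global'"
            )


def _channel_features(values: np.ndarray, window: int) -> np.ndarray:
    """Per-channel feature column; an exactly constant channel yields zeros.

    In multi-channel mode a channel can legitimately be flat over the
    query's cycle window (e.g. cyan through S/G2/M): it then carries no
    dynamics and contributes a zero feature column, which matches the
    reference best where that channel is flat too. Tracks where *every*
    channel is flat are rejected upstream as unalignable.
    """
    from .signal_processing import smooth as _smooth

    smoothed = _smooth(np.asarray(values, dtype=float), window)
    if smoothed.std() == 0:
        return np.zeros(len(smoothed) - 1)
    from .signal_processing import derivative as _derivative
    from .signal_processing import zscore as _zscore

    return _derivative(_zscore(smoothed))


def _reference_features(
    reference: ReferenceCurve, channels: Sequence[str], config: AlignmentConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocessed (possibly tiled) reference features and point percentages."""
    if config.tile_reference:
        pct = np.concatenate([reference.percentage[:-1], reference.percentage + 100.0])
        signals = {
            ch: np.concatenate(
                [reference.channel_means[ch][:-1], reference.channel_means[ch]]
            )
            for ch in channels
        }
    else:
        pct = reference.percentage
        signals = {ch: reference.channel_means[ch] for ch in channels}
    if len(channels) == 1:
        features = preprocess_signal(signals[channels[0]], config.window)[:, None]
    else:
        features = np.column_stack(
            [_channel_features(signals[ch], config.window) for ch in channels]
        )
    return features, pct


def _pooled_features(
    signals: dict[str, np.ndarray], channels: Sequence[str], window: int
) -> np.ndarray:
    """Smoothed, pooled-scale-normalized first differences, stacked.

    Channels are mean-centered individually but divided by one shared
    scale — the RMS of the per-channel standard deviations — so the
    relative amplitude between channels survives normalization.
    """
    from .signal_processing import smooth as _smooth

    smoothed = [_smooth(np.asarray(signals[ch], float), window) for ch in channels]
    scale = float(np.sqrt(np.mean([s.var() for s in smoothed])))
    if scale == 0:
        raise UnalignableTrackError(
            "all channels are constant (DARK); track is unalignable"
        )
    return np.column_stack([np.diff((s - s.mean()) / scale) for s in smoothed])


def _tiled_signals(
    reference: ReferenceCurve, channels: Sequence[str], tile: bool
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Raw (untransformed) reference signals and point percentages."""
    if tile:
        pct = np.concatenate([reference.percentage[:-1], reference.percentage + 100.0])
        signals = {
            ch: np.concatenate(
                [reference.channel_means[ch][:-1], reference.channel_means[ch]]
            )
            for ch in channels
        }
    else:
        pct = reference.percentage.copy()
        signals = {ch: reference.channel_means[ch].copy() for ch in channels}
    return signals, pct


def _window_features(raw: np.ndarray, n: int, window: int) -> np.ndarray:
    """Features of every length-``n`` sliding window of a raw reference signal.

    Each window gets the *identical* transform chain a query receives —
    shrinking-edge smoothing, z-scoring over the window, first difference —
    so a query that is an exact reference slice produces bit-identical
    features. Returns shape (n_windows, n-1); exactly constant windows
    yield zeros.
    """
    from .signal_processing import smooth as _smooth

    windows = _smooth(np.lib.stride_tricks.sliding_window_view(raw, n), window)
    mean = windows.mean(axis=1, keepdims=True)
    std = windows.std(axis=1, keepdims=True)
    safe = np.where(std == 0, 1.0, std)
    z = np.where(std == 0, 0.0, (windows - mean) / safe)
    return np.diff(z, axis=1)


def _window_features_pooled(
    raw: dict[str, np.ndarray], channels: Sequence[str], n: int, window: int
) -> np.ndarray:
    """Pooled-scale features of every length-``n`` sliding reference window.

    The window-local analogue of :func:`_pooled_features`: channels are
    mean-centered per window but share one scale per window (RMS of the
    per-channel standard deviations), mirroring exactly what a query of
    length ``n`` undergoes. Returns shape (n_windows, n-1, n_channels).
    """
    from .signal_processing import smooth as _smooth

    smoothed = [
        _smooth(np.lib.stride_tricks.sliding_window_view(raw[ch], n), window)
        for ch in channels
    ]
    var = np.mean([w.var(axis=1) for w in smoothed], axis=0)
    scale = np.sqrt(var)[:, None]
    safe = np.where(scale == 0, 1.0, scale)
    cols = [
        np.diff(
            np.where(scale == 0, 0.0, (w - w.mean(axis=1, keepdims=True)) / safe),
            axis=1,
        )
        for w in smoothed
    ]
    return np.stack(cols, axis=2)


def _best_window_start(query: np.ndarray, candidates: np.ndarray) -> int:
    """Index of the candidate window with the lowest open-end DTW cost.

    ``query`` is (n, c); ``candidates`` is (S, m, c) of identically
    normalized reference windows. The DP is batched across candidates:
    closed at the window start, open at its end, steps {(1,0),(0,1),(1,1)}.
    Ties resolve to the earliest start.
    """
    S, m, _ = candidates.shape
    n = len(query)
    # local cost L[s, i, j]: squared Euclidean, consistent with the exact DP
    local = ((query[None, :, None, :] - candidates[:, None, :, :]) ** 2).sum(axis=3)
    acc = np.empty((S, n, m))
    acc[:, 0, 0] = local[:, 0, 0]
    for j in range(1, m):
        acc[:, 0, j] = acc[:, 0, j - 1] + local[:, 0, j]
    for i in range(1, n):
        acc[:, i, 0] = acc[:, i - 1, 0] + local[:, i, 0]
        li = local[:, i]
        ai, aim1 = acc[:, i], acc[:, i - 1]
        for j in range(1, m):
            ai[:, j] = li[:, j] + np.minimum(
                np.minimum(aim1[:, j - 1], aim1[:, j]), ai[:, j - 1]
            )
    scores = acc[:, n - 1, :].min(axis=1)
    return int(np.argmin(scores))


def align_track(
    track: IntensityTrack,
    reference: ReferenceCurve,
    config: AlignmentConfig | None = None,
) -> AlignmentResult:
    """Align a track to the reference cycle and score it.

    Pipeline: preprocess both the track and the reference identically
    (smooth → z-score → derivative per channel), run subsequence DTW,
    convert the matched reference percentages into per-frame pseudotime,
    compute the relative time distortion, and flag arrest. Deterministic
    for fixed inputs and configuration. Zero-variance (DARK) tracks raise
    :class:`UnalignableTrackError` — they are unalignable, not arrested.
    """
    config = config or AlignmentConfig()
    if len(track) < config.min_length:
        raise ValueError(
            f"track {track.track_id} has {len(track)} frames; "
            f"minimum is {config.min_length}"
        )
    channels = list(config.channels) if config.channels else list(reference.channel_means)
    for ch in channels:
        if ch not in track.channel_means:
            raise KeyError(f"track {track.track_id} lacks channel {ch!r}")

    if config.normalization in ("pooled", "windowed_pooled"):
        query = _pooled_features(track.channel_means, channels, config.window)
    elif len(channels) == 1:
        query = preprocess_signal(track.channel_means[channels[0]], config.window)[:, None]
    else:
        if all(
            np.std(track.channel_means[ch]) == 0 for ch in channels
        ):
            raise UnalignableTrackError(
                f"track {track.track_id}: all channels are constant (DARK); "
                f"track is unalignable"
            )
        query = np.column_stack(
            [_channel_features(track.channel_means[ch], config.window) for ch in channels]
        )

    if config.normalization == "pooled":
        raw, ref_pct = _tiled_signals(reference, channels, config.tile_reference)
        ref_features = _pooled_features(raw, channels, config.window)
        path, distance, window = subsequence_dtw(query, ref_features)
    elif config.normalization in ("windowed", "windowed_pooled"):
        raw, ref_pct_all = _tiled_signals(reference, channels, config.tile_reference)
        n_points = len(track)
        if len(ref_pct_all) < n_points:
            raise ValueError(
                f"track {track.track_id} is longer than the reference grid"
            )
        if config.normalization == "windowed_pooled":
            candidates = _window_features_pooled(
                raw, channels, n_points, config.window
            )
        else:
            candidates = np.stack(
                [_window_features(raw[ch], n_points, config.window) for ch in channels],
                axis=2,
            )
        s = _best_window_start(query, candidates)
        ref_features = candidates[s]
        ref_pct = ref_pct_all[s : s + n_points]
        path, distance, window = subsequence_dtw(query, ref_features)
        window = (window[0] + s, window[1] + s)
    else:
        ref_features, ref_pct = _reference_features(reference, channels, config)
        path, distance, window = subsequence_dtw(query, ref_features)
    distortion = time_distortion(path)
    relative = relative_time_distortion(distortion, len(track))
    pseudotime = assign_pseudotime(path, ref_pct, n_frames=len(track))
    pseudotime = np.mod(pseudotime, 100.0)
    arrested = relative > config.arrest.threshold
    return AlignmentResult(
        path=path,
        distance=distance,
        ref_window=window,
        pseudotime=pseudotime,
        time_distortion=distortion,
        relative_time_distortion=relative,
        arrested=arrested,
        normalized_distance=distance / len(track),
    )


def align_tracks(
    tracks: Sequence[IntensityTrack],
    reference: ReferenceCurve,
    config: AlignmentConfig | None = None,
) -> pd.DataFrame:
    """Align many tracks; returns a tidy per-frame report.

    Unalignable (zero-variance) and too-short tracks are reported with a
    status instead of aborting the run.
    """
    config = config or AlignmentConfig()
    rows = []
    for track in tracks:
        try:
            result = align_track(track, reference, config)
        except UnalignableTrackError:
            status, result = "unalignable", None
        except ValueError:
            status, result = "too_short", None
        else:
            status = "ok"
        for i, frame in enumerate(track.frames):
            rows.append(
                {
                    "track_id": track.track_id,
                    "branch": track.branch,
                    "frame": int(frame),
                    "status": status,
                    "pseudotime": (
                        float(result.pseudotime[i]) if result is not None else np.nan
                    ),
                    "relative_time_distortion": (
                        result.relative_time_distortion if result is not None else np.nan
                    ),
                    "normalized_distance": (
                        result.normalized_distance if result is not None else np.nan
                    ),
                    "arrested": result.arrested if result is not None else False,
                }
            )
    return pd.DataFrame(rows)
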