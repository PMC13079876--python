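"""Synthetic FUCCI tracks and movies with full ground truth.

The generator emulates the signal structure of a two-color cell-cycle
reporter movie: cyan rises through G1, both channels are high across the
G1/S window, magenta dominates S/G2/M, and both channels are near-dark in
a short window around mitosis. Optional ingredients mirror the failure
modes seen in real multiplexed acquisitions: a cytoplasmic (tubulin-like)
channel with nucleus-shaped voids, spectral bleed-through from that channel
into cyan, G1-arrested subpopulations, and additive Gaussian noise scaled
to a target SNR under the in-mask/background SNR estimator.

Every stochastic draw is routed through a single seed, so all generated
artifacts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .evaluation import compute_snr
from .phases import ClassifierConfig, PhaseLabel, classify_intensity
from .signal_processing import IntensityTrack
from .track_io import ImageStack, LabelStack, Spot, Track


def _default_cyan_profile(g1_end: float, g1s_end: float, dark: float):
    """Saturating rise through G1, fall through G1/S, faint decaying tail.

    Breakpoints are placed so the slope keeps changing (real reporter
    kinetics decelerate as the protein accumulates); the intensity crosses
    10% of the maximum exactly at the end of the dark window (sensor turns
    on) and at the G1/S → S/G2/M boundary (sensor turns off).
    """
    rise = ((0.06, 0.1), (0.23, 0.42), (0.43, 0.68), (0.65, 0.86), (0.85, 0.97))
    fall = ((0.4, 0.62), (0.73, 0.32),)
    pts = [(0.0, 0.0), (dark, 0.1)]
    for f, v in rise[1:]:
        pts.append((dark + f * (g1_end - dark), v))
    pts.append((g1_end, 1.0))
    for f, v in fall:
        pts.append((g1_end + f * (g1s_end - g1_end), v))
    pts.append((g1s_end, 0.1))
    pts += [(58.0, 0.04), (70.0, 0.02), (88.0, 0.01), (97.0, 0.0), (100.0, 0.0)]
    return tuple(pts)


def _default_magenta_profile(g1_end: float, g1s_end: float, dark: float):
    """Decelerating accumulation from the G1/S boundary, sharp mitotic drop.

    Exactly zero through most of G1 (the reporter is absent, not faintly
    drifting), crossing 10% of the maximum exactly at the G1 → G1/S
    boundary, rising with continuously decreasing slope to a late-cycle
    peak, then degraded steeply into the mitotic dark window.
    """
    onset = g1_end - dark
    pts = [(0.0, 0.0), (onset, 0.0), (g1_end, 0.1)]
    rise = ((45.0, 0.32), (51.0, 0.56), (58.0, 0.74), (66.0, 0.86), (75.0, 0.94))
    pts += [p for p in rise if p[0] > g1_end]
    pts += [(85.0, 1.0), (91.0, 0.55), (97.0, 0.0), (100.0, 0.0)]
    return tuple(pts)


@dataclass(frozen=True)
class CycleModel:
    """Piecewise-linear model of FUCCI intensity versus cycle percentage.

    Defaults: a 100-frame cycle split 40% G1 / 15% G1/S / 45% S/G2/M, a
    ±3% near-dark window around mitosis, Gaussian intensity noise with a
    standard deviation of 5% of the dynamic range, and no bleed-through.
    The default profiles are a minimal piecewise-linear reading of typical
    reporter dynamics — a stand-in for any specific cell line's measured
    reference, with every breakpoint configurable.
    """

    cycle_frames: int = 100
    phase_fractions: tuple[float, float, float] = (0.40, 0.15, 0.45)  # G1, G1/S, S/G2/M
    dark_window: float = 3.0  # percentage span around mitosis with both channels ~0
    cyan_profile: tuple[tuple[float, float], ...] | None = None
    magenta_profile: tuple[tuple[float, float], ...] | None = None
    noise_sigma: float = 0.05  # fraction of dynamic range
    bleed_through: float = 0.0  # fraction of cytoplasmic signal added to cyan
    bleaching: float = 0.0015  # multiplicative intensity loss per frame
    arrest_plateau: float = 35.0  # percentage where arrested cells halt (late G1)
    arrest_speed: float = 0.15  # residual progression rate of arrested cells
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        if any(f <= 0 for f in self.phase_fractions):
            raise ValueError("phase fractions must be positive")
        if not 0 <= self.bleed_through < 1:
            raise ValueError("bleed_through must be in [0, 1)")
        if not 0 <= self.bleaching < 1:
            raise ValueError("bleaching must be in [0, 1)")
        g1_end = 100.0 * self.phase_fractions[0]
        g1s_end = 100.0 * (self.phase_fractions[0] + self.phase_fractions[1])
        if self.cyan_profile is None:
            object.__setattr__(
                self, "cyan_profile",
                _default_cyan_profile(g1_end, g1s_end, self.dark_window),
            )
        if self.magenta_profile is None:
            object.__setattr__(
                self, "magenta_profile",
                _default_magenta_profile(g1_end, g1s_end, self.dark_window),
            )
        for profile in (self.cyan_profile, self.magenta_profile):
            if any(v < 0 for _, v in profile):
                raise ValueError("profiles must be non-negative")

    @property
    def g1_end(self) -> float:
        return 100.0 * self.phase_fractions[0]

    @property
    def g1s_end(self) -> float:
        return 100.0 * (self.phase_fractions[0] + self.phase_fractions[1])

    @property
    def dynamic_range(self) -> float:
        return max(
            max(v for _, v in self.cyan_profile),
            max(v for _, v in self.magenta_profile),
        )

    def intensity(self, percentage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Noiseless (cyan, magenta) intensity at the given percentages."""
        pct = np.asarray(percentage, dtype=float)
        cx, cv = zip(*self.cyan_profile)
        mx, mv = zip(*self.magenta_profile)
        return np.interp(pct, cx, cv), np.interp(pct, mx, mv)

    def phase_at(self, percentage: float) -> PhaseLabel:
        """The phase encoded by the noiseless profiles at one percentage.

        Defined as the 10%-threshold color combination of the profiles
        themselves, which makes the simulator's ground truth and the
        intensity classifier agree by construction on noiseless data.
        """
        cyan, magenta = self.intensity(np.array([percentage]))
        cx = max(v for _, v in self.cyan_profile)
        mx = max(v for _, v in self.magenta_profile)
        return classify_intensity(
            float(cyan[0]), float(magenta[0]), cx, mx, ClassifierConfig()
        )


def simulate_fucci_track(
    model: CycleModel,
    start_percentage: float,
    n_frames: int,
    arrested: bool = False,
    rng: np.random.Generator | None = None,
    track_id: int = 0,
) -> tuple[IntensityTrack, np.ndarray]:
    """One synthetic intensity track plus its ground-truth percentages.

    Normal cells advance linearly at 100/cycle_frames percent per frame,
    wrapping at 100. Arrested cells progress at a strongly reduced rate
    (``arrest_speed`` of the normal pace — the G1 reporter keeps slowly
    accumulating in an arrested cell) until they reach the G1 plateau
    percentage, where they stay indefinitely. Intensities are the profile
    values attenuated by photobleaching (``(1 - bleaching)`` per frame, as
    in any real time-lapse) plus Gaussian noise (``noise_sigma`` × dynamic
    range), clipped at zero.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    step = 100.0 / model.cycle_frames
    raw = start_percentage + step * np.arange(n_frames)
    if arrested:
        if start_percentage >= model.arrest_plateau:
            pct = np.full(n_frames, start_percentage)
        else:
            crawl = start_percentage + model.arrest_speed * step * np.arange(n_frames)
            pct = np.minimum(crawl, model.arrest_plateau)
    else:
        pct = raw % 100.0
    cyan, magenta = model.intensity(pct)
    if model.bleaching > 0:
        decay = (1.0 - model.bleaching) ** np.arange(n_frames)
        cyan = cyan * decay
        magenta = magenta * decay
    sigma = model.noise_sigma * model.dynamic_range
    if sigma > 0:
        cyan = cyan + rng.normal(0.0, sigma, n_frames)
        magenta = magenta + rng.normal(0.0, sigma, n_frames)
    track = IntensityTrack(
        track_id=track_id,
        branch="",
        frames=np.arange(n_frames),
        channel_means={
            "cyan": np.clip(cyan, 0.0, None),
            "magenta": np.clip(magenta, 0.0, None),
        },
        interpolated_mask=np.zeros(n_frames, dtype=bool),
    )
    return track, pct


@dataclass(frozen=True)
class MovieConfig:
    """Geometry, population and acquisition parameters of a rendered movie."""

    frames: int = 60
    height: int = 256
    width: int = 256
    n_nuclei: int = 10
    nucleus_radius: tuple[float, float] = (8.0, 12.0)
    target_snr: float | None = None  # None = no pixel noise
    tubulin_on: bool = False
    motion_sigma: float = 1.0  # pixels per frame of random walk
    arrest_fraction: float = 0.0
    noise_floor: float = 0.05  # minimum pixel-noise sigma when targeting an SNR
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.frames, self.height, self.width, self.n_nuclei) <= 0:
            raise ValueError("dimensions and nucleus count must be positive")
        if not 0 <= self.arrest_fraction <= 1:
            raise ValueError("arrest_fraction must be in [0, 1]")


def simulate_population(
    model: CycleModel, movie_cfg: MovieConfig
) -> list[tuple[IntensityTrack, np.ndarray, bool]]:
    """A seeded mixed population of normal and G1-arrested tracks.

    ``round(arrest_fraction * n_nuclei)`` tracks are arrested, the rest
    cycle normally. Normal cells start uniformly anywhere on the cycle;
    arrested cells start uniformly within G1 below the arrest plateau —
    a cell arrested at the G1 checkpoint cannot sit in S/G2/M.
    """
    rng = np.random.default_rng(movie_cfg.seed)
    n = movie_cfg.n_nuclei
    n_arrested = int(round(movie_cfg.arrest_fraction * n))
    out = []
    for i in range(n):
        arrested = i < n_arrested
        if arrested:
            start = float(rng.uniform(model.dark_window, model.arrest_plateau))
        else:
            start = float(rng.uniform(0.0, 100.0))
        track, pct = simulate_fucci_track(
            model, start, movie_cfg.frames, arrested=arrested, rng=rng, track_id=i
        )
        out.append((track, pct, arrested))
    return out


def _place_nuclei(cfg: MovieConfig, r_max: float, rng: np.random.Generator) -> np.ndarray:
    margin = r_max + 2.0
    min_sep = 2.0 * r_max + 4.0
    if cfg.width <= 2 * margin or cfg.height <= 2 * margin:
        raise ValueError("nuclei do not fit in the frame")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < cfg.n_nuclei:
        tries += 1
        if tries > 5000 * cfg.n_nuclei:
            raise ValueError(
                f"cannot place {cfg.n_nuclei} nuclei of radius <= {r_max} in "
                f"{cfg.height}x{cfg.width} without overlap"
            )
        x = rng.uniform(margin, cfg.width - margin)
        y = rng.uniform(margin, cfg.height - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_sep**2 for cx, cy in centers):
            centers.append((x, y))
    return np.array(centers)  # (n, 2) as (x, y)


def _solve_noise(
    stacks: dict[str, np.ndarray],
    inside: np.ndarray,
    target: float,
    sigma0: float,
) -> tuple[float, float]:
    """Baseline offset and noise sigma hitting the target SNR.

    The estimator pools pixels over all masks, so the in-mask standard
    deviation contains both the biological intensity spread and the pixel
    noise. When the noiseless stack's SNR already exceeds the target, the
    noise sigma is raised; otherwise a uniform nuclear baseline (mimicking
    non-specific nuclear fluorescence) is added until the target is met.
    """

    def snr_at(c: float, sigma: float) -> float:
        values = []
        for arr in stacks.values():
            mu_in = arr[inside].mean()
            mu_out = arr[~inside].mean() if (~inside).any() else 0.0
            var_in = arr[inside].var()
            values.append((mu_in + c - mu_out) / np.sqrt(var_in + sigma**2))
        return max(values)

    if snr_at(0.0, sigma0) >= target:
        lo, hi = sigma0, sigma0
        while snr_at(0.0, hi) > target:
            hi *= 2
            if hi > 1e6:
                break
        for _ in range(60):
            mid = (lo + hi) / 2
            if snr_at(0.0, mid) > target:
                lo = mid
            else:
                hi = mid
        return 0.0, (lo + hi) / 2
    lo, hi = 0.0, 1.0
    while snr_at(hi, sigma0) < target:
        hi *= 2
        if hi > 1e6:
            break
    for _ in range(60):
        mid = (lo + hi) / 2
        if snr_at(mid, sigma0) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2, sigma0


def render_movie(
    population: Sequence[tuple[IntensityTrack, np.ndarray, bool]],
    cfg: MovieConfig,
    model: CycleModel | None = None,
) -> tuple[ImageStack, LabelStack, list[Track]]:
    """Render a population into a multichannel movie with ground truth.

    Nuclei are ellipses performing seeded random walks; the cyan/magenta
    channels take each track's intensity uniformly inside its mask. With
    ``tubulin_on`` a cytoplasmic annulus with a nucleus-shaped void is
    added, and ``model.bleed_through`` of it leaks into the cyan channel.
    With ``target_snr`` set, a nuclear baseline and additive Gaussian noise
    are calibrated so the in-mask/background SNR estimator on the output
    approximates the target. Returns the image stack, the ground-truth
    label stack (nucleus i has label i+1 in every frame) and ground-truth
    tracks.
    """
    if len(population) != cfg.n_nuclei:
        raise ValueError("population size must equal n_nuclei")
    rng = np.random.default_rng(cfg.seed + 1)  # independent of population draws
    r_lo, r_hi = cfg.nucleus_radius
    if cfg.n_nuclei * np.pi * r_hi**2 > 0.5 * cfg.height * cfg.width:
        raise ValueError("infeasible geometry: nuclei cover too much of the frame")
    radii = rng.uniform(r_lo, r_hi, size=(cfg.n_nuclei, 2))  # (ry, rx) per nucleus
    centers = _place_nuclei(cfg, r_hi, rng)
    steps = rng.normal(0.0, cfg.motion_sigma, size=(cfg.frames, cfg.n_nuclei, 2))
    steps[0] = 0.0
    margin = r_hi + 2.0
    walks = np.cumsum(steps, axis=0) + centers[None, :, :]
    walks[..., 0] = np.clip(walks[..., 0], margin, cfg.width - margin)
    walks[..., 1] = np.clip(walks[..., 1], margin, cfg.height - margin)

    channel_names = ("cyan", "magenta") + (("tubulin",) if cfg.tubulin_on else ())
    images = np.zeros((cfg.frames, len(channel_names), cfg.height, cfg.width))
    labels = np.zeros((cfg.frames, cfg.height, cfg.width), dtype=np.int32)
    annulus_width = 4.0
    tubulin_level = 0.8

    for t in range(cfg.frames):
        for i, (track, _, _) in enumerate(population):
            x, y = walks[t, i]
            ry, rx = radii[i]
            rr, cc = draw_ellipse(y, x, ry, rx, shape=(cfg.height, cfg.width))
            labels[t, rr, cc] = i + 1
            images[t, 0, rr, cc] = track.channel_means["cyan"][t]
            images[t, 1, rr, cc] = track.channel_means["magenta"][t]
        if cfg.tubulin_on:
            for i in range(cfg.n_nuclei):
                x, y = walks[t, i]
                ry, rx = radii[i]
                rr, cc = draw_ellipse(
                    y, x, ry + annulus_width, rx + annulus_width,
                    shape=(cfg.height, cfg.width),
                )
                ring = labels[t, rr, cc] != i + 1
                images[t, 2, rr[ring], cc[ring]] = tubulin_level
    bleed = model.bleed_through if model is not None else 0.0
    if cfg.tubulin_on and bleed > 0:
        images[:, 0] += bleed * images[:, 2]

    if cfg.target_snr is not None:
        inside = labels > 0
        baseline, sigma = _solve_noise(
            {"cyan": images[:, 0], "magenta": images[:, 1]},
            inside,
            cfg.target_snr,
            cfg.noise_floor,
        )
        for c in (0, 1):
            images[:, c][inside] += baseline
        images += 3.0 * sigma  # global pedestal so clipping at 0 stays rare
        images += rng.normal(0.0, sigma, size=images.shape)
        images = np.clip(images, 0.0, None)

    tracks = []
    spot_id = 0
    for i, (track, _, _) in enumerate(population):
        spots = []
        for t in range(cfg.frames):
            x, y = walks[t, i]
            spots.append(
                Spot(
                    spot_id=spot_id,
                    frame=t,
                    x=float(x),
                    y=float(y),
                    label_value=i + 1,
                    name=f"T{i}",
                )
            )
            spot_id += 1
        tracks.append(Track(track_id=i, spots=tuple(spots)))
    stack = ImageStack(data=images, channel_names=channel_names)
    return stack, LabelStack(data=labels), tracks


@dataclass
class SimulatedMovie:
    """A rendered movie bundled with its complete ground truth."""

    images: ImageStack
    labels: LabelStack
    tracks: list[Track]
    intensity_tracks: list[IntensityTrack]
    percentages: list[np.ndarray]
    arrested: list[bool]
    model: CycleModel
    config: MovieConfig

    @property
    def snr(self) -> float:
        return compute_snr(self.images, self.labels).snr

    def phase_of(self, nucleus: int, frame: int) -> PhaseLabel:
        return self.model.phase_at(float(self.percentages[nucleus][frame]))


def simulate_movie(model: CycleModel, cfg: MovieConfig) -> SimulatedMovie:
    """Population + rendering in one call, with ground truth attached."""
    population = simulate_population(model, cfg)
    images, labels, tracks = render_movie(population, cfg, model=model)
    return SimulatedMovie(
        images=images,
        labels=labels,
        tracks=tracks,
        intensity_tracks=[p[0] for p in population],
        percentages=[p[1] for p in population],
        arrested=[p[2] for p in population],
        model=model,
        config=cfg,
    )
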