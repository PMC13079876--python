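"""Intensity-based cell-cycle phase calling and sensor-scheme translation.

Two-color cell-cycle reporters encode the phase in the combination of two
nuclear fluorophores. In the convention used throughout this package
("FUCCI" scheme) cyan-only marks G1, both colors mark the G1/S transition,
and magenta-only marks S/G2/M. Around mitosis both channels are close to
dark, which is reported as the explicit ``DARK`` outcome rather than forced
into one of the three phases.

The classifier is the classic thresholding rule: a channel counts as "on"
when its intensity exceeds a fixed fraction (default 10%) of the channel's
maximum signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .errors import VocabularyError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .signal_processing import IntensityTrack


class PhaseLabel(str, Enum):
    """Closed vocabulary of per-mask cell-cycle calls."""

    G1 = "G1"
    G1S = "G1/S"
    SG2M = "S/G2/M"
    DARK = "DARK"


#: Accepted spellings for each phase (JSON files, CLI arguments).
_PHASE_ALIASES: dict[str, PhaseLabel] = {
    "G1": PhaseLabel.G1,
    "G1/S": PhaseLabel.G1S,
    "G1S": PhaseLabel.G1S,
    "S/G2/M": PhaseLabel.SG2M,
    "SG2M": PhaseLabel.SG2M,
    "DARK": PhaseLabel.DARK,
}


def parse_phase(value: str) -> PhaseLabel:
    """Parse a phase string, raising :class:`VocabularyError` if unknown."""
    key = str(value).strip().upper()
    try:
        return _PHASE_ALIASES[key]
    except KeyError:
        allowed = sorted({p.value for p in PhaseLabel})
        raise VocabularyError(
            f"unknown phase label {value!r}; allowed values: {allowed}"
        ) from None


class ColorCombination(str, Enum):
    """The three informative color combinations of a two-color sensor."""

    CYAN_ONLY = "cyan-only"
    BOTH = "both"
    MAGENTA_ONLY = "magenta-only"


@dataclass(frozen=True)
class SensorScheme:
    """Mapping from color combination to phase name for one sensor family.

    The mapping must be a bijection on the three color combinations; the
    near-dark window of each sensor is described in ``dark_phase_note``
    because it differs between sensor families and carries no color
    information.
    """

    name: str
    mapping: Mapping[ColorCombination, str]
    dark_phase_note: str = ""

    def __post_init__(self) -> None:
        keys = set(self.mapping)
        if keys != set(ColorCombination):
            raise ValueError(
                f"scheme {self.name!r} must map exactly the three color "
                f"combinations, got {sorted(k.value for k in keys)}"
            )
        if len(set(self.mapping.values())) != 3:
            raise ValueError(f"scheme {self.name!r} mapping is not a bijection")

    def combination_for(self, phase_name: str) -> ColorCombination:
        for combo, name in self.mapping.items():
            if name == phase_name:
                return combo
        raise VocabularyError(
            f"phase {phase_name!r} is not produced by scheme {self.name!r}; "
            f"known phases: {sorted(self.mapping.values())}"
        )


FUCCI_SCHEME = SensorScheme(
    name="fucci",
    mapping={
        ColorCombination.CYAN_ONLY: PhaseLabel.G1.value,
        ColorCombination.BOTH: PhaseLabel.G1S.value,
        ColorCombination.MAGENTA_ONLY: PhaseLabel.SG2M.value,
    },
    dark_phase_note="both channels near-dark shortly before and after mitosis",
)

PIP_FUCCI_SCHEME = SensorScheme(
    name="pip-fucci",
    mapping={
        ColorCombination.CYAN_ONLY: "G1",
        ColorCombination.MAGENTA_ONLY: "S",
        ColorCombination.BOTH: "G2/M",
    },
    dark_phase_note="both channels near-dark between the G1 and S phases",
)

SCHEMES: dict[str, SensorScheme] = {
    FUCCI_SCHEME.name: FUCCI_SCHEME,
    PIP_FUCCI_SCHEME.name: PIP_FUCCI_SCHEME,
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of the relative-threshold classifier.

    relative_threshold
        Fraction of the per-channel maximum above which a channel counts as
        "on" (default 0.10, i.e. 10% of the maximum signal per channel).
    max_scope
        Where the per-channel maximum is taken from: ``per_track`` (default,
        maximum of the track's per-mask mean intensities) or ``per_dataset``
        (caller-supplied global maxima).
    """

    relative_threshold: float = 0.10
    max_scope: str = "per_track"

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_threshold < 1.0:
            raise ValueError("relative_threshold must be in (0, 1)")
        if self.max_scope not in ("per_track", "per_dataset"):
            raise ValueError("max_scope must be 'per_track' or 'per_dataset'")


def classify_intensity(
    cyan: float,
    magenta: float,
    cyan_max: float,
    magenta_max: float,
    config: ClassifierConfig | None = None,
) -> PhaseLabel:
    """Call the phase of one mask from its two mean nuclear intensities.

    A channel is "on" when its intensity exceeds
    ``relative_threshold * channel_max``. The four on/off combinations map to
    G1 (cyan only), G1/S (both), S/G2/M (magenta only) and DARK (neither).
    """
    config = config or ClassifierConfig()
    if cyan_max <= 0 or magenta_max <= 0:
        raise ValueError(
            "per-channel maxima must be positive; all-dark channels cannot "
            "be thresholded"
        )
    cyan_on = cyan > config.relative_threshold * cyan_max
    magenta_on = magenta > config.relative_threshold * magenta_max
    if cyan_on and not magenta_on:
        return PhaseLabel.G1
    if cyan_on and magenta_on:
        return PhaseLabel.G1S
    if magenta_on:
        return PhaseLabel.SG2M
    return PhaseLabel.DARK


def classify_track(
    track: "IntensityTrack",
    config: ClassifierConfig | None = None,
    cyan_channel: str = "cyan",
    magenta_channel: str = "magenta",
    dataset_maxima: Mapping[str, float] | None = None,
) -> list[PhaseLabel]:
    """Per-frame phase calls for an intensity track.

    With ``max_scope='per_track'`` the thresholds are relative to the
    maximum mean intensity the track itself attains in each channel; with
    ``'per_dataset'`` the caller supplies global maxima (e.g. over a whole
    movie). An all-zero channel cannot be thresholded: it is treated as
    permanently off with a warning, and if both channels are dark every
    frame is DARK.
    """
    config = config or ClassifierConfig()
    cyan = np.asarray(track.channel_means[cyan_channel], dtype=float)
    magenta = np.asarray(track.channel_means[magenta_channel], dtype=float)
    if cyan.size == 0:
        raise ValueError("track is empty")

    if config.max_scope == "per_dataset":
        if dataset_maxima is None:
            raise ValueError("max_scope='per_dataset' requires dataset_maxima")
        cyan_max = float(dataset_maxima[cyan_channel])
        magenta_max = float(dataset_maxima[magenta_channel])
    else:
        cyan_max = float(np.max(cyan))
        magenta_max = float(np.max(magenta))

    labels: list[PhaseLabel] = []
    dark_channels = [m <= 0 for m in (cyan_max, magenta_max)]
    if any(dark_channels):
        warnings.warn(
            "channel with zero maximum intensity treated as permanently off",
            stacklevel=2,
        )
    for c, m in zip(cyan, magenta):
        c_on = cyan_max > 0 and c > config.relative_threshold * cyan_max
        m_on = magenta_max > 0 and m > config.relative_threshold * magenta_max
        if c_on and not m_on:
            labels.append(PhaseLabel.G1)
        elif c_on and m_on:
            labels.append(PhaseLabel.G1S)
        elif m_on:
            labels.append(PhaseLabel.SG2M)
        else:
            labels.append(PhaseLabel.DARK)
    return labels


def classify_tracks(
    tracks: Sequence["IntensityTrack"],
    config: ClassifierConfig | None = None,
    cyan_channel: str = "cyan",
    magenta_channel: str = "magenta",
    baseline_correct: bool = True,
) -> list[list[PhaseLabel]]:
    """Dataset-scope classification of many tracks with baseline correction.

    Real movies carry a non-specific nuclear baseline (autofluorescence,
    camera offset) on top of the reporter signal; thresholding raw means at
    10% of the maximum then never switches a channel off. With
    ``baseline_correct`` the per-channel minimum mask mean over the whole
    dataset — the darkest nucleus, typically one passing through mitosis —
    is subtracted before thresholding, and the threshold is taken relative
    to the corrected dataset maximum.
    """
    config = config or ClassifierConfig()
    channels = (cyan_channel, magenta_channel)
    lo = {
        ch: min(float(np.min(tr.channel_means[ch])) for tr in tracks)
        for ch in channels
    }
    if not baseline_correct:
        lo = {ch: 0.0 for ch in channels}
    hi = {
        ch: max(float(np.max(tr.channel_means[ch])) for tr in tracks) - lo[ch]
        for ch in channels
    }
    out = []
    for tr in tracks:
        calls = []
        for c, m in zip(tr.channel_means[cyan_channel], tr.channel_means[magenta_channel]):
            c_on = hi[cyan_channel] > 0 and (
                c - lo[cyan_channel] > config.relative_threshold * hi[cyan_channel]
            )
            m_on = hi[magenta_channel] > 0 and (
                m - lo[magenta_channel]
                > config.relative_threshold * hi[magenta_channel]
            )
            if c_on and not m_on:
                calls.append(PhaseLabel.G1)
            elif c_on and m_on:
                calls.append(PhaseLabel.G1S)
            elif m_on:
                calls.append(PhaseLabel.SG2M)
            else:
                calls.append(PhaseLabel.DARK)
        out.append(calls)
    return out


def map_phases(
    labels: Sequence[PhaseLabel | str],
    source: SensorScheme,
    target: SensorScheme,
) -> list[str]:
    """Translate phase names between sensor conventions.

    The translation goes through the shared color-combination key: e.g. the
    two-color appearance is named G1/S under the FUCCI scheme but G2/M under
    PIP-FUCCI, while magenta-only is S/G2/M under FUCCI and S under
    PIP-FUCCI. G1 (cyan-only) is the same in both. DARK carries no color
    information and maps to DARK.
    """
    out: list[str] = []
    for label in labels:
        name = label.value if isinstance(label, PhaseLabel) else str(label)
        if name == PhaseLabel.DARK.value:
            out.append(PhaseLabel.DARK.value)
            continue
        combo = source.combination_for(name)
        out.append(target.mapping[combo])
    return out
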