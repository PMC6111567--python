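"""Rating-to-class mapping on the 2D arousal-valence plane.

Trials carry continuous arousal and valence self-ratings on a 1-9 scale.
Six scheme variants (four scheme families) map a rating pair to a class:

* ``1D-2CLS-arousal`` / ``1D-2CLS-valence`` -- high iff the rating is
  strictly greater than 5, otherwise low;
* ``1D-3CLS-arousal`` / ``1D-3CLS-valence`` -- high on [6.5, 9], neutral on
  the open interval (3.5, 6.5), low on [1, 3.5];
* ``2D-4CLS`` -- quadrants of the plane with the same >5 convention on each
  axis (HAHV, LAHV, LALV, HALV);
* ``2D-5CLS`` -- the quadrants plus a central neutral box; a trial is
  neutral iff BOTH ratings lie in (3.5, 6.5), otherwise the quadrant rule
  applies.

A rating exactly equal to 5 is "low" on that axis, following the
greater-than-five / otherwise phrasing of the scheme definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from collections.abc import Iterable

__all__ = [
    "SCHEME_NAMES",
    "LabelScheme",
    "ClassLabel",
    "label_scheme",
    "label_rating",
    "class_counts",
    "chance_level",
    "non_neutral_classes",
]

_SCHEME_CLASSES: dict[str, tuple[str, ...]] = {
    "1D-2CLS-arousal": ("LA", "HA"),
    "1D-2CLS-valence": ("LV", "HV"),
    "1D-3CLS-arousal": ("LA", "neutral", "HA"),
    "1D-3CLS-valence": ("LV", "neutral", "HV"),
    "2D-4CLS": ("HAHV", "LAHV", "LALV", "HALV"),
    "2D-5CLS": ("HAHV", "LAHV", "LALV", "HALV", "neutral"),
}

SCHEME_NAMES: tuple[str, ...] = tuple(_SCHEME_CLASSES)


@dataclass(frozen=True)
class LabelScheme:
    """One labeling scheme and its ordered class set."""

    name: str
    classes: tuple[str, ...]

    def __contains__(self, label: str) -> bool:
        return label in self.classes


@dataclass(frozen=True)
class ClassLabel:
    scheme: str
    label: str


def label_scheme(name: str) -> LabelScheme:
    try:
        return LabelScheme(name, _SCHEME_CLASSES[name])
    except KeyError:
        valid = ", ".join(SCHEME_NAMES)
        raise KeyError(f"unknown labeling scheme {name!r}; valid names: {valid}") from None


def _check_rating(value: float, scale: str) -> float:
    value = float(value)
    if not (1.0 <= value <= 9.0):
        raise ValueError(f"{scale} rating {value} outside the [1, 9] scale")
    return value


def _three_level(value: float, low: str, high: str) -> str:
    if value >= 6.5:
        return high
    if value <= 3.5:
        return low
    return "neutral"


def _quadrant(arousal: float, valence: float) -> str:
    a = "H" if arousal > 5 else "L"
    v = "H" if valence > 5 else "L"
    return f"{a}A{v}V"


def label_rating(arousal: float, valence: float, scheme: LabelScheme | str) -> ClassLabel:
    """Assign the class of a rating pair under one scheme."""
    if isinstance(scheme, str):
        scheme = label_scheme(scheme)
    arousal = _check_rating(arousal, "arousal")
    valence = _check_rating(valence, "valence")
    name = scheme.name
    if name == "1D-2CLS-arousal":
        label = "HA" if arousal > 5 else "LA"
    elif name == "1D-2CLS-valence":
        label = "HV" if valence > 5 else "LV"
    elif name == "1D-3CLS-arousal":
        label = _three_level(arousal, "LA", "HA")
    elif name == "1D-3CLS-valence":
        label = _three_level(valence, "LV", "HV")
    elif name == "2D-4CLS":
        label = _quadrant(arousal, valence)
    elif name == "2D-5CLS":
        if 3.5 < arousal < 6.5 and 3.5 < valence < 6.5:
            label = "neutral"
        else:
            label = _quadrant(arousal, valence)
    else:  # pragma: no cover - label_scheme() already validated the name
        raise KeyError(name)
    return ClassLabel(scheme=name, label=label)


def class_counts(
    ratings: Iterable[tuple[float, float]], scheme: LabelScheme | str
) -> dict[str, int]:
    """Count trials per class; every class of the scheme appears, possibly 0."""
    if isinstance(scheme, str):
        scheme = label_scheme(scheme)
    counts = Counter(label_rating(a, v, scheme).label for a, v in ratings)
    return {cls: counts.get(cls, 0) for cls in scheme.classes}


def chance_level(scheme: LabelScheme | str) -> float:
    """Random-guess accuracy in percent: the reciprocal of the class count."""
    if isinstance(scheme, str):
        scheme = label_scheme(scheme)
    return 100.0 / len(scheme.classes)


def non_neutral_classes(scheme: LabelScheme | str) -> tuple[str, ...]:
    """The scheme's classes with ``neutral`` removed (neutral-exclusion runs)."""
    if isinstance(scheme, str):
        scheme = label_scheme(scheme)
    return tuple(c for c in scheme.classes if c != "neutral")
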