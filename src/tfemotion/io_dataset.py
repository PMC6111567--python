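"""Trial containers, dataset I/O, channel montages and windowing.

The on-disk dataset layout is deliberately plain text so it can be inspected
and produced by any tool: a ``ratings.tsv`` table (one row per trial) plus one
tab-delimited numeric matrix per trial under ``trials/``.  Each trial file
starts with a header line of channel names; the following rows are the
channels, in header order, one sample per column.

Trials are assumed to be already preprocessed (down-sampled, band-limited,
artifact-cleaned); this module only offers common-average referencing as an
optional utility for raw inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MONTAGE",
    "CHANNEL_PAIRS",
    "Trial",
    "ChannelConfiguration",
    "Segment",
    "channel_config",
    "channel_config_names",
    "common_average_reference",
    "n_windows",
    "segment_trial",
    "read_dataset",
    "write_dataset",
    "write_feature_table",
    "read_feature_table",
]

#: The 22 scalp electrodes used throughout: 11 left/right symmetric pairs
#: covering parietal, frontal, temporal and occipital regions.
CHANNEL_PAIRS: tuple[tuple[str, str], ...] = (
    ("P3", "P4"),
    ("P7", "P8"),
    ("CP5", "CP6"),
    ("F3", "F4"),
    ("F7", "F8"),
    ("FC1", "FC2"),
    ("FC5", "FC6"),
    ("AF3", "AF4"),
    ("FP1", "FP2"),
    ("T7", "T8"),
    ("O1", "O2"),
)

#: All electrodes appearing in any configuration.
MONTAGE: tuple[str, ...] = tuple(ch for pair in CHANNEL_PAIRS for ch in pair)

# Channel groups as used by the four named configurations.  C2 covers the
# frontal and temporal areas, C3 the parietal and occipital areas, C4 is the
# union of all selected channels.
_C2_CHANNELS = ("FP1", "FP2", "F3", "F4", "F7", "F8", "FC1", "FC2", "T7", "T8", "FC5", "FC6")
_C3_CHANNELS = ("P3", "P4", "CP5", "CP6", "P7", "P8", "O1", "O2")
_C4_CHANNELS = (
    "P3", "P4", "P7", "P8", "CP5", "CP6", "F3", "F4", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6", "AF3", "AF4", "FP1", "FP2", "T7", "T8", "O1", "O2",
)


@dataclass(frozen=True)
class ChannelConfiguration:
    """A named, ordered group of electrodes used for one analysis cell."""

    name: str
    channels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.channels)


def _build_configurations() -> dict[str, ChannelConfiguration]:
    configs: dict[str, ChannelConfiguration] = {}
    for left, right in CHANNEL_PAIRS:
        name = f"C1:{left}-{right}"
        configs[name] = ChannelConfiguration(name, (left, right))
    configs["C2"] = ChannelConfiguration("C2", _C2_CHANNELS)
    configs["C3"] = ChannelConfiguration("C3", _C3_CHANNELS)
    configs["C4"] = ChannelConfiguration("C4", _C4_CHANNELS)
    return configs


_CONFIGURATIONS = _build_configurations()


def channel_config_names() -> tuple[str, ...]:
    """All valid configuration names (11 symmetric pairs plus C2, C3, C4)."""
    return tuple(_CONFIGURATIONS)


def channel_config(name: str) -> ChannelConfiguration:
    """Look up a channel configuration by name, e.g. ``"C4"`` or ``"C1:T7-T8"``."""
    try:
        return _CONFIGURATIONS[name]
    except KeyError:
        valid = ", ".join(_CONFIGURATIONS)
        raise KeyError(f"unknown channel configuration {name!r}; valid names: {valid}") from None


@dataclass
class Trial:
    """One subject x stimulus EEG recording with its emotion self-ratings.

    ``signal`` is ``(n_channels, n_samples)`` in microvolt-scale arbitrary
    units.  The first ``baseline_seconds`` of each trial is a pre-stimulus
    baseline that is dropped before analysis.  ``arousal`` and ``valence``
    are continuous self-assessment ratings on a 1-9 scale.
    """

    subject_id: str
    trial_id: str
    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    arousal: float
    valence: float
    baseline_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) array")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"trial {self.subject_id}/{self.trial_id}: {self.signal.shape[0]} signal rows "
                f"but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"trial {self.subject_id}/{self.trial_id}: duplicate channel names")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.baseline_seconds < 0:
            raise ValueError("baseline_seconds must be nonnegative")
        for scale, value in (("arousal", self.arousal), ("valence", self.valence)):
            if not (1.0 <= value <= 9.0):
                raise ValueError(
                    f"trial {self.subject_id}/{self.trial_id}: {scale} rating {value} "
                    "outside the [1, 9] scale"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return the signal row for one electrode."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"trial {self.subject_id}/{self.trial_id} has no channel {name!r}") from None
        return self.signal[idx]


@dataclass(frozen=True)
class Segment:
    """One windowed slice of a single channel, the unit of TFR analysis."""

    values: np.ndarray
    channel: str
    window_index: int
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("segment values must be 1-D")

    def __len__(self) -> int:
        return self.values.size


def common_average_reference(signal: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every channel.

    After referencing, the cross-channel mean is zero at every sample; the
    operation is idempotent.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[0] < 1:
        raise ValueError("signal must be (n_channels >= 1, n_samples)")
    return signal - signal.mean(axis=0, keepdims=True)


def n_windows(n_samples: int, window: int, step: int) -> int:
    """Number of left-aligned window positions; trailing partial windows drop."""
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def segment_trial(
    trial: Trial,
    window: int = 512,
    step: int = 256,
    drop_baseline: bool = True,
    channels: tuple[str, ...] | None = None,
) -> dict[str, list[Segment]]:
    """Slice a trial into overlapping per-channel segments.

    Windows start at offsets ``0, step, 2*step, ...`` of the post-baseline
    signal and are aligned identically across channels.  A 60 s, 128 Hz trial
    with ``window=512`` and ``step=256`` yields 29 positions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (1 <= step <= window):
        raise ValueError("step must satisfy 1 <= step <= window")
    start = int(round(trial.baseline_seconds * trial.fs)) if drop_baseline else 0
    length = trial.n_samples - start
    count = n_windows(length, window, step)
    if count < 1:
        raise ValueError(
            f"trial {trial.subject_id}/{trial.trial_id}: {length} post-baseline samples, "
            f"shorter than one {window}-sample window"
        )
    names = trial.channel_names if channels is None else tuple(channels)
    out: dict[str, list[Segment]] = {}
    for name in names:
        row = trial.channel(name)
        out[name] = [
            Segment(row[start + w * step : start + w * step + window], name, w, trial.fs)
            for w in range(count)
        ]
    return out


# ---------------------------------------------------------------------------
# dataset directory I/O


def _trial_path(root: Path, subject_id: str, trial_id: str) -> Path:
    return root / "trials" / f"{subject_id}_{trial_id}.tsv"


def write_dataset(trials: list[Trial], root: str | os.PathLike) -> None:
    """Write trials and their ratings table under ``root``.

    Matrices are written at full double precision so a read/write round-trip
    is numerically exact.
    """
    root = Path(root)
    (root / "trials").mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        rows.append(
            {
                "subject_id": trial.subject_id,
                "trial_id": trial.trial_id,
                "arousal": trial.arousal,
                "valence": trial.valence,
                "fs": trial.fs,
                "baseline_s": trial.baseline_seconds,
            }
        )
        path = _trial_path(root, trial.subject_id, trial.trial_id)
        with open(path, "w") as fh:
            fh.write("\t".join(trial.channel_names) + "\n")
            np.savetxt(fh, trial.signal, fmt="%.17g", delimiter="\t")
    pd.DataFrame(rows).to_csv(root / "ratings.tsv", sep="\t", index=False)


def _read_trial_matrix(path: Path) -> tuple[tuple[str, ...], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric value in trial file {path}: {exc}") from None
    return tuple(header), matrix


def read_dataset(root: str | os.PathLike, montage: tuple[str, ...] | None = MONTAGE) -> list[Trial]:
    """Read every trial under ``root``, validating against the ratings table.

    Every trial file must have a ratings row and vice versa; channel headers
    must be unique and (unless ``montage=None``) drawn from the known
    electrode montage.
    """
    root = Path(root)
    ratings_path = root / "ratings.tsv"
    if not ratings_path.exists():
        raise FileNotFoundError(f"no ratings table at {ratings_path}")
    ratings = pd.read_csv(ratings_path, sep="\t", dtype={"subject_id": str, "trial_id": str})
    trials: list[Trial] = []
    seen = set()
    for row in ratings.itertuples(index=False):
        path = _trial_path(root, row.subject_id, row.trial_id)
        if not path.exists():
            raise FileNotFoundError(
                f"ratings table lists trial {row.subject_id}/{row.trial_id} but {path} is missing"
            )
        channel_names, matrix = _read_trial_matrix(path)
        if montage is not None:
            unknown = [ch for ch in channel_names if ch not in montage]
            if unknown:
                raise ValueError(f"trial file {path} has channels outside the montage: {unknown}")
        baseline = float(getattr(row, "baseline_s", 3.0))
        trials.append(
            Trial(
                subject_id=row.subject_id,
                trial_id=row.trial_id,
                signal=matrix,
                fs=float(row.fs),
                channel_names=channel_names,
                arousal=float(row.arousal),
                valence=float(row.valence),
                baseline_seconds=baseline,
            )
        )
        seen.add((row.subject_id, row.trial_id))
    trial_dir = root / "trials"
    if trial_dir.exists():
        for path in sorted(trial_dir.glob("*.tsv")):
            subject_id, _, trial_id = path.stem.partition("_")
            if (subject_id, trial_id) not in seen:
                raise ValueError(f"trial file {path} has no row in the ratings table")
    return trials


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-(subject, trial, window) feature table as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str, "trial_id": str})
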