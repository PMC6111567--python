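"""Thirteen descriptors of a time-frequency surface and vector assembly.

Eight of the descriptors extend classical time-domain statistics to the
joint time-frequency plane (mean, variance, skewness, kurtosis, sum of log
amplitudes, mean absolute deviation, root-mean-square, inter-quartile
range); five extend spectral descriptors (flatness, flux, spectral roll-off,
normalized Renyi entropy, energy concentration).  All are computed over the
full M x N surface of one channel segment, and the per-channel blocks are
concatenated in a fixed canonical order to form the window's feature vector.

Conventions that the formulas leave open:

* unsubscripted logarithms (SLA) are natural; the Renyi entropy is in bits;
* magnitudes inside logarithms are floored at ``log_floor`` so all-zero or
  negative-valued surfaces cannot produce non-finite features;
* flatness is evaluated in the log domain (geometric over arithmetic mean of
  magnitudes) so the M*N-term product cannot underflow;
* the inter-quartile range sorts each frequency column's time values before
  indexing the quartile positions;
* the roll-off has two modes: ``"index"`` (default) reports the normalized
  frequency-bin index below which a fraction ``lambda_rolloff`` of the
  time-marginal mass lies, while ``"literal"`` reports the plain
  ``lambda_rolloff``-scaled total sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_dataset import ChannelConfiguration, Trial, segment_trial
from . import tfr as _tfr

__all__ = [
    "FEATURE_NAMES",
    "FeatureParams",
    "FeatureVector",
    "extract_features",
    "assemble_window_vector",
    "feature_names_for",
    "feature_kind",
    "extract_trial_features",
    "extract_feature_table",
]

logger = logging.getLogger(__name__)

#: Canonical per-channel descriptor order.
FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "sla",
    "mad",
    "rms",
    "iqr",
    "fls",
    "flx",
    "sro",
    "nre",
    "ec",
)


@dataclass(frozen=True)
class FeatureParams:
    """Tunable constants of the descriptor set.

    ``lambda_rolloff`` is the roll-off mass fraction (default 0.85), ``nu``
    the Renyi entropy order (default 3), ``flux_offsets`` the (time, freq)
    forward-difference lags (default (1, 1)).
    """

    lambda_rolloff: float = 0.85
    nu: int = 3
    flux_offsets: tuple[int, int] = (1, 1)
    log_floor: float = 1e-12
    sro_mode: str = "index"

    def __post_init__(self) -> None:
        if not (0 < self.lambda_rolloff <= 1):
            raise ValueError("lambda_rolloff must be in (0, 1]")
        if self.nu < 2:
            raise ValueError("nu must be >= 2")
        if min(self.flux_offsets) < 1:
            raise ValueError("flux offsets must be >= 1")
        if self.sro_mode not in ("index", "literal"):
            raise ValueError("sro_mode must be 'index' or 'literal'")


@dataclass(frozen=True)
class FeatureVector:
    """Ordered concatenation of 13 descriptors per channel at one window."""

    values: np.ndarray
    names: tuple[str, ...]
    window_index: int
    subject_id: str | None = None
    trial_id: str | None = None

    def __len__(self) -> int:
        return self.values.size


def _quartile_position(q: float, M: int) -> int:
    """1-based quartile index round(q * (M + 1)), half away from zero."""
    return int(np.clip(np.floor(q * (M + 1) + 0.5), 1, M))


def extract_features(tfr, params: FeatureParams | None = None) -> dict[str, float]:
    """Compute the 13 descriptors of one time-frequency surface.

    ``tfr`` may be a :class:`~tfemotion.tfr.TFR` or a bare M x N array.
    Returns an ordered name -> value mapping following ``FEATURE_NAMES``.
    """
    if params is None:
        params = FeatureParams()
    rho = np.asarray(getattr(tfr, "values", tfr), dtype=float)
    if rho.ndim != 2 or rho.shape[0] < 2 or rho.shape[1] < 2:
        raise ValueError("time-frequency surface must be at least 2 x 2")
    if not np.all(np.isfinite(rho)):
        raise ValueError("time-frequency surface contains non-finite values")
    M, N = rho.shape
    total = float(rho.sum())
    mean = total / (M * N)
    centered = rho - mean
    variance = float(np.mean(centered**2))
    if variance > 0:
        skewness = float(np.mean(centered**3)) / variance**1.5
        kurtosis = float(np.mean(centered**4)) / variance**2
    else:  # degenerate constant surface: third/fourth moments are 0/0
        skewness = 0.0
        kurtosis = 0.0

    magnitude = np.abs(rho)
    log_mag = np.log(np.maximum(magnitude, params.log_floor))
    sla = float(log_mag.sum())
    mad = float(np.mean(np.abs(centered)))

    if mean < 0:
        logger.warning("negative surface mean %g in RMS; using |mean|", mean)
    rms = float(np.sqrt(abs(mean)))

    lo = _quartile_position(0.25, M)
    hi = _quartile_position(0.75, M)
    ordered = np.sort(rho, axis=0)
    iqr = float(np.mean(ordered[hi - 1] - ordered[lo - 1]))

    mean_mag = float(np.mean(magnitude))
    if mean_mag > 0:
        fls = float(np.exp(np.mean(log_mag)) / mean_mag)
    else:
        fls = 1.0  # all-zero surface: geometric == arithmetic mean

    l, k = params.flux_offsets
    if l < M and k < N:
        flx = float(np.sum(rho[l:, k:] - rho[: M - l, : N - k]))
    else:
        flx = 0.0

    if params.sro_mode == "literal":
        sro = params.lambda_rolloff * total
    else:
        marginal = rho.sum(axis=0)
        cumulative = np.cumsum(marginal)
        threshold = params.lambda_rolloff * total
        reached = np.nonzero(cumulative >= threshold)[0]
        roll_bin = int(reached[0]) + 1 if reached.size else N
        sro = roll_bin / N

    if total != 0:
        p = rho / total  # equals rho / (M * N * mean)
        power_sum = float(np.sum(p**params.nu))
        if power_sum <= 0:
            logger.warning("nonpositive Renyi power sum %g; flooring", power_sum)
            power_sum = params.log_floor
        nre = float(np.log2(power_sum) / (1 - params.nu))
    else:
        logger.warning("zero-sum surface in Renyi entropy; flooring")
        nre = float(np.log2(params.log_floor) / (1 - params.nu))

    ec = float(np.sum(magnitude**2))

    values = {
        "mean": mean,
        "variance": variance,
        "skewness": skewness,
        "kurtosis": kurtosis,
        "sla": sla,
        "mad": mad,
        "rms": rms,
        "iqr": iqr,
        "fls": fls,
        "flx": flx,
        "sro": sro,
        "nre": nre,
        "ec": ec,
    }
    return {name: values[name] for name in FEATURE_NAMES}


def feature_names_for(config: ChannelConfiguration) -> tuple[str, ...]:
    """Canonical ``<channel>__<feature>`` column names for a configuration."""
    return tuple(f"{ch}__{feat}" for ch in config.channels for feat in FEATURE_NAMES)


def feature_kind(column_name: str) -> str:
    """The descriptor kind of a ``<channel>__<feature>`` column name."""
    channel, sep, kind = column_name.partition("__")
    if not sep or kind not in FEATURE_NAMES:
        raise ValueError(f"not a canonical feature column name: {column_name!r}")
    return kind


def assemble_window_vector(
    per_channel_features: dict[str, dict[str, float]],
    config: ChannelConfiguration,
    window_index: int,
    subject_id: str | None = None,
    trial_id: str | None = None,
) -> FeatureVector:
    """Concatenate per-channel descriptor blocks in canonical order.

    The input mapping's iteration order is irrelevant; channels follow the
    configuration and descriptors follow ``FEATURE_NAMES``.
    """
    values = []
    for channel in config.channels:
        if channel not in per_channel_features:
            raise KeyError(f"missing features for channel {channel!r}")
        block = per_channel_features[channel]
        values.extend(block[name] for name in FEATURE_NAMES)
    return FeatureVector(
        values=np.asarray(values, dtype=float),
        names=feature_names_for(config),
        window_index=window_index,
        subject_id=subject_id,
        trial_id=trial_id,
    )


def extract_trial_features(
    trial: Trial,
    config: ChannelConfiguration,
    kernel=None,
    window: int = 512,
    step: int = 256,
    params: FeatureParams | None = None,
) -> list[FeatureVector]:
    """Run the TFR + descriptor stage over every window of one trial.

    Each windowed segment of each configured channel is made analytic,
    transformed with the requested kernel (Choi-Williams by default), and
    summarized by the 13 descriptors; per-channel blocks are concatenated
    into one vector per window position.
    """
    if kernel is None:
        kernel = _tfr.KernelSpec(kind="cwd", beta=0.5)
    segments = segment_trial(trial, window=window, step=step, channels=config.channels)
    count = len(next(iter(segments.values())))
    vectors = []
    for w in range(count):
        per_channel = {}
        for channel in config.channels:
            analytic = _tfr.analytic_signal(segments[channel][w])
            surface = (
                _tfr.wvd(analytic) if kernel.kind == "wvd" else _tfr.cwd(analytic, kernel)
            )
            per_channel[channel] = extract_features(surface, params)
        vectors.append(
            assemble_window_vector(
                per_channel, config, w, subject_id=trial.subject_id, trial_id=trial.trial_id
            )
        )
    return vectors


def extract_feature_table(
    trials: list[Trial],
    config: ChannelConfiguration,
    kernel=None,
    window: int = 512,
    step: int = 256,
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """Feature table over trials: one row per (subject, trial, window).

    Leading columns identify the row and carry the trial's ratings; the
    remaining columns are the canonical ``<channel>__<feature>`` descriptors.
    """
    rows = []
    for trial in trials:
        for vec in extract_trial_features(trial, config, kernel, window, step, params):
            row = {
                "subject_id": trial.subject_id,
                "trial_id": trial.trial_id,
                "window_index": vec.window_index,
                "arousal": trial.arousal,
                "valence": trial.valence,
            }
            row.update(zip(vec.names, vec.values))
            rows.append(row)
    return pd.DataFrame(rows)
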