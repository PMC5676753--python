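"""Sliding-window feature extraction for cyclic sensor signals.

Per selected channel, five features are computed for every sample: the raw
(calibrated, unfiltered) value, the windowed variance, and the three
coefficients of a least-squares second-order polynomial fit over the window.
The window trails the current sample (ends at it) with an overlap of
``window − 1`` samples, so the feature matrix has exactly one row per input
sample; the first ``window − 1`` rows use truncated windows that are refitted
on the shorter support.  The polynomial abscissa is normalized to ``[0, 1]``
per window and the variance uses the population formula (divide by *n*).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import SensorRecording, ValidationError

FEATURES_PER_CHANNEL = 5
_FEATURE_SUFFIXES = ("raw", "var", "c0", "c1", "c2")


@dataclass
class FeatureMatrix:
    """Per-sample feature rows aligned with the source recording."""

    values: np.ndarray  # (n_samples, n_features)
    feature_names: tuple[str, ...]
    window_len_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValidationError("feature matrix shape does not match names")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SubjectStats:
    """Per-feature mean and s.d. of one subject, reusable on unseen data."""

    mean: np.ndarray
    std: np.ndarray


def parse_axes_combo(combo) -> tuple[str, ...]:
    """Parse an axis combination such as ``"AXGZ"`` into ``("AX", "GZ")``.

    Tuples/lists pass through unchanged; compact strings are split into
    two-character channel names (the field's conventional shorthand).
    """
    if not isinstance(combo, str):
        return tuple(combo)
    if len(combo) % 2 != 0 or not combo:
        raise ValidationError(f"cannot parse axes combination {combo!r}")
    return tuple(combo[i : i + 2] for i in range(0, len(combo), 2))


def select_axes(recording: SensorRecording, axes_combo) -> SensorRecording:
    """Restrict a recording to the requested channels, in the requested order."""
    names = parse_axes_combo(axes_combo)
    missing = [a for a in names if a not in recording.channel_names]
    if missing:
        raise ValidationError(
            f"unknown axes {missing}; recording has {recording.channel_names}"
        )
    idx = [recording.channel_names.index(a) for a in names]
    return SensorRecording(
        recording.samples[:, idx],
        channel_names=names,
        sampling_rate=recording.sampling_rate,
        subject_id=recording.subject_id,
    )


def _polyfit_design(npts: int) -> np.ndarray:
    """Pseudo-inverse of the quadratic design matrix on [0, 1], degree
    reduced when there are fewer points than coefficients."""
    t = np.linspace(0.0, 1.0, npts) if npts > 1 else np.zeros(1)
    deg = min(2, npts - 1)
    X = np.vander(t, deg + 1, increasing=True)  # (npts, deg+1)
    return np.linalg.pinv(X)  # (deg+1, npts)


def window_features(
    signal, window_len_s: float, sampling_rate: float | None = None
) -> FeatureMatrix:
    """Compute the per-sample feature matrix of a (multi)channel signal.

    ``signal`` may be a :class:`SensorRecording` or an ``(n, c)`` array (then
    ``sampling_rate`` is required and channels are named ``ch0..``).
    """
    if isinstance(signal, SensorRecording):
        data = signal.samples
        channels = signal.channel_names
        fs = signal.sampling_rate
    else:
        data = np.atleast_2d(np.asarray(signal, dtype=float))
        if data.shape[0] == 1 and data.ndim == 2 and np.asarray(signal).ndim == 1:
            data = data.T
        if sampling_rate is None:
            raise ValidationError("sampling_rate required for array input")
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
        fs = sampling_rate
    n = data.shape[0]
    w = int(round(window_len_s * fs))
    if w < 3:
        raise ValidationError(f"window of {w} samples is too short (need >= 3)")
    if w > n:
        raise ValidationError(f"window of {w} samples exceeds signal length {n}")

    pinv_full = _polyfit_design(w)  # (3, w)
    cols = []
    names = []
    for c, ch in enumerate(channels):
        x = data[:, c]
        raw = x
        var = np.empty(n)
        coef = np.zeros((n, 3))
        # full trailing windows: rows w-1 .. n-1
        W = sliding_window_view(x, w)  # (n-w+1, w)
        var[w - 1 :] = W.var(axis=1)
        coef[w - 1 :, :] = W @ pinv_full.T
        # truncated leading windows: rows 0 .. w-2
        for i in range(w - 1):
            win = x[: i + 1]
            var[i] = win.var()
            p = _polyfit_design(i + 1)
            coef[i, : p.shape[0]] = p @ win
        cols.append(np.column_stack([raw, var, coef]))
        names.extend(f"{ch}:{s}" for s in _FEATURE_SUFFIXES)
    return FeatureMatrix(np.hstack(cols), tuple(names), w)


def compute_features(
    recording: SensorRecording, axes_combo, window_len_s: float
) -> FeatureMatrix:
    """Convenience: axis selection followed by windowed feature extraction."""
    return window_features(select_axes(recording, axes_combo), window_len_s)


_STD_FLOOR = 1e-8


def normalize_per_subject(
    features_by_subject: Mapping[str, FeatureMatrix],
) -> tuple[dict[str, FeatureMatrix], dict[str, SubjectStats]]:
    """Standardize every feature to zero mean / unit s.d. per subject.

    Removes inter-person differences in amplitude and mean.  Returns the
    normalized matrices and the per-subject statistics so that unseen data
    from the same subject can be transformed identically.  Constant features
    get a floored s.d. and normalize to zeros.
    """
    normalized: dict[str, FeatureMatrix] = {}
    stats: dict[str, SubjectStats] = {}
    for subject, fm in features_by_subject.items():
        if fm.n_samples < 2:
            raise ValidationError(
                f"subject {subject!r} has {fm.n_samples} sample(s); need >= 2"
            )
        mean = fm.values.mean(axis=0)
        std = np.maximum(fm.values.std(axis=0), _STD_FLOOR)
        stats[subject] = SubjectStats(mean=mean, std=std)
        normalized[subject] = apply_normalization(fm, stats[subject])
    return normalized, stats


def apply_normalization(fm: FeatureMatrix, stats: SubjectStats) -> FeatureMatrix:
    """Apply stored per-subject statistics to a (possibly unseen) matrix."""
    values = (fm.values - stats.mean) / stats.std
    return FeatureMatrix(values, fm.feature_names, fm.window_len_samples)
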