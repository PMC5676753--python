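"""Data containers and text-based I/O for sensor recordings, labels and models.

Conventions used throughout the package:

* sample indices are 0-based;
* label intervals are half-open ``[start, end)`` in samples;
* the sampling rate is authoritative — timestamps in sensor files are
  optional and are regenerated from the rate on write.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

DEFAULT_CHANNELS = ("AX", "AY", "AZ", "GX", "GY", "GZ")

MODEL_FORMAT = "cycleseg-hhmm"
MODEL_VERSION = 1


class ParseError(ValueError):
    """A sensor or label file could not be parsed."""


class SchemaError(ValueError):
    """File structure does not match the expected schema."""


class ValidationError(ValueError):
    """A container violated one of its invariants."""


class ModelFormatError(ValueError):
    """A model file is unreadable, truncated or of the wrong version."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SensorRecording:
    """Multichannel calibrated sensor time series for one subject.

    ``samples`` has shape ``(n_samples, n_channels)``; channel order follows
    ``channel_names`` (accelerometer AX/AY/AZ, gyroscope GX/GY/GZ by default).
    """

    samples: np.ndarray
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 200.0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D array")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{self.samples.shape[1]} columns but "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class Segment:
    """One labeled half-open interval ``[start, end)`` of samples."""

    start: int
    end: int
    class_name: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentBoundarySet:
    """Ordered, non-overlapping labeled intervals (cycles, bouts or both).

    Within a bout of one class, consecutive cycles are contiguous: the end of
    cycle *k* equals the start of cycle *k + 1*.  Gaps between entries are
    allowed (e.g. transition regions excluded from labeling).
    """

    entries: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [
            e if isinstance(e, Segment) else Segment(*e) for e in self.entries
        ]
        self.validate()

    def validate(self) -> None:
        for prev, cur in zip(self.entries, self.entries[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"entries overlap or are unsorted: "
                    f"[{prev.start},{prev.end}) then [{cur.start},{cur.end})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentBoundarySet) and self.entries == other.entries

    def of_class(self, class_name: str) -> "SegmentBoundarySet":
        return SegmentBoundarySet(
            [e for e in self.entries if e.class_name == class_name]
        )

    def shifted(self, offset: int) -> "SegmentBoundarySet":
        return SegmentBoundarySet(
            [Segment(e.start + offset, e.end + offset, e.class_name) for e in self.entries]
        )

    def start_boundaries(self) -> np.ndarray:
        return np.array([e.start for e in self.entries], dtype=int)

    def per_sample_labels(self, n_samples: int, fill: str = "") -> np.ndarray:
        """Class label per sample; samples outside any entry get ``fill``."""
        labels = np.full(n_samples, fill, dtype=object)
        for e in self.entries:
            labels[e.start : min(e.end, n_samples)] = e.class_name
        return labels

    def merged_bouts(self) -> "SegmentBoundarySet":
        """Merge contiguous same-class entries into bouts."""
        bouts: list[Segment] = []
        for e in self.entries:
            if bouts and bouts[-1].class_name == e.class_name and bouts[-1].end == e.start:
                bouts[-1] = Segment(bouts[-1].start, e.end, e.class_name)
            else:
                bouts.append(e)
        return SegmentBoundarySet(bouts)


@dataclass
class RunConfig:
    """Pipeline configuration mirroring the grid-searched model parameters.

    Defaults correspond to the best segmentation model found on real gait
    data: sagittal-plane gyroscope only, 0.5 s windows, four internal states
    per cyclic class, three rest states, 10-component diagonal GMMs fitted
    with 10 EM iterations, and the training-iteration schedule
    ``[1, 2, 5, 8, 13, 21]`` (six outer loops).
    """

    axes_combo: tuple[str, ...] = ("GZ",)
    window_len_s: float = 0.5
    n_states: int = 4
    n_rest_states: int = 3
    gmm_components: int = 10
    gmm_em_iters: int = 10
    gmm_update_iters: int = 3
    ti_schedule: tuple[int, ...] = (1, 2, 5, 8, 13, 21)
    seed: int = 0

    def __post_init__(self) -> None:
        self.axes_combo = tuple(self.axes_combo)
        self.ti_schedule = tuple(int(t) for t in self.ti_schedule)
        if not 0 < self.window_len_s <= 2:
            raise ValidationError("window_len_s must be in (0, 2]")
        if self.n_states < 2:
            raise ValidationError("n_states must be >= 2")
        if any(b <= a for a, b in zip(self.ti_schedule, self.ti_schedule[1:])):
            raise ValidationError("ti_schedule must be strictly increasing")
        if self.gmm_components < 1 or self.gmm_em_iters < 1:
            raise ValidationError("GMM settings must be positive")


# ---------------------------------------------------------------------------
# sensor tables
# ---------------------------------------------------------------------------


def write_recording(recording: SensorRecording, path, timestamps: bool = True) -> None:
    """Write a recording as a delimited text table (one row per sample)."""
    df = pd.DataFrame(recording.samples, columns=list(recording.channel_names))
    if timestamps:
        df.insert(0, "time_s", np.arange(recording.n_samples) / recording.sampling_rate)
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording(
    path,
    sampling_rate: float = 200.0,
    channel_names: Sequence[str] | None = None,
    subject_id: str | None = None,
) -> SensorRecording:
    """Read a delimited sensor table written by :func:`write_recording`.

    A leading ``time_s`` column is accepted and discarded; the sampling rate
    passed in is authoritative.  Malformed numeric cells raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # header/shape problems
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise SchemaError(f"{path}: empty sensor table")
    if df.columns[0] == "time_s":
        df = df.drop(columns=["time_s"])
    names = tuple(channel_names) if channel_names is not None else tuple(df.columns)
    if tuple(df.columns) != names:
        raise SchemaError(
            f"{path}: channel columns {tuple(df.columns)} do not match {names}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        # +2: 1-based line numbers and one header line
        raise ParseError(f"{path}: non-numeric cell at line {row + 2}")
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0, 0])
        raise ParseError(f"{path}: missing value at line {row + 2}")
    return SensorRecording(
        numeric.to_numpy(dtype=float),
        channel_names=names,
        sampling_rate=sampling_rate,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# label files
# ---------------------------------------------------------------------------


def write_labels(boundaries: SegmentBoundarySet, path) -> None:
    df = pd.DataFrame(
        [(e.start, e.end, e.class_name) for e in boundaries],
        columns=["start_sample", "end_sample", "class"],
    )
    df.to_csv(path, index=False)


def read_labels(path) -> SegmentBoundarySet:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return SegmentBoundarySet([])
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = ["start_sample", "end_sample", "class"]
    if list(df.columns)[:3] != required:
        raise SchemaError(f"{path}: expected columns {required}")
    if len(df) == 0:
        return SegmentBoundarySet([])
    entries = [
        Segment(int(r.start_sample), int(r.end_sample), str(r["class"]))
        for _, r in df.iterrows()
    ]
    return SegmentBoundarySet(entries)  # validates sortedness/overlap


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------


def _gmm_to_dict(gmm) -> dict:
    return {
        "weights": gmm.weights.tolist(),
        "means": gmm.means.tolist(),
        "variances": gmm.variances.tolist(),
    }


def _class_hmm_to_dict(hmm) -> dict:
    return {
        "class_name": hmm.class_name,
        "n_states": hmm.n_states,
        "log_transitions": hmm.log_transitions.tolist(),
        "emissions": [_gmm_to_dict(g) for g in hmm.emissions],
    }


def _class_hmm_from_dict(d):
    from .hmm_core import ClassHMM, GaussianMixtureDiag

    emissions = [
        GaussianMixtureDiag(
            np.array(g["weights"]), np.array(g["means"]), np.array(g["variances"])
        )
        for g in d["emissions"]
    ]
    return ClassHMM(
        class_name=d["class_name"],
        n_states=int(d["n_states"]),
        log_transitions=np.array(d["log_transitions"], dtype=float),
        emissions=emissions,
    )


def save_model(model, path) -> None:
    """Serialize a ClassHMM or HierarchicalHMM to JSON text.

    Serialization is deterministic for a fixed model: keys are written in a
    fixed order and floats at full precision.
    """
    from .hierarchical import HierarchicalHMM

    if isinstance(model, HierarchicalHMM):
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "kind": "hierarchical",
            "class_order": list(model.class_order),
            "class_models": {
                name: _class_hmm_to_dict(m) for name, m in model.class_models.items()
            },
            "class_log_transitions": model.class_log_transitions.tolist(),
        }
    else:
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "kind": "class",
            "model": _class_hmm_to_dict(model),
        }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path):
    from .hierarchical import HierarchicalHMM

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: unreadable or truncated model file") from exc
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not a {MODEL_FORMAT} file")
    if payload.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: model version {payload.get('version')} "
            f"(expected {MODEL_VERSION})"
        )
    if payload["kind"] == "class":
        return _class_hmm_from_dict(payload["model"])
    class_models = {
        name: _class_hmm_from_dict(d) for name, d in payload["class_models"].items()
    }
    return HierarchicalHMM(
        class_models=class_models,
        class_order=tuple(payload["class_order"]),
        class_log_transitions=np.array(payload["class_log_transitions"], dtype=float),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["axes_combo"] = list(config.axes_combo)
    data["ti_schedule"] = list(config.ti_schedule)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
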