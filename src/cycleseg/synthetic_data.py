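"""Synthetic quasi-periodic IMU-style signals with known cycle boundaries.

Emulates continuous ankle-sensor recordings of rest / walking / running: six
channels (3-axis accelerometer AX–AZ, 3-axis gyroscope GX–GZ) sampled at
200 Hz, where the sagittal-plane gyroscope (GZ) carries the dominant cyclic
component.  The cycle boundary convention follows mid-stance: phase 0 of
every template is its minimum-motion point (all dynamic channels at their
resting value), so ground-truth boundaries sit at the "sensor stationary"
instant rather than at a signal peak.  Tempo jitter is realized by per-cycle
resampling of the template (cycle closure stays exact), amplitude jitter by
scaling the deviation from the resting value, and transitions between
segments by linear cross-fades whose extents are recorded so evaluation can
ignore them.

No claim of biomechanical realism is made — the walk/run waveforms are
acknowledged stand-ins with distinct amplitude and frequency content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    DEFAULT_CHANNELS,
    Segment,
    SegmentBoundarySet,
    SensorRecording,
    ValidationError,
    write_labels,
    write_recording,
)

GRAVITY = 9.81
_CANONICAL_LEN = 201  # template grid, endpoint included (closure explicit)


@dataclass
class CycleTemplate:
    """Canonical one-cycle waveform of one class over unit duration.

    ``waveform`` has shape ``(L, n_channels)`` with ``waveform[0] ==
    waveform[-1]`` per channel (cycle closure); ``phase_anchors`` mark the
    fractional positions of salient extrema; ``nominal_duration_s`` is the
    class's typical cycle duration.
    """

    class_name: str
    waveform: np.ndarray
    phase_anchors: tuple[float, ...] = ()
    nominal_duration_s: float = 1.0
    cyclic: bool = True

    def __post_init__(self) -> None:
        self.waveform = np.atleast_2d(np.asarray(self.waveform, dtype=float))
        if self.waveform.shape[0] < 20:
            raise ValidationError("canonical template length must be >= 20")
        if self.waveform.shape[1] < 2:
            raise ValidationError("templates need at least 2 channels")
        if not np.allclose(self.waveform[0], self.waveform[-1], atol=1e-9):
            raise ValidationError("waveform must close (start == end per channel)")

    @property
    def rest_values(self) -> np.ndarray:
        """Per-channel value at the stationary phase (cycle boundary)."""
        return self.waveform[0]

    def resample(self, n: int) -> np.ndarray:
        """Linearly resample one cycle onto ``n`` samples at phases k/n."""
        grid = np.linspace(0.0, 1.0, self.waveform.shape[0])
        phases = np.arange(n) / n
        return np.column_stack(
            [np.interp(phases, grid, self.waveform[:, c]) for c in range(self.waveform.shape[1])]
        )


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of a generated sequence.

    Cyclic classes are specified by ``n_cycles`` (optionally overriding the
    template's nominal cycle duration); rest-like classes by ``duration_s``.
    """

    class_name: str
    n_cycles: int | None = None
    duration_s: float | None = None
    cycle_duration_s: float | None = None


@dataclass
class SequenceSpec:
    """Recipe for a continuous multi-segment recording."""

    segments: list[SegmentSpec]
    tempo_jitter: float = 0.0
    amplitude_jitter: float = 0.0
    noise_sd: float = 0.0
    transition_ramp_s: float = 0.0

    def __post_init__(self) -> None:
        if self.tempo_jitter < 0 or self.amplitude_jitter < 0:
            raise ValidationError("jitters must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not self.segments:
            raise ValidationError("spec must contain at least one segment")


@dataclass
class GroundTruth:
    """True labels of a generated recording.

    ``boundaries`` holds one entry per cycle (and one per rest bout);
    ``transition_regions`` are half-open sample intervals of cross-fades,
    to be excluded from evaluation.
    """

    boundaries: SegmentBoundarySet
    transition_regions: list[tuple[int, int]] = field(default_factory=list)

    def evaluation_mask(self, n_samples: int) -> np.ndarray:
        """Boolean mask of samples that carry a trusted label."""
        mask = np.zeros(n_samples, dtype=bool)
        for e in self.boundaries:
            mask[e.start : min(e.end, n_samples)] = True
        for a, b in self.transition_regions:
            mask[a:b] = False
        return mask


def _bump(phase, amp, center, width):
    """Periodic Gaussian event at fractional position ``center``."""
    out = np.zeros_like(phase)
    for k in (-1, 0, 1):  # wrap neighbours keep the waveform periodic
        out += amp * np.exp(-0.5 * ((phase - center - k) / width) ** 2)
    return out


def make_default_templates(seed: int = 0) -> dict[str, CycleTemplate]:
    """Rest, walk and run templates on the six standard IMU channels.

    Each cyclic class is a pattern of localized within-cycle events
    (periodic Gaussian bumps, the swing/impact analogs of a stride) on top
    of a resting baseline, so the minimum-motion phase at the cycle boundary
    is a brief instant rather than a plateau — mirroring mid-stance, where
    an ankle sensor is only momentarily stationary.  Walk and run differ in
    amplitude (run roughly twice walk on the dominant sagittal gyroscope GZ)
    and in frequency content (run's events are narrower and more numerous);
    rest is constant gravity on AX.
    """
    rng = np.random.default_rng(seed)
    phase = np.linspace(0.0, 1.0, _CANONICAL_LEN)
    jit = rng.uniform(-0.02, 0.02, size=12)  # mild seeded variation

    def build(name, dur, events):
        wf = np.zeros((_CANONICAL_LEN, len(DEFAULT_CHANNELS)))
        wf[:, 0] = GRAVITY
        anchors = []
        for ch, amp, center, width in events:
            wf[:, ch] += _bump(phase, amp, center, width)
            if ch == 5:
                anchors.append(center)
        # remove the (tiny) residual at phase 0 so closure is exact and the
        # boundary sits exactly at the resting value
        wf -= wf[0] - np.concatenate([[GRAVITY], np.zeros(len(DEFAULT_CHANNELS) - 1)])
        return CycleTemplate(
            name, wf, phase_anchors=tuple(anchors), nominal_duration_s=dur
        )

    # channel order: AX AY AZ GX GY GZ
    walk = build(
        "walk",
        1.0,
        [
            (5, 2.2, 0.30 + jit[0], 0.09),   # forward swing
            (5, -1.3, 0.62 + jit[1], 0.10),  # back swing
            (0, 1.2, 0.55 + jit[2], 0.06),   # heel-strike bounce
            (1, 0.5, 0.35 + jit[3], 0.10),
            (3, -0.4, 0.50 + jit[4], 0.12),
            (4, 0.5, 0.70 + jit[5], 0.10),
        ],
    )
    run = build(
        "run",
        0.7,
        [
            (5, 4.5, 0.34 + jit[6], 0.06),   # stronger, sharper swing
            (5, -2.6, 0.64 + jit[7], 0.06),
            (5, 1.6, 0.88 + jit[8], 0.05),
            (0, 3.5, 0.52 + jit[9], 0.04),   # impact spike
            (1, 0.9, 0.30 + jit[10], 0.07),
            (4, 0.8, 0.75 + jit[11], 0.07),
        ],
    )
    rest_wf = np.zeros((_CANONICAL_LEN, len(DEFAULT_CHANNELS)))
    rest_wf[:, 0] = GRAVITY
    rest = CycleTemplate(
        "rest", rest_wf, phase_anchors=(), nominal_duration_s=1.0, cyclic=False
    )
    return {"rest": rest, "walk": walk, "run": run}


def gen_recording(
    spec: SequenceSpec,
    templates: Mapping[str, CycleTemplate],
    sampling_rate: float = 200.0,
    seed: int = 0,
    subject_id: str = "S00",
) -> tuple[SensorRecording, GroundTruth]:
    """Generate a continuous recording and its ground truth.

    With all jitters and noise at zero, every cycle of a class is an
    identical resampled copy of its template, and boundaries fall exactly at
    multiples of the cycle length.  Boundaries mark the start sample of every
    cycle plus the end of the last cycle of each cyclic segment.
    """
    if sampling_rate <= 0:
        raise ValidationError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    n_channels = next(iter(templates.values())).waveform.shape[1]
    blocks: list[np.ndarray] = []
    entries: list[Segment] = []
    transitions: list[tuple[int, int]] = []
    cursor = 0
    ramp = int(round(spec.transition_ramp_s * sampling_rate))
    for si, seg in enumerate(spec.segments):
        if seg.class_name not in templates:
            raise ValidationError(f"unknown class {seg.class_name!r}")
        tpl = templates[seg.class_name]
        if si > 0 and ramp > 0:
            prev_tpl = templates[spec.segments[si - 1].class_name]
            alpha = np.linspace(0.0, 1.0, ramp, endpoint=False)[:, None]
            ramp_block = (1 - alpha) * prev_tpl.rest_values + alpha * tpl.rest_values
            blocks.append(ramp_block)
            transitions.append((cursor, cursor + ramp))
            cursor += ramp
        if tpl.cyclic and seg.n_cycles is not None:
            if seg.n_cycles < 1:
                raise ValidationError("n_cycles must be >= 1 for cyclic segments")
            cyc_s = seg.cycle_duration_s or tpl.nominal_duration_s
            base = cyc_s * sampling_rate
            for _ in range(seg.n_cycles):
                factor = max(0.2, 1.0 + rng.normal(0.0, spec.tempo_jitter)) if spec.tempo_jitter > 0 else 1.0
                m = max(tpl.waveform.shape[0] // 10, int(round(base * factor)))
                cycle = tpl.resample(m)
                if spec.amplitude_jitter > 0:
                    scale = max(0.1, 1.0 + rng.normal(0.0, spec.amplitude_jitter))
                    cycle = tpl.rest_values + scale * (cycle - tpl.rest_values)
                blocks.append(cycle)
                entries.append(Segment(cursor, cursor + m, seg.class_name))
                cursor += m
        else:
            if seg.duration_s is None:
                raise ValidationError(
                    f"segment {seg.class_name!r} needs duration_s (non-cyclic)"
                )
            m = int(round(seg.duration_s * sampling_rate))
            blocks.append(np.tile(tpl.rest_values, (m, 1)))
            entries.append(Segment(cursor, cursor + m, seg.class_name))
            cursor += m
    samples = np.vstack(blocks)
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, samples.shape)
    recording = SensorRecording(
        samples,
        channel_names=DEFAULT_CHANNELS[:n_channels],
        sampling_rate=sampling_rate,
        subject_id=subject_id,
    )
    truth = GroundTruth(SegmentBoundarySet(entries), transitions)
    return recording, truth


def gen_primitive_set(
    recording: SensorRecording,
    truth: GroundTruth,
    cycles_min: int = 5,
    cycles_max: int = 20,
    seed: int = 0,
    exclude_classes: Sequence[str] = ("rest",),
):
    """Split labeled cycle runs into training primitives of 5–20 cycles.

    Each primitive covers a whole number of consecutive same-class cycles,
    starting at a true cycle start and ending at a true cycle end.  Runs
    shorter than ``cycles_min`` (and leftovers shorter than ``cycles_min``)
    are dropped, so the summed repetition counts never exceed the number of
    true cycles.
    """
    from .smart_annotation import CyclePrimitive

    rng = np.random.default_rng(seed)
    runs: list[list[Segment]] = []
    for e in truth.boundaries:
        if e.class_name in exclude_classes:
            continue
        if runs and runs[-1][-1].class_name == e.class_name and runs[-1][-1].end == e.start:
            runs[-1].append(e)
        else:
            runs.append([e])
    primitives = []
    for run in runs:
        pos = 0
        while len(run) - pos >= cycles_min:
            remaining = len(run) - pos
            k = int(rng.integers(cycles_min, min(cycles_max, remaining) + 1))
            if remaining - k < cycles_min:
                k = min(remaining, cycles_max)
            chunk = run[pos : pos + k]
            primitives.append(
                CyclePrimitive(
                    recording=recording,
                    start=chunk[0].start,
                    end=chunk[-1].end,
                    class_name=chunk[0].class_name,
                    repetition_count=k,
                )
            )
            pos += k
    if not primitives:
        raise ValidationError(
            f"no class has at least {cycles_min} consecutive cycles"
        )
    return primitives


def gen_subject_pool(
    n_subjects: int,
    walk_cycles: int = 12,
    run_cycles: int = 12,
    rest_s: float = 4.0,
    tempo_jitter: float = 0.05,
    amplitude_jitter: float = 0.05,
    noise_sd: float = 0.1,
    transition_ramp_s: float = 0.25,
    sampling_rate: float = 200.0,
    seed: int = 0,
) -> tuple[dict[str, SensorRecording], dict[str, GroundTruth]]:
    """Generate a pool of subjects, each a continuous rest-walk-rest-run-rest
    recording, for train/test experiments.

    Every subject shares the default templates (built from ``seed``) but gets
    its own jitter/noise realization.  Subject ids are ``S00, S01, ...``.
    """
    templates = make_default_templates(seed)
    spec = SequenceSpec(
        segments=[
            SegmentSpec("rest", duration_s=rest_s),
            SegmentSpec("walk", n_cycles=walk_cycles),
            SegmentSpec("rest", duration_s=rest_s),
            SegmentSpec("run", n_cycles=run_cycles),
            SegmentSpec("rest", duration_s=rest_s),
        ],
        tempo_jitter=tempo_jitter,
        amplitude_jitter=amplitude_jitter,
        noise_sd=noise_sd,
        transition_ramp_s=transition_ramp_s,
    )
    recordings: dict[str, SensorRecording] = {}
    truths: dict[str, GroundTruth] = {}
    for i in range(n_subjects):
        sid = f"S{i:02d}"
        recordings[sid], truths[sid] = gen_recording(
            spec, templates, sampling_rate, seed=seed + 1000 + i, subject_id=sid
        )
    return recordings, truths


def write_fixture(
    out_dir,
    spec: SequenceSpec,
    templates: Mapping[str, CycleTemplate] | None = None,
    sampling_rate: float = 200.0,
    seed: int = 0,
    subject_id: str = "S00",
) -> tuple[Path, Path]:
    """Generate and write a recording + label file pair (for tests/demos)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    templates = templates or make_default_templates(seed)
    rec, truth = gen_recording(spec, templates, sampling_rate, seed, subject_id)
    rec_path = out_dir / f"{subject_id}_recording.csv"
    lab_path = out_dir / f"{subject_id}_labels.csv"
    write_recording(rec, rec_path)
    write_labels(truth.boundaries, lab_path)
    return rec_path, lab_path
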