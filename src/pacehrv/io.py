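"""Reading, writing and validation of annotated cardiac beat-event tables.

A beat series is the pipeline's ground format: one row per annotated atrial
event (sinus beat, pacing stimulus, ectopic beat or artifact) with its time in
integer milliseconds from the start of the recording.  The on-disk dialect is
a plain CSV with a ``time_ms,label`` header, preceded by an optional block of
``# key=value`` metadata lines, chosen so that files diff cleanly and can be
edited by hand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Closed set of admissible event labels.
LABELS = frozenset({"sinus", "pace_stim", "ectopic", "artifact"})

HEADER = "time_ms,label"


@dataclass(frozen=True)
class BeatEvent:
    """A single annotated atrial event.

    Parameters
    ----------
    time : int
        Event time in milliseconds from the start of the recording (>= 0).
    label : str
        One of ``sinus``, ``pace_stim``, ``ectopic``, ``artifact``.
    """

    time: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(
                f"unknown beat label {self.label!r}; expected one of {sorted(LABELS)}"
            )
        if self.time < 0:
            raise ValueError(f"negative event time {self.time}")


@dataclass
class BeatSeries:
    """Time-stamped, labeled cardiac events for one patient.

    Times must be strictly increasing; at least two events are needed to
    define any PP interval.  ``metadata`` is a free-form string-to-string
    mapping (provenance, simulation seed, AV conduction ramps ...) that
    round-trips through the file format.
    """

    patient_id: str
    events: list[BeatEvent] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "BeatSeries":
        """Check label set and strict time monotonicity; return self."""
        prev = -1
        for i, ev in enumerate(self.events):
            if ev.label not in LABELS:
                raise ValueError(f"row {i}: unknown label {ev.label!r}")
            if ev.time <= prev:
                raise ValueError(
                    f"row {i}: non-monotone time {ev.time} after {prev}"
                )
            prev = ev.time
        return self

    def times(self, label: str | None = None) -> np.ndarray:
        """Event times in ms, optionally restricted to one label."""
        if label is None:
            return np.array([ev.time for ev in self.events], dtype=float)
        return np.array(
            [ev.time for ev in self.events if ev.label == label], dtype=float
        )

    def events_between(
        self, start: float, end: float, labels: Iterable[str] | None = None
    ) -> list[BeatEvent]:
        """Events with start <= time <= end, optionally filtered by label."""
        keep = set(labels) if labels is not None else None
        return [
            ev
            for ev in self.events
            if start <= ev.time <= end and (keep is None or ev.label in keep)
        ]

    def __len__(self) -> int:
        return len(self.events)


def write_beat_series(series: BeatSeries, path: str | os.PathLike) -> None:
    """Write a beat series as delimited text (metadata block + CSV body)."""
    series.validate()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# patient_id={series.patient_id}\n")
        for key in sorted(series.metadata):
            fh.write(f"# {key}={series.metadata[key]}\n")
        fh.write(HEADER + "\n")
        for ev in series.events:
            fh.write(f"{int(ev.time)},{ev.label}\n")


def read_beat_series(path: str | os.PathLike) -> BeatSeries:
    """Read a beat series file, validating labels and time monotonicity.

    Raises
    ------
    ValueError
        On a non-monotone time (naming the offending data row), an unknown
        label, or a malformed header.
    """
    metadata: dict[str, str] = {}
    patient_id = os.path.splitext(os.path.basename(path))[0]
    events: list[BeatEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    body_start = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            key = key.strip()
            if key == "patient_id":
                patient_id = value.strip()
            elif key:
                metadata[key] = value.strip()
        elif line.strip() == "":
            continue
        else:
            if line.strip() != HEADER:
                raise ValueError(
                    f"{path}: expected header {HEADER!r}, found {line.strip()!r}"
                )
            body_start = i + 1
            break
    if body_start is None:
        raise ValueError(f"{path}: no {HEADER!r} header found")

    prev_time = -1
    for row_no, line in enumerate(lines[body_start:], start=1):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}: row {row_no}: expected 2 fields, got {line!r}")
        time_str, label = parts[0].strip(), parts[1].strip()
        time = int(time_str)
        if label not in LABELS:
            raise ValueError(f"{path}: row {row_no}: unknown label {label!r}")
        if time <= prev_time:
            raise ValueError(
                f"{path}: row {row_no}: non-monotone time {time} (previous {prev_time})"
            )
        prev_time = time
        events.append(BeatEvent(time=time, label=label))

    return BeatSeries(patient_id=patient_id, events=events, metadata=metadata)


def cohort_file_name(patient_index: int) -> str:
    return f"patient_{patient_index:03d}.csv"


def write_cohort(
    series_list: Sequence[BeatSeries], out_dir: str | os.PathLike
) -> list[str]:
    """Write one beat-series file per patient with stable names.

    Returns the list of file paths written (``patient_000.csv`` ...).
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, series in enumerate(series_list):
        path = os.path.join(out_dir, cohort_file_name(i))
        write_beat_series(series, path)
        paths.append(path)
    return paths
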