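"""Locating pacing epochs and extracting the 4-cycle measurement windows.

The measurement protocol defines four periods: A and C are the four
consecutive sinus PP intervals immediately preceding the first and second
pacing burst; B and D are the first four sinus cycles after the return of
sinus rhythm following each burst.  The interval from the last pacing
stimulus to the first spontaneous sinus beat is the sinus node recovery time
(SNRT) and is, by default, excluded from the post-pacing HRV window — the
protocol reports it as a separate electrophysiological parameter.  A window
contaminated by ectopy, artifacts or ineffective stimulation is invalid and
must be re-measured at least 2 minutes later (the repeat rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BeatSeries

#: a sinus interval deviating more than this fraction from the median of the
#: other three is treated as an unlabeled premature beat
ECTOPY_DEVIATION_FRAC = 0.20

#: pace stimuli separated by more than this many ms start a new epoch
EPOCH_SPLIT_GAP_MS = 5000.0


@dataclass
class PPWindow:
    """One period's four consecutive PP intervals with validity status."""

    period: str  # one of A, B, C, D
    intervals: tuple[float, ...] | None
    valid: bool
    rejection_reason: str | None = None

    def require_valid(self) -> tuple[float, ...]:
        if not self.valid or self.intervals is None:
            raise ValueError(
                f"window {self.period} is invalid ({self.rejection_reason}); "
                "refusing to compute metrics on it"
            )
        return self.intervals


@dataclass
class PacingEpoch:
    """A contiguous run of pacing stimuli."""

    first_stim_time: float
    last_stim_time: float
    n_stimuli: int
    effective: bool  # False when capture gaps interrupt the run

    @property
    def duration_ms(self) -> float:
        return self.last_stim_time - self.first_stim_time


@dataclass
class AuditEntry:
    """One applied measurement decision (discard/replacement)."""

    patient_id: str
    period: str
    reason: str
    replacement_time: float | None = None


@dataclass
class ProtocolMeasurement:
    """Windows and recovery interval measured around one pacing epoch."""

    epoch: PacingEpoch
    pre: PPWindow
    post: PPWindow
    recovery_interval: float | None  # ms, SNRT

    @property
    def valid(self) -> bool:
        return self.epoch.effective and self.pre.valid and self.post.valid


def locate_pacing_epochs(series: BeatSeries) -> list[PacingEpoch]:
    """Group contiguous runs of pacing stimuli into epochs.

    A protocol-conformant series yields exactly two epochs; an epoch whose
    stimulus train contains capture gaps (an inter-stimulus interval more
    than 1.5x the run's median) is flagged ineffective.
    """
    stim_times = series.times("pace_stim")
    if stim_times.size == 0:
        raise ValueError(f"{series.patient_id}: no pacing found")
    epochs: list[PacingEpoch] = []
    gaps = np.diff(stim_times)
    breaks = np.nonzero(gaps > EPOCH_SPLIT_GAP_MS)[0]
    bounds = np.concatenate(([0], breaks + 1, [stim_times.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        run = stim_times[lo:hi]
        effective = True
        if run.size >= 3:
            run_gaps = np.diff(run)
            effective = bool(np.all(run_gaps <= 1.5 * np.median(run_gaps)))
        epochs.append(
            PacingEpoch(
                first_stim_time=float(run[0]),
                last_stim_time=float(run[-1]),
                n_stimuli=int(run.size),
                effective=effective,
            )
        )
    return epochs


def _contamination(
    series: BeatSeries, start: float, end: float
) -> str | None:
    """Reason string if any ectopic/artifact event lies in [start, end]."""
    for ev in series.events_between(start, end, labels=("ectopic", "artifact")):
        return ev.label if ev.label == "artifact" else "ectopy"
    return None


def _interval_outlier(intervals: np.ndarray) -> bool:
    """True when one interval deviates >20% from the median of the others."""
    for i in range(intervals.size):
        others = np.delete(intervals, i)
        med = np.median(others)
        if med > 0 and abs(intervals[i] - med) > ECTOPY_DEVIATION_FRAC * med:
            return True
    return False


def _window_from_beats(beats: np.ndarray, series: BeatSeries, period: str) -> PPWindow:
    reason = _contamination(series, float(beats[0]), float(beats[-1]))
    intervals = np.diff(beats)
    if reason is not None:
        return PPWindow(period=period, intervals=tuple(intervals), valid=False,
                        rejection_reason=reason)
    if np.any(intervals <= 0):
        return PPWindow(period=period, intervals=tuple(intervals), valid=False,
                        rejection_reason="non-positive interval")
    if _interval_outlier(intervals):
        return PPWindow(period=period, intervals=tuple(intervals), valid=False,
                        rejection_reason="suspected unlabeled ectopy")
    return PPWindow(period=period, intervals=tuple(float(x) for x in intervals),
                    valid=True)


def extract_pre_window(
    series: BeatSeries, epoch: PacingEpoch, period: str
) -> PPWindow:
    """The last 4 sinus PP intervals strictly before the pacing epoch."""
    sinus = series.times("sinus")
    before = sinus[sinus < epoch.first_stim_time]
    if before.size < 5:
        return PPWindow(period=period, intervals=None, valid=False,
                        rejection_reason="fewer than 5 sinus beats before pacing")
    return _window_from_beats(before[-5:], series, period)


def extract_post_window(
    series: BeatSeries,
    epoch: PacingEpoch,
    period: str,
    include_recovery_beat: bool = False,
) -> tuple[PPWindow, float | None]:
    """The first 4 sinus cycles after the return of sinus rhythm, plus SNRT.

    Returns ``(window, recovery_interval)`` where the recovery interval is
    the time from the last stimulus to the first spontaneous sinus beat.  By
    default that pause is excluded from the HRV window (it is the SNRT, a
    separate metric); with ``include_recovery_beat=True`` it is counted as
    the window's first cycle instead.
    """
    sinus = series.times("sinus")
    after = sinus[sinus > epoch.last_stim_time]
    if after.size == 0:
        return (
            PPWindow(period=period, intervals=None, valid=False,
                     rejection_reason="no sinus return after pacing"),
            None,
        )
    recovery = float(after[0] - epoch.last_stim_time)
    need = 4 if include_recovery_beat else 5
    if after.size < need:
        return (
            PPWindow(period=period, intervals=None, valid=False,
                     rejection_reason="fewer than 4 clean cycles after pacing"),
            recovery,
        )
    if include_recovery_beat:
        beats = after[:4]
        window = _window_from_beats(
            np.concatenate(([epoch.last_stim_time], beats)), series, period
        )
    else:
        window = _window_from_beats(after[:5], series, period)
    return window, recovery


def measure_epoch(
    series: BeatSeries,
    epoch: PacingEpoch,
    periods: tuple[str, str],
    include_recovery_beat: bool = False,
) -> ProtocolMeasurement:
    """Measure the pre and post windows around one pacing epoch."""
    pre = extract_pre_window(series, epoch, periods[0])
    post, recovery = extract_post_window(
        series, epoch, periods[1], include_recovery_beat
    )
    if not epoch.effective:
        reason = "ineffective stimulation (capture gaps)"
        pre = PPWindow(period=periods[0], intervals=pre.intervals, valid=False,
                       rejection_reason=reason)
        post = PPWindow(period=periods[1], intervals=post.intervals, valid=False,
                        rejection_reason=reason)
    return ProtocolMeasurement(epoch=epoch, pre=pre, post=post,
                               recovery_interval=recovery)


def apply_repeat_rule(
    measurements: Sequence[ProtocolMeasurement],
    series: BeatSeries,
    spare_epochs: Sequence[PacingEpoch] = (),
    include_recovery_beat: bool = False,
    min_gap_ms: float = 120000.0,
) -> tuple[list[ProtocolMeasurement], list[AuditEntry]]:
    """Re-measure contaminated protocols on a spare epoch >= 2 min later.

    For each protocol measurement with an invalid window, the earliest unused
    spare pacing epoch starting at least ``min_gap_ms`` after the
    contaminated epoch is measured in its place (keeping the period labels).
    Every discard is recorded in the audit log; a protocol with no usable
    replacement stays invalid and is excluded pairwise downstream.
    """
    audit: list[AuditEntry] = []
    final: list[ProtocolMeasurement] = []
    used: set[float] = set()
    for meas in measurements:
        if meas.valid:
            final.append(meas)
            continue
        for win in (meas.pre, meas.post):
            if not win.valid:
                audit.append(AuditEntry(
                    patient_id=series.patient_id, period=win.period,
                    reason=win.rejection_reason or "invalid",
                ))
        periods = (meas.pre.period, meas.post.period)
        replacement = None
        for spare in spare_epochs:
            if spare.first_stim_time in used:
                continue
            if spare.first_stim_time < meas.epoch.last_stim_time + min_gap_ms:
                continue
            candidate = measure_epoch(series, spare, periods, include_recovery_beat)
            if candidate.valid:
                replacement = candidate
                used.add(spare.first_stim_time)
                break
        if replacement is not None:
            for entry in audit:
                if entry.patient_id == series.patient_id and entry.period in periods \
                        and entry.replacement_time is None:
                    entry.replacement_time = replacement.epoch.first_stim_time
            final.append(replacement)
        else:
            final.append(meas)  # stays invalid -> missing downstream
    return final, audit


def measure_patient(
    series: BeatSeries, include_recovery_beat: bool = False
) -> tuple[dict[str, ProtocolMeasurement], list[AuditEntry]]:
    """Full per-patient measurement: periods A/B and C/D plus repeat rule.

    Returns a mapping ``{"AB": ..., "CD": ...}`` of final protocol
    measurements (possibly invalid when no replacement existed) and the
    audit log of every discarded window.
    """
    epochs = locate_pacing_epochs(series)
    protocol_epochs = epochs[:2]
    spares = epochs[2:]
    period_pairs = [("A", "B"), ("C", "D")]
    measurements = [
        measure_epoch(series, ep, periods, include_recovery_beat)
        for ep, periods in zip(protocol_epochs, period_pairs)
    ]
    final, audit = apply_repeat_rule(
        measurements, series, spares, include_recovery_beat
    )
    keys = ["AB", "CD"][: len(final)]
    return dict(zip(keys, final)), audit
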