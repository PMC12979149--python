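"""Ultra-short HRV metrics and electrophysiological parameters.

Two time-domain indices are computed on each 4-interval window:

* ``RMSSD = sqrt( sum_{i=1}^{n-1} (PP_{i+1} - PP_i)^2 / (n-1) )`` with n = 4,
  i.e. the root mean square of the three successive PP differences;
* ``dPP = PP_max - PP_min``, the range of the four intervals.

Both are vagally mediated beat-to-beat variability measures; the 4-beat
window makes them usable intraoperatively, inside a single respiratory
cycle.  The module also derives the sinus node recovery time (SNRT), its
corrected form cSNRT = SNRT - baseline cycle length, and the atrioventricular
Wenckebach point (highest atrial pacing rate with 1:1 AV conduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windows import PPWindow


@dataclass
class UltraShortHRV:
    """Per-window HRV summary (ms)."""

    period: str
    rmssd: float
    delta_pp: float
    median_cl: float


@dataclass
class EPParams:
    """Post-pacing electrophysiological parameters (periods B or D)."""

    period: str
    snrt: float  # ms
    csnrt: float  # ms
    wp_rate: float | None = None  # bpm
    wp_cycle_length: float | None = None  # ms


def rmssd(window: PPWindow) -> float:
    """Root mean square of successive differences over the 4-beat window."""
    intervals = np.asarray(window.require_valid(), dtype=float)
    d = np.diff(intervals)
    return float(np.sqrt(np.mean(d * d)))


#: alias emphasising the fixed 4-interval window length
rmssd4 = rmssd


def delta_pp(window: PPWindow) -> float:
    """Range (longest minus shortest PP interval) of the window."""
    intervals = np.asarray(window.require_valid(), dtype=float)
    return float(np.max(intervals) - np.min(intervals))


def median_cl(window: PPWindow) -> float:
    """Median cycle length of the window (mean of the two middle values)."""
    intervals = np.asarray(window.require_valid(), dtype=float)
    return float(np.median(intervals))


def snrt_csnrt(
    recovery_interval: float,
    baseline_window: PPWindow,
    aggregator: str = "mean",
) -> tuple[float, float]:
    """SNRT and corrected SNRT for one protocol.

    The baseline cycle length is aggregated from the same protocol's four
    pre-pacing intervals; the mean is the default (median available via
    ``aggregator="median"``).  A negative cSNRT (supra-normal recovery) is
    allowed but anomalous.
    """
    intervals = np.asarray(baseline_window.require_valid(), dtype=float)
    if aggregator == "mean":
        baseline = float(np.mean(intervals))
    elif aggregator == "median":
        baseline = float(np.median(intervals))
    else:
        raise ValueError(f"unknown baseline aggregator {aggregator!r}")
    snrt = float(recovery_interval)
    return snrt, snrt - baseline


def _is_one_to_one(ratio) -> bool:
    if isinstance(ratio, str):
        a, _, b = ratio.partition(":")
        return a.strip() == b.strip() != ""
    if isinstance(ratio, (tuple, list)):
        return len(ratio) == 2 and ratio[0] == ratio[1]
    return float(ratio) >= 1.0 - 1e-9  # conducted fraction


def wenckebach_point(av_conduction_trace: dict) -> tuple[float, float]:
    """Highest atrial pacing rate with 1:1 AV conduction.

    Parameters
    ----------
    av_conduction_trace : dict
        Map of pacing rate (bpm) to conducted ratio, from an incremental
        ramp.  Ratios may be strings (``"1:1"``, ``"4:3"``), pairs, or a
        conducted fraction (1.0 means 1:1).

    Returns
    -------
    (wp_rate, wp_cycle_length)
        The Wenckebach point in bpm and its cycle-length equivalent in ms.

    Raises
    ------
    ValueError
        If the ramp never conducts 1:1, or never blocks ("WP not reached
        in ramp" — the ramp must be extended).
    """
    if not av_conduction_trace:
        raise ValueError("empty AV conduction trace")
    one_to_one = [r for r, ratio in av_conduction_trace.items() if _is_one_to_one(ratio)]
    blocked = [r for r, ratio in av_conduction_trace.items() if not _is_one_to_one(ratio)]
    if not blocked:
        raise ValueError("WP not reached in ramp (all rates conduct 1:1)")
    if not one_to_one:
        raise ValueError("no 1:1 conduction anywhere in the ramp")
    wp_rate = float(max(one_to_one))
    return wp_rate, 60000.0 / wp_rate


def hrv_from_window(window: PPWindow) -> UltraShortHRV:
    """All three per-window summaries in one record."""
    return UltraShortHRV(
        period=window.period,
        rmssd=rmssd(window),
        delta_pp=delta_pp(window),
        median_cl=median_cl(window),
    )
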