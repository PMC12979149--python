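import numpy as np
import pandas as pd
import pytest

from pacehrv import BeatEvent, BeatSeries, SimParams


def series_from_times(times_labels, patient_id="p0", metadata=None):
    """Build a BeatSeries from (time_ms, label) pairs."""
    events = [BeatEvent(time=int(t), label=lab) for t, lab in times_labels]
    return BeatSeries(patient_id=patient_id, events=events,
                      metadata=metadata or {}).validate()


def protocol_series(
    cl=800,
    n_pre=10,
    paced_cl=600,
    n_stim=51,
    snrt_excess=347,
    n_post=10,
    n_epochs=2,
    gap_ms=120000,
    contaminate=(),
    patient_id="p0",
):
    """Deterministic two-epoch protocol series on a regular cycle-length grid.

    ``contaminate`` is a list of (time_ms, label) extra events to inject.
    """
    events = []
    t = 0
    for _ in range(n_pre):
        events.append((t, "sinus"))
        t += cl
    last = events[-1][0]
    for epoch in range(n_epochs):
        stim0 = last + cl  # pacing starts one cycle after the last sinus beat
        for j in range(n_stim):
            events.append((stim0 + j * paced_cl, "pace_stim"))
        last_stim = stim0 + (n_stim - 1) * paced_cl
        t = last_stim + cl + snrt_excess  # SNRT beat
        for _ in range(n_post):
            events.append((t, "sinus"))
            t += cl
        last = t - cl
        if epoch < n_epochs - 1:
            while t < last_stim + gap_ms:
                events.append((t, "sinus"))
                t += cl
            last = t - cl
    events.extend(contaminate)
    events.sort()
    return series_from_times(events, patient_id=patient_id)


def make_frame(data):
    """Cohort frame from {metric: {period: values}} with MultiIndex columns."""
    cols = {}
    for metric, periods in data.items():
        for period, values in periods.items():
            cols[(metric, period)] = list(values)
    frame = pd.DataFrame(cols)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    frame.index = [f"patient_{i:03d}" for i in range(len(frame))]
    frame.index.name = "patient_id"
    return frame


@pytest.fixture
def fast_params():
    """Default-physiology parameters with shortened quiet segments."""
    return SimParams(n_patients=8, rest_duration=8.0, inter_protocol_gap=130.0,
                     tail_duration=6.0, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
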