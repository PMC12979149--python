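import numpy as np
import pytest

from pacehrv import (
    apply_repeat_rule,
    extract_post_window,
    extract_pre_window,
    locate_pacing_epochs,
    measure_patient,
)
from pacehrv.windows import measure_epoch

from conftest import protocol_series, series_from_times


class TestLocatePacingEpochs:
    def test_two_epochs_at_expected_times(self):
        series = protocol_series()
        epochs = locate_pacing_epochs(series)
        assert len(epochs) == 2
        # pacing starts one cycle after 10 pre beats (~7.2 s of rest here)
        assert epochs[0].duration_ms == 50 * 600
        assert epochs[1].first_stim_time - epochs[0].last_stim_time >= 120000
        assert all(e.effective for e in epochs)

    def test_single_run_gives_one_epoch(self):
        series = protocol_series(n_epochs=1)
        assert len(locate_pacing_epochs(series)) == 1

    def test_capture_gap_flags_ineffective(self):
        events = [(i * 800, "sinus") for i in range(6)]
        stim0 = 6 * 800
        stims = [stim0 + j * 600 for j in range(20) if j != 10]  # missing capture
        events += [(t, "pace_stim") for t in stims]
        events += [(stims[-1] + 1200 + i * 800, "sinus") for i in range(8)]
        series = series_from_times(events)
        (epoch,) = locate_pacing_epochs(series)
        assert not epoch.effective

    def test_no_pacing_is_an_error(self):
        series = series_from_times([(0, "sinus"), (800, "sinus"), (1600, "sinus")])
        with pytest.raises(ValueError, match="no pacing"):
            locate_pacing_epochs(series)


class TestPreWindow:
    def test_regular_beats(self):
        events = [(i * 800, "sinus") for i in range(5)] + [(4000, "pace_stim")]
        series = series_from_times(events)
        (epoch,) = locate_pacing_epochs(series)
        window = extract_pre_window(series, epoch, "A")
        assert window.valid
        assert window.intervals == (800.0, 800.0, 800.0, 800.0)

    def test_irregular_arithmetic(self):
        beats = [0, 800, 1620, 2410, 3215]
        events = [(t, "sinus") for t in beats] + [(4000, "pace_stim")]
        series = series_from_times(events)
        (epoch,) = locate_pacing_epochs(series)
        window = extract_pre_window(series, epoch, "A")
        assert window.intervals == (800.0, 820.0, 790.0, 805.0)

    def test_ectopic_in_window_invalidates(self):
        events = [(i * 800, "sinus") for i in range(5)]
        events.append((1900, "ectopic"))  # near the 3rd beat
        events.append((4000, "pace_stim"))
        series = series_from_times(sorted(events))
        (epoch,) = locate_pacing_epochs(series)
        window = extract_pre_window(series, epoch, "A")
        assert not window.valid
        assert window.rejection_reason == "ectopy"

    def test_too_few_beats_invalid_with_reason(self):
        events = [(0, "sinus"), (800, "sinus"), (1600, "pace_stim")]
        series = series_from_times(events)
        (epoch,) = locate_pacing_epochs(series)
        window = extract_pre_window(series, epoch, "A")
        assert not window.valid
        assert "fewer than 5" in window.rejection_reason

    def test_unlabeled_premature_beat_caught_by_deviation_rule(self):
        # one interval deviates >20% from the median of the other three
        beats = [0, 800, 1600, 2100, 2900]  # 500 ms premature cycle
        events = [(t, "sinus") for t in beats] + [(3600, "pace_stim")]
        series = series_from_times(events)
        (epoch,) = locate_pacing_epochs(series)
        window = extract_pre_window(series, epoch, "A")
        assert not window.valid
        assert "ectopy" in window.rejection_reason

    def test_window_ends_strictly_before_first_stimulus(self):
        series = protocol_series()
        for epoch, period in zip(locate_pacing_epochs(series), "AC"):
            sinus = series.times("sinus")
            last_used = sinus[sinus < epoch.first_stim_time][-1]
            assert last_used < epoch.first_stim_time
            window = extract_pre_window(series, epoch, period)
            assert window.valid


class TestPostWindow:
    def fixture_series(self):
        events = [(i * 850, "sinus") for i in range(6)]
        events += [(5100 + j * 600, "pace_stim") for j in range(42)]  # last at 29700
        events += [(29700 + 300, "pace_stim")]  # make last stim exactly 30000
        events += [(t, "sinus") for t in (31147, 31997, 32847, 33697, 34547, 35397)]
        return series_from_times(sorted(events))

    def test_recovery_and_intervals(self):
        series = self.fixture_series()
        epoch = locate_pacing_epochs(series)[-1]
        assert epoch.last_stim_time == 30000
        window, recovery = extract_post_window(series, epoch, "B")
        assert recovery == 1147
        assert window.valid
        assert window.intervals == (850.0, 850.0, 850.0, 850.0)

    def test_include_recovery_beat_variant(self):
        series = self.fixture_series()
        epoch = locate_pacing_epochs(series)[-1]
        window, recovery = extract_post_window(series, epoch, "B",
                                               include_recovery_beat=True)
        assert recovery == 1147
        assert window.intervals == (1147.0, 850.0, 850.0, 850.0)

    def test_artifact_among_first_post_beats_invalidates(self):
        series = self.fixture_series()
        events = list(series.events)
        from pacehrv import BeatEvent
        events.append(BeatEvent(time=32000, label="artifact"))
        series.events = sorted(events, key=lambda e: e.time)
        epoch = locate_pacing_epochs(series)[-1]
        window, _ = extract_post_window(series, epoch, "B")
        assert not window.valid
        assert window.rejection_reason == "artifact"

    def test_insufficient_post_beats(self):
        events = [(i * 800, "sinus") for i in range(6)]
        events += [(5000 + j * 600, "pace_stim") for j in range(10)]
        events += [(11500, "sinus"), (12300, "sinus")]
        series = series_from_times(events)
        epoch = locate_pacing_epochs(series)[-1]
        window, recovery = extract_post_window(series, epoch, "B")
        assert not window.valid
        assert recovery == 11500 - (5000 + 9 * 600)

    def test_post_window_starts_at_or_after_sinus_return(self):
        series = protocol_series()
        for epoch, period in zip(locate_pacing_epochs(series), "BD"):
            window, recovery = extract_post_window(series, epoch, period)
            assert window.valid
            first_sinus = series.times("sinus")
            first_sinus = first_sinus[first_sinus > epoch.last_stim_time][0]
            assert recovery == first_sinus - epoch.last_stim_time


class TestRepeatRule:
    def test_all_valid_is_identity_with_empty_log(self):
        series = protocol_series()
        measurements, audit = measure_patient(series)
        assert audit == []
        assert measurements["AB"].valid and measurements["CD"].valid

    def test_invalid_window_replaced_by_spare_epoch(self):
        # artifact lands inside the B window of epoch 1; a third (spare)
        # epoch exists >= 120 s after it
        series = protocol_series(n_epochs=3)
        epochs = locate_pacing_epochs(series)
        b_start = epochs[0].last_stim_time + 800
        from pacehrv import BeatEvent
        series.events.append(BeatEvent(time=int(b_start + 400), label="artifact"))
        series.events.sort(key=lambda e: e.time)
        measurements, audit = measure_patient(series)
        assert measurements["AB"].valid
        assert measurements["AB"].epoch.first_stim_time == epochs[2].first_stim_time
        assert len(audit) == 1
        assert audit[0].period == "B"
        assert audit[0].replacement_time == epochs[2].first_stim_time

    def test_invalid_window_without_spare_marks_protocol_missing(self):
        series = protocol_series(n_epochs=2)
        epochs = locate_pacing_epochs(series)
        from pacehrv import BeatEvent
        series.events.append(
            BeatEvent(time=int(epochs[1].last_stim_time + 1200), label="ectopic"))
        series.events.sort(key=lambda e: e.time)
        measurements, audit = measure_patient(series)
        assert measurements["AB"].valid
        assert not measurements["CD"].valid
        assert any(e.period == "D" and e.replacement_time is None for e in audit)

    def test_spare_epoch_must_be_two_minutes_later(self):
        series = protocol_series(n_epochs=2)
        epochs = locate_pacing_epochs(series)
        from pacehrv import BeatEvent
        series.events.append(
            BeatEvent(time=int(epochs[0].last_stim_time + 1200), label="artifact"))
        series.events.sort(key=lambda e: e.time)
        meas = [measure_epoch(series, epochs[0], ("A", "B"))]
        # offer the second epoch as a spare: it is ~120 s later, so usable
        final, audit = apply_repeat_rule(meas, series, spare_epochs=epochs[1:])
        assert final[0].valid
        # but with a 10-minute minimum gap it is not
        final, audit = apply_repeat_rule(meas, series, spare_epochs=epochs[1:],
                                         min_gap_ms=600000)
        assert not final[0].valid
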