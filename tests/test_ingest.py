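"""Session parsing, wear masks and wear summaries."""

import numpy as np
import pandas as pd
import pytest

from e4wild import (
    SessionFormatError,
    apply_sleep_mask,
    detect_nonwear,
    read_session,
    reference_cohort,
    reference_summary,
    summarize_cohort_table,
    wear_summary,
    write_session,
)
from e4wild.ingest import sleep_intervals, usable_tags

from helpers import T0, make_session


def test_round_trip_preserves_numeric_content(tmp_path, effect_cohort):
    s = effect_cohort.sessions[0]
    folder = write_session(s, tmp_path / s.session_id)
    back = read_session(folder)
    assert back.participant_id == s.participant_id
    for name, ch in s.channels.items():
        assert back.channels[name].rate == ch.rate
        assert back.channels[name].start_time == ch.start_time
        # values survive to the printed precision of the dialect
        np.testing.assert_allclose(back.channels[name].values, ch.values,
                                   atol=6e-3)
    np.testing.assert_allclose(back.tags, s.tags)
    # second round trip is bit-exact
    folder2 = write_session(back, tmp_path / "again")
    again = read_session(folder2)
    for name in back.channels:
        np.testing.assert_array_equal(again.channels[name].values,
                                      back.channels[name].values)


def test_missing_and_empty_channels_are_format_errors(tmp_path):
    s = make_session(duration=60)
    folder = write_session(s, tmp_path / "x")
    (folder / "HR.csv").unlink()
    with pytest.raises(SessionFormatError, match="HR"):
        read_session(folder)
    (folder / "HR.csv").write_text("1600000000\n1\n")  # header only, no samples
    with pytest.raises(SessionFormatError, match="empty channel"):
        read_session(folder)


def test_non_monotone_tags_rejected():
    with pytest.raises(SessionFormatError, match="monotone"):
        make_session(tags=[T0 + 100, T0 + 50])


def test_tags_outside_coverage_are_dropped():
    s = make_session(duration=600, tags=[T0 - 50, T0 + 100, T0 + 700])
    assert s.tags.tolist() == [T0 + 100]


class TestNonwear:
    def test_all_off_body_is_entirely_nonwear(self):
        s = make_session(eda=np.zeros(1800 * 4), temp=np.full(1800 * 4, 25.0))
        mask = detect_nonwear(s)
        d = mask.durations()
        assert d["nonwear"] == pytest.approx(1800)
        assert d["wear"] == 0

    def test_clean_session_is_single_wear_interval(self):
        mask = detect_nonwear(make_session())
        assert mask.wear == [(T0, T0 + 1800.0)]

    def test_mid_session_gap_found_exactly(self):
        """10-min zeroed block -> one non-wear interval of 600 s, matching a
        brute-force scan of the 4 Hz grid."""
        eda = np.full(1800 * 4, 1.0)
        temp = np.full(1800 * 4, 33.0)
        eda[600 * 4:1200 * 4] = 0.0
        temp[600 * 4:1200 * 4] = 25.0
        s = make_session(eda=eda, temp=temp)
        mask = detect_nonwear(s, min_gap=300)
        nw = mask.of_state("nonwear")
        assert nw == [(T0 + 600.0, T0 + 1200.0)]
        # oracle: longest run of sub-floor samples
        off = (eda < 0.03) & (temp < 30)
        assert off.sum() / 4 == 600

    def test_short_gap_below_min_gap_ignored(self):
        eda = np.full(1800 * 4, 1.0)
        temp = np.full(1800 * 4, 33.0)
        eda[100 * 4:200 * 4] = 0.0
        temp[100 * 4:200 * 4] = 25.0
        mask = detect_nonwear(make_session(eda=eda, temp=temp), min_gap=300)
        assert mask.of_state("nonwear") == []

    def test_min_gap_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_nonwear(make_session(), min_gap=0)


class TestSleepMask:
    def test_sleep_window_masks_expected_hours(self):
        s = make_session(duration=86400, start=1_600_041_600)  # full UTC day
        mask = apply_sleep_mask(s, (23.0, 7.0))
        assert mask.durations()["sleep"] == pytest.approx(8 * 3600)

    def test_daytime_session_untouched_by_sleep(self):
        mask = apply_sleep_mask(make_session(), (23.0, 7.0))
        assert mask.durations()["sleep"] == 0

    def test_partition_law(self):
        """wear + nonwear + sleep == span even when intervals overlap."""
        eda = np.full(86400 * 4, 1.0)
        temp = np.full(86400 * 4, 33.0)
        eda[: 8 * 3600 * 4] = 0.0          # non-wear overlapping sleep
        temp[: 8 * 3600 * 4] = 25.0
        s = make_session(duration=86400, eda=eda, temp=temp,
                         start=1_600_041_600)
        mask = apply_sleep_mask(s, (23.0, 7.0))
        d = mask.durations()
        assert sum(d.values()) == pytest.approx(s.duration, abs=0.25)

    def test_ill_formed_window_rejected(self):
        with pytest.raises(ValueError):
            sleep_intervals((0.0, 10.0), (5.0, 5.0))
        with pytest.raises(ValueError):
            sleep_intervals((0.0, 10.0), (-1.0, 30.0))

    def test_tags_in_masked_time_dropped(self):
        eda = np.full(1800 * 4, 1.0)
        temp = np.full(1800 * 4, 33.0)
        eda[:600 * 4] = 0.0
        temp[:600 * 4] = 25.0
        s = make_session(eda=eda, temp=temp,
                         tags=[T0 + 100, T0 + 900])
        mask = detect_nonwear(s)
        assert usable_tags(s, mask).tolist() == [T0 + 900]


class TestWearSummary:
    def test_simple_rates(self):
        s = make_session(duration=3600, tags=[T0 + 600, T0 + 1200])
        df = wear_summary([s])
        row = df.loc["P00"]
        assert row["n_tags"] == 2
        assert row["n_hours"] == pytest.approx(1.0)
        assert row["mean_tags_per_hour"] == pytest.approx(2.0)
        assert row["n_days"] == 1

    def test_zero_wear_reports_missing_rate(self):
        s = make_session(eda=np.zeros(1800 * 4), temp=np.full(1800 * 4, 25.0))
        mask = detect_nonwear(s)
        df = wear_summary([s], {("P00", "P00_s0"): mask})
        assert np.isnan(df.loc["P00", "mean_tags_per_hour"])

    def test_permutation_invariance(self, effect_cohort, effect_masks):
        fwd = wear_summary(effect_cohort.sessions, effect_masks)
        rev = wear_summary(effect_cohort.sessions[::-1], effect_masks)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_reference_row_and_totals(self):
        ref = reference_cohort()
        assert ref.loc["0", "n_hours"] / ref.loc["0", "n_days"] == \
            pytest.approx(6.48, abs=0.01)
        s = reference_summary()
        assert s["total_days"] == 270
        assert s["mean_days"] == pytest.approx(33.75)

    def test_summarize_cohort_table_trivial(self):
        df = pd.DataFrame({"n_tags": [2, 4], "n_hours": [1.0, 2.0],
                           "n_days": [1, 2],
                           "mean_hours_per_day": [1.0, 1.0]})
        out = summarize_cohort_table(df)
        assert out["total_tags"] == 6
        assert out["mean_days"] == 1.5
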