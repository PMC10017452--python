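import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cagerest.datamodel import (
    AnalysisConfig,
    CageMetadata,
    DataError,
    FormatError,
    LightSchedule,
)
from cagerest.io import (
    ELECTRODE_COLS,
    load_config,
    read_capacitance_csv,
    read_metadata_csv,
    save_config,
    write_capacitance_csv,
    write_metadata_csv,
)
from cagerest.phases import assign_phases, exclude_days, weekly_aggregate
from tests.conftest import make_record


class TestCapacitanceIO:
    def test_roundtrip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = make_record(rng.normal(size=(240, 12)), fs=4.0)
        path = tmp_path / "cap.csv"
        write_capacitance_csv(rec, path)
        back = read_capacitance_csv(path, fs=4.0)
        assert back.fs == 4.0
        assert back.n_samples == rec.n_samples
        np.testing.assert_allclose(back.values, rec.values, rtol=1e-9)
        assert not back.mask.any()

    def test_wrong_column_count_is_format_error(self, tmp_path):
        ts = pd.date_range("2021-03-01 07:00:00", periods=8, freq="250ms")
        df = pd.DataFrame({"timestamp": ts, "cage_id": "C01"})
        for c in ELECTRODE_COLS[:11]:  # 11 electrodes only
            df[c] = 0.0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_capacitance_csv(path, fs=4.0)

    def test_gap_becomes_masked_samples(self, tmp_path):
        # 4 Hz file with a 2-min hole: brute-force count of missing slots
        step = pd.Timedelta(milliseconds=250)
        t0 = pd.Timestamp("2021-03-01 07:00:00")
        before = pd.date_range(t0, periods=960, freq=step)  # 4 min
        after = pd.date_range(
            before[-1] + pd.Timedelta(minutes=2) + step, periods=960, freq=step
        )
        ts = before.append(after)
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(len(ts), 12)), columns=ELECTRODE_COLS)
        df.insert(0, "cage_id", "C01")
        df.insert(0, "timestamp", ts)
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        rec = read_capacitance_csv(path, fs=4.0)
        full_grid = pd.date_range(ts[0], ts[-1], freq=step)
        expected_missing = len(full_grid) - len(ts)  # independent oracle
        assert expected_missing == 480  # 2 min at 4 Hz
        assert rec.mask.sum() == expected_missing
        assert rec.n_samples == len(full_grid)

    def test_non_monotone_timestamps_rejected(self, tmp_path):
        ts = pd.date_range("2021-03-01 07:00:00", periods=8, freq="250ms")
        df = pd.DataFrame(np.zeros((8, 12)), columns=ELECTRODE_COLS)
        df.insert(0, "cage_id", "C01")
        df.insert(0, "timestamp", ts[::-1])
        path = tmp_path / "rev.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DataError):
            read_capacitance_csv(path, fs=4.0)


class TestSeriesRoundTrip:
    def test_activity_and_immobility_value_identical(self, tmp_path):
        from cagerest.datamodel import ActivitySeries, ImmobilitySeries
        from cagerest.io import (
            read_activity_csv,
            read_immobility_csv,
            write_activity_csv,
            write_immobility_csv,
        )

        rng = np.random.default_rng(6)
        t0 = pd.Timestamp("2021-03-01 07:00:00")
        act = ActivitySeries(cage_id="C01", start_time=t0, values=rng.uniform(0, 1, 120))
        imm = ImmobilitySeries(
            cage_id="C01",
            start_time=t0,
            values=rng.integers(0, 2, 600).astype(np.int8),
            mask=rng.random(600) < 0.05,
        )
        write_activity_csv([act], tmp_path / "a.csv")
        write_immobility_csv([imm], tmp_path / "i.csv")
        (a_back,) = read_activity_csv(tmp_path / "a.csv")
        (i_back,) = read_immobility_csv(tmp_path / "i.csv")
        assert a_back.start_time == t0 and i_back.start_time == t0
        np.testing.assert_allclose(a_back.values, act.values, rtol=1e-9)
        np.testing.assert_array_equal(i_back.values, imm.values)
        np.testing.assert_array_equal(i_back.mask, imm.mask)


class TestMetadataAndConfig:
    def test_metadata_roundtrip(self, tmp_path):
        metas = [
            CageMetadata(
                "C01", "WT", "M",
                cage_change_dates=frozenset({dt.date(2021, 3, 1), dt.date(2021, 3, 8)}),
            ),
            CageMetadata("C02", "MUT", "F"),
        ]
        path = tmp_path / "meta.csv"
        write_metadata_csv(metas, path)
        back = read_metadata_csv(path)
        assert back == metas

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = AnalysisConfig(bout_min=60, bout_bins=(3.0, 10.0))
        path = tmp_path / "config.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("no_such_field: 1\n")
        with pytest.raises(FormatError):
            load_config(tmp_path / "c.yaml")

    def test_three_mice_per_cage_rejected(self):
        with pytest.raises(ValueError):
            CageMetadata("C01", "WT", "M", n_animals=3)


class TestPhases:
    def test_lights_on_is_light_hour_zero(self, schedule):
        out = assign_phases(pd.DatetimeIndex(["2021-03-01 07:00:00"]), schedule)
        assert out["phase"].iloc[0] == "LIGHT"
        assert out["hour_post_lights_on"].iloc[0] == 0

    def test_lights_off_boundary_is_dark_hour_twelve(self, schedule):
        out = assign_phases(pd.DatetimeIndex(["2021-03-01 19:00:00"]), schedule)
        assert out["phase"].iloc[0] == "DARK"
        assert out["hour_post_lights_on"].iloc[0] == 12

    def test_full_day_partitions_720_720(self, schedule):
        ts = pd.date_range("2021-03-01 07:00:00", periods=1440, freq="1min")
        out = assign_phases(ts, schedule)
        assert (out["phase"] == "LIGHT").sum() == 720
        assert (out["phase"] == "DARK").sum() == 720
        assert out["day"].nunique() == 1

    def test_pre_lights_on_belongs_to_previous_day(self, schedule):
        out = assign_phases(pd.DatetimeIndex(["2021-03-02 03:00:00"]), schedule)
        assert out["day"].iloc[0] == pd.Timestamp("2021-03-01")
        assert out["hour_post_lights_on"].iloc[0] == 20


class TestExcludeDays:
    @staticmethod
    def _daily_table(n_days=35, cage_id="C01", start=dt.date(2021, 3, 1)):
        days = [pd.Timestamp(start) + pd.Timedelta(days=i) for i in range(n_days)]
        return pd.DataFrame(
            {
                "cage_id": cage_id,
                "day": days,
                "phase": "LIGHT",
                "metric": "activity_mean",
                "value": np.arange(n_days, dtype=float),
            }
        )

    def test_weekly_changes_leave_30_of_35_days(self, meta_factory):
        changes = {dt.date(2021, 3, 1) + dt.timedelta(days=7 * k) for k in range(5)}
        meta = meta_factory(changes=changes)
        table = self._daily_table()
        out = exclude_days(table, [meta])
        assert len(out) == 30

    def test_idempotent(self, meta_factory):
        meta = meta_factory(changes={dt.date(2021, 3, 3)})
        once = exclude_days(self._daily_table(), [meta])
        twice = exclude_days(once, [meta])
        pd.testing.assert_frame_equal(once, twice)

    def test_no_changes_identity(self, meta_factory):
        table = self._daily_table()
        out = exclude_days(table, [meta_factory()])
        pd.testing.assert_frame_equal(out, table)

    def test_all_days_excluded_warns(self, meta_factory):
        table = self._daily_table(n_days=3)
        changes = {dt.date(2021, 3, 1) + dt.timedelta(days=k) for k in range(3)}
        with pytest.warns(UserWarning):
            out = exclude_days(table, [meta_factory(changes=changes)])
        assert out.empty


class TestWeeklyAggregate:
    def test_constant_days_give_their_value(self):
        table = pd.DataFrame(
            {
                "cage_id": "C01",
                "day": pd.date_range("2021-03-01", periods=6, freq="D"),
                "phase": "DARK",
                "metric": "rdi",
                "value": 2.0,
            }
        )
        out = weekly_aggregate(table, start_day="2021-03-01")
        assert len(out) == 1
        assert out["value"].iloc[0] == 2.0
        assert out["week"].iloc[0] == 1

    def test_simple_mean(self):
        table = pd.DataFrame(
            {
                "cage_id": "C01",
                "day": pd.date_range("2021-03-01", periods=3, freq="D"),
                "phase": "DARK",
                "metric": "rdi",
                "value": [0.0, 3.0, 6.0],
            }
        )
        out = weekly_aggregate(table, start_day="2021-03-01")
        assert out["value"].iloc[0] == 3.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        days = pd.date_range("2021-03-01", periods=21, freq="D")
        rows = []
        for cage in ("C01", "C02"):
            for day in days:
                for phase in ("LIGHT", "DARK"):
                    rows.append(
                        {
                            "cage_id": cage,
                            "day": day,
                            "phase": phase,
                            "metric": "activity_mean",
                            "value": rng.random(),
                        }
                    )
        table = pd.DataFrame(rows)
        out = weekly_aggregate(table, start_day="2021-03-01")
        # independent oracle: direct summation per group
        for r in out.itertuples():
            week_days = days[(7 * (r.week - 1)) : (7 * r.week)]
            sel = table[
                (table["cage_id"] == r.cage_id)
                & (table["phase"] == r.phase)
                & table["day"].isin(week_days)
            ]["value"].to_numpy()
            assert abs(sel.sum() / len(sel) - r.value) < 1e-12


def test_light_schedule_rejects_inverted_times():
    with pytest.raises(ValueError):
        LightSchedule(lights_on=dt.time(19, 0), lights_off=dt.time(7, 0))
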