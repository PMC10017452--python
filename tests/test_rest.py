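import numpy as np
import pandas as pd
import pytest

from cagerest.datamodel import DARK, LIGHT, ActivitySeries, ImmobilitySeries
from cagerest.rest import (
    detect_rest_bouts,
    least_active_hour,
    least_active_hour_histogram,
    long_bout_fraction,
    percent_zero_per_hour,
    time_weighted_histogram,
)

T0 = pd.Timestamp("2021-03-01 07:00:00")


def imm_series(values, mask=None, start=T0):
    return ImmobilitySeries(cage_id="C01", start_time=start, values=values, mask=mask)


def act_series(values, start=T0):
    return ActivitySeries(cage_id="C01", start_time=start, values=values)


def rle_bouts(values, mask, bout_min):
    """Independent run-length-encoding oracle (masked seconds break runs)."""
    runs = []
    start = None
    for i, (v, m) in enumerate(zip(values, mask)):
        if v == 1 and not m:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - start))
                start = None
    if start is not None:
        runs.append((start, len(values) - start))
    return [(s, d) for s, d in runs if d >= bout_min]


class TestPercentZeroPerHour:
    def test_fully_immobile_hour_is_100(self, schedule):
        out = percent_zero_per_hour(imm_series(np.ones(3600, dtype=np.int8)), schedule)
        assert len(out) == 1
        assert out["value"].iloc[0] == 100.0
        assert out["hour_post_lights_on"].iloc[0] == 0

    def test_half_immobile_hour_is_50(self, schedule):
        v = np.zeros(3600, dtype=np.int8)
        v[:1800] = 1
        out = percent_zero_per_hour(imm_series(v), schedule)
        assert out["value"].iloc[0] == 50.0

    def test_matches_brute_force_count(self, schedule):
        rng = np.random.default_rng(41)
        v = rng.integers(0, 2, 6 * 3600).astype(np.int8)
        mask = rng.random(len(v)) < 0.05
        out = percent_zero_per_hour(imm_series(v, mask=mask), schedule)
        for r in out.itertuples():
            h = r.hour_post_lights_on
            sl = slice(h * 3600, (h + 1) * 3600)
            ok = ~mask[sl]
            expected = 100.0 * (v[sl][ok] == 1).sum() / ok.sum()
            assert r.value == pytest.approx(expected, abs=1e-12)

    def test_renormalises_by_unmasked_seconds(self, schedule):
        v = np.ones(3600, dtype=np.int8)
        mask = np.zeros(3600, dtype=bool)
        mask[:1800] = True
        out = percent_zero_per_hour(imm_series(v, mask=mask), schedule)
        assert out["value"].iloc[0] == 100.0


class TestLeastActiveHour:
    def test_forced_minimum_found(self, schedule):
        v = np.ones(1440)
        v[300:360] = 0.0
        out = least_active_hour(act_series(v), schedule)
        assert out["start_minute"].iloc[0] == 300
        assert out["mean_activity"].iloc[0] == 0.0
        assert out["phase_of_start"].iloc[0] == LIGHT

    def test_constant_series_ties_break_earliest(self, schedule):
        out = least_active_hour(act_series(np.full(1440, 0.2)), schedule)
        assert out["start_minute"].iloc[0] == 0

    def test_matches_exhaustive_search(self, schedule):
        rng = np.random.default_rng(43)
        v = rng.uniform(0, 1, 1440)
        v[rng.choice(1440, 40, replace=False)] = np.nan
        out = least_active_hour(act_series(v), schedule)
        # oracle: all 1381 windows, NaN-aware means, >10 masked skipped
        best = (np.inf, None)
        for s in range(1381):
            w = v[s : s + 60]
            n_masked = np.isnan(w).sum()
            if n_masked > 10:
                continue
            mean = np.nanmean(w)
            if mean < best[0]:
                best = (mean, s)
        assert out["start_minute"].iloc[0] == best[1]
        assert out["mean_activity"].iloc[0] == pytest.approx(best[0])

    def test_mean_never_exceeds_daily_mean(self, schedule):
        rng = np.random.default_rng(47)
        v = rng.uniform(0, 1, 1440)
        out = least_active_hour(act_series(v), schedule)
        assert out["mean_activity"].iloc[0] <= v.mean() + 1e-12

    def test_dark_start_labelled_dark(self, schedule):
        v = np.ones(1440)
        v[800:860] = 0.0
        out = least_active_hour(act_series(v), schedule)
        assert out["phase_of_start"].iloc[0] == DARK


class TestLeastActiveHourHistogram:
    def test_single_spike(self):
        res = pd.DataFrame(
            {"start_minute": [120] * 8, "phase_of_start": [LIGHT] * 8}
        )
        hist, dark_frac = least_active_hour_histogram(res)
        assert dark_frac == 0.0
        assert hist["count"].sum() == 8
        assert hist.loc[hist["bin_start_minute"] == 120, "count"].iloc[0] == 8

    def test_dark_fraction_arithmetic(self):
        res = pd.DataFrame(
            {
                "start_minute": list(range(100)),
                "phase_of_start": [DARK] * 10 + [LIGHT] * 90,
            }
        )
        _, dark_frac = least_active_hour_histogram(res)
        assert dark_frac == pytest.approx(0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            least_active_hour_histogram(pd.DataFrame(columns=["start_minute", "phase_of_start"]))


class TestDetectRestBouts:
    def test_39s_run_is_no_bout(self, schedule):
        v = np.zeros(200, dtype=np.int8)
        v[10:49] = 1
        out = detect_rest_bouts(imm_series(v), schedule)
        assert out.empty

    def test_50s_run_is_one_bout(self, schedule):
        v = np.zeros(200, dtype=np.int8)
        v[10:60] = 1
        out = detect_rest_bouts(imm_series(v), schedule)
        assert len(out) == 1
        assert out["duration_s"].iloc[0] == 50
        assert out["phase"].iloc[0] == LIGHT

    def test_matches_rle_oracle(self, schedule):
        rng = np.random.default_rng(53)
        # blocky binary signal so runs of many lengths occur
        v = (rng.random(5000) < 0.6).astype(np.int8)
        v = np.repeat(v[:250], 20)
        mask = rng.random(len(v)) < 0.01
        out = detect_rest_bouts(imm_series(v, mask=mask), schedule, bout_min=40)
        got = {
            ((r.start - T0).total_seconds(), r.duration_s) for r in out.itertuples()
        }
        expected = {(float(s), d) for s, d in rle_bouts(v, mask, 40)}
        assert got == expected

    def test_masked_seconds_break_runs(self, schedule):
        v = np.ones(100, dtype=np.int8)
        mask = np.zeros(100, dtype=bool)
        mask[50] = True
        out = detect_rest_bouts(imm_series(v, mask=mask), schedule)
        assert list(out["duration_s"]) == [50, 49]

    def test_onset_phase_attribution_across_boundary(self, schedule):
        # bout starting 30 s before lights-off runs into the dark phase
        start = pd.Timestamp("2021-03-01 18:59:00")
        v = np.zeros(300, dtype=np.int8)
        v[10:160] = 1  # starts 18:59:10, 150 s
        out = detect_rest_bouts(imm_series(v, start=start), schedule)
        assert len(out) == 1
        assert out["phase"].iloc[0] == LIGHT  # attributed to onset phase
        split = detect_rest_bouts(
            imm_series(v, start=start), schedule, split_at_phase_boundary=True
        )
        assert list(split["phase"]) == [LIGHT, DARK]
        assert list(split["duration_s"]) == [50, 100]

    def test_raising_bout_min_is_monotone(self, schedule):
        rng = np.random.default_rng(59)
        v = np.repeat((rng.random(200) < 0.7).astype(np.int8), 35)
        prev_n, prev_t = np.inf, np.inf
        for bm in (10, 40, 120, 600):
            out = detect_rest_bouts(imm_series(v), schedule, bout_min=bm)
            n, tot = len(out), out["duration_s"].sum()
            assert n <= prev_n and tot <= prev_t
            prev_n, prev_t = n, tot


class TestBoutHistograms:
    @staticmethod
    def _bouts(durations_min, phase=DARK):
        return pd.DataFrame(
            {
                "cage_id": "C01",
                "start": T0,
                "day": T0.normalize(),
                "duration_s": [int(d * 60) for d in durations_min],
                "phase": phase,
            }
        )

    def test_single_10min_bout(self):
        out = time_weighted_histogram(self._bouts([10]), DARK)
        assert list(out["weight"]) == [0.0, 1.0, 0.0]

    def test_4_and_16_minute_bouts(self):
        out = time_weighted_histogram(self._bouts([4, 16]), DARK)
        np.testing.assert_allclose(out["weight"], [0.2, 0.0, 0.8])

    def test_matches_brute_force_summation(self):
        rng = np.random.default_rng(61)
        durs = rng.uniform(40 / 60, 60, 200)  # minutes
        out = time_weighted_histogram(self._bouts(durs), DARK)
        secs = np.array([int(d * 60) for d in durs], dtype=float)
        edges = [0, 300, 900, np.inf]
        expected = [
            secs[(secs >= lo) & (secs < hi)].sum() / secs.sum()
            for lo, hi in zip(edges, edges[1:])
        ]
        np.testing.assert_allclose(out["weight"], expected, rtol=1e-12)
        assert out["weight"].sum() == pytest.approx(1.0)

    def test_empty_phase_gives_zero_weights_flagged(self):
        out = time_weighted_histogram(self._bouts([10], phase=LIGHT), DARK)
        assert (out["weight"] == 0).all()
        assert (out["flag"] == "empty").all()

    def test_long_bout_fraction_arithmetic(self):
        out = long_bout_fraction(self._bouts([31, 1]), DARK)
        assert out == pytest.approx(31 / 32)

    def test_no_long_bouts_gives_zero(self):
        assert long_bout_fraction(self._bouts([5, 29]), DARK) == 0.0
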