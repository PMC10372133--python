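import numpy as np
import pytest

from hypoburden import (
    MissingChannelError,
    ValidationError,
    detect_alarms,
    detect_episodes,
    threshold_spans,
)
from hypoburden.episode_detection import episodes_to_frame
from tests.conftest import make_series, random_trace, triangle_trace


def brute_force_spans(t, m, threshold, direction, fine_dt=0.05):
    """Independent oracle: dense resampling + maximal-run scan.

    The trace is linearly interpolated on a fine grid; excursions are
    maximal runs of strict threshold violation, with rectangle-sum areas.
    """
    tf = np.arange(t[0], t[-1] + fine_dt / 2, fine_dt)
    mf = np.interp(tf, t, m)
    viol = mf < threshold if direction == "below" else mf > threshold
    spans = []
    i = 0
    n = len(tf)
    while i < n:
        if not viol[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and viol[j + 1]:
            j += 1
        deficit = (threshold - mf[i:j + 1]) if direction == "below" else (mf[i:j + 1] - threshold)
        spans.append(
            {
                "start": tf[i],
                "end": tf[j],
                "area_min": float(np.sum(deficit) * fine_dt / 60.0),
                "extreme": float(mf[i:j + 1].min() if direction == "below" else mf[i:j + 1].max()),
            }
        )
        i = j + 1
    return spans


class TestEpisodes:
    def test_constant_above_threshold_yields_nothing(self):
        s = make_series(np.arange(0, 600, 20.0), np.full(30, 70.0))
        assert detect_episodes(s, 65.0, "below") == []

    def test_triangular_dip_crossings_and_area(self, triangle_series):
        (ep,) = detect_episodes(triangle_series, 65.0, "below", min_duration_s=60.0)
        # 70->60 at 5 mmHg/min crosses 65 one minute into the descent
        assert ep.start_s == pytest.approx(180.0)
        assert ep.end_s == pytest.approx(300.0)
        assert ep.duration_min == pytest.approx(2.0)
        assert ep.nadir_or_peak_mmHg == pytest.approx(60.0)
        # triangle: base 2 min x height 5 mmHg / 2
        assert ep.area_mmHg_min == pytest.approx(5.0)

    def test_short_dip_excluded_but_span_kept(self):
        # 40 s below threshold: not an event under the >1-min rule
        t, m = triangle_trace(baseline=70, nadir=63, dip_len_s=80.0, dip_start_s=200.0)
        s = make_series(t, m)
        assert detect_episodes(s, 65.0, "below", min_duration_s=60.0) == []
        spans = threshold_spans(s, 65.0, "below")
        assert len(spans) == 1 and spans[0].duration_s < 60.0

    def test_exactly_at_threshold_is_not_an_excursion(self):
        s = make_series(np.arange(0, 600, 20.0), np.full(30, 65.0))
        assert threshold_spans(s, 65.0, "below") == []
        assert threshold_spans(s, 65.0, "above") == []

    def test_two_samples_minimum(self):
        with pytest.raises(ValidationError):
            make_series([0.0], [70.0])

    def test_gap_splits_episode(self):
        t = np.concatenate([np.arange(0, 300, 20.0), np.arange(700, 1000, 20.0)])
        s = make_series(t, np.full(len(t), 60.0))
        eps = detect_episodes(s, 65.0, "below", min_duration_s=60.0)
        assert len(eps) == 2
        assert eps[0].end_s == 280.0 and eps[1].start_s == 700.0

    @pytest.mark.parametrize("direction,threshold", [("below", 65.0), ("above", 110.0)])
    def test_matches_brute_force_on_random_traces(self, direction, threshold):
        rng = np.random.default_rng(42)
        for _ in range(60):
            around = 65.0 if direction == "below" else 108.0
            t, m = random_trace(rng, around=around)
            s = make_series(t, m)
            got = threshold_spans(s, threshold, direction)
            want = brute_force_spans(t, m, threshold, direction)
            assert len(got) == len(want)
            for ep, ref in zip(got, want):
                assert ep.start_s == pytest.approx(ref["start"], abs=0.06)
                assert ep.end_s == pytest.approx(ref["end"], abs=0.06)
                assert ep.nadir_or_peak_mmHg == pytest.approx(ref["extreme"], abs=1e-9)
                assert ep.area_mmHg_min == pytest.approx(ref["area_min"], rel=5e-3, abs=0.02)

    def test_episodes_disjoint_ordered_within_window(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            t, m = random_trace(rng)
            s = make_series(t, m)
            eps = threshold_spans(s, 65.0, "below")
            for a, b in zip(eps, eps[1:]):
                assert a.end_s < b.start_s
            for ep in eps:
                assert t[0] <= ep.start_s < ep.end_s <= t[-1]

    def test_refinement_convergence(self):
        # smooth dip sampled at 20 s vs 1 s: boundaries within one coarse
        # sample, areas within 2%
        def trace(dt):
            t = np.arange(0.0, 1800.0 + dt / 2, dt)
            m = 75.0 - 18.0 * np.exp(-((t - 900.0) / 240.0) ** 2)
            return make_series(t, m)

        coarse = detect_episodes(trace(20.0), 65.0, "below")
        fine = detect_episodes(trace(1.0), 65.0, "below")
        assert len(coarse) == len(fine) == 1
        assert abs(coarse[0].start_s - fine[0].start_s) < 20.0
        assert abs(coarse[0].end_s - fine[0].end_s) < 20.0
        assert coarse[0].area_mmHg_min == pytest.approx(fine[0].area_mmHg_min, rel=0.02)

    def test_serialization_columns(self, triangle_series):
        eps = detect_episodes(triangle_series, 65.0, "below")
        df = episodes_to_frame(eps, "p1")
        assert list(df.columns) == [
            "patient_id", "threshold_mmHg", "direction", "start_s", "end_s",
            "duration_min", "nadir_or_peak_mmHg", "area_mmHg_min",
        ]
        assert len(df) == 1


def hpi_series(values, dt=20.0):
    t = np.arange(len(values)) * dt
    return make_series(t, np.full(len(values), 75.0), hpi=np.asarray(values, float))


class TestAlarms:
    def test_missing_channel_errors(self, triangle_series):
        with pytest.raises(MissingChannelError, match="hpi"):
            detect_alarms(triangle_series)

    def test_constant_high_index_one_alarm(self):
        s = hpi_series([90.0] * 30)
        (alarm,) = detect_alarms(s)
        assert alarm.start_s == 0.0
        assert alarm.end_s == s.t[-1]

    def test_short_high_spell_does_not_open(self):
        # two samples (40 s) at 90 then normalized: onset rule unmet
        s = hpi_series([90, 90] + [80] * 20)
        assert detect_alarms(s) == []

    def test_brief_normalization_merges_alarms(self):
        # 2 min high, 30-40 s below trigger, 2 min high -> one alarm
        s = hpi_series([90] * 6 + [80] * 2 + [90] * 6 + [50] * 6)
        alarms = detect_alarms(s)
        assert len(alarms) == 1
        assert alarms[0].start_s == 0.0
        assert alarms[0].end_s == s.t[13]

    def test_full_normalization_separates_alarms(self):
        s = hpi_series([90] * 6 + [80] * 3 + [90] * 6 + [50] * 6)
        assert len(detect_alarms(s)) == 2

    def test_matches_brute_force_automaton(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            vals = rng.choice([80.0, 90.0], size=rng.integers(4, 60))
            s = hpi_series(vals)
            got = [(a.start_s, a.end_s) for a in detect_alarms(s)]
            want = brute_force_alarms(s.t, vals)
            assert got == want


def brute_force_alarms(t, hpi, trigger=85.0, k=3):
    """Oracle: explicit per-sample state machine with counters."""
    alarms = []
    open_start = None
    last_on = None
    on_run = 0
    off_run = 0
    for i, v in enumerate(hpi):
        if v >= trigger:
            on_run += 1
            off_run = 0
            if open_start is None and on_run >= k:
                open_start = t[i - k + 1]
            if open_start is not None:
                last_on = i
        else:
            off_run += 1
            on_run = 0
            if open_start is not None and off_run >= k:
                alarms.append((float(t[np.searchsorted(t, open_start)]), float(t[last_on])))
                open_start = None
    if open_start is not None:
        alarms.append((float(open_start), float(t[last_on])))
    return alarms
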