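import numpy as np
import pytest

from paleogene.paleotemp import (
    LwpConfig,
    TemperatureSeries,
    WarmingInterval,
    detect_lwps,
    in_lwp,
    range_overlaps_lwp,
    read_temperature,
)
from paleogene.synthetic import ExcursionSpec, simulate_temperature


def brute_force_lwps(series, cfg=LwpConfig()):
    """Independent oracle: every maximal non-decreasing index pair, trimmed of
    leading/trailing plateaus, kept iff it clears both thresholds."""
    ts, ages = series.ts, series.ages
    n = len(ts)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if any(ts[k + 1] < ts[k] for k in range(i, j)):
                continue
            # maximality
            if i > 0 and ts[i - 1] <= ts[i]:
                continue
            if j < n - 1 and ts[j + 1] >= ts[j]:
                continue
            a, b = i, j
            while a < b and ts[a + 1] == ts[a]:
                a += 1
            while b > a and ts[b - 1] == ts[b]:
                b -= 1
            delta = ts[b] - ts[a]
            duration = ages[a] - ages[b]
            if delta > cfg.min_delta_t and duration >= cfg.min_duration - 1e-9:
                out.append((ages[a], ages[b], delta, duration))
    return sorted(out, key=lambda item: -item[0])


def cooling_with_bump(bump_amp, bump_old=7.8, bump_young=7.3):
    """Linear cooling 20→12 °C over 66→0 MYA plus one superimposed rise."""
    ages = np.linspace(66.0, 0.0, 331)  # 0.2 MY grid
    ages = np.unique(np.concatenate([ages, [bump_old, bump_young]]))[::-1]
    ts = 12.0 + 8.0 * ages / 66.0
    # ramp from 0 at bump_old up to bump_amp at bump_young, staying raised
    ramp = np.clip((bump_old - ages) / (bump_old - bump_young), 0.0, 1.0)
    return TemperatureSeries(ages=ages, ts=ts + bump_amp * ramp)


class TestReadTemperature:
    def test_two_rows(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("66 26\n0 14\n")
        s = read_temperature(p)
        assert list(s.ages) == [66.0, 0.0]
        assert list(s.ts) == [26.0, 14.0]

    def test_orientation_normalized(self, tmp_path):
        fwd, rev = tmp_path / "f.txt", tmp_path / "r.txt"
        fwd.write_text("66,26\n10,18\n0,14\n")
        rev.write_text("0,14\n10,18\n66,26\n")
        a, b = read_temperature(fwd), read_temperature(rev)
        assert np.array_equal(a.ages, b.ages)
        assert np.array_equal(a.ts, b.ts)

    def test_duplicate_age_collapsed_by_mean(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("66 26\n10.0 15\n10.0 16\n0 14\n")
        s = read_temperature(p)
        assert len(s) == 3
        assert s.ts[list(s.ages).index(10.0)] == pytest.approx(15.5)

    def test_non_numeric_row_names_line(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("66 26\nten 15\n")
        with pytest.raises(ValueError, match=":2"):
            read_temperature(p)

    def test_too_short_rejected(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("66 26\n")
        with pytest.raises(ValueError, match="at least 2"):
            read_temperature(p)


class TestDetectLwps:
    def test_monotone_cooling_is_empty(self):
        ages = np.linspace(66, 0, 200)
        s = TemperatureSeries(ages=ages, ts=12 + 8 * ages / 66)
        assert detect_lwps(s) == []

    def test_superimposed_rise_detected_once(self):
        s = cooling_with_bump(1.0)
        (iv,) = detect_lwps(s)
        assert iv.start_age >= 7.8 and iv.end_age <= 7.3
        # the cooling trend (8/66 °C per MY) eats into the 1.0 °C rise
        assert iv.delta_t >= 1.0 - 0.5 * 8.0 / 66.0 - 1e-9
        assert brute_force_lwps(s) == [
            (iv.start_age, iv.end_age, pytest.approx(iv.delta_t),
             pytest.approx(iv.duration))
        ]

    def test_sub_threshold_rise_ignored(self):
        assert detect_lwps(cooling_with_bump(0.4)) == []

    def test_short_rise_ignored(self):
        # +1.0 °C but over only 0.1 MY
        s = cooling_with_bump(1.0, bump_old=7.45, bump_young=7.35)
        assert detect_lwps(s) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        ages = np.sort(rng.uniform(0, 66, size=n))[::-1]
        ts = np.cumsum(rng.normal(0, 0.4, size=n)) + 15
        s = TemperatureSeries(ages=ages, ts=ts)
        got = [
            (iv.start_age, iv.end_age, pytest.approx(iv.delta_t),
             pytest.approx(iv.duration))
            for iv in detect_lwps(s)
        ]
        assert brute_force_lwps(s) == got

    def test_intervals_disjoint_and_valid(self):
        rng = np.random.default_rng(42)
        ages = np.sort(rng.uniform(0, 66, size=300))[::-1]
        ts = np.cumsum(rng.normal(0, 0.5, size=300)) + 15
        cfg = LwpConfig()
        lwps = detect_lwps(TemperatureSeries(ages=ages, ts=ts), cfg)
        assert lwps
        for iv in lwps:
            assert iv.delta_t > cfg.min_delta_t
            assert iv.duration >= cfg.min_duration - 1e-9
        for a, b in zip(lwps, lwps[1:]):
            assert a.end_age > b.start_age  # ordered oldest first, disjoint

    def test_dip_tolerance_merges_across_small_dips(self):
        ages = np.array([10.0, 9.8, 9.6, 9.4, 9.2, 9.0])
        ts = np.array([14.0, 14.3, 14.25, 14.5, 14.45, 14.8])
        assert detect_lwps(TemperatureSeries(ages=ages, ts=ts)) == []
        (iv,) = detect_lwps(
            TemperatureSeries(ages=ages, ts=ts), LwpConfig(dip_tolerance=0.1)
        )
        assert (iv.start_age, iv.end_age) == (10.0, 9.0)
        assert iv.delta_t == pytest.approx(0.8)

    def test_median_smoothing_suppresses_single_spike(self):
        ages = np.linspace(20, 0, 81)  # 0.25 MY grid
        ts = 14 + 0.05 * ages
        ts = ts.copy()
        ts[40] += 2.0  # one-sample spike: a rise of 2 °C over 0.25 MY
        s = TemperatureSeries(ages=ages, ts=ts)
        assert len(detect_lwps(s)) == 1
        assert detect_lwps(s, LwpConfig(smoothing_window=1.0)) == []


class TestPointAndRangeQueries:
    IV = [WarmingInterval(7.8, 7.3, 0.9, 0.5)]

    @pytest.mark.parametrize(
        "age,inside",
        [(7.5, True), (7.8, True), (7.3, True), (7.9, False), (2.0, False)],
    )
    def test_in_lwp_inclusive_bounds(self, age, inside):
        assert in_lwp(age, self.IV) is inside

    def test_empty_interval_list(self):
        assert not in_lwp(7.5, [])

    @pytest.mark.parametrize(
        "rng,overlaps",
        [((7.0, 7.4), True), ((2.0, 3.0), False), ((7.9, 8.2), False),
         ((6.0, 9.0), True)],
    )
    def test_range_overlap(self, rng, overlaps):
        assert range_overlaps_lwp(rng, self.IV) is overlaps

    def test_degenerate_range_equals_point_query(self):
        for age in (7.5, 7.8, 9.0):
            assert range_overlaps_lwp((age, age), self.IV) == in_lwp(age, self.IV)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            range_overlaps_lwp((3.0, 2.0), self.IV)


class TestThresholdSharpness:
    @pytest.mark.parametrize("amplitude", [0.3, 0.4, 0.6, 1.0])
    @pytest.mark.parametrize("duration", [0.1, 0.25, 0.5])
    def test_flat_baseline_grid(self, amplitude, duration):
        series, truth = simulate_temperature(
            oldest=20.0,
            trend_start=15.0,
            trend_end=15.0,
            excursions=[ExcursionSpec(10.0, amplitude, duration)],
            n_points=200,
            noise_sd=0.0,
            seed=3,
        )
        detected = detect_lwps(series)
        should = amplitude > 0.5 and duration >= 0.25
        assert (len(detected) == 1) is should
        assert (len(truth) == 1) is should
        if should:
            (iv,) = detected
            assert iv.start_age == pytest.approx(10.0 + duration)
            assert iv.end_age == pytest.approx(10.0)
            assert iv.delta_t == pytest.approx(amplitude)
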