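"""Activity taxonomy and metric extraction on analytic traces."""

import math

import numpy as np
import pytest

import condcorr as cc
from condcorr.classify import (
    BurstDescriptor,
    ClassifierConfig,
    burst_metrics,
    classify,
    detect_maxima,
    detect_spikes,
    is_periodic,
    rise_phase_slopes,
    segment_bursts,
    slow_wave,
)
from condcorr.simulate import VoltageTrace
from condcorr.synth import TraceFixtureSpec, fixture_family, make_trace


def _trace(t, V):
    t = np.asarray(t, float)
    return VoltageTrace(t, np.asarray(V, float), np.zeros_like(t))


class TestMaximaAndSpikes:
    def test_constant_trace_has_no_maxima(self):
        t = np.arange(0, 100, 0.1)
        mt, _ = detect_maxima(_trace(t, np.full_like(t, -55.0)))
        assert len(mt) == 0

    def test_sinusoid_crest_count_and_times(self):
        t = np.arange(0, 500, 0.05)
        V = -50 + 10 * np.sin(2 * np.pi * t / 100.0)  # 5 full cycles
        mt, mv = detect_maxima(_trace(t, V))
        assert len(mt) == 5
        assert np.allclose(mt, [25, 125, 225, 325, 425], atol=0.05)

    def test_triangle_apexes_match_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 200, 0.1)
        V = -60 + 20 * np.abs(((t / 17.0) % 2) - 1) + rng.normal(0, 0.01, t.size)
        mt, _ = detect_maxima(_trace(t, V))
        brute = [
            t[i] for i in range(1, len(t) - 1) if V[i] > V[i - 1] and V[i] > V[i + 1]
        ]
        assert np.array_equal(mt, brute)

    def test_spike_threshold_is_strict(self):
        mt = np.array([10.0, 20.0, 30.0])
        mv = np.array([-40.0, -29.9, 0.0])
        st, sv = detect_spikes(mt, mv, -30.0)
        assert list(st) == [20.0, 30.0]
        st, _ = detect_spikes(mt, np.array([-40.0, -35.0, -31.0]), -30.0)
        assert len(st) == 0
        st, _ = detect_spikes(mt, mv, -20.0)  # configurable threshold
        assert list(st) == [30.0]


class TestPeriodicity:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([50.0, 50.0, 50.0], True),
            ([50.0, 50.0, 51.0], False),  # 1.3% max deviation from the mean
            ([50.0, 50.4], True),  # 0.4% deviation
        ],
    )
    def test_one_percent_rule(self, intervals, expected):
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        assert is_periodic(times, 0.01) is expected

    def test_needs_three_events(self):
        with pytest.raises(ValueError):
            is_periodic([0.0, 50.0])


class TestBurstSegmentation:
    def test_thirty_percent_rule_groups_spikes(self):
        # ISIs 20,20,500 repeating -> bursts of three spikes
        spikes = []
        t = 0.0
        for _ in range(4):
            spikes += [t, t + 20, t + 40]
            t += 540.0
        bursts = segment_bursts(np.array(spikes), 0.3)
        assert [b.n_spikes for b in bursts] == [3, 3, 3, 3]

    def test_gap_qualification_uses_max_isi(self):
        # ISIs [20, 360, 20, 500]: both 360 and 500 are within 30% of 500
        spikes = np.array([0.0, 20.0, 380.0, 400.0, 900.0])
        bursts = segment_bursts(spikes, 0.3)
        assert [b.n_spikes for b in bursts] == [2, 2, 1]

    def test_burst_metrics_definitions(self):
        bursts = [
            BurstDescriptor(np.array([0.0, 200.0]), 0.0, 200.0),
            BurstDescriptor(np.array([1000.0, 1200.0]), 1000.0, 1200.0),
            BurstDescriptor(np.array([2000.0, 2200.0]), 2000.0, 2200.0),
        ]
        period, duration, duty, spb = burst_metrics(bursts)
        assert period == pytest.approx(1000.0)
        assert duration == pytest.approx(200.0)
        assert duty == pytest.approx(0.2)
        assert spb == pytest.approx(2.0)

    def test_one_spike_bursts_have_zero_duty_cycle(self):
        bursts = [BurstDescriptor(np.array([t]), t, t) for t in (0.0, 500.0, 1000.0)]
        _, duration, duty, spb = burst_metrics(bursts)
        assert duration == 0.0 and duty == 0.0 and spb == 1.0


class TestSlopesAndSlowWave:
    def test_linear_ramp_slopes(self):
        spec = TraceFixtureSpec(
            "periodic_bursting",
            burst_period=1000.0,
            burst_duration=100.0,
            spikes_per_burst=3,
            rise_slopes=0.075,  # -60 -> -30 over 400 ms
        )
        d = classify(make_trace(spec))
        for got in (d.slope_average, d.slope_initial, d.slope_central):
            assert got == pytest.approx(0.075, rel=0.02)

    def test_two_segment_ramp_orders_slopes(self):
        spec = TraceFixtureSpec(
            "periodic_bursting",
            burst_period=1500.0,
            burst_duration=150.0,
            spikes_per_burst=4,
            rise_slopes=(0.02, 0.10),
        )
        d = classify(make_trace(spec))
        assert d.slope_initial == pytest.approx(0.02, rel=0.05)
        assert d.slope_central == pytest.approx(0.10, rel=0.05)
        # average over points 1-4 = (s1 + 2*s2) / 3, strictly between the two
        assert d.slope_initial < d.slope_average < d.slope_central
        assert d.slope_average == pytest.approx((0.02 + 2 * 0.10) / 3, rel=0.05)

    def test_slow_wave_peak_and_amplitude(self):
        spec = TraceFixtureSpec(
            "periodic_bursting",
            burst_period=1000.0,
            burst_duration=200.0,
            spikes_per_burst=4,
            slow_wave_peak=-32.0,
            trough=-62.0,
        )
        d = classify(make_trace(spec))
        assert d.slow_wave_peak == pytest.approx(-32.0, abs=0.1)
        assert d.slow_wave_amplitude == pytest.approx(30.0, abs=0.2)


class TestClassification:
    def test_flat_trace_is_silent(self):
        t = np.arange(0, 2000, 0.05)
        assert classify(_trace(t, np.full_like(t, -60.0))).activity_class == "silent"

    def test_subthreshold_oscillation_is_silent(self):
        t = np.arange(0, 4000, 0.05)
        V = -50 + 10 * np.sin(2 * np.pi * t / 500.0)  # peaks at -40 mV
        d = classify(_trace(t, V))
        assert d.activity_class == "silent" and d.n_maxima > 0 and d.n_spikes == 0

    def test_regular_spike_train(self):
        spec = TraceFixtureSpec("periodic_spiking", frequency=20.0)
        d = classify(make_trace(spec))
        assert d.activity_class == "periodic_spiking"
        assert d.spike_frequency == pytest.approx(20.0, abs=0.05)

    def test_regular_bursts(self):
        spec = TraceFixtureSpec(
            "periodic_bursting",
            burst_period=1000.0,
            burst_duration=200.0,
            spikes_per_burst=3,
        )
        d = classify(make_trace(spec))
        assert d.activity_class == "periodic_bursting"
        assert d.duty_cycle == pytest.approx(0.2, abs=3 * 0.05 / 1000.0)

    def test_time_shift_leaves_class_and_metrics_unchanged(self):
        spec = TraceFixtureSpec(
            "periodic_bursting",
            burst_period=800.0,
            burst_duration=160.0,
            spikes_per_burst=4,
        )
        tr = make_trace(spec)
        d1 = classify(tr)
        shifted = VoltageTrace(tr.time + 1234.5, tr.V, tr.Ca)
        d2 = classify(shifted)
        r1, r2 = d1.to_record(), d2.to_record()
        for key in r1:
            v1, v2 = r1[key], r2[key]
            if isinstance(v1, float) and math.isnan(v1):
                assert math.isnan(v2)
            else:
                assert v1 == pytest.approx(v2)

    def test_uniform_offset_changes_only_threshold_outcomes(self):
        spec = TraceFixtureSpec("periodic_spiking", frequency=10.0, spike_peak=-25.0)
        tr = make_trace(spec)
        assert classify(tr).activity_class == "periodic_spiking"
        lowered = VoltageTrace(tr.time, tr.V - 10.0, tr.Ca)  # peaks now -35 mV
        d = classify(lowered)
        assert d.activity_class == "silent" and d.n_spikes == 0

    def test_classifier_is_total_and_deterministic_on_fixture_family(self):
        for spec, expected in fixture_family()[::7]:
            tr = make_trace(spec)
            d1, d2 = classify(tr), classify(tr)
            assert d1.to_record().keys() == d2.to_record().keys()
            assert d1.activity_class == d2.activity_class != ""


def test_fixture_family_spans_all_classes():
    from condcorr.classify import ACTIVITY_CLASSES

    classes = {exp["activity_class"] for _, exp in fixture_family()}
    assert classes == set(ACTIVITY_CLASSES)
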