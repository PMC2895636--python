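"""Activity taxonomy and scalar activity metrics from a voltage trace.

A trace is assigned exactly one of six classes — silent, periodic spiking,
irregular spiking, periodic bursting, irregular bursting, one-spike bursting —
plus an ``unclassifiable`` escape hatch for pathological traces.  The rules:

* a voltage maximum above the spike threshold (-30 mV) is a spike; all other
  maxima are sub-threshold activity;
* a train is periodic when every inter-event interval is within 1% of the
  mean interval;
* an inter-spike interval is an inter-burst interval when it is within 30% of
  the largest inter-spike interval of the trace; bursts are the maximal spike
  runs between inter-burst intervals.

Two rules the taxonomy needs but that are genuinely underdetermined are made
explicit here (see also the package methods note): a segmented trace only
counts as bursting when intra- and inter-burst intervals are separated in
time scale (``max intra-ISI <= burst_separation_ratio * min inter-ISI``), and
a trace whose inter-spike intervals are all inter-burst is a one-spike
burster only when sub-threshold maxima (a slow wave) exist between spikes —
otherwise it is tonic spiking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.signal import find_peaks

from .simulate import VoltageTrace

__all__ = [
    "ACTIVITY_CLASSES",
    "ClassifierConfig",
    "ActivityDescriptor",
    "BurstDescriptor",
    "detect_maxima",
    "detect_spikes",
    "is_periodic",
    "segment_bursts",
    "burst_metrics",
    "rise_phase_slopes",
    "slow_wave",
    "classify",
]

ACTIVITY_CLASSES = (
    "silent",
    "periodic_spiking",
    "irregular_spiking",
    "periodic_bursting",
    "irregular_bursting",
    "one_spike_bursting",
)

BURSTING_CLASSES = ("periodic_bursting", "irregular_bursting", "one_spike_bursting")
SPIKING_CLASSES = ("periodic_spiking", "irregular_spiking")

METRIC_COLUMNS = (
    "spike_frequency",
    "burst_period",
    "burst_duration",
    "duty_cycle",
    "spikes_per_burst",
    "slow_wave_peak",
    "slow_wave_amplitude",
    "slope_average",
    "slope_initial",
    "slope_central",
    "spike_height",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Classification thresholds; defaults follow the reference analysis."""

    spike_threshold: float = -30.0  # mV, strict "greater than"
    periodicity_tol: float = 0.01  # fraction of the mean interval, inclusive
    interburst_fraction: float = 0.3  # "within 30% of the largest ISI"
    burst_separation_ratio: float = 0.5  # intra/inter time-scale separation
    min_events: int = 3  # fewer maxima than this is unclassifiable


@dataclass
class ActivityDescriptor:
    """Class label plus every scalar activity metric (NaN where undefined)."""

    activity_class: str
    spike_frequency: float = math.nan  # Hz
    burst_period: float = math.nan  # ms
    burst_duration: float = math.nan  # ms
    duty_cycle: float = math.nan
    spikes_per_burst: float = math.nan
    slow_wave_peak: float = math.nan  # mV
    slow_wave_amplitude: float = math.nan  # mV
    slope_average: float = math.nan  # mV/ms
    slope_initial: float = math.nan
    slope_central: float = math.nan
    spike_height: float = math.nan  # mV
    n_maxima: int = 0
    n_spikes: int = 0

    def to_record(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class BurstDescriptor:
    """One burst: its spikes and, once computed, rise-phase landmarks."""

    spike_times: np.ndarray  # ms
    start: float  # ms, first spike time
    end: float  # ms, last spike time
    interburst_min: tuple[float, float] | None = None  # (time, V) after burst
    rise_points: np.ndarray | None = None  # (5, 2) of (time, V)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def detect_maxima(trace: VoltageTrace):
    """Strict local maxima of the sampled trace as ``(times, values)``.

    Plateau crests count once (at their midpoint); monotone or constant
    traces have none.
    """
    V = np.asarray(trace.V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("trace contains non-finite voltages")
    idx, _ = find_peaks(V)
    return np.asarray(trace.time)[idx], V[idx]


def detect_spikes(max_times, max_values, threshold: float = -30.0):
    """Maxima strictly above the spike threshold."""
    max_times = np.asarray(max_times)
    max_values = np.asarray(max_values)
    keep = max_values > threshold
    return max_times[keep], max_values[keep]


def is_periodic(event_times, tol: float = 0.01) -> bool:
    """True when every inter-event interval is within ``tol`` of their mean."""
    t = np.asarray(event_times, dtype=float)
    if len(t) < 3:
        raise ValueError("periodicity needs at least three events")
    iv = np.diff(t)
    mean = iv.mean()
    if mean <= 0:
        return False
    return bool(np.all(np.abs(iv - mean) <= tol * mean))


def segment_bursts(spike_times, interburst_fraction: float = 0.3) -> list[BurstDescriptor]:
    """Split a spike train into bursts by the 30%-of-maximum-ISI rule.

    Every inter-spike interval within ``interburst_fraction`` of the largest
    interval (inclusive) separates bursts; the comparison uses the
    per-trace maximum interval.
    """
    t = np.asarray(spike_times, dtype=float)
    if len(t) < 2:
        raise ValueError("burst segmentation needs at least two spikes")
    isi = np.diff(t)
    cut = (1.0 - interburst_fraction) * isi.max()
    is_gap = isi >= cut
    bursts = []
    start = 0
    for i, gap in enumerate(is_gap):
        if gap:
            seg = t[start : i + 1]
            bursts.append(BurstDescriptor(seg, seg[0], seg[-1]))
            start = i + 1
    seg = t[start:]
    bursts.append(BurstDescriptor(seg, seg[0], seg[-1]))
    return bursts


def burst_metrics(bursts: list[BurstDescriptor]):
    """(burst_period, burst_duration, duty_cycle, spikes_per_burst).

    The period is measured between consecutive burst starts; duty cycle is
    mean duration over mean period.  Duration of a one-spike burst is zero.
    """
    if len(bursts) < 2:
        raise ValueError("burst metrics need at least two bursts")
    starts = np.array([b.start for b in bursts])
    period = float(np.diff(starts).mean())
    duration = float(np.mean([b.end - b.start for b in bursts]))
    duty = duration / period if period > 0 else math.nan
    spb = float(np.mean([b.n_spikes for b in bursts]))
    return period, duration, duty, spb


def _interburst_minima(trace: VoltageTrace, bursts: list[BurstDescriptor]):
    """Locate the voltage minimum between each consecutive burst pair."""
    t = np.asarray(trace.time)
    V = np.asarray(trace.V)
    for k in range(len(bursts) - 1):
        lo, hi = bursts[k].end, bursts[k + 1].start
        sel = (t > lo) & (t < hi)
        if not sel.any():
            continue
        i = np.argmin(V[sel])
        bursts[k].interburst_min = (float(t[sel][i]), float(V[sel][i]))


def rise_phase_slopes(
    trace: VoltageTrace, bursts: list[BurstDescriptor], threshold: float = -30.0
):
    """Slow-wave rise-phase slopes: (average, initial, central), in mV/ms.

    For each inter-burst interval: point 1 is the inter-burst minimum and
    point 5 the next upward crossing of the spike threshold; points 2-4 cut
    the span into four equal time sections.  The average slope runs from
    point 1 to 4 (the 4-5 section is dropped to avoid the first-spike
    upstroke artifact), the initial slope from 1 to 2, and the central slope
    from 2 to 4.  Values are averaged over bursts; bursts where the
    threshold crossing cannot be found are skipped.
    """
    _interburst_minima(trace, bursts)
    t = np.asarray(trace.time)
    V = np.asarray(trace.V)
    s_avg, s_ini, s_cen = [], [], []
    for k in range(len(bursts) - 1):
        if bursts[k].interburst_min is None:
            continue
        t1, v1 = bursts[k].interburst_min
        # first upward threshold crossing after the minimum
        sel = np.nonzero((t > t1) & (t <= bursts[k + 1].spike_times[0]))[0]
        t5 = None
        for i in sel:
            if V[i] > threshold and V[i - 1] <= threshold:
                frac = (threshold - V[i - 1]) / (V[i] - V[i - 1])
                t5 = t[i - 1] + frac * (t[i] - t[i - 1])
                break
        if t5 is None or t5 <= t1:
            continue
        tp = t1 + np.arange(5) * (t5 - t1) / 4.0
        vp = np.interp(tp, t, V)
        vp[0] = v1
        vp[4] = threshold
        s_avg.append((vp[3] - vp[0]) / (tp[3] - tp[0]))
        s_ini.append((vp[1] - vp[0]) / (tp[1] - tp[0]))
        s_cen.append((vp[3] - vp[1]) / (tp[3] - tp[1]))
        bursts[k].rise_points = np.column_stack([tp, vp])
    if not s_avg:
        return math.nan, math.nan, math.nan
    return float(np.mean(s_avg)), float(np.mean(s_ini)), float(np.mean(s_cen))


def slow_wave(trace: VoltageTrace, bursts: list[BurstDescriptor], maxima=None):
    """(slow_wave_peak, slow_wave_amplitude) in mV, averaged over bursts.

    The slow-wave peak is approximated by the last voltage maximum belonging
    to a burst (the last maximum before the following inter-burst minimum);
    the amplitude is that peak minus the between-burst minimum.
    """
    if maxima is None:
        maxima = detect_maxima(trace)
    mt, mv = maxima
    _interburst_minima(trace, bursts)
    peaks, amps = [], []
    for k in range(len(bursts) - 1):
        if bursts[k].interburst_min is None:
            continue
        t_min, v_min = bursts[k].interburst_min
        sel = (mt >= bursts[k].start) & (mt < t_min)
        if not sel.any():
            continue
        peak = mv[sel][-1]
        peaks.append(peak)
        amps.append(peak - v_min)
    if not peaks:
        return math.nan, math.nan
    return float(np.mean(peaks)), float(np.mean(amps))


def classify(trace: VoltageTrace, cfg: ClassifierConfig | None = None) -> ActivityDescriptor:
    """Assign one activity class and populate all applicable metrics."""
    cfg = cfg or ClassifierConfig()
    mt, mv = detect_maxima(trace)
    desc = ActivityDescriptor(activity_class="silent", n_maxima=len(mt))
    if len(mt) == 0:
        return desc

    st, sv = detect_spikes(mt, mv, cfg.spike_threshold)
    desc.n_spikes = len(st)
    if len(st) == 0:
        # sub-threshold oscillation only; no spikes to analyse
        return desc
    if len(mt) < cfg.min_events or len(st) < 2:
        desc.activity_class = "unclassifiable"
        return desc

    desc.spike_height = float(np.mean(sv))
    isi = np.diff(st)
    desc.spike_frequency = 1000.0 / isi.mean()
    sub_maxima = np.count_nonzero(mv <= cfg.spike_threshold) > 0

    cut = (1.0 - cfg.interburst_fraction) * isi.max()
    all_gaps = bool(np.all(isi >= cut))
    spiking_periodic = is_periodic(mt, cfg.periodicity_tol) if len(mt) >= 3 else False

    if all_gaps:
        # every interval qualifies as inter-burst: one spike per "burst"
        if sub_maxima:
            desc.activity_class = "one_spike_bursting"
            bursts = [BurstDescriptor(np.array([s]), s, s) for s in st]
            desc.burst_period, desc.burst_duration, desc.duty_cycle, desc.spikes_per_burst = (
                burst_metrics(bursts)
            )
            desc.slow_wave_peak, desc.slow_wave_amplitude = slow_wave(trace, bursts, (mt, mv))
            desc.slope_average, desc.slope_initial, desc.slope_central = rise_phase_slopes(
                trace, bursts, cfg.spike_threshold
            )
        else:
            desc.activity_class = (
                "periodic_spiking" if spiking_periodic else "irregular_spiking"
            )
        return desc

    bursts = segment_bursts(st, cfg.interburst_fraction)
    intra = [np.diff(b.spike_times) for b in bursts if b.n_spikes > 1]
    inter = [
        bursts[k + 1].start - bursts[k].end for k in range(len(bursts) - 1)
    ]
    separated = (
        len(bursts) >= 2
        and len(intra) > 0
        and max(x.max() for x in intra) <= cfg.burst_separation_ratio * min(inter)
    )
    if separated:
        starts = [b.start for b in bursts]
        burst_periodic = is_periodic(starts, cfg.periodicity_tol) if len(starts) >= 3 else False
        desc.activity_class = "periodic_bursting" if burst_periodic else "irregular_bursting"
        desc.burst_period, desc.burst_duration, desc.duty_cycle, desc.spikes_per_burst = (
            burst_metrics(bursts)
        )
        desc.slow_wave_peak, desc.slow_wave_amplitude = slow_wave(trace, bursts, (mt, mv))
        desc.slope_average, desc.slope_initial, desc.slope_central = rise_phase_slopes(
            trace, bursts, cfg.spike_threshold
        )
        return desc

    desc.activity_class = "periodic_spiking" if spiking_periodic else "irregular_spiking"
    return desc
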