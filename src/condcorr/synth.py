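"""Synthetic inputs: analytic trace fixtures, planted databases, small grids.

Three generators cover everything the pipeline needs for testing without
external data:

* :func:`make_trace` builds piecewise-linear voltage waveforms with known
  class and metrics (spike times snapped to the sampling grid), so classifier
  tests are exact up to sampling quantization and independent of the ODE
  integrator;
* :func:`make_planted_db` draws surrogate model-record tables whose planted
  conductance pairs follow a diagonal band on the grid with a given adherence
  probability — the minimal generator for the near-linear band structure the
  correlation miner targets — while unplanted conductances stay uniform and
  independent;
* :func:`make_reduced_grid_db` simulates and classifies a coarsened version
  of the full conductance grid with the real model.

All generators are seeded and embed their generating spec in the output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, METRIC_COLUMNS, classify
from .database import CONDUCTANCES, ModelDatabase
from .model import GridDefinition, KineticsModel, load_default_model
from .simulate import SimulationConfig, VoltageTrace, run_grid

__all__ = [
    "TraceFixtureSpec",
    "PlantedDatabaseSpec",
    "make_trace",
    "make_planted_db",
    "make_reduced_grid_db",
    "fixture_family",
]

_SPIKE_HALF_WIDTH = 1.0  # ms, rise/fall time of a fixture spike
_THR = -30.0  # mV, spike threshold the fixtures are built around


@dataclass
class TraceFixtureSpec:
    """Construction parameters for one analytic voltage-trace fixture."""

    activity_class: str
    frequency: float | None = None  # Hz, spikers
    burst_period: float | None = None  # ms
    burst_duration: float | None = None  # ms
    spikes_per_burst: int | None = None
    spike_peak: float = 10.0  # mV
    trough: float = -60.0  # mV
    slow_wave_peak: float = -35.0  # mV, sub-threshold hump closing each burst
    rise_slopes: tuple[float, float] | float = 0.075  # mV/ms; tuple = two-segment
    jitter: float = 0.0  # fractional interval jitter (irregular classes)
    dt: float = 0.05  # ms
    duration: float = 6000.0  # ms
    seed: int = 0

    def validate(self):
        if self.activity_class not in (
            "silent",
            "periodic_spiking",
            "irregular_spiking",
            "periodic_bursting",
            "irregular_bursting",
            "one_spike_bursting",
        ):
            raise ValueError(f"unknown class {self.activity_class!r}")
        if self.activity_class != "silent":
            if not (self.spike_peak > _THR > self.trough):
                raise ValueError("need spike_peak > -30 mV > trough")
        if "bursting" in self.activity_class:
            if not (_THR > self.slow_wave_peak > self.trough):
                raise ValueError("slow-wave peak must sit between trough and threshold")
            if self.burst_period is None:
                raise ValueError("bursting fixtures need burst_period")
            if self.activity_class != "one_spike_bursting":
                if self.burst_duration is None or self.spikes_per_burst is None:
                    raise ValueError("multi-spike bursts need duration and spikes_per_burst")
                if not 0 < self.burst_duration / self.burst_period < 1:
                    raise ValueError("implied duty cycle must be in (0, 1)")
                if self.spikes_per_burst < 2:
                    raise ValueError("use one_spike_bursting for single-spike bursts")
        elif "spiking" in self.activity_class and self.frequency is None:
            raise ValueError("spiking fixtures need a frequency")


def _snap(t: float, dt: float) -> float:
    return round(t / dt) * dt


def _rise_time(spec: TraceFixtureSpec) -> tuple[float, float, float]:
    """(rise time, first-quarter slope, remaining slope) to reach -30 mV."""
    span = _THR - spec.trough
    if isinstance(spec.rise_slopes, (tuple, list)):
        s1, s2 = spec.rise_slopes
        if s1 <= 0 or s2 <= 0:
            raise ValueError("rise slopes must be positive")
        t_r = span / (0.25 * s1 + 0.75 * s2)
    else:
        s1 = s2 = float(spec.rise_slopes)
        if s1 <= 0:
            raise ValueError("rise slope must be positive")
        t_r = span / s1
    return t_r, s1, s2


def make_trace(spec: TraceFixtureSpec) -> VoltageTrace:
    """Build the waveform; ``classify`` recovers the spec's class and metrics
    within one sampling interval's quantization.  Contradictory specs raise."""
    spec.validate()
    dt = spec.dt
    rng = np.random.default_rng(spec.seed)
    t_grid = np.arange(0.0, spec.duration + dt / 2, dt)
    prov = {"fixture": asdict(spec)}

    if spec.activity_class == "silent":
        return VoltageTrace(t_grid, np.full_like(t_grid, spec.trough), np.zeros_like(t_grid) + 0.05, prov)

    w = _SPIKE_HALF_WIDTH
    pts_t: list[float] = [0.0]
    pts_v: list[float] = [spec.trough]

    if spec.activity_class in ("periodic_spiking", "irregular_spiking"):
        T = 1000.0 / spec.frequency
        jit = spec.jitter if spec.activity_class == "irregular_spiking" else 0.0
        peaks = []
        t = _snap(5 * w, dt)
        while t < spec.duration - 2 * w:
            peaks.append(t)
            step = T * (1.0 + jit * rng.uniform(-1.0, 1.0))
            if step <= 2 * w + dt:
                raise ValueError("inter-spike interval too short for spike width")
            t = _snap(t + step, dt)
        for p in peaks:
            pts_t += [p - w, p, p + w]
            pts_v += [spec.trough, spec.spike_peak, spec.trough]
        prov["realized_frequency"] = 1000.0 / float(np.mean(np.diff(peaks)))
    else:
        t_r, s1, s2 = _rise_time(spec)
        jit = spec.jitter if spec.activity_class == "irregular_bursting" else 0.0
        one_spike = spec.activity_class == "one_spike_bursting"
        P = spec.burst_period
        D = 0.0 if one_spike else spec.burst_duration
        n_spk = 1 if one_spike else spec.spikes_per_burst
        delta = 0.0 if n_spk == 1 else D / (n_spk - 1)
        if n_spk > 1 and delta <= 2 * w + dt:
            raise ValueError("spikes per burst too dense for spike width")
        hump_lead = 5.0  # ms from last spike to the slow-wave hump
        gap_needed = 2 * w + hump_lead + t_r + 2 * dt
        base = -40.0 if not one_spike else -50.0

        starts = []
        t = _snap(max(t_r + 2 * w, 50.0), dt)
        while t < spec.duration - D - 2 * w:
            starts.append(t)
            step = P * (1.0 + jit * rng.uniform(-1.0, 1.0))
            if step - D <= gap_needed:
                raise ValueError("inter-burst gap too short for slow-wave geometry")
            t = _snap(t + step, dt)
        if len(starts) < 3:
            raise ValueError("duration too short for at least three bursts")

        for k, t_k in enumerate(starts):
            spike_peaks = [_snap(t_k + j * delta, dt) for j in range(n_spk)]
            for j, p in enumerate(spike_peaks):
                if j == 0:
                    # rise phase delivered the trace to -30 mV at p - w
                    pts_t += [p]
                    pts_v += [spec.spike_peak]
                else:
                    pts_t += [p - w, p]
                    pts_v += [base, spec.spike_peak]
                pts_t += [p + w]
                pts_v += [base]
            t_end = spike_peaks[-1]
            if k + 1 < len(starts):
                t_next = starts[k + 1]
                t_cross = _snap(t_next - w, dt)
                t_trough = _snap(t_cross - t_r, dt)
                t_hump = _snap(t_end + w + hump_lead, dt)
                if not (t_end + w < t_hump < t_trough < t_cross):
                    raise ValueError("cycle geometry collapsed; widen the inter-burst gap")
                pts_t += [t_hump, t_trough]
                pts_v += [spec.slow_wave_peak, spec.trough]
                if s1 != s2:
                    t_q = t_trough + 0.25 * (t_cross - t_trough)
                    pts_t += [t_q]
                    pts_v += [spec.trough + s1 * 0.25 * (t_cross - t_trough)]
                pts_t += [t_cross]
                pts_v += [_THR]
        prov["realized_burst_period"] = float(np.mean(np.diff(starts)))
        prov["realized_rise_time"] = t_r

    pts_t.append(spec.duration + dt)
    pts_v.append(pts_v[-1])
    tp = np.asarray(pts_t)
    if np.any(np.diff(tp) <= 0):
        raise ValueError("fixture breakpoints are not strictly increasing")
    V = np.interp(t_grid, tp, np.asarray(pts_v))
    return VoltageTrace(t_grid, V, np.zeros_like(t_grid) + 0.05, prov)


@dataclass
class PlantedDatabaseSpec:
    """Surrogate model-record table with planted pairwise dependencies.

    ``planted`` maps an activity-type label to a list of
    ``(pair, sign, band_width, adherence)`` entries: with probability
    ``adherence`` a model of that type lands uniformly inside the diagonal
    (or anti-diagonal) band of the pair's grid, otherwise uniformly anywhere.
    """

    n_models: int
    n_levels: int = 6
    types: tuple[tuple[str, float], ...] = (
        ("periodic_bursting", 0.3),
        ("periodic_spiking", 0.3),
        ("silent", 0.4),
    )
    planted: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self):
        weights = [w for _, w in self.types]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("type weights must be non-negative and sum to 1")
        for label, deps in self.planted.items():
            if label not in {t for t, _ in self.types}:
                raise ValueError(f"planted type {label!r} not in the mixture")
            for pair, sign, width, adherence in deps:
                if sign not in "+-":
                    raise ValueError("planted sign must be '+' or '-'")
                if not 0 <= adherence <= 1:
                    raise ValueError("adherence must be in [0, 1]")
                if not 1 <= width <= self.n_levels:
                    raise ValueError("band width out of range")


def _band_cells(n_levels: int, sign: str, width: int) -> np.ndarray:
    i, j = np.indices((n_levels, n_levels))
    if sign == "+":
        mask = np.abs(i - j) < width
    else:
        mask = np.abs(i + j - (n_levels - 1)) < width
    return np.flatnonzero(mask.ravel())


def make_planted_db(spec: PlantedDatabaseSpec) -> ModelDatabase:
    """Draw the surrogate database; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.n_levels
    names = CONDUCTANCES
    labels = [t for t, _ in spec.types]
    weights = [w for _, w in spec.types]
    types = rng.choice(len(labels), size=spec.n_models, p=weights)

    grid_idx = rng.integers(0, L, size=(spec.n_models, len(names)))
    col = {n: i for i, n in enumerate(names)}
    for label, deps in spec.planted.items():
        members = np.flatnonzero(types == labels.index(label))
        for pair, sign, width, adherence in deps:
            band = _band_cells(L, sign, width)
            adherent = members[rng.random(len(members)) < adherence]
            cells = band[rng.integers(0, len(band), size=len(adherent))]
            grid_idx[adherent, col[pair[0]]] = cells // L
            grid_idx[adherent, col[pair[1]]] = cells % L

    grid = GridDefinition(names, L, tuple(load_default_model().grid.max_gbar))
    records = {}
    for i, n in enumerate(names):
        records[f"grid_{n}"] = grid_idx[:, i]
    levels = {n: grid.levels(n) for n in names}
    for i, n in enumerate(names):
        records[f"g_{n}"] = levels[n][grid_idx[:, i]]
    records["activity_class"] = [labels[t] for t in types]
    df = pd.DataFrame(records)
    for m in METRIC_COLUMNS:
        df[m] = math.nan
    meta = {
        "grid": {"names": list(names), "n_levels": L, "max_gbar": list(grid.max_gbar)},
        "kinetics": "synthetic-planted",
        "planted_spec": {
            "n_models": spec.n_models,
            "n_levels": L,
            "types": [list(t) for t in spec.types],
            "planted": {
                k: [[list(p), s, w, a] for p, s, w, a in v]
                for k, v in spec.planted.items()
            },
            "seed": spec.seed,
        },
    }
    return ModelDatabase(df, meta=meta)


def make_reduced_grid_db(
    levels: int = 3,
    model: KineticsModel | None = None,
    sim_cfg: SimulationConfig | None = None,
    classifier_cfg: ClassifierConfig | None = None,
    checkpoint_dir: str | None = None,
) -> ModelDatabase:
    """Simulate and classify a coarse grid (``levels`` equidistant values per
    conductance over the full ranges); deterministic."""
    model = model or load_default_model()
    sim_cfg = sim_cfg or SimulationConfig()
    ccfg = classifier_cfg or ClassifierConfig()
    grid = model.grid.subgrid(levels)
    return run_grid(
        grid, model, sim_cfg, lambda tr: classify(tr, ccfg), checkpoint_dir=checkpoint_dir
    )


def fixture_family(dt: float = 0.05, duration: float = 6000.0):
    """A parameterized family of >=100 trace fixtures spanning all classes.

    Returns ``list of (spec, expected)`` where ``expected`` holds the
    construction values the classifier should recover.
    """
    out = []

    def add(spec, **expected):
        expected["activity_class"] = spec.activity_class
        out.append((spec, expected))

    for i in range(6):
        add(TraceFixtureSpec("silent", trough=-68.0 + 3 * i, dt=dt, duration=duration))
    for f in (1.0, 2.0, 5.0, 8.0, 12.0, 20.0, 35.0, 50.0, 65.0, 80.0, 100.0, 150.0):
        add(
            TraceFixtureSpec("periodic_spiking", frequency=f, dt=dt, duration=duration),
            spike_frequency=f,
        )
    for f in (2.0, 5.0, 15.0, 30.0, 60.0, 90.0):
        for seed in (1, 2, 3):
            add(
                TraceFixtureSpec(
                    "irregular_spiking",
                    frequency=f,
                    jitter=0.15,
                    seed=seed,
                    dt=dt,
                    duration=duration,
                ),
            )
    for P in (600.0, 1000.0, 1500.0, 2000.0):
        for duty in (0.1, 0.2, 0.3):
            for n in (3, 5, 8):
                # rise time set to 40% of the inter-burst gap so the cycle
                # geometry is always feasible
                s = round(30.0 / (0.4 * P * (1.0 - duty)), 4)
                add(
                    TraceFixtureSpec(
                        "periodic_bursting",
                        burst_period=P,
                        burst_duration=duty * P,
                        spikes_per_burst=n,
                        rise_slopes=s,
                        slow_wave_peak=-35.0,
                        dt=dt,
                        duration=duration,
                    ),
                    burst_period=P,
                    duty_cycle=duty,
                    spikes_per_burst=n,
                    slope_initial=s,
                    slope_central=s,
                    slow_wave_amplitude=25.0,
                )
    for s1, s2 in ((0.02, 0.1), (0.05, 0.2), (0.03, 0.12)):
        add(
            TraceFixtureSpec(
                "periodic_bursting",
                burst_period=1500.0,
                burst_duration=150.0,
                spikes_per_burst=4,
                rise_slopes=(s1, s2),
                dt=dt,
                duration=duration,
            ),
            duty_cycle=0.1,
            slope_initial=s1,
            slope_central=s2,
        )
    for P in (800.0, 1200.0):
        for duty in (0.15, 0.25):
            for seed in (1, 2, 3):
                add(
                    TraceFixtureSpec(
                        "irregular_bursting",
                        burst_period=P,
                        burst_duration=duty * P,
                        spikes_per_burst=4,
                        jitter=0.05,
                        seed=seed,
                        dt=dt,
                        duration=duration,
                    ),
                )
    for P in (400.0, 700.0, 1100.0, 1600.0, 2000.0):
        for swp in (-45.0, -38.0):
            add(
                TraceFixtureSpec(
                    "one_spike_bursting",
                    burst_period=P,
                    slow_wave_peak=swp,
                    rise_slopes=round(30.0 / (0.35 * P), 4),
                    dt=dt,
                    duration=duration,
                ),
                spikes_per_burst=1,
                duty_cycle=0.0,
            )
    # sweep spike peaks and troughs for robustness of threshold handling
    for pk in (-25.0, -10.0, 0.0, 25.0):
        add(
            TraceFixtureSpec("periodic_spiking", frequency=10.0, spike_peak=pk, dt=dt,
                             duration=duration),
            spike_frequency=10.0,
            spike_height=pk,
        )
    for duty in (0.05, 0.4, 0.6):
        add(
            TraceFixtureSpec(
                "periodic_bursting",
                burst_period=2000.0,
                burst_duration=duty * 2000.0,
                spikes_per_burst=6,
                rise_slopes=0.06,
                dt=dt,
                duration=3 * 6000.0 if duty >= 0.4 else duration,
            ),
            duty_cycle=duty,
        )
    return out
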