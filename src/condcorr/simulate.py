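"""Numerical integration of the model and batch grid runs.

The integrator is the exponential-Euler scheme that is standard for this model
family: gating variables relax exactly toward their voltage-dependent steady
state over one step, and the membrane equation is advanced with the
instantaneous total conductance.  Gating curves are evaluated from
pre-tabulated voltage samples (linear interpolation) so the inner loop is
model-agnostic and jit-compiled once.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .model import GridDefinition, KineticsModel, ModelParameters, evaluate_gating

__all__ = ["SimulationConfig", "VoltageTrace", "SimulationDiverged", "simulate", "run_grid"]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``i_inject`` is a constant injected current in nA (0 for the database
    protocol); ``record_dt`` down-samples the stored trace and must be a
    multiple of ``dt``.
    """

    dt: float = 0.05  # ms
    total_duration: float = 10000.0  # ms
    transient_discard: float = 4000.0  # ms
    integrator: str = "exponential_euler"
    initial_V: float = -50.0  # mV
    init_gates_steady: bool = True
    i_inject: float = 0.0  # nA
    record_dt: float | None = None  # ms; defaults to dt

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.transient_discard < self.total_duration:
            raise ValueError("need 0 <= transient_discard < total_duration")
        if self.integrator != "exponential_euler":
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.record_dt is not None:
            ratio = self.record_dt / self.dt
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                raise ValueError("record_dt must be a positive multiple of dt")

    def provenance(self) -> dict:
        return {
            "dt": self.dt,
            "total_duration": self.total_duration,
            "transient_discard": self.transient_discard,
            "integrator": self.integrator,
            "initial_V": self.initial_V,
            "i_inject": self.i_inject,
        }


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential and calcium concentration."""

    time: np.ndarray  # ms
    V: np.ndarray  # mV
    Ca: np.ndarray  # uM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.time) == len(self.V) == len(self.Ca)):
            raise ValueError("trace vectors must have equal length")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time_ms": self.time, "V_mV": self.V, "Ca_uM": self.Ca}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "VoltageTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(df["time_ms"].to_numpy(), df["V_mV"].to_numpy(), df["Ca_uM"].to_numpy())


class SimulationDiverged(RuntimeError):
    def __init__(self, grid_index, time_ms):
        self.grid_index = grid_index
        self.time_ms = time_ms
        super().__init__(
            f"non-finite state at t = {time_ms:.2f} ms for grid index {list(grid_index)}"
        )


@njit(cache=True)
def _integrate(
    V0,
    Ca0,
    m0,
    h0,
    gbar,
    dt,
    n_steps,
    rec0,
    rec_every,
    m_inf_t,
    h_inf_t,
    tau_m_t,
    tau_h_t,
    p,
    q,
    rev,
    is_ca,
    ca_half,
    v_min,
    v_step,
    cm,
    area,
    ca_tau,
    ca_f,
    ca_rest,
    ca_ext,
    ca_pref,
    ca_floor,
    i_density,
):  # pragma: no cover - exercised through simulate()
    nch = gbar.size
    nv = m_inf_t.shape[1]
    n_rec = 0
    k = rec0
    while k <= n_steps:
        n_rec += 1
        k += rec_every
    V_out = np.empty(n_rec)
    Ca_out = np.empty(n_rec)
    V = V0
    Ca = Ca0
    m = m0.copy()
    h = h0.copy()
    j = 0
    for step in range(n_steps):
        x = (V - v_min) / v_step
        if x < 0.0:
            x = 0.0
        if x > nv - 1.0:
            x = nv - 1.0
        i0 = int(x)
        if i0 >= nv - 1:
            i0 = nv - 2
        f = x - i0
        g_sum = 0.0
        ge_sum = i_density
        i_ca_density = 0.0
        eca = ca_pref * math.log(ca_ext / Ca)
        for c in range(nch):
            gate = 1.0
            if p[c] > 0:
                minf = m_inf_t[c, i0] * (1.0 - f) + m_inf_t[c, i0 + 1] * f
                if ca_half[c] > 0.0:
                    minf *= Ca / (Ca + ca_half[c])
                taum = tau_m_t[c, i0] * (1.0 - f) + tau_m_t[c, i0 + 1] * f
                m[c] = minf + (m[c] - minf) * math.exp(-dt / taum)
                mm = m[c]
                for _ in range(p[c] - 1):
                    mm *= m[c]
                gate *= mm
            if q[c] > 0:
                hinf = h_inf_t[c, i0] * (1.0 - f) + h_inf_t[c, i0 + 1] * f
                tauh = tau_h_t[c, i0] * (1.0 - f) + tau_h_t[c, i0 + 1] * f
                h[c] = hinf + (h[c] - hinf) * math.exp(-dt / tauh)
                gate *= h[c]
            g = gbar[c] * gate
            if is_ca[c]:
                e = eca
                i_ca_density += g * (V - eca)
            else:
                e = rev[c]
            g_sum += g
            ge_sum += g * e
        if g_sum > 0.0:
            v_inf = ge_sum / g_sum
            V = v_inf + (V - v_inf) * math.exp(-dt * g_sum / cm)
        else:
            V = V + dt * ge_sum / cm
        i_ca_nA = i_ca_density * area * 1000.0
        ca_inf = ca_rest - ca_f * i_ca_nA
        Ca = ca_inf + (Ca - ca_inf) * math.exp(-dt / ca_tau)
        if Ca < ca_floor:
            Ca = ca_floor
        if not (math.isfinite(V) and math.isfinite(Ca)):
            return V_out, Ca_out, step + 1, False
        if step + 1 >= rec0 and (step + 1 - rec0) % rec_every == 0:
            V_out[j] = V
            Ca_out[j] = Ca
            j += 1
    return V_out, Ca_out, n_steps, True


def simulate(
    params: ModelParameters, model: KineticsModel, cfg: SimulationConfig
) -> VoltageTrace:
    """Integrate one parameter set; deterministic for fixed inputs.

    Returns the trace sampled over ``[transient_discard, total_duration]``.
    Raises :class:`SimulationDiverged` if the state becomes non-finite.
    """
    t = model.tables()
    mem = model.membrane
    ca = model.calcium
    dt = cfg.dt
    n_steps = int(round(cfg.total_duration / dt))
    rec0 = int(round(cfg.transient_discard / dt))
    if rec0 < 1:
        rec0 = 1
    rec_every = int(round((cfg.record_dt or dt) / dt))

    Ca0 = ca.rest
    if cfg.init_gates_steady:
        m0 = np.ones(len(model.channels))
        h0 = np.ones(len(model.channels))
        for i, ch in enumerate(model.channels):
            m_inf, h_inf, _, _ = evaluate_gating(ch, cfg.initial_V, Ca0)
            if ch.p > 0:
                m0[i] = float(m_inf)
            if ch.q > 0:
                h0[i] = float(h_inf)
    else:
        m0 = np.zeros(len(model.channels))
        h0 = np.ones(len(model.channels))

    i_density = cfg.i_inject * 1e-3 / mem.area  # nA -> uA/cm^2
    V_out, Ca_out, last_step, ok = _integrate(
        float(cfg.initial_V),
        float(Ca0),
        m0,
        h0,
        np.asarray(params.gbar, dtype=float),
        dt,
        n_steps,
        rec0,
        rec_every,
        t.m_inf,
        t.h_inf,
        t.tau_m,
        t.tau_h,
        t.p,
        t.q,
        t.reversal,
        t.is_calcium,
        t.ca_half,
        t.v_min,
        t.v_step,
        mem.specific_capacitance,
        mem.area,
        ca.tau,
        ca.current_factor,
        ca.rest,
        ca.external,
        ca.nernst_prefactor,
        ca.floor,
        i_density,
    )
    if not ok:
        raise SimulationDiverged(params.grid_index, last_step * dt)
    time = (rec0 + np.arange(len(V_out)) * rec_every) * dt
    prov = cfg.provenance()
    prov["kinetics"] = model.name
    prov["grid_index"] = [int(i) for i in params.grid_index]
    return VoltageTrace(time=time, V=V_out, Ca=Ca_out, provenance=prov)


def _chunk_path(checkpoint_dir: str, chunk: int) -> str:
    return os.path.join(checkpoint_dir, f"chunk_{chunk:06d}.tsv")


def run_grid(
    grid: GridDefinition,
    model: KineticsModel,
    cfg: SimulationConfig,
    classifier,
    checkpoint_dir: str | None = None,
    chunk_size: int = 512,
    progress=None,
):
    """Simulate and classify every grid point; returns a :class:`ModelDatabase`.

    ``classifier`` maps a :class:`VoltageTrace` to an object with a
    ``to_record()`` dict (see :func:`condcorr.classify.classify`).  Records are
    produced in lexicographic grid order and are independent of chunking, so
    partial runs checkpointed to ``checkpoint_dir`` resume without changing
    the result.  A checkpoint chunk with the wrong shape is a hard error.
    """
    from .database import ModelDatabase  # local import avoids a cycle

    indices = list(grid.iter_indices())
    chunks = [indices[i : i + chunk_size] for i in range(0, len(indices), chunk_size)]
    frames = []
    if checkpoint_dir is not None:
        os.makedirs(checkpoint_dir, exist_ok=True)
    for ci, chunk in enumerate(chunks):
        if checkpoint_dir is not None:
            path = _chunk_path(checkpoint_dir, ci)
            if os.path.exists(path):
                try:
                    df = pd.read_csv(path, sep="\t")
                except Exception as exc:
                    raise RuntimeError(f"corrupt checkpoint chunk {path}: {exc}") from exc
                if len(df) != len(chunk):
                    raise RuntimeError(
                        f"corrupt checkpoint chunk {path}: "
                        f"{len(df)} rows, expected {len(chunk)}"
                    )
                frames.append(df)
                continue
        rows = []
        for idx in chunk:
            params = ModelParameters.from_index(grid, idx)
            try:
                trace = simulate(params, model, cfg)
                desc = classifier(trace)
                rec = desc.to_record()
            except SimulationDiverged:
                rec = {"activity_class": "unclassifiable"}
            row = {f"grid_{n}": int(v) for n, v in zip(grid.names, idx)}
            row.update({f"g_{n}": g for n, g in zip(grid.names, params.gbar)})
            row.update(rec)
            rows.append(row)
            if progress is not None:
                progress(row)
        df = pd.DataFrame(rows)
        if checkpoint_dir is not None:
            path = _chunk_path(checkpoint_dir, ci)
            df.to_csv(path, sep="\t", index=False)
            # read back so a fresh run and a resumed run are byte-identical
            df = pd.read_csv(path, sep="\t")
        frames.append(df)
    records = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    meta = {
        "grid": {
            "names": list(grid.names),
            "n_levels": grid.n_levels,
            "max_gbar": list(grid.max_gbar),
        },
        "kinetics": model.name,
        "simulation": cfg.provenance(),
    }
    return ModelDatabase(records, meta=meta)
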