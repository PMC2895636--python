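"""Single-compartment conductance-based neuron model, defined as data.

The membrane carries eight Hodgkin-Huxley-style currents (fast Na, fast and
slow transient Ca, A-type K, Ca-dependent K, delayed-rectifier K, the
hyperpolarization-activated mixed-ion H current, and an ohmic leak) plus an
intracellular calcium pool that sets the calcium reversal through the Nernst
relation.  All kinetics are loaded from a structured YAML configuration so the
integrator core stays model-agnostic and the numeric transcription remains
auditable; the shipped default is ``data/stg_kinetics.yaml``.

Each current has density ``I = gbar * m^p * h^q * (V - E)`` (mS/cm^2, mV ->
uA/cm^2) with first-order gating ``dx/dt = (x_inf(V) - x) / tau_x(V)``.  The
calcium-dependent K current's activation carries an extra ``Ca/(Ca+K)``
factor.  Maximal conductances live on an 8-dimensional grid of equidistant
levels from zero to a per-channel maximum.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "GateFunction",
    "ChannelKinetics",
    "MembraneConfig",
    "CalciumConfig",
    "GridDefinition",
    "ModelParameters",
    "KineticsModel",
    "evaluate_gating",
    "nernst_calcium",
    "load_default_model",
]

V_RANGE = (-120.0, 60.0)  # mV; gating tables clamp outside this window


def _logistic(V, v_half, k):
    return 1.0 / (1.0 + np.exp((V - v_half) / k))


def _eval_form(spec: dict, V, Ca=None):
    form = spec["form"]
    if form == "logistic":
        return _logistic(V, spec["v_half"], spec["k"])
    if form == "logistic_ca":
        if Ca is None:
            raise ValueError("logistic_ca form requires a calcium concentration")
        return (Ca / (Ca + spec["ca_half"])) * _logistic(V, spec["v_half"], spec["k"])
    if form == "sigmoid_offset":
        return spec["a"] + spec["b"] / (1.0 + np.exp((V - spec["v_half"]) / spec["k"]))
    if form == "double_exponential":
        return spec["a"] + spec["b"] / (
            np.exp((V - spec["v1"]) / spec["k1"]) + np.exp((V - spec["v2"]) / spec["k2"])
        )
    if form == "product_sigmoids":
        return (spec["a"] / (1.0 + np.exp((V - spec["v1"]) / spec["k1"]))) * (
            spec["b"] + spec["c"] / (1.0 + np.exp((V - spec["v2"]) / spec["k2"]))
        )
    raise ValueError(f"unknown kinetics form {form!r}")


@dataclass(frozen=True)
class GateFunction:
    """One voltage-(and optionally calcium-)dependent kinetics curve."""

    spec: dict

    def __call__(self, V, Ca=None):
        Vc = np.clip(V, *V_RANGE)
        return _eval_form(self.spec, Vc, Ca)

    @property
    def ca_dependent(self) -> bool:
        return self.spec["form"] == "logistic_ca"


@dataclass(frozen=True)
class ChannelKinetics:
    """Kinetics of one ionic current: exponents, reversal, gating curves.

    ``reversal`` is either a fixed potential in mV or the string ``"calcium"``
    for currents whose reversal tracks the intracellular calcium pool.
    """

    name: str
    reversal: float | str
    p: int
    q: int
    m_inf: GateFunction | None = None
    h_inf: GateFunction | None = None
    tau_m: GateFunction | None = None
    tau_h: GateFunction | None = None

    def __post_init__(self):
        if self.p < 0 or self.q < 0:
            raise ValueError(f"channel {self.name}: exponents must be non-negative")
        if self.p > 0 and (self.m_inf is None or self.tau_m is None):
            raise ValueError(f"channel {self.name}: p>0 requires m_inf and tau_m")
        if self.q > 0 and (self.h_inf is None or self.tau_h is None):
            raise ValueError(f"channel {self.name}: q>0 requires h_inf and tau_h")

    @property
    def calcium_reversal(self) -> bool:
        return self.reversal == "calcium"


def evaluate_gating(kin: ChannelKinetics, V, Ca=None):
    """Evaluate (m_inf, h_inf, tau_m, tau_h) for one channel.

    Channels without an inactivation gate (q=0) report ``h_inf = 1`` and
    ``tau_h = 1`` (the value is never used).  Raises on non-finite voltage or
    non-positive calcium so a bad integration state is diagnosed by channel.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError(f"channel {kin.name}: non-finite voltage input")
    if Ca is not None:
        Ca = np.asarray(Ca, dtype=float)
        if not np.all(np.isfinite(Ca)) or np.any(Ca <= 0):
            raise ValueError(f"channel {kin.name}: calcium must be finite and > 0")

    one = np.ones_like(V, dtype=float)
    if kin.p > 0:
        m_inf = kin.m_inf(V, Ca)
        tau_m = kin.tau_m(V, Ca)
    else:
        m_inf, tau_m = one, one
    if kin.q > 0:
        h_inf = kin.h_inf(V, Ca)
        tau_h = kin.tau_h(V, Ca)
    else:
        h_inf, tau_h = one, one
    return m_inf, h_inf, tau_m, tau_h


@dataclass(frozen=True)
class MembraneConfig:
    """Passive membrane constants (per-area convention)."""

    specific_capacitance: float = 1.0  # uF/cm^2
    area: float = 6.2832e-4  # cm^2
    v_table_min: float = -120.0
    v_table_max: float = 60.0
    v_table_step: float = 0.01

    def __post_init__(self):
        if self.specific_capacitance <= 0 or self.area <= 0:
            raise ValueError("membrane constants must be positive")


@dataclass(frozen=True)
class CalciumConfig:
    """Intracellular calcium pool: first-order buffering plus current drive.

    ``tau * dCa/dt = -current_factor * I_Ca[nA] - Ca + rest``; the calcium
    reversal is ``nernst_prefactor * ln(external / Ca)``.
    """

    tau: float = 200.0  # ms
    current_factor: float = 14.96  # uM/nA
    rest: float = 0.05  # uM
    external: float = 3000.0  # uM
    nernst_prefactor: float = 12.199  # mV
    floor: float = 1e-4  # uM

    def __post_init__(self):
        for name in ("tau", "current_factor", "rest", "external", "nernst_prefactor", "floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"calcium config: {name} must be positive")


def nernst_calcium(ca_in, calcium: CalciumConfig):
    """Calcium reversal potential (mV) from the intracellular concentration."""
    ca_in = np.asarray(ca_in, dtype=float)
    if np.any(ca_in <= 0) or not np.all(np.isfinite(ca_in)):
        raise ValueError("intracellular calcium must be finite and > 0")
    return calcium.nernst_prefactor * np.log(calcium.external / ca_in)


@dataclass(frozen=True)
class GridDefinition:
    """Equidistant conductance levels, zero to max, per channel."""

    names: tuple[str, ...]
    n_levels: int
    max_gbar: tuple[float, ...]

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("grid needs at least one level")
        if len(self.names) != len(self.max_gbar):
            raise ValueError("names and max_gbar length mismatch")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def size(self) -> int:
        return self.n_levels ** self.n_channels

    def levels(self, name: str) -> np.ndarray:
        i = self.names.index(name)
        if self.n_levels == 1:
            return np.array([0.0])
        return np.linspace(0.0, self.max_gbar[i], self.n_levels)

    def gbar_from_index(self, grid_index: Sequence[int]) -> np.ndarray:
        idx = np.asarray(grid_index, dtype=int)
        if idx.shape != (self.n_channels,):
            raise ValueError("grid index has wrong length")
        if np.any(idx < 0) or np.any(idx >= self.n_levels):
            raise ValueError("grid index out of range")
        if self.n_levels == 1:
            return np.zeros(self.n_channels)
        return np.asarray(self.max_gbar) * idx / (self.n_levels - 1)

    def iter_indices(self) -> Iterator[tuple[int, ...]]:
        """All grid points in lexicographic order (first channel slowest)."""
        return itertools.product(range(self.n_levels), repeat=self.n_channels)

    def subgrid(self, n_levels: int) -> "GridDefinition":
        """Same conductance ranges sampled at a different resolution."""
        return GridDefinition(self.names, n_levels, self.max_gbar)


@dataclass(frozen=True)
class ModelParameters:
    """One grid point: the 8 maximal conductances and their level indices."""

    gbar: np.ndarray
    grid_index: np.ndarray

    @classmethod
    def from_index(cls, grid: GridDefinition, grid_index: Sequence[int]) -> "ModelParameters":
        idx = np.asarray(grid_index, dtype=int)
        return cls(gbar=grid.gbar_from_index(idx), grid_index=idx)


class KineticsModel:
    """A complete model definition loaded from one configuration file."""

    def __init__(
        self,
        channels: Sequence[ChannelKinetics],
        membrane: MembraneConfig,
        calcium: CalciumConfig,
        grid: GridDefinition,
        name: str = "unnamed",
        schema_version: int = 1,
        status: str = "",
        raw: dict | None = None,
    ):
        self.channels = tuple(channels)
        self.membrane = membrane
        self.calcium = calcium
        self.grid = grid
        self.name = name
        self.schema_version = schema_version
        self.status = status
        self._raw = raw
        self._tables: GatingTables | None = None

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels)

    @classmethod
    def from_dict(cls, cfg: dict) -> "KineticsModel":
        channels = []
        for ch in cfg["channels"]:
            channels.append(
                ChannelKinetics(
                    name=ch["name"],
                    reversal=ch["reversal"],
                    p=int(ch.get("p", 0)),
                    q=int(ch.get("q", 0)),
                    m_inf=GateFunction(ch["m_inf"]) if "m_inf" in ch else None,
                    h_inf=GateFunction(ch["h_inf"]) if "h_inf" in ch else None,
                    tau_m=GateFunction(ch["tau_m"]) if "tau_m" in ch else None,
                    tau_h=GateFunction(ch["tau_h"]) if "tau_h" in ch else None,
                )
            )
        mem = cfg.get("membrane", {})
        membrane = MembraneConfig(
            specific_capacitance=mem.get("specific_capacitance", 1.0),
            area=mem.get("area", 6.2832e-4),
            v_table_min=mem.get("v_table_min", -120.0),
            v_table_max=mem.get("v_table_max", 60.0),
            v_table_step=mem.get("v_table_step", 0.01),
        )
        ca = cfg.get("calcium", {})
        calcium = CalciumConfig(
            tau=ca.get("tau", 200.0),
            current_factor=ca.get("current_factor", 14.96),
            rest=ca.get("rest", 0.05),
            external=ca.get("external", 3000.0),
            nernst_prefactor=ca.get("nernst_prefactor", 12.199),
            floor=ca.get("floor", 1e-4),
        )
        names = tuple(ch.name for ch in channels)
        g = cfg["grid"]
        grid = GridDefinition(
            names=names,
            n_levels=int(g["n_levels"]),
            max_gbar=tuple(float(g["max"][n]) for n in names),
        )
        return cls(
            channels,
            membrane,
            calcium,
            grid,
            name=cfg.get("name", "unnamed"),
            schema_version=int(cfg.get("schema_version", 1)),
            status=cfg.get("status", ""),
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path) -> "KineticsModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        if self._raw is not None:
            return self._raw
        raise ValueError("model was not built from a configuration dict")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- gating tables for the integrator ---------------------------------

    def tables(self) -> "GatingTables":
        if self._tables is None:
            self._tables = GatingTables.build(self)
        return self._tables


@dataclass(frozen=True)
class GatingTables:
    """Voltage-sampled gating curves packed for the numerical core.

    Calcium-gated activations store only the voltage factor; the integrator
    multiplies in ``Ca/(Ca+ca_half)`` at run time.  Reversals of calcium
    currents are recomputed from the Nernst relation each step.
    """

    v_min: float
    v_step: float
    m_inf: np.ndarray  # (n_channels, n_v)
    h_inf: np.ndarray
    tau_m: np.ndarray
    tau_h: np.ndarray
    p: np.ndarray  # int exponents
    q: np.ndarray
    reversal: np.ndarray  # mV; ignored where is_calcium
    is_calcium: np.ndarray  # bool
    ca_half: np.ndarray  # uM; 0 where not calcium-gated

    @classmethod
    def build(cls, model: KineticsModel) -> "GatingTables":
        mem = model.membrane
        V = np.arange(mem.v_table_min, mem.v_table_max + mem.v_table_step / 2, mem.v_table_step)
        n = len(model.channels)
        m_inf = np.ones((n, V.size))
        h_inf = np.ones((n, V.size))
        tau_m = np.ones((n, V.size))
        tau_h = np.ones((n, V.size))
        ca_half = np.zeros(n)
        for i, ch in enumerate(model.channels):
            if ch.p > 0:
                if ch.m_inf.ca_dependent:
                    # store the voltage factor; Ca factor applied per step
                    m_inf[i] = _logistic(V, ch.m_inf.spec["v_half"], ch.m_inf.spec["k"])
                    ca_half[i] = ch.m_inf.spec["ca_half"]
                else:
                    m_inf[i] = ch.m_inf(V)
                tau_m[i] = ch.tau_m(V)
            if ch.q > 0:
                h_inf[i] = ch.h_inf(V)
                tau_h[i] = ch.tau_h(V)
        for name, arr, lo, hi in (
            ("m_inf", m_inf, 0.0, 1.0),
            ("h_inf", h_inf, 0.0, 1.0),
        ):
            if np.any(arr < lo - 1e-12) or np.any(arr > hi + 1e-12):
                raise ValueError(f"{name} outside [0,1] over the table range")
        if np.any(tau_m <= 0) or np.any(tau_h <= 0):
            raise ValueError("time constants must be strictly positive over the table range")
        reversal = np.array(
            [0.0 if ch.calcium_reversal else float(ch.reversal) for ch in model.channels]
        )
        return cls(
            v_min=float(V[0]),
            v_step=float(mem.v_table_step),
            m_inf=m_inf,
            h_inf=h_inf,
            tau_m=tau_m,
            tau_h=tau_h,
            p=np.array([ch.p for ch in model.channels], dtype=np.int64),
            q=np.array([ch.q for ch in model.channels], dtype=np.int64),
            reversal=reversal,
            is_calcium=np.array([ch.calcium_reversal for ch in model.channels]),
            ca_half=ca_half,
        )


def load_default_model() -> KineticsModel:
    """The shipped generic STG model (``data/stg_kinetics.yaml``)."""
    ref = importlib.resources.files("condcorr") / "data" / "stg_kinetics.yaml"
    with importlib.resources.as_file(ref) as path:
        return KineticsModel.from_yaml(path)
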