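"""Model-database persistence and population segmentation.

A :class:`ModelDatabase` is a table of grid-point records — per-channel grid
level, maximal conductance, activity class, and every scalar activity metric —
plus provenance metadata (grid definition, kinetics version, simulation
settings).  Storage is a TSV with a JSON sidecar, schema-versioned.

Populations are cut from the database either by binning a single metric
(left-closed, right-open bins, open-ended at both extremes) or by a
conjunction of closed metric ranges (the multi-criteria "pacemaker" style
definitions).  The reference-mode scheme set reconstructs the 47 sub-populations
used for the correlation screen; edges and ranges the reference analysis
did not report are flagged as reconstructions in the config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ACTIVITY_CLASSES, METRIC_COLUMNS

__all__ = [
    "SCHEMA_VERSION",
    "ModelDatabase",
    "PartitionScheme",
    "Population",
    "write_db",
    "read_db",
    "read_supplementary_dump",
    "partition",
    "select_by_criteria",
    "reference_config",
    "reference_populations",
]

SCHEMA_VERSION = 1

CONDUCTANCES = ("Na", "CaT", "CaS", "A", "KCa", "Kd", "H", "leak")

_KNOWN_COLUMNS = (
    tuple(f"grid_{n}" for n in CONDUCTANCES)
    + tuple(f"g_{n}" for n in CONDUCTANCES)
    + ("activity_class",)
    + METRIC_COLUMNS
    + ("n_maxima", "n_spikes")
)


@dataclass
class ModelDatabase:
    """Records plus provenance; the unit every downstream stage consumes."""

    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.records) and "activity_class" not in self.records.columns:
            raise ValueError("records must carry an activity_class column")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def conductance_names(self) -> tuple[str, ...]:
        if "grid" in self.meta and "names" in self.meta["grid"]:
            return tuple(self.meta["grid"]["names"])
        return tuple(
            c[len("grid_") :] for c in self.records.columns if c.startswith("grid_")
        )

    @property
    def n_levels(self) -> int:
        if "grid" in self.meta and "n_levels" in self.meta["grid"]:
            return int(self.meta["grid"]["n_levels"])
        cols = [c for c in self.records.columns if c.startswith("grid_")]
        return int(self.records[cols].to_numpy().max()) + 1 if cols else 0

    def grid_levels(self, name: str) -> np.ndarray:
        return self.records[f"grid_{name}"].to_numpy()

    def class_mask(self, activity_class: str) -> np.ndarray:
        return (self.records["activity_class"] == activity_class).to_numpy()

    def subset(self, pop: "Population") -> pd.DataFrame:
        return self.records.iloc[pop.index]


@dataclass(frozen=True)
class PartitionScheme:
    """Single-metric binning restricted to one activity class."""

    metric: str
    edges: tuple[float, ...]
    activity_class: str
    label: str = ""

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) == 0 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be non-empty and strictly increasing")


@dataclass
class Population:
    """A labelled member list referencing rows of one database."""

    label: str
    index: np.ndarray  # positional row indices
    scheme: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.index)


def write_db(db: ModelDatabase, path: str) -> None:
    """TSV plus ``<path>.meta.json`` sidecar; lossless round-trip."""
    db.records.to_csv(path, sep="\t", index=False)
    meta = dict(db.meta)
    meta["schema_version"] = SCHEMA_VERSION
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_db(path: str) -> ModelDatabase:
    records = pd.read_csv(path, sep="\t")
    unknown = [c for c in records.columns if c not in _KNOWN_COLUMNS]
    if unknown:
        raise ValueError(f"unknown database columns: {unknown}")
    meta_path = str(path) + ".meta.json"
    meta: dict = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
        version = meta.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"database schema version {version} != supported {SCHEMA_VERSION}"
            )
    return ModelDatabase(records, meta=meta)


def read_supplementary_dump(path: str, column_map: dict, grid=None):
    """Parse a whitespace-delimited model-database dump.

    ``column_map`` maps record fields (``g_Na`` ... ``g_leak``,
    ``activity_class`` or metric names) to 0-based column positions in the
    file.  Grid level indices are recovered by matching conductance values to
    ``grid`` (a :class:`condcorr.model.GridDefinition`) when given.  Returns
    ``(database, rejects)`` where ``rejects`` lists ``(line_number, reason)``
    for every row that failed the map — nothing is silently skipped.
    """
    need = max(column_map.values()) + 1
    rows, rejects = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or line.lstrip().startswith("#"):
                continue
            if len(parts) < need:
                rejects.append((ln, f"expected >= {need} fields, got {len(parts)}"))
                continue
            row = {}
            try:
                for name, col in column_map.items():
                    if name == "activity_class":
                        row[name] = parts[col]
                    else:
                        row[name] = float(parts[col])
            except ValueError as exc:
                rejects.append((ln, str(exc)))
                continue
            rows.append(row)
    records = pd.DataFrame(rows)
    if len(records) and "activity_class" not in records.columns:
        records["activity_class"] = "unknown"
    meta: dict = {"source": str(path)}
    if grid is not None and len(records):
        for i, name in enumerate(grid.names):
            col = f"g_{name}"
            if col not in records.columns:
                continue
            levels = grid.levels(name)
            vals = records[col].to_numpy()
            idx = np.abs(vals[:, None] - levels[None, :]).argmin(axis=1)
            records[f"grid_{name}"] = idx
        meta["grid"] = {
            "names": list(grid.names),
            "n_levels": grid.n_levels,
            "max_gbar": list(grid.max_gbar),
        }
    return ModelDatabase(records, meta=meta), rejects


def partition(db: ModelDatabase, scheme: PartitionScheme) -> list[Population]:
    """Disjoint, covering populations of the scheme's activity class.

    Bins are left-closed right-open; the first bin is everything below the
    first edge and the last bin everything at or above the last edge, so a
    record at an edge falls in the upper bin.
    """
    mask = db.class_mask(scheme.activity_class)
    if scheme.metric in db.records.columns:
        values = db.records[scheme.metric].to_numpy(dtype=float)
    else:  # metric never computed for this database: nothing qualifies
        values = np.full(len(db), np.nan)
    ok = mask & np.isfinite(values)
    edges = np.asarray(scheme.edges, dtype=float)
    bins = np.concatenate([[-np.inf], edges, [np.inf]])
    which = np.digitize(values, edges, right=False)  # value >= edge -> upper bin
    pops = []
    prefix = scheme.label or scheme.activity_class
    for b in range(len(edges) + 1):
        lo, hi = bins[b], bins[b + 1]
        if b == 0:
            name = f"{prefix} {scheme.metric}<{edges[0]:g}"
        elif b == len(edges):
            name = f"{prefix} {scheme.metric}>={edges[-1]:g}"
        else:
            name = f"{prefix} {scheme.metric} {lo:g}-{hi:g}"
        idx = np.nonzero(ok & (which == b))[0]
        pops.append(
            Population(
                label=name,
                index=idx,
                scheme={
                    "metric": scheme.metric,
                    "low": None if np.isneginf(lo) else lo,
                    "high": None if np.isposinf(hi) else hi,
                    "activity_class": scheme.activity_class,
                },
            )
        )
    return pops


def select_by_criteria(
    db: ModelDatabase,
    criteria_set: list[tuple[str, float, float]],
    label: str = "criteria",
    activity_class: str | None = None,
) -> Population:
    """Conjunction of closed metric ranges, optionally within one class."""
    keep = np.ones(len(db), dtype=bool)
    if activity_class is not None:
        keep &= db.class_mask(activity_class)
    for metric, low, high in criteria_set:
        if low > high:
            raise ValueError(f"criterion {metric}: empty range [{low}, {high}]")
        v = db.records[metric].to_numpy(dtype=float)
        keep &= np.isfinite(v) & (v >= low) & (v <= high)
    return Population(
        label=label,
        index=np.nonzero(keep)[0],
        scheme={"criteria": list(criteria_set), "activity_class": activity_class},
    )


def reference_config() -> dict:
    """The default partition schemes and pacemaker criteria.

    Frequency and duty-cycle edges follow the reference analysis.  The
    three slow-wave rise-slope schemes and the pacemaker ranges other than
    slow-wave amplitude 10-30 mV are reconstructions (the reference analysis
    found the outcome robust to boundary shifts); they are marked
    ``reconstructed`` here and are ordinary config entries.
    """
    return {
        "single_metric": [
            {
                "metric": "spike_frequency",
                "activity_class": "periodic_spiking",
                "edges": [10.0, 25.0, 50.0, 75.0],
                "label": "spikers",
                "status": "printed",
            },
            {
                "metric": "duty_cycle",
                "activity_class": "periodic_bursting",
                "edges": [0.05, 0.1, 0.2, 0.4, 0.6],
                "label": "bursters",
                "status": "printed",
            },
            {
                "metric": "slope_average",
                "activity_class": "periodic_bursting",
                "edges": [0.01, 0.02, 0.04, 0.08, 0.15],
                "label": "bursters",
                "status": "reconstructed",
            },
            {
                "metric": "slope_initial",
                "activity_class": "periodic_bursting",
                "edges": [0.005, 0.01, 0.02, 0.04, 0.08],
                "label": "bursters",
                "status": "reconstructed",
            },
            {
                "metric": "slope_central",
                "activity_class": "periodic_bursting",
                "edges": [0.02, 0.05, 0.1, 0.2, 0.4],
                "label": "bursters",
                "status": "reconstructed",
            },
        ],
        "single_metric_off_by_default": [
            {
                "metric": "spike_height",
                "activity_class": "periodic_spiking",
                "edges": [-10.0, 0.0, 10.0, 20.0],
                "label": "spikers",
                "status": "reconstructed; off by default (lower success rate)",
            },
            {
                "metric": "spikes_per_burst",
                "activity_class": "periodic_bursting",
                "edges": [2.0, 4.0, 8.0, 16.0],
                "label": "bursters",
                "status": "reconstructed; off by default (lower success rate)",
            },
        ],
        "pacemaker_criteria": {
            "swa": {"metric": "slow_wave_amplitude", "low": 10.0, "high": 30.0,
                    "status": "printed"},
            "swp": {"metric": "slow_wave_peak", "low": -50.0, "high": -20.0,
                    "status": "reconstructed-approximate"},
            "dc": {"metric": "duty_cycle", "low": 0.2, "high": 0.5,
                   "status": "reconstructed-approximate"},
            "bp": {"metric": "burst_period", "low": 500.0, "high": 2000.0,
                   "status": "reconstructed-approximate"},
            "spb": {"metric": "spikes_per_burst", "low": 3.0, "high": 20.0,
                    "status": "reconstructed-approximate"},
        },
        "pacemaker_combinations": [
            ["swa", "swp"],
            ["swa", "dc"],
            ["swp", "dc"],
            ["swa", "swp", "dc"],
            ["swa", "swp", "bp"],
            ["swa", "swp", "dc", "bp"],
            ["swa", "swp", "dc", "bp", "spb"],
        ],
    }


def reference_populations(db: ModelDatabase, config: dict | None = None) -> list[Population]:
    """The 47 sub-populations screened for correlations in reference mode.

    6 activity-class groups, 5 spike-frequency groups, 6 duty-cycle groups,
    3 rise-slope schemes x 6 groups, 5 single pacemaker-criterion populations
    and 7 criterion combinations.
    """
    cfg = config or reference_config()
    pops: list[Population] = []
    for cls in ACTIVITY_CLASSES:
        pops.append(
            Population(
                label=f"all {cls}",
                index=np.nonzero(db.class_mask(cls))[0],
                scheme={"activity_class": cls},
            )
        )
    for sm in cfg["single_metric"]:
        scheme = PartitionScheme(
            metric=sm["metric"],
            edges=tuple(sm["edges"]),
            activity_class=sm["activity_class"],
            label=sm["label"],
        )
        pops.extend(partition(db, scheme))
    crit = cfg["pacemaker_criteria"]
    for key, c in crit.items():
        pops.append(
            select_by_criteria(
                db,
                [(c["metric"], c["low"], c["high"])],
                label=f"pacemaker {key}",
                activity_class="periodic_bursting",
            )
        )
    for combo in cfg["pacemaker_combinations"]:
        criteria = [(crit[k]["metric"], crit[k]["low"], crit[k]["high"]) for k in combo]
        pops.append(
            select_by_criteria(
                db,
                criteria,
                label="pacemaker " + "+".join(combo),
                activity_class="periodic_bursting",
            )
        )
    labels = [p.label for p in pops]
    if len(set(labels)) != len(labels):
        raise ValueError("population labels are not unique")
    return pops
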