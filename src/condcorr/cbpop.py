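"""Correlation-based populations and enrichment of a target activity type.

A correlation observed in activity type *i* is turned into a mask: the set of
grid cells of the pair's conductance plot holding at least 3% of the type-*i*
models.  Scanning the whole database — irrespective of activity type — for
models whose conductance pairs fall inside one mask or the conjunction of
several yields the correlation-based population cb_i.  Enrichment is
quantified as::

    %Success_cb  = 100 * N(cb_i  & type_i) / N(cb_i)
    %Success_orig = 100 * N(type_i) / N(database)
    f_Success    = %Success_cb / %Success_orig

``f_Success > 1`` means imposing the correlation makes the target activity
type more likely.  Matched random masks and ideal diagonal-band masks provide
the null controls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlate import ConductanceHistogram2D
from .database import ModelDatabase, Population

__all__ = [
    "MASK_THRESHOLD",
    "CorrelationMask",
    "SuccessReport",
    "mask_from_correlation",
    "select_cb_population",
    "success",
    "random_control_masks",
    "ideal_linear_mask",
    "success_frame",
]

MASK_THRESHOLD = 0.03


@dataclass
class CorrelationMask:
    """Included grid cells of one conductance pair."""

    pair: tuple[str, str]
    cells: np.ndarray  # (n_levels, n_levels) bool
    source_label: str = ""
    threshold: float | None = None

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=bool)

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())

    @property
    def empty(self) -> bool:
        return self.n_cells == 0


@dataclass
class SuccessReport:
    """Enrichment of one target type by one correlation-based population."""

    target_label: str
    cb_label: str
    cb_size: int
    pct_success_cb: float
    pct_success_original: float
    f_success: float
    n_masks: int = 1


def mask_from_correlation(
    h: ConductanceHistogram2D, threshold: float = MASK_THRESHOLD
) -> CorrelationMask:
    """Cells holding at least ``threshold`` of the population (inclusive)."""
    if h.N == 0:
        raise ValueError("cannot build a mask from an empty histogram")
    cells = h.counts / h.N >= threshold
    return CorrelationMask(
        pair=h.pair, cells=cells, source_label=h.population_label, threshold=threshold
    )


def select_cb_population(
    db: ModelDatabase, masks: list[CorrelationMask], label: str = "cb"
) -> Population:
    """Models of the whole database inside every mask (conjunction).

    Selection ignores activity type by construction.  An empty mask is
    refused; disjoint masks on the same pair may legitimately produce an
    empty population, which is returned as such.
    """
    if not masks:
        raise ValueError("need at least one mask")
    keep = np.ones(len(db), dtype=bool)
    for m in masks:
        if m.empty:
            raise ValueError(f"mask on pair {m.pair} is empty")
        ia = db.grid_levels(m.pair[0])
        ib = db.grid_levels(m.pair[1])
        keep &= m.cells[ia, ib]
    return Population(
        label=label,
        index=np.nonzero(keep)[0],
        scheme={"masks": [{"pair": list(m.pair), "n_cells": m.n_cells} for m in masks]},
    )


def success(db: ModelDatabase, cb: Population, type_pop: Population) -> SuccessReport:
    """%Success of the cb population versus the original database."""
    if cb.size == 0:
        raise ValueError("success undefined for an empty cb population")
    if type_pop.size == 0:
        raise ValueError("target type has no members in the database")
    overlap = len(np.intersect1d(cb.index, type_pop.index, assume_unique=True))
    pct_cb = 100.0 * overlap / cb.size
    pct_orig = 100.0 * type_pop.size / len(db)
    return SuccessReport(
        target_label=type_pop.label,
        cb_label=cb.label,
        cb_size=cb.size,
        pct_success_cb=pct_cb,
        pct_success_original=pct_orig,
        f_success=pct_cb / pct_orig,
    )


def random_control_masks(
    n_masks: int,
    cells_per_mask: int,
    n_levels: int,
    rng: np.random.Generator,
    conductance_names: tuple[str, ...],
) -> list[CorrelationMask]:
    """Uniformly random masks on uniformly random pairs; seed-reproducible.

    Each mask covers ``cells_per_mask`` distinct cells — matched to the cell
    count of the correlation mask it controls for, which is the minimal fair
    control when only the mask's footprint is specified.
    """
    if not 1 <= cells_per_mask <= n_levels * n_levels:
        raise ValueError("cells_per_mask out of range")
    pairs = list(itertools.combinations(conductance_names, 2))
    masks = []
    for _ in range(n_masks):
        pair = pairs[rng.integers(len(pairs))]
        flat = rng.choice(n_levels * n_levels, size=cells_per_mask, replace=False)
        cells = np.zeros(n_levels * n_levels, dtype=bool)
        cells[flat] = True
        masks.append(
            CorrelationMask(
                pair=pair, cells=cells.reshape(n_levels, n_levels), source_label="random"
            )
        )
    return masks


def ideal_linear_mask(
    pair: tuple[str, str], n_levels: int, width: int = 1, sign: str = "+"
) -> CorrelationMask:
    """Diagonal band of the given width and slope sign."""
    if n_levels < 2:
        raise ValueError("need at least two grid levels")
    if width < 1:
        raise ValueError("band width must be >= 1")
    i, j = np.indices((n_levels, n_levels))
    if sign == "+":
        cells = np.abs(i - j) < width
    elif sign == "-":
        cells = np.abs(i + j - (n_levels - 1)) < width
    else:
        raise ValueError("sign must be '+' or '-'")
    return CorrelationMask(pair=pair, cells=cells, source_label=f"ideal{sign}w{width}")


def success_frame(reports: list[SuccessReport]) -> pd.DataFrame:
    """Tidy table of success reports (Table S3 shape)."""
    return pd.DataFrame(
        {
            "target": [r.target_label for r in reports],
            "cb_population": [r.cb_label for r in reports],
            "n_masks": [r.n_masks for r in reports],
            "cb_size": [r.cb_size for r in reports],
            "pct_success_cb": [r.pct_success_cb for r in reports],
            "pct_success_original": [r.pct_success_original for r in reports],
            "f_success": [r.f_success for r in reports],
        }
    )
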