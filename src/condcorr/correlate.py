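"""Pairwise conductance dependence screening within activity populations.

For every pair of the eight conductances, the models of a population are
binned on the simulation grid into a 2-D histogram.  Two non-parametric
statistics with fixed cutoffs define a correlation:

* the raw chi-squared independence statistic, ``sum (O-E)^2 / E`` with
  ``E = row * col / N``, must exceed 500 — deliberately unscaled, so larger
  populations reach the cutoff more easily on this sparsely sampled grid;
* the Spearman rank correlation (midranks for the pervasive grid ties) must
  satisfy ``|rho| > 0.2`` to confirm a linear trend.

Both cutoffs are strict inequalities.  The independence matrix (outer product
of the normalized 1-D marginals) and the difference matrix (observed minus
expected, in percent of the population) support the visual check for
edge-effect false positives; an automatic edge-concentration heuristic flags
suspect results for review instead of silently excluding them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .database import ModelDatabase, Population

__all__ = [
    "ConductanceHistogram2D",
    "CorrelationResult",
    "histogram2d",
    "chi2_independence",
    "spearman",
    "independence_and_difference",
    "edge_concentration",
    "scan",
    "results_frame",
    "sign_matrix",
]

CHI2_CUTOFF = 500.0
RHO_CUTOFF = 0.2


@dataclass
class ConductanceHistogram2D:
    """Grid-level counts of one conductance pair in one population."""

    pair: tuple[str, str]
    counts: np.ndarray  # (n_levels, n_levels) int
    population_label: str = ""
    N: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.N == 0:
            self.N = int(self.counts.sum())
        if self.counts.sum() != self.N or np.any(self.counts < 0):
            raise ValueError("counts must be non-negative and sum to N")


@dataclass
class CorrelationResult:
    """Statistics and pass/fail flags for one pair in one population."""

    pair: tuple[str, str]
    chi2: float
    rho: float
    passes_chi2: bool
    passes_rho: bool
    is_correlation: bool
    slope_sign: str  # "+", "-" or ""
    flagged_visual: bool
    N: int
    population_label: str = ""


def histogram2d(
    db: ModelDatabase, pop: Population, pair: tuple[str, str], n_levels: int | None = None
) -> ConductanceHistogram2D:
    """Counts by grid level; the other six conductances are marginalized."""
    a, b = pair
    if a == b:
        raise ValueError("pair members must be distinct")
    names = db.conductance_names
    for name in pair:
        if name not in names:
            raise KeyError(f"unknown conductance {name!r}")
    L = n_levels or db.n_levels
    ia = db.grid_levels(a)[pop.index]
    ib = db.grid_levels(b)[pop.index]
    counts = np.bincount(ia * L + ib, minlength=L * L).reshape(L, L)
    return ConductanceHistogram2D(pair=(a, b), counts=counts, population_label=pop.label)


def chi2_independence(h: ConductanceHistogram2D) -> float:
    """Raw chi-squared statistic of independence for a 2-D histogram.

    Expected counts come from the row/column marginals; cells in a row or
    column with zero marginal are dropped (their expectation is undefined).
    """
    O = h.counts.astype(float)
    N = O.sum()
    if N == 0:
        raise ValueError("empty histogram: chi-squared undefined")
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    E = np.outer(row, col) / N
    mask = E > 0
    return float(((O[mask] - E[mask]) ** 2 / E[mask]).sum())


def spearman(db: ModelDatabase, pop: Population, pair: tuple[str, str]) -> float:
    """Spearman rank correlation of the pair's conductance values (midrank
    ties).  Returns NaN when either conductance is constant in the
    population — such a pair cannot satisfy the linear-trend criterion."""
    a, b = pair
    x = db.grid_levels(a)[pop.index]
    y = db.grid_levels(b)[pop.index]
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(x, y).statistic
    return float(rho)


def independence_and_difference(h: ConductanceHistogram2D):
    """(independence matrix, difference matrix).

    The independence matrix is the outer product of the two normalized 1-D
    marginals scaled back to model counts; the difference matrix is the
    per-cell deviation of the observed counts from it, in percent of the
    population (``100 * (O - E) / N``), and sums to zero.
    """
    O = h.counts.astype(float)
    N = O.sum()
    if N == 0:
        raise ValueError("empty histogram")
    expected = np.outer(O.sum(axis=1) / N, O.sum(axis=0) / N) * N
    difference = 100.0 * (O - expected) / N
    return expected, difference


def edge_concentration(h: ConductanceHistogram2D) -> float:
    """Fraction of the population sitting at level zero of either axis.

    High values mark the edge-effect pattern behind most visually rejected
    correlations (a conductance that is zero for most models)."""
    O = h.counts.astype(float)
    N = O.sum()
    if N == 0:
        return 0.0
    on_edge = O[0, :].sum() + O[:, 0].sum() - O[0, 0]
    return float(on_edge / N)


def scan(
    db: ModelDatabase,
    pop: Population,
    chi2_cutoff: float = CHI2_CUTOFF,
    rho_cutoff: float = RHO_CUTOFF,
    edge_flag_threshold: float = 0.5,
    low_n_floor: int = 100,
) -> list[CorrelationResult]:
    """All C(8,2)=28 pair results for one population, deterministic order.

    Correlations require ``chi2 > chi2_cutoff`` and ``|rho| > rho_cutoff``
    (strict).  Populations smaller than ``low_n_floor`` are still scanned but
    emit a warning; results concentrated on grid edges are flagged for visual
    review, never dropped.
    """
    if pop.size == 0:
        raise ValueError(f"population {pop.label!r} is empty")
    if pop.size < low_n_floor:
        warnings.warn(
            f"population {pop.label!r} has only {pop.size} models; "
            "statistics may be unreliable",
            stacklevel=2,
        )
    results = []
    for pair in itertools.combinations(db.conductance_names, 2):
        h = histogram2d(db, pop, pair)
        chi2 = chi2_independence(h)
        rho = spearman(db, pop, pair)
        passes_chi2 = chi2 > chi2_cutoff
        passes_rho = bool(np.isfinite(rho) and abs(rho) > rho_cutoff)
        is_corr = passes_chi2 and passes_rho
        sign = ""
        if is_corr:
            sign = "+" if rho > 0 else "-"
        flagged = is_corr and edge_concentration(h) > edge_flag_threshold
        results.append(
            CorrelationResult(
                pair=pair,
                chi2=chi2,
                rho=rho,
                passes_chi2=passes_chi2,
                passes_rho=passes_rho,
                is_correlation=is_corr,
                slope_sign=sign,
                flagged_visual=flagged,
                N=pop.size,
                population_label=pop.label,
            )
        )
    return results


def results_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy table of scan results (one row per population x pair)."""
    return pd.DataFrame(
        {
            "population": [r.population_label for r in results],
            "pair": ["/".join(r.pair) for r in results],
            "N": [r.N for r in results],
            "chi2": [r.chi2 for r in results],
            "rho": [r.rho for r in results],
            "is_correlation": [r.is_correlation for r in results],
            "slope_sign": [r.slope_sign for r in results],
            "flagged_visual": [r.flagged_visual for r in results],
        }
    )


def sign_matrix(results_by_population: dict[str, list[CorrelationResult]]) -> pd.DataFrame:
    """Population x pair matrix of correlation signs ("+", "-", "")."""
    pairs = sorted({"/".join(r.pair) for rs in results_by_population.values() for r in rs})
    table = pd.DataFrame("", index=list(results_by_population), columns=pairs)
    for label, rs in results_by_population.items():
        for r in rs:
            if r.is_correlation:
                table.loc[label, "/".join(r.pair)] = r.slope_sign
    return table
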