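"""Chi-squared / Spearman screening against brute-force oracles."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import condcorr as cc
from condcorr.correlate import (
    ConductanceHistogram2D,
    chi2_independence,
    edge_concentration,
    histogram2d,
    independence_and_difference,
    scan,
    sign_matrix,
    spearman,
)
from condcorr.database import CONDUCTANCES, Population
from condcorr.synth import PlantedDatabaseSpec, make_planted_db


def chi2_oracle(counts):
    """Direct double-loop evaluation of sum (O-E)^2/E from marginals."""
    O = np.asarray(counts, float)
    n = O.sum()
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    total = 0.0
    for i in range(O.shape[0]):
        for j in range(O.shape[1]):
            e = row[i] * col[j] / n
            if e > 0:
                total += (O[i, j] - e) ** 2 / e
    return total


def spearman_oracle(x, y):
    """Midrank-and-Pearson evaluation independent of scipy."""

    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def _pop_db(levels_a, levels_b, n_levels=6):
    """Tiny database whose CaS/KCa levels are given explicitly."""
    import pandas as pd

    n = len(levels_a)
    df = pd.DataFrame({"activity_class": ["periodic_bursting"] * n})
    for name in CONDUCTANCES:
        df[f"grid_{name}"] = 0
        df[f"g_{name}"] = 0.0
    df["grid_CaS"] = list(levels_a)
    df["grid_KCa"] = list(levels_b)
    db = cc.ModelDatabase(
        df, meta={"grid": {"names": list(CONDUCTANCES), "n_levels": n_levels}}
    )
    return db, Population("toy", np.arange(n))


class TestHistogram:
    def test_unit_cells_for_known_grid_points(self):
        db, pop = _pop_db([0, 1, 2, 5], [3, 3, 0, 5])
        h = histogram2d(db, pop, ("CaS", "KCa"))
        assert h.N == 4 and h.counts.sum() == 4
        for (i, j) in [(0, 3), (1, 3), (2, 0), (5, 5)]:
            assert h.counts[i, j] == 1

    def test_swapped_pair_transposes_counts(self):
        rng = np.random.default_rng(1)
        db, pop = _pop_db(rng.integers(0, 6, 50), rng.integers(0, 6, 50))
        a = histogram2d(db, pop, ("CaS", "KCa")).counts
        b = histogram2d(db, pop, ("KCa", "CaS")).counts
        assert np.array_equal(a, b.T)

    def test_counts_match_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        la, lb = rng.integers(0, 6, 200), rng.integers(0, 6, 200)
        db, pop = _pop_db(la, lb)
        h = histogram2d(db, pop, ("CaS", "KCa"))
        brute = np.zeros((6, 6), int)
        for i, j in zip(la, lb):
            brute[i, j] += 1
        assert np.array_equal(h.counts, brute)

    def test_unknown_conductance_rejected(self):
        db, pop = _pop_db([0], [0])
        with pytest.raises(KeyError):
            histogram2d(db, pop, ("CaS", "gXYZ"))


class TestChi2:
    def test_uniform_counts_give_zero(self):
        h = ConductanceHistogram2D(("CaS", "KCa"), np.full((6, 6), 3))
        assert chi2_independence(h) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_diagonal_matches_oracle(self):
        counts = np.diag([10] * 6)
        h = ConductanceHistogram2D(("CaS", "KCa"), counts)
        assert chi2_independence(h) == pytest.approx(chi2_oracle(counts), rel=1e-12)
        assert chi2_independence(h) == pytest.approx(60 * 5.0)  # N*(k-1) for diagonal

    def test_1000_random_histograms_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            counts = rng.integers(0, 20, size=(6, 6))
            if counts.sum() == 0:
                continue
            h = ConductanceHistogram2D(("CaS", "KCa"), counts)
            assert chi2_independence(h) == pytest.approx(
                chi2_oracle(counts), rel=1e-12, abs=1e-12
            )

    def test_matches_scipy_on_nondegenerate_tables(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(4)
        counts = rng.integers(1, 30, size=(6, 6))
        h = ConductanceHistogram2D(("CaS", "KCa"), counts)
        ref = chi2_contingency(counts, correction=False).statistic
        assert chi2_independence(h) == pytest.approx(ref, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_permutation_transpose_invariance_and_scaling(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 15, size=(6, 6))
        if counts.sum() == 0:
            return
        h = lambda c: ConductanceHistogram2D(("CaS", "KCa"), c)
        base = chi2_independence(h(counts))
        perm = rng.permutation(6)
        assert chi2_independence(h(counts[perm][:, perm])) == pytest.approx(base, rel=1e-9)
        assert chi2_independence(h(counts.T)) == pytest.approx(base, rel=1e-9)
        # raw statistic scales linearly with counts (deliberate N-dependence)
        assert chi2_independence(h(counts * 7)) == pytest.approx(7 * base, rel=1e-9)

    def test_empty_histogram_is_an_error(self):
        h = ConductanceHistogram2D(("CaS", "KCa"), np.zeros((6, 6), int))
        with pytest.raises(ValueError):
            chi2_independence(h)


class TestSpearman:
    def test_diagonal_and_antidiagonal(self):
        db, pop = _pop_db([0, 1, 2, 3, 4, 5], [0, 1, 2, 3, 4, 5])
        assert spearman(db, pop, ("CaS", "KCa")) == pytest.approx(1.0)
        db, pop = _pop_db([0, 1, 2, 3, 4, 5], [5, 4, 3, 2, 1, 0])
        assert spearman(db, pop, ("CaS", "KCa")) == pytest.approx(-1.0)

    def test_constant_margin_is_undefined(self):
        db, pop = _pop_db([2, 2, 2, 2], [0, 1, 2, 3])
        assert np.isnan(spearman(db, pop, ("CaS", "KCa")))

    def test_200_model_population_matches_midrank_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            la, lb = rng.integers(0, 6, 200), rng.integers(0, 6, 200)
            db, pop = _pop_db(la, lb)
            rho = spearman(db, pop, ("CaS", "KCa"))
            assert rho == pytest.approx(spearman_oracle(la, lb), abs=1e-12)

    def test_axis_reversal_flips_sign(self):
        rng = np.random.default_rng(6)
        la, lb = rng.integers(0, 6, 300), rng.integers(0, 6, 300)
        db1, pop = _pop_db(la, lb)
        db2, _ = _pop_db(la, 5 - lb)
        assert spearman(db1, pop, ("CaS", "KCa")) == pytest.approx(
            -spearman(db2, pop, ("CaS", "KCa")), abs=1e-12
        )


class TestIndependenceMatrix:
    def test_product_form_gives_zero_difference(self):
        a = np.array([1, 2, 3, 4, 5, 6])
        b = np.array([6, 1, 2, 2, 1, 6])
        counts = np.outer(a, b)
        h = ConductanceHistogram2D(("CaS", "KCa"), counts)
        assert chi2_independence(h) == pytest.approx(0.0, abs=1e-9)
        expected, diff = independence_and_difference(h)
        assert np.allclose(diff, 0.0, atol=1e-10)
        assert expected.sum() == pytest.approx(h.N)

    def test_diagonal_difference_signs_and_zero_sum(self):
        h = ConductanceHistogram2D(("CaS", "KCa"), np.diag([10] * 6))
        expected, diff = independence_and_difference(h)
        assert np.all(np.diag(diff) > 0)
        off = diff[~np.eye(6, dtype=bool)]
        assert np.all(off <= 0)
        assert diff.sum() == pytest.approx(0.0, abs=1e-9)


class TestScan:
    def test_all_28_pairs_in_deterministic_order(self, planted_db, burster_pop):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res1 = scan(planted_db, burster_pop)
            res2 = scan(planted_db, burster_pop)
        assert len(res1) == 28
        assert [r.pair for r in res1] == list(itertools.combinations(CONDUCTANCES, 2))
        assert [(r.chi2, r.rho) for r in res1] == [(r.chi2, r.rho) for r in res2]

    def test_only_planted_pair_flagged(self, planted_db, burster_pop):
        res = scan(planted_db, burster_pop)
        flagged = [r for r in res if r.is_correlation]
        assert [r.pair for r in flagged] == [("CaS", "KCa")]
        assert flagged[0].slope_sign == "+"
        assert flagged[0].chi2 > 500 and flagged[0].rho > 0.2

    def test_low_n_population_warns_but_computes(self, planted_db):
        tiny = Population("tiny", np.arange(20))
        with pytest.warns(UserWarning, match="20 models"):
            res = scan(planted_db, tiny)
        assert len(res) == 28

    def test_edge_concentration_heuristic(self):
        counts = np.zeros((6, 6), int)
        counts[0, :] = 20  # everything at level zero of the first conductance
        h = ConductanceHistogram2D(("CaT", "KCa"), counts)
        assert edge_concentration(h) == pytest.approx(1.0)
        spread = ConductanceHistogram2D(("CaT", "KCa"), np.full((6, 6), 2))
        assert edge_concentration(spread) == pytest.approx(11 / 36)

    def test_sign_matrix_shape(self, planted_db, burster_pop):
        res = scan(planted_db, burster_pop)
        table = sign_matrix({"bursters": res})
        assert table.loc["bursters", "CaS/KCa"] == "+"
        assert (table != "").sum().sum() == 1
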