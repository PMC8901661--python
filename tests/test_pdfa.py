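"""Permuted DFA: bookkeeping, classifier, permutation scheme, results."""

import numpy as np
import pandas as pd
import pytest

from vocalence.pdfa import (
    CellMap, PdfaDesign, balanced_selection, build_cells, dfa_classify,
    run_pdfa, _permute_within_pigs,
)

FEATS = ("Dur", "AmpModRate", "Q50", "WienEntropy")


def _table(rows):
    return pd.DataFrame(rows)


def _grid_table(n_pigs=2, n_valence=2, calls_per_cell=3, rng=None, sep=0.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    for p in range(n_pigs):
        for v in range(n_valence):
            for _ in range(calls_per_cell):
                mu = sep * v
                rows.append({
                    "pig_id": f"p{p}",
                    "valence": ["negative", "positive", "neutral"][v],
                    **{f: rng.normal(mu) for f in FEATS},
                })
    return _table(rows)


def _null_table(rng, n_pigs=10, calls_pp=12):
    rows = []
    for p in range(n_pigs):
        for _ in range(calls_pp):
            rows.append({"pig_id": f"p{p}",
                         "valence": rng.choice(["negative", "positive"]),
                         **{f: rng.normal() for f in FEATS}})
    return _table(rows)


class TestBuildCells:
    def test_grid_cells(self):
        cm = build_cells(_grid_table(), PdfaDesign())
        assert len(cm.cells) == 4
        assert all(idx.size == 3 for idx in cm.cells.values())
        assert cm.crossed_pigs == {0, 1}

    def test_single_valence_pig_not_crossed(self):
        df = _grid_table()
        df.loc[df.pig_id == "p1", "valence"] = "negative"
        cm = build_cells(df, PdfaDesign())
        assert 1 not in cm.crossed_pigs
        assert (1, 0) in cm.cells and (1, 1) not in cm.cells

    def test_incomplete_rows_dropped_and_counted(self):
        df = _grid_table(n_pigs=4)
        df.loc[:4, "AmpModRate"] = np.nan
        cm = build_cells(df, PdfaDesign())
        assert cm.n_dropped == 5
        assert sum(i.size for i in cm.cells.values()) == len(df) - 5

    def test_single_level_errors(self):
        df = _grid_table(n_valence=1)
        with pytest.raises(ValueError, match="2 test-factor levels"):
            build_cells(df, PdfaDesign())


class TestBalancedSelection:
    def test_sizes(self):
        cm = build_cells(_grid_table(), PdfaDesign())
        deriv, hold = balanced_selection(cm.cells, PdfaDesign(min_calls_per_cell=2),
                                         np.random.default_rng(0))
        assert deriv.size == 8
        assert hold.size == 12 - 8
        assert np.intersect1d(deriv, hold).size == 0

    def test_cell_at_minimum_fully_selected(self):
        cm = build_cells(_grid_table(calls_per_cell=2), PdfaDesign())
        deriv, hold = balanced_selection(cm.cells, PdfaDesign(min_calls_per_cell=2),
                                         np.random.default_rng(0))
        assert deriv.size == 8 and hold.size == 0

    def test_redraws_differ_but_sizes_match(self):
        cm = build_cells(_grid_table(calls_per_cell=6), PdfaDesign())
        d1, _ = balanced_selection(cm.cells, PdfaDesign(), np.random.default_rng(1))
        d2, _ = balanced_selection(cm.cells, PdfaDesign(), np.random.default_rng(2))
        assert d1.size == d2.size
        assert not np.array_equal(d1, d2)

    def test_missing_level_errors(self):
        cm = build_cells(_grid_table(calls_per_cell=2), PdfaDesign())
        cells = {k: v for k, v in cm.cells.items() if not (k[1] == 1 and k[0] == 0)}
        with pytest.raises(ValueError, match="eligible"):
            balanced_selection(cells, PdfaDesign(min_calls_per_cell=3),
                               np.random.default_rng(0))


class TestDfaClassify:
    def test_separated_classes_near_perfect(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        y = np.repeat([0, 1], 20)
        X[y == 1, 0] += 10.0
        Xh = rng.normal(size=(30, 2))
        yh = np.repeat([0, 1], 15)
        Xh[yh == 1, 0] += 10.0
        pd_, ph_ = dfa_classify(X, y, Xh, yh)
        assert pd_ == 100.0 and ph_ == 100.0

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for i in range(20):
            X = rng.normal(size=(60, 3))
            y = rng.integers(0, 2, 60)
            Xh = rng.normal(size=(200, 3))
            yh = rng.integers(0, 2, 200)
            accs.append(dfa_classify(X, y, Xh, yh)[1])
        assert abs(np.mean(accs) - 50.0) < 5.0

    def test_three_class_brute_force_oracle(self):
        # six hand points; oracle = nearest class mean in whitened space
        X = np.array([[0.0, 0], [0.2, 0.1], [3.0, 0], [3.1, 0.2],
                      [0.0, 4.0], [0.3, 4.1]])
        y = np.array([0, 0, 1, 1, 2, 2])
        Xh = np.array([[0.1, 0.0], [2.9, 0.1], [0.1, 3.9], [1.5, 2.0]])
        means = np.stack([X[y == c].mean(0) for c in (0, 1, 2)])
        pooled = sum((X[y == c] - means[c]).T @ (X[y == c] - means[c])
                     for c in (0, 1, 2)) / (6 - 3)
        inv = np.linalg.inv(pooled + 1e-6 * np.trace(pooled) / 2 * np.eye(2))
        d2 = np.array([[(r - m) @ inv @ (r - m) for m in means] for r in Xh])
        expected = d2.argmin(axis=1)
        yh = expected  # assert agreement with the oracle's own assignment
        _, ph_ = dfa_classify(X, y, Xh, yh, ridge_rel=1e-6)
        assert ph_ == 100.0

    def test_singular_covariance_ridged_with_warning(self):
        X = np.zeros((10, 2))
        X[5:, 0] = 1.0
        y = np.repeat([0, 1], 5)
        with pytest.warns(UserWarning, match="singular"):
            dfa_classify(X, y, X, y)

    def test_too_small_derivation_errors(self):
        with pytest.raises(ValueError):
            dfa_classify(np.zeros((4, 4)), np.array([0, 0, 1, 1]), np.zeros((1, 4)), [0])


class TestPermutationScheme:
    def test_labels_stay_within_pigs(self):
        rng = np.random.default_rng(0)
        cm = build_cells(_null_table(rng), PdfaDesign())
        perm = _permute_within_pigs(cm, rng)
        for p in set(cm.pigs):
            idx = cm.pigs == p
            assert sorted(perm[idx]) == sorted(cm.labels[idx])

    def test_single_level_pig_untouched(self):
        df = _grid_table(n_pigs=3)
        df.loc[df.pig_id == "p2", "valence"] = "negative"
        cm = build_cells(df, PdfaDesign())
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = _permute_within_pigs(cm, rng)
            idx = cm.pigs == 2
            assert np.array_equal(perm[idx], cm.labels[idx])


class TestRunPdfa:
    def test_deterministic_given_seed(self):
        tab = _null_table(np.random.default_rng(3))
        d = PdfaDesign(n_permutations=100, n_selection_reps=3, rng_seed=7)
        r1, r2 = run_pdfa(tab, d), run_pdfa(tab, d)
        assert r1 == r2

    def test_relative_cross_consistency(self):
        tab = _null_table(np.random.default_rng(4))
        r = run_pdfa(tab, PdfaDesign(n_permutations=100, n_selection_reps=3, rng_seed=1))
        assert r.relative_cross == pytest.approx(
            r.pct_cross_classified / r.chance_cross_classified)
        assert 0 < r.p_cross <= 1 and 0 < r.p_classified <= 1
        assert 0 <= r.pct_classified <= 100

    def test_chance_near_100_over_k_for_three_levels(self):
        rng = np.random.default_rng(5)
        rows = []
        for p in range(9):
            for v in ("negative", "positive", "neutral"):
                for _ in range(6):
                    rows.append({"pig_id": f"p{p}", "valence": v,
                                 **{f: rng.normal() for f in FEATS}})
        r = run_pdfa(_table(rows), PdfaDesign(n_permutations=150,
                                              n_selection_reps=3, rng_seed=0))
        assert r.n_levels == 3
        assert r.chance_cross_classified == pytest.approx(100 / 3, abs=3.0)

    def test_monotone_in_separation(self):
        def sep_table(sep, seed):
            rng = np.random.default_rng(seed)
            rows = []
            for p in range(8):
                off = rng.normal(0, 0.3, len(FEATS))
                for v in (0, 1):
                    for _ in range(8):
                        rows.append({"pig_id": f"p{p}",
                                     "valence": "positive" if v else "negative",
                                     **{f: rng.normal(sep * v + off[i])
                                        for i, f in enumerate(FEATS)}})
            return _table(rows)

        d = PdfaDesign(n_permutations=100, n_selection_reps=10, rng_seed=0)
        weak = run_pdfa(sep_table(0.0, 1), d)
        strong = run_pdfa(sep_table(3.0, 1), d)
        assert strong.pct_cross_classified > weak.pct_cross_classified

    def test_n_permutations_floor_enforced(self):
        with pytest.raises(ValueError, match="n_permutations"):
            PdfaDesign(n_permutations=50).validate()
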