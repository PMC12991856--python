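"""Structural summaries, deadwood typology and coverage-based richness."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from forest_csb.biodiversity import (
    IncidenceMatrix,
    deadwood_type_richness,
    diameter_class,
    expected_richness_at_coverage,
    incidence_from_long,
    incidence_to_long,
    sample_coverage,
    standardize_richness,
    structural_summaries,
    _interpolated_richness,
)
from forest_csb.harmonize import DeadwoodPiece, TreeRecord
from .conftest import random_piece
from .oracles import oracle_deadwood_type_richness, oracle_richness_at_coverage


def im(matrix: dict, taxon="beetles", site="S1") -> IncidenceMatrix:
    return IncidenceMatrix(taxon, site, pd.DataFrame(matrix).T)


class TestDiameterClass:
    @pytest.mark.parametrize(
        "d,cls", [(15, 1), (20, 1), (24.9, 1), (25, 2), (34.9, 2), (35, 3),
                  (49.9, 3), (50, 4), (60, 4), (200, 4)]
    )
    def test_lower_inclusive_bins(self, d, cls):
        assert diameter_class(d) == cls

    def test_below_threshold_raises(self):
        with pytest.raises(ValueError):
            diameter_class(14.9)


class TestDeadwoodTypeRichness:
    def test_no_pieces(self):
        assert deadwood_type_richness([]) == 0

    def test_explicit_enumeration(self):
        pieces = [
            DeadwoodPiece("P", "log", 20, 18, 4, 2, "coniferous"),
            DeadwoodPiece("P", "log", 20, 16, 5, 2, "coniferous"),
            DeadwoodPiece("P", "snag", 30, None, 8, 1, "coniferous"),
        ]
        assert deadwood_type_richness(pieces) == 2

    def test_full_combination_space_is_60(self):
        diam = {1: 20, 2: 30, 3: 40, 4: 60}
        pieces = [
            DeadwoodPiece("P", pos, diam[c], None, 3, s, "broadleaved")
            for c in range(1, 5)
            for pos in ("log", "snag", "stump")
            for s in range(1, 6)
        ]
        assert deadwood_type_richness(pieces) == 60

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            pieces = [random_piece(rng) for _ in range(rng.integers(0, 40))]
            assert deadwood_type_richness(pieces) == oracle_deadwood_type_richness(pieces)


class TestStructuralSummaries:
    def test_mean_and_richness(self):
        trees = [TreeRecord("P", s, d, 20.0) for s, d in
                 [("a", 20.0), ("a", 30.0), ("b", 40.0)]]
        richness, mean_dbh = structural_summaries(trees)
        assert richness == 2
        assert mean_dbh == pytest.approx(30.0)

    def test_single_species_richness(self):
        trees = [TreeRecord("P", "a", d, 20.0) for d in (15.0, 20.0, 30.0)]
        assert structural_summaries(trees)[0] == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            structural_summaries([])

    def test_oracle_recomputation(self, rng):
        from .conftest import random_tree

        trees = [random_tree(rng) for _ in range(100)]
        richness, mean_dbh = structural_summaries(trees)
        assert richness == len({t.species for t in trees})
        assert mean_dbh == pytest.approx(sum(t.dbh for t in trees) / 100)


class TestSampleCoverage:
    def test_no_uniques_means_full_coverage(self):
        m = im({"a": [1, 1, 0], "b": [0, 1, 1]})
        assert sample_coverage(m) == 1.0

    def test_worked_example(self):
        # T=4 units, incidence frequencies {3,2,1,1}: U=7, Q1=2, Q2=1
        m = im({"a": [1, 1, 1, 0], "b": [1, 1, 0, 0],
                "c": [1, 0, 0, 0], "d": [0, 1, 0, 0]})
        assert sample_coverage(m) == pytest.approx(1 - (2 / 7) * (6 / 8), abs=1e-9)

    def test_no_detections_raises(self):
        with pytest.raises(ValueError):
            sample_coverage(im({"a": [0, 0]}))

    def test_unit_permutation_and_species_relabel_invariance(self, rng):
        mat = (rng.random((8, 6)) < 0.4).astype(int)
        mat[0, 0] = 1  # ensure detections
        a = IncidenceMatrix("t", "s", pd.DataFrame(mat))
        perm = rng.permutation(6)
        b = IncidenceMatrix("t", "s", pd.DataFrame(mat[:, perm]))
        c = IncidenceMatrix("t", "s", pd.DataFrame(mat[rng.permutation(8), :]))
        assert sample_coverage(a) == pytest.approx(sample_coverage(b))
        assert sample_coverage(a) == pytest.approx(sample_coverage(c))
        t95 = expected_richness_at_coverage
        assert t95(a) == pytest.approx(t95(b), abs=1e-10)
        assert t95(a) == pytest.approx(t95(c), abs=1e-10)

    def test_duplicating_a_unit_increases_coverage_on_average(self, rng):
        # Per-matrix monotonicity does NOT hold for the Good-Turing-corrected
        # estimator (duplicating a unit that holds doubletons shrinks Q2 and
        # can lower the estimate), but added effort must raise estimated
        # coverage in aggregate, and the estimate stays in [0, 1].
        changes = []
        for _ in range(1000):
            S, T = rng.integers(2, 10), rng.integers(2, 8)
            mat = (rng.random((S, T)) < rng.uniform(0.2, 0.8)).astype(int)
            if mat.sum() == 0:
                continue
            before = sample_coverage(IncidenceMatrix("t", "s", pd.DataFrame(mat)))
            dup = np.hstack([mat, mat[:, [rng.integers(T)]]])
            after = sample_coverage(IncidenceMatrix("t", "s", pd.DataFrame(dup)))
            assert 0.0 <= after <= 1.0
            changes.append(after - before)
        assert np.mean(changes) > 0


class TestExpectedRichness:
    def test_fixed_point_at_reference_coverage(self):
        m = im({"a": [1, 1, 1, 0], "b": [1, 1, 0, 0],
                "c": [1, 0, 0, 0], "d": [0, 1, 0, 0]})
        assert expected_richness_at_coverage(m, sample_coverage(m)) == 4.0

    def test_single_species_is_one_at_any_target(self):
        m = im({"a": [1, 1, 1, 1, 1]})
        for target in (0.3, 0.5, 0.9, 0.99):
            assert expected_richness_at_coverage(m, target) == pytest.approx(1.0)

    def test_interpolation_matches_subset_enumeration(self, rng):
        mat = (rng.random((6, 8)) < 0.4).astype(int)
        mat[0, 0] = 1
        mat = mat[mat.sum(axis=1) > 0]
        T = 8
        y = mat.sum(axis=1).astype(float)
        for t in (1, 3, 5, 7):
            brute = np.mean(
                [(mat[:, list(c)].sum(axis=1) > 0).sum()
                 for c in combinations(range(T), t)]
            )
            assert _interpolated_richness(T, y, t) == pytest.approx(brute, abs=1e-10)

    def test_agrees_with_independent_oracle(self, rng):
        for _ in range(50):
            S, T = rng.integers(3, 15), rng.integers(3, 12)
            mat = (rng.random((S, T)) < rng.uniform(0.15, 0.7)).astype(int)
            if mat.sum() == 0:
                continue
            m = IncidenceMatrix("t", "s", pd.DataFrame(mat))
            y = [int(v) for v in m.frequencies()]
            for target in (0.6, 0.9, 0.95, 0.99):
                ours = expected_richness_at_coverage(m, target)
                ref = oracle_richness_at_coverage(y, T, target)
                assert ours == pytest.approx(ref, abs=1e-8)

    def test_monotone_in_target(self, rng):
        mat = (rng.random((12, 9)) < 0.35).astype(int)
        mat[0, 0] = 1
        m = IncidenceMatrix("t", "s", pd.DataFrame(mat))
        targets = np.linspace(0.3, 0.995, 30)
        values = [expected_richness_at_coverage(m, t) for t in targets]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_invalid_target_raises(self):
        m = im({"a": [1, 0]})
        with pytest.raises(ValueError):
            expected_richness_at_coverage(m, 1.0)


class TestStandardizeRichness:
    def test_ratio_examples(self):
        recs = standardize_richness(
            {"P1": 5, "P2": 0}, {"S1": 20.0}, {"P1": "S1", "P2": "S1"}, "birds"
        )
        assert recs[0].ratio == pytest.approx(0.25)
        assert recs[1].ratio == 0.0

    def test_plots_share_site_denominator(self):
        recs = standardize_richness(
            {"P1": 4, "P2": 8}, {"S1": 16.0}, {"P1": "S1", "P2": "S1"}, "x"
        )
        assert recs[0].expected_site == recs[1].expected_site == 16.0

    def test_scale_free(self):
        a = standardize_richness({"P1": 5}, {"S1": 20.0}, {"P1": "S1"}, "x")[0]
        b = standardize_richness({"P1": 10}, {"S1": 40.0}, {"P1": "S1"}, "x")[0]
        assert a.ratio == pytest.approx(b.ratio)

    def test_missing_site_expectation_raises(self):
        with pytest.raises(KeyError):
            standardize_richness({"P1": 5}, {}, {"P1": "S1"}, "x")


class TestIncidenceIO:
    def test_long_format_round_trip(self, rng):
        mat = (rng.random((5, 4)) < 0.5).astype(int)
        mat[0, 0] = 1
        m = IncidenceMatrix(
            "fungi", "S1",
            pd.DataFrame(mat, index=[f"f{i}" for i in range(5)],
                         columns=[f"u{j}" for j in range(4)]),
            unit_plots={f"u{j}": f"P{j}" for j in range(4)},
        )
        back = incidence_from_long(incidence_to_long([m]))
        assert len(back) == 1
        detected = m.matrix.loc[m.matrix.sum(axis=1) > 0]
        pd.testing.assert_frame_equal(
            back[0].matrix.sort_index(), detected.sort_index(), check_dtype=False
        )

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            IncidenceMatrix("t", "s", pd.DataFrame({"a": [2, 0]}).T)
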