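"""GA variable tallies, loadings-difference discovery, [M+H]+ annotation."""

from pathlib import Path

import numpy as np
import pytest

from fibropsi.interpret import (
    CompoundEntry,
    annotate_mz,
    annotation_to_dataframe,
    load_compound_table,
    loadings_difference,
    tally_ga_variables,
)
from fibropsi.io import SpectralMatrix
from fibropsi.reduce import ReductionResult, pca_fit

DATA = Path(__file__).resolve().parents[1] / "data"


def _ga_run(mz_set):
    return ReductionResult(method="GA", selected_mz=sorted(mz_set))


class TestTally:
    def test_doubled_variables_retained(self):
        tally = tally_ga_variables([_ga_run({1, 2}), _ga_run({2, 3}), _ga_run({2, 4})])
        assert tally.retained == [2]
        assert tally.counts == {1: 1, 2: 3, 3: 1, 4: 1}

    def test_single_run_retains_nothing(self):
        tally = tally_ga_variables([_ga_run({5, 9})])
        assert tally.retained == []

    def test_three_identical_runs_retain_the_set(self):
        tally = tally_ga_variables([_ga_run({7, 8})] * 3)
        assert tally.retained == [7, 8]

    def test_retained_monotone_in_threshold(self):
        runs = [_ga_run({1, 2}), _ga_run({2, 3}), _ga_run({1, 2, 4})]
        previous = None
        for th in (1, 2, 3, 4):
            retained = set(tally_ga_variables(runs, threshold=th).retained)
            if previous is not None:
                assert retained <= previous
            previous = retained

    def test_rejects_non_ga_runs(self):
        with pytest.raises(ValueError, match="GA"):
            tally_ga_variables([ReductionResult(method="SPA", selected_mz=[1])])


def _toy_matrix(case_elevated, n=20, p=15, amount=10.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(50.0, 1.0, size=(n, p))
    labels = np.asarray(["CG"] * (n // 2) + ["FG"] * (n // 2), dtype=object)
    for mz in case_elevated:
        X[n // 2:, mz] += amount
    return SpectralMatrix(
        X=X, mz_axis=np.arange(p),
        sample_ids=[f"s{i}" for i in range(n)], labels=labels,
    )


class TestLoadingsDifference:
    def test_identical_class_means_select_nothing(self):
        matrix = _toy_matrix([], amount=0.0)
        matrix.X[10:] = matrix.X[:10]  # exact mirror of the control rows
        report = loadings_difference(matrix, pca_fit(matrix.X, 2))
        assert report.selected_mz == []

    def test_single_case_elevated_variable_found(self):
        matrix = _toy_matrix([7], amount=15.0)
        report = loadings_difference(matrix, pca_fit(matrix.X, 2))
        assert report.selected_mz == [7]
        assert report.difference[7] < 0

    def test_selected_peaks_are_negative_in_difference(self, preprocessed_small):
        pca = pca_fit(preprocessed_small.X, 5)
        report = loadings_difference(preprocessed_small, pca, depth_frac=0.2)
        for v in report.selected_mz:
            i = int(np.where(report.mz_axis == v)[0][0])
            assert report.difference[i] < 0

    def test_recovers_planted_case_peaks(self, preprocessed_small, small_cohort):
        _, _, truth = small_cohort
        pca = pca_fit(preprocessed_small.X, 5)
        report = loadings_difference(preprocessed_small, pca, depth_frac=0.2)
        assert set(report.selected_mz) == truth.planted_case_mz

    def test_class_swap_selects_mirror_peaks(self):
        matrix = _toy_matrix([7], amount=15.0)
        pca = pca_fit(matrix.X, 2)
        base = loadings_difference(matrix, pca)
        swapped = _toy_matrix([7], amount=15.0)
        swapped.labels = np.where(swapped.labels == "CG", "FG", "CG").astype(object)
        mirrored = loadings_difference(swapped, pca)
        np.testing.assert_allclose(mirrored.difference, -base.difference)
        assert 7 not in mirrored.selected_mz  # now control-elevated


class TestAnnotate:
    def test_empty_table_yields_no_hits(self):
        assert annotate_mz([579], []) == []

    def test_hit_within_tolerance(self):
        entry = CompoundEntry("near", 577.950)
        (hit,) = annotate_mz([579.0], [entry], tolerance=0.1)
        assert hit.mass_error == pytest.approx(579.0 - 578.95728, abs=1e-9)

    def test_miss_outside_tolerance(self):
        entry = CompoundEntry("far", 578.900)
        assert annotate_mz([579.0], [entry], tolerance=0.1) == []

    def test_hits_sorted_by_absolute_error_and_monotone_in_tolerance(self):
        table = [
            CompoundEntry("a", 579.0 - 1.00728 + 0.08),
            CompoundEntry("b", 579.0 - 1.00728 - 0.02),
            CompoundEntry("c", 579.0 - 1.00728 + 0.3),
        ]
        tight = annotate_mz([579.0], table, tolerance=0.05)
        loose = annotate_mz([579.0], table, tolerance=0.1)
        assert [h.name for h in tight] == ["b"]
        assert [h.name for h in loose] == ["b", "a"]
        assert {h.name for h in tight} <= {h.name for h in loose}

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError, match="positive"):
            CompoundEntry("bad", 0.0)


def test_synthetic_compound_table_annotates_planted_mz():
    table = load_compound_table(DATA / "compounds" / "synthetic_compound_table.csv")
    hits = annotate_mz([301, 579], table, tolerance=0.1)
    assert {h.query_mz for h in hits} == {301.0, 579.0}
    df = annotation_to_dataframe(hits)
    assert list(df.columns) == ["mz", "name", "mass_error", "class"]


def test_reference_mz_fixtures_parse():
    import pandas as pd

    doubled = pd.read_csv(DATA / "reference_mz" / "doubled_ga_variables.csv")
    pc1 = pd.read_csv(DATA / "reference_mz" / "pc1_selected_variables.csv")
    assert len(doubled) == 31
    assert pc1["mz"].tolist() == [301, 311, 325, 338, 579]
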