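"""Feature alignment, fold changes, trend classes and differential selection."""

import pytest

from mycoderep.datasets import demo_feature_table, load_demo_fold_matrix
from mycoderep.pipeline import differential_peaks
from mycoderep.spectra_features import (
    ChromatographicFeature,
    FeatureTable,
    FragmentSpectrum,
    NewMetabolite,
    TrendCategory,
    align_features,
    classify_trend,
    fold_change,
    read_mgf,
    select_differential,
    write_mgf,
)
from mycoderep.synthetic_data import (
    ScenarioConfig,
    expected_differential_ids,
    generate_experiment,
    match_table_to_truth,
)


def _feat(mz, rt, area=100.0, group="G1", **kw):
    return ChromatographicFeature(mz=mz, retention_time=rt, area=area, group_id=group, **kw)


class TestMgfIO:
    def test_round_trip_identity(self, tmp_path):
        spectra = [
            FragmentSpectrum("a", 400.25, "positive", 5.5, ((100.0, 3.0), (150.5, 9.0)), "G1"),
            FragmentSpectrum("b", 612.10, "negative", 2.0, ((88.0, 1.0),), "G3"),
        ]
        path = tmp_path / "rt.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 2
        for orig, rec in zip(spectra, back):
            assert rec.precursor_mz == pytest.approx(orig.precursor_mz)
            assert rec.polarity == orig.polarity
            assert rec.retention_time == pytest.approx(orig.retention_time)
            assert rec.peaks == orig.peaks
            assert rec.group_id == orig.group_id

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_three_spectrum_fixture(self, tmp_path):
        expected_mz = [310.5, 471.2, 995.0]
        spectra = [
            FragmentSpectrum(f"s{i}", mz, "positive", 1.0 * i, ((100.0, 1.0),))
            for i, mz in enumerate(expected_mz)
        ]
        path = tmp_path / "three.mgf"
        write_mgf(spectra, path)
        assert [s.precursor_mz for s in read_mgf(path)] == pytest.approx(expected_mz)

    def test_scan_range_enforced(self):
        with pytest.raises(ValueError, match="scan range"):
            FragmentSpectrum("x", 2500.0, "positive", 1.0, ((100.0, 1.0),))


class TestAlignFeatures:
    def test_merge_within_tolerance(self):
        table = align_features(
            {"G1": [_feat(400.10, 5.0)], "G2": [_feat(400.15, 5.1, group="G2")]},
            mz_tol=0.3,
            rt_tol=0.5,
        )
        assert len(table) == 1

    def test_split_outside_tolerance(self):
        table = align_features(
            {"G1": [_feat(400.10, 5.0)], "G2": [_feat(400.15, 5.1, group="G2")]},
            mz_tol=0.01,
            rt_tol=0.5,
        )
        assert len(table) == 2

    def test_never_merges_same_group_twice(self):
        # two co-eluting features from one group must stay distinct rows
        table = align_features({"G1": [_feat(400.1, 5.0), _feat(400.2, 5.05, area=50)]})
        assert len(table) == 2

    def test_recovers_ground_truth_feature_count(self, default_experiment):
        table = align_features(default_experiment.features)
        assert len(table) == len(default_experiment.truth.metabolites)

    def test_permutation_invariant_row_count(self, default_experiment):
        feats = default_experiment.features
        reversed_groups = {g: list(reversed(list(v))) for g, v in feats.items()}
        assert len(align_features(feats)) == len(align_features(reversed_groups))


class TestFoldChange:
    @pytest.fixture()
    def table(self):
        return FeatureTable.from_areas(
            {"p": {"G1": 100.0, "G2": 100.0, "G3": 1047.0, "G4": 0.0, "G5": 500.0}},
            groups=("G1", "G2", "G3", "G4", "G5"),
        )

    def test_ratio(self, table):
        assert fold_change(table, "p", "G3", "G1") == pytest.approx(10.47)

    def test_identity(self, table):
        assert fold_change(table, "p", "G2", "G1") == pytest.approx(1.00)

    def test_new_flag(self, table):
        fc = fold_change(table, "p", "G5", "G4")
        assert isinstance(fc, NewMetabolite) and fc.area == 500.0

    def test_undefined_when_both_below_floor(self, table):
        assert fold_change(table, "p", "G4", "G4") is None

    def test_unknown_group_raises(self, table):
        with pytest.raises(KeyError):
            fold_change(table, "p", "G9", "G1")

    def test_reciprocity(self, table):
        ab = fold_change(table, "p", "G3", "G5")
        ba = fold_change(table, "p", "G5", "G3")
        assert ab * ba == pytest.approx(1.0, abs=0.02)


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "fold,category",
        [
            (0.0, TrendCategory.DECREASED_5X_OR_MORE),
            (0.14, TrendCategory.DECREASED_5X_OR_MORE),
            (0.2, TrendCategory.DECREASED_5X_OR_MORE),  # inclusive boundary
            (0.21, TrendCategory.DECREASED_LT_5X),
            (0.99, TrendCategory.DECREASED_LT_5X),
            (1.0, TrendCategory.UNCHANGED),
            (1.01, TrendCategory.INCREASED_LT_5X),
            (1.58, TrendCategory.INCREASED_LT_5X),
            (4.99, TrendCategory.INCREASED_LT_5X),
            (5.0, TrendCategory.INCREASED_5X_OR_MORE),  # inclusive boundary
            (10.47, TrendCategory.INCREASED_5X_OR_MORE),
        ],
    )
    def test_step_function(self, fold, category):
        assert classify_trend(fold) is category

    def test_new_major_minor_split(self):
        assert classify_trend(NewMetabolite(area=900.0), 500.0) is TrendCategory.NEW_MAJOR
        assert classify_trend(NewMetabolite(area=100.0), 500.0) is TrendCategory.NEW_MINOR

    def test_negative_fold_raises(self):
        with pytest.raises(ValueError):
            classify_trend(-0.5)


class TestSelectDifferential:
    def test_demo_fold_matrix_yields_fifteen_peaks(self):
        table = demo_feature_table()
        assert len(differential_peaks(table)) == 15

    def test_all_unity_table_empty_selection(self):
        table = FeatureTable.from_areas(
            {f"p{i}": {"G1": 100.0, "G3": 100.0, "G4": 100.0} for i in range(5)},
            groups=("G1", "G3", "G4"),
        )
        assert select_differential(table, {"G3": "G1", "G4": "G1"}) == []

    def test_monotone_in_min_fold(self):
        table = demo_feature_table()
        loose = set(differential_peaks(table, min_fold=1.5))
        strict = set(differential_peaks(table, min_fold=3.0))
        assert strict <= loose

    def test_missing_reference_raises(self):
        table = FeatureTable.from_areas({"p": {"G3": 1.0}}, groups=("G3",))
        with pytest.raises(KeyError):
            select_differential(table, {"G3": "G1"})

    def test_synthetic_selection_matches_planted_truth(self, default_experiment):
        table = align_features(default_experiment.features)
        selected = differential_peaks(table)
        mapping = match_table_to_truth(table, default_experiment.truth)
        selected_mets = {m for m, p in mapping.items() if p in set(selected)}
        assert selected_mets == expected_differential_ids(
            default_experiment.truth.metabolites
        )


class TestDemoFoldMatrix:
    def test_trend_categories_match_published_legend(self):
        """Strong/weak arrows in the fold matrix map onto the right classes."""
        tidy = load_demo_fold_matrix()
        by = {
            (r["reference"], r["peak"], r["group"]): r for _, r in tidy.iterrows()
        }
        assert classify_trend(by[("G2", 1, "G3")]["fold"]) is TrendCategory.DECREASED_5X_OR_MORE
        assert classify_trend(by[("G2", 1, "G7")]["fold"]) is TrendCategory.INCREASED_LT_5X
        assert classify_trend(by[("G2", 8, "G7")]["fold"]) is TrendCategory.INCREASED_5X_OR_MORE
        assert by[("G1", 14, "G6")]["is_new"] and by[("G1", 14, "G6")]["new_major"]
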