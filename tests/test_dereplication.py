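"""Adduct arithmetic, MW windows, UV logic, taxonomic staging, star flags."""

import pytest

from mycoderep.chem_mass import parse_formula
from mycoderep.datasets import annotate_demo_peak, load_demo_catalog, load_demo_peaks
from mycoderep.dereplication import (
    ADDUCT_SHIFTS,
    AnnotationEvidence,
    CandidateRecord,
    UVVerdict,
    deduce_neutral_mass,
    flag_reliability,
    halogenation_by_taxon,
    mw_filter,
    read_catalog,
    taxon_scope,
    uv_compatibility,
    write_catalog,
)
from mycoderep.spectra_features import END_ABSORPTION


class TestDeduceNeutralMass:
    @pytest.mark.parametrize(
        "mz,adduct,expected",
        [
            (759.36, "[M+H]+", 758.35),
            (427.26, "[M+Na]+", 404.27),
            (441.07, "[M-H]-", 442.08),
        ],
    )
    def test_worked_examples(self, mz, adduct, expected):
        assert deduce_neutral_mass(mz, adduct) == pytest.approx(expected, abs=0.005)

    def test_unknown_adduct_raises(self):
        with pytest.raises(ValueError, match="adduct"):
            deduce_neutral_mass(500.0, "[M+K]+")

    @pytest.mark.parametrize("adduct", sorted(ADDUCT_SHIFTS))
    def test_inverts_adduct_application(self, adduct):
        mz = 512.34
        neutral = mz - ADDUCT_SHIFTS[adduct]
        assert neutral + ADDUCT_SHIFTS[adduct] == pytest.approx(mz, abs=1e-5)


class TestMwFilter:
    @pytest.fixture()
    def catalog(self):
        return [
            CandidateRecord(name="unguisin-like", mw=758.92),
            CandidateRecord(name="nidulin-like", mw=443.70),
        ]

    def test_within_one_dalton(self, catalog):
        assert [c.name for c in mw_filter(catalog, 758.35)] == ["unguisin-like"]

    def test_chlorinated_window_widens(self, catalog):
        assert mw_filter(catalog, 442.08, chlorinated=False) == []
        hits = mw_filter(catalog, 442.08, chlorinated=True)
        assert [c.name for c in hits] == ["nidulin-like"]  # delta = 1.62 <= 2

    def test_widening_never_removes_hits(self, catalog):
        narrow = {c.name for c in mw_filter(catalog, 758.6, chlorinated=False)}
        wide = {c.name for c in mw_filter(catalog, 758.6, chlorinated=True)}
        assert narrow <= wide

    def test_empty_catalog(self):
        assert mw_filter([], 400.0) == []

    def test_inconsistent_mw_vs_formula_rejected(self):
        with pytest.raises(ValueError, match="disagrees"):
            CandidateRecord(name="bad", mw=310.0, formula=parse_formula("C16H28N4O2"))


class TestUvCompatibility:
    def test_end_absorption_vs_rich_maxima(self):
        rich = (230.0, 294.0, 369.0)
        assert uv_compatibility(END_ABSORPTION, rich) is UVVerdict.INCOMPATIBLE

    def test_end_absorption_both_sides(self):
        assert uv_compatibility(END_ABSORPTION, END_ABSORPTION) is UVVerdict.COMPATIBLE

    def test_identical_lists(self):
        uv = (231.0, 238.0, 247.0)
        assert uv_compatibility(uv, uv) is UVVerdict.COMPATIBLE

    def test_candidate_without_uv_unknown(self):
        assert uv_compatibility((231.0,), None) is UVVerdict.UNKNOWN

    def test_divergent_maxima_incompatible(self):
        assert (
            uv_compatibility((229.0, 264.0, 280.0, 422.0), (196.0, 293.0, 452.0))
            is UVVerdict.INCOMPATIBLE
        )


class TestTaxonScope:
    def test_genus_stage_filters(self):
        catalog = [
            CandidateRecord(name="a", mw=300.0, taxon="Aspergillus terreus"),
            CandidateRecord(name="b", mw=300.0, taxon="Cosmospora vilior"),
            CandidateRecord(name="c", mw=300.0, taxon="A. unguis"),
        ]
        stage1, stage2 = taxon_scope(catalog, "Aspergillus")
        assert {c.name for c in stage1} == {"a", "c"}
        assert {c.name for c in stage2} == {"a", "b", "c"}

    def test_empty_catalog(self):
        assert taxon_scope([], "Aspergillus") == ([], [])

    def test_kingdom_widening_on_demo_dichloro_peak(self):
        """The dichlorinated peak has no genus-level hit; stage 2 fungi appear."""
        hits = annotate_demo_peak("14")
        assert hits and all(h.stage == 2 for h in hits)
        assert all("Aspergillus" not in h.candidate.taxon for h in hits)


class TestFlagReliability:
    def test_ms2_match_stars(self):
        starred, excluded = flag_reliability(
            AnnotationEvidence(mw_match=True, ms2_cosine=0.76)
        )
        assert starred and not excluded

    def test_mw_only_unstarred(self):
        starred, excluded = flag_reliability(AnnotationEvidence(mw_match=True))
        assert not starred and not excluded

    def test_uv_incompatible_excludes_without_ms2(self):
        starred, excluded = flag_reliability(
            AnnotationEvidence(mw_match=True, uv=UVVerdict.INCOMPATIBLE, taxon_in_genus=True)
        )
        assert excluded and not starred

    def test_ms2_overrides_uv_incompatibility(self):
        starred, excluded = flag_reliability(
            AnnotationEvidence(mw_match=True, ms2_cosine=0.70, uv=UVVerdict.INCOMPATIBLE)
        )
        assert starred and not excluded

    def test_starred_subset_of_mw_match(self):
        for kwargs in (
            {"ms2_cosine": 0.9},
            {"uv": UVVerdict.COMPATIBLE},
            {"isotope_consistent": True},
            {"taxon_in_genus": True},
        ):
            starred, _ = flag_reliability(AnnotationEvidence(mw_match=False, **kwargs))
            assert not starred


class TestHalogenationByTaxon:
    @pytest.mark.parametrize(
        "records,chlorinated,expected",
        [
            ([141, 377], [3, 9], 2.3),
            ([19, 58], [3, 21], 31.2),
            ([40, 60], [0, 0], 0.0),
        ],
    )
    def test_per_source_arithmetic(self, records, chlorinated, expected):
        assert halogenation_by_taxon(records, chlorinated) == expected

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            halogenation_by_taxon([0], [0])


class TestCatalogIO:
    def test_round_trip(self, tmp_path):
        catalog = load_demo_catalog()
        path = tmp_path / "cat.csv"
        write_catalog(catalog, path)
        back = read_catalog(path)
        assert [c.name for c in back] == [c.name for c in catalog]
        assert [c.mw for c in back] == pytest.approx([c.mw for c in catalog])
        assert [c.uv_maxima for c in back] == [c.uv_maxima for c in catalog]
        assert [c.n_cl for c in back] == [c.n_cl for c in catalog]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_catalog(tmp_path / "nope.csv")


class TestDemoAnnotation:
    def test_chlorine_counts_drive_isotope_evidence(self):
        peaks = load_demo_peaks()
        assert peaks["14"].isotope_cluster is not None
        hits = annotate_demo_peak("14")
        assert all(h.evidence.isotope_consistent for h in hits)
        assert {h.candidate.n_cl for h in hits} == {2}

    def test_trichloro_peak_annotates_despite_off_grid_satellite(self):
        hits = annotate_demo_peak("15")
        assert [h.candidate.name for h in hits] == ["Nidulin"]
        assert hits[0].evidence.isotope_consistent
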