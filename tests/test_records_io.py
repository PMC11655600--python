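"""Domain types, CSV round trips, and diet-label derivation."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beelecty import io as bio
from beelecty.records import (
    DietLabel,
    HostAssignment,
    OccurrenceRecord,
    VisitationRecord,
    normalize_sex,
)

FAMILIES = ["Asteraceae", "Fabaceae", "Rosaceae", "Salicaceae", "Cleomaceae"]


def make_visit(**kw):
    base = dict(
        record_id="r1",
        bee_species="Andrena salicis",
        bee_genus="Andrena",
        bee_family="Andrenidae",
        plant_genus="Salix",
        plant_family="Salicaceae",
        sex="female",
        source_category="specimen",
    )
    base.update(kw)
    return VisitationRecord(**base)


class TestRecords:
    def test_bee_species_must_be_binomial(self):
        with pytest.raises(ValueError):
            make_visit(bee_species="Andrena")
        with pytest.raises(ValueError):
            make_visit(bee_species="Andrena cf. salicis")

    @pytest.mark.parametrize(
        "raw,expected",
        [("F", "female"), ("f", "female"), ("♀", "female"), ("MALE", "male"),
         ("♂", "male"), ("", "unknown"), ("worker", "unknown")],
    )
    def test_sex_alias_table(self, raw, expected):
        assert normalize_sex(raw) == expected

    def test_occurrence_bounds(self):
        with pytest.raises(ValueError):
            OccurrenceRecord("Andrena salicis", 91.0, 0.0)
        with pytest.raises(ValueError):
            OccurrenceRecord("Andrena salicis", 0.0, -181.0)

    def test_specialist_label_requires_single_family(self):
        with pytest.raises(ValueError):
            DietLabel(
                bee_species="Andrena salicis",
                label="specialist",
                host_families={"Salicaceae", "Rosaceae"},
            )


class TestVisitationIO:
    def test_three_row_csv_parses_identically(self, tmp_path):
        records = [make_visit(record_id=f"r{i}", plant_genus=g)
                   for i, g in enumerate(["Salix", "Rosa", "Solidago"])]
        path = tmp_path / "v.csv"
        bio.write_visitation(records, path)
        back, rejects = bio.read_visitation(path)
        assert len(rejects) == 0
        assert back == records

    def test_sex_alias_resolved_on_read(self, tmp_path):
        path = tmp_path / "v.csv"
        path.write_text(
            "record_id,bee_species,bee_genus,bee_family,plant_genus,plant_family,sex,source_category\n"
            "r1,Andrena salicis,Andrena,Andrenidae,Salix,Salicaceae,F,museum\n"
        )
        recs, rejects = bio.read_visitation(path)
        assert recs[0].sex == "female"
        assert recs[0].source_category == "specimen"
        assert len(rejects) == 0

    def test_synonym_map_renames_plant_taxa(self, tmp_path):
        rec = make_visit(plant_genus="OldGenus")
        path = tmp_path / "v.csv"
        bio.write_visitation([rec], path)
        back, _ = bio.read_visitation(path, synonym_map={"OldGenus": "NewGenus"})
        assert back[0].plant_genus == "NewGenus"
        # unmapped names pass through unchanged
        back2, _ = bio.read_visitation(path, synonym_map={"Other": "Thing"})
        assert back2[0].plant_genus == "OldGenus"

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        path = tmp_path / "v.csv"
        path.write_text("record_id,bee_species\nr1,Andrena salicis\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            bio.read_visitation(path)

    def test_malformed_row_collected_with_line_number(self, tmp_path):
        path = tmp_path / "v.csv"
        path.write_text(
            "record_id,bee_species,bee_genus,bee_family,plant_genus,plant_family\n"
            "r1,Andrena salicis,Andrena,Andrenidae,Salix,Salicaceae\n"
            "r2,NotABinomial,Andrena,Andrenidae,Salix,Salicaceae\n"
        )
        recs, rejects = bio.read_visitation(path)
        assert len(recs) == 1
        assert len(rejects) == 1
        assert rejects.rows[0]["line"] == 3

    def test_gzip_accepted(self, tmp_path):
        import gzip

        path = tmp_path / "v.csv.gz"
        content = (
            "record_id,bee_species,bee_genus,bee_family,plant_genus,plant_family\n"
            "r1,Andrena salicis,Andrena,Andrenidae,Salix,Salicaceae\n"
        )
        with gzip.open(path, "wt") as fh:
            fh.write(content)
        recs, _ = bio.read_visitation(path)
        assert len(recs) == 1


class TestOccurrenceIO:
    def test_round_trip_with_and_without_dates(self, tmp_path):
        records = [
            OccurrenceRecord("Andrena salicis", 40.5, -100.25, datetime.date(2015, 6, 1)),
            OccurrenceRecord("Andrena salicis", 41.0, -99.0, None),
        ]
        path = tmp_path / "o.csv"
        bio.write_occurrences(records, path)
        back, rejects = bio.read_occurrences(path)
        assert len(rejects) == 0
        assert back == records


class TestPollenHosts:
    @pytest.mark.parametrize(
        "loads,expected",
        [
            ({"A": 0.90, "B": 0.10}, {"A", "B"}),
            ({"A": 0.96, "B": 0.04}, {"A"}),
            ({"A": 1.0}, {"A"}),
            ({"A": 0.95, "B": 0.05}, {"A", "B"}),  # threshold is inclusive
        ],
    )
    def test_five_percent_rule(self, loads, expected):
        assert bio.pollen_hosts_from_loads(loads) == expected

    def test_fractions_over_one_rejected(self):
        with pytest.raises(ValueError):
            bio.pollen_hosts_from_loads({"A": 0.9, "B": 0.3})


class TestDietLabels:
    def test_single_family_two_genera_is_specialist(self):
        label = bio.derive_diet_label(
            [
                HostAssignment("Melissodes agilis", "Asteraceae", "Helianthus"),
                HostAssignment("Melissodes agilis", "Asteraceae", "Solidago"),
            ]
        )
        assert label.label == "specialist"
        assert label.host_families == {"Asteraceae"}
        assert label.host_genera == {"Helianthus", "Solidago"}

    def test_two_families_is_generalist(self):
        label = bio.derive_diet_label(
            [
                HostAssignment("Apis mellifera", "Asteraceae"),
                HostAssignment("Apis mellifera", "Fabaceae"),
            ]
        )
        assert label.label == "generalist"

    def test_taxonomically_split_host_family_keeps_both(self):
        # a host genus listed under two families (e.g. Capparaceae vs
        # Cleomaceae): both retained, label follows the size rule
        label = bio.derive_diet_label(
            [
                HostAssignment("Perdita cleomellae", "Capparaceae", "Cleomella"),
                HostAssignment("Perdita cleomellae", "Cleomaceae", "Cleomella"),
            ]
        )
        assert label.host_families == {"Capparaceae", "Cleomaceae"}
        assert label.label == "generalist"

    def test_generalist_assertion_overrides_single_family(self):
        label = bio.derive_diet_label(
            [HostAssignment("Apis mellifera", "Asteraceae", generalist_assertion=True)]
        )
        assert label.label == "generalist"

    def test_empty_assignments_error(self):
        with pytest.raises(ValueError):
            bio.derive_diet_label([])


class TestMergeLabels:
    def spec(self, sp, fam="Asteraceae", source="fowler"):
        return DietLabel(sp, "specialist", {fam}, set(), source)

    def gen(self, sp, fams=("Asteraceae", "Fabaceae"), source="literature"):
        return DietLabel(sp, "generalist", set(fams), set(), source)

    def test_literature_wins_and_counts_replacement(self):
        merged, report = bio.merge_label_sources(
            [self.spec("Andrena salicis")], [self.gen("Andrena salicis")]
        )
        assert merged[0].label == "generalist"
        assert report.n_replacements == 1

    def test_fowler_only_species_kept(self):
        merged, report = bio.merge_label_sources([self.spec("Andrena salicis")], [])
        assert merged[0].label == "specialist"
        assert report.n_replacements == 0

    def test_identical_labels_not_counted_as_replacement(self):
        merged, report = bio.merge_label_sources(
            [self.spec("Andrena salicis")],
            [self.spec("Andrena salicis", source="literature")],
        )
        assert report.n_both == 1
        assert report.n_replacements == 0

    def test_duplicate_species_within_source_errors(self):
        with pytest.raises(ValueError, match="duplicate species"):
            bio.merge_label_sources(
                [self.spec("Andrena salicis"), self.spec("Andrena salicis")], []
            )

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["Bee one", "Bee two", "Bee three", "Bee four"]),
                st.booleans(),
            ),
            unique_by=lambda t: t[0],
            max_size=4,
        ),
        st.lists(
            st.tuples(
                st.sampled_from(["Bee one", "Bee two", "Bee three", "Bee four"]),
                st.booleans(),
            ),
            unique_by=lambda t: t[0],
            max_size=4,
        ),
    )
    @settings(deadline=None, max_examples=50)
    def test_merge_is_idempotent(self, fowler_rows, lit_rows):
        fowler = [
            self.spec(sp, source="fowler") if is_spec else self.gen(sp, source="fowler")
            for sp, is_spec in fowler_rows
        ]
        lit = [
            self.spec(sp, source="literature") if is_spec else self.gen(sp)
            for sp, is_spec in lit_rows
        ]
        merged, _ = bio.merge_label_sources(fowler, lit)
        again, report = bio.merge_label_sources(merged, merged)
        assert {l.bee_species: l.label for l in again} == {
            l.bee_species: l.label for l in merged
        }
        assert report.n_replacements == 0


class TestLabelRoundTrip:
    def test_labels_csv_round_trip(self, tmp_path, small_bundle):
        path = tmp_path / "labels.csv"
        bio.write_labels(small_bundle.labels, path)
        back = bio.read_labels(path)
        orig = {l.bee_species: l for l in small_bundle.labels}
        for label in back:
            o = orig[label.bee_species]
            assert (label.label, label.host_families, label.host_genera) == (
                o.label,
                o.host_families,
                o.host_genera,
            )
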