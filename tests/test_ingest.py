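"""Ingest contracts: IO round-trip, map validation, harmonization, batching."""

import numpy as np
import pandas as pd
import pytest

from ehrshift.errors import (
    InsufficientBatchesError,
    MappingConflictError,
    SchemaError,
    ValidationError,
)
from ehrshift.ingest import (
    CodeMap,
    batch_by_year,
    feature_columns,
    harmonize_codes,
    load_code_map,
    read_admissions,
)
from ehrshift.synthetic import AdmissionTable, default_code_map, write_cohort


def _mini_table(codes_rows, admissions_rows=None):
    admissions = pd.DataFrame(
        admissions_rows
        or [
            {"admission_id": "a1", "year": 2008, "age": 60.0, "gender": "F",
             "ethnicity": "White", "outcome": 0},
            {"admission_id": "a2", "year": 2009, "age": 70.0, "gender": "M",
             "ethnicity": "Black", "outcome": 1},
        ]
    )
    codes = pd.DataFrame(codes_rows, columns=["admission_id", "coding_system", "axis", "code"])
    return AdmissionTable(admissions=admissions, codes=codes)


class TestReadAdmissions:
    def test_round_trip_equals_generated_table(self, tmp_path, null_cohort):
        scenario, table = null_cohort
        paths = write_cohort(table, scenario, tmp_path)
        back = read_admissions(paths["admissions"], paths["codes"])
        assert back == table

    def test_missing_outcome_column_is_schema_error(self, tmp_path, null_cohort):
        scenario, table = null_cohort
        paths = write_cohort(table, scenario, tmp_path)
        broken = pd.read_csv(paths["admissions"]).drop(columns=["outcome"])
        broken.to_csv(tmp_path / "broken.csv", index=False)
        with pytest.raises(SchemaError, match="outcome"):
            read_admissions(tmp_path / "broken.csv", paths["codes"])

    def test_minor_admission_excluded(self, tmp_path, null_cohort):
        scenario, table = null_cohort
        adm = table.admissions.copy()
        adm.loc[0, "age"] = 17.0
        AdmissionTable(admissions=adm, codes=table.codes)
        paths = write_cohort(
            AdmissionTable(admissions=adm, codes=table.codes), scenario, tmp_path
        )
        back = read_admissions(paths["admissions"], paths["codes"])
        assert len(back.admissions) == len(adm) - 1

    def test_orphan_code_rows_rejected(self, tmp_path, null_cohort):
        scenario, table = null_cohort
        codes = pd.concat(
            [
                table.codes,
                pd.DataFrame(
                    [{"admission_id": "ghost", "coding_system": "ICD-9",
                      "axis": "diagnosis", "code": "1400"}]
                ),
            ],
            ignore_index=True,
        )
        paths = write_cohort(
            AdmissionTable(admissions=table.admissions, codes=codes),
            scenario, tmp_path,
        )
        with pytest.raises(ValidationError, match="ghost"):
            read_admissions(paths["admissions"], paths["codes"])


class TestCodeMap:
    def test_bundled_map_covers_both_systems_and_axes(self, code_map):
        t = code_map.table
        assert set(t.coding_system) == {"ICD-9", "ICD-10"}
        assert set(t.axis) == {"diagnosis", "procedure"}

    def test_conflicting_chapters_rejected(self):
        t = pd.DataFrame(
            [
                ("ICD-9", "diagnosis", "X", "A"),
                ("ICD-9", "diagnosis", "X", "B"),
            ],
            columns=["coding_system", "axis", "code", "chapter"],
        )
        with pytest.raises(MappingConflictError):
            CodeMap(t)

    def test_same_code_different_axes_allowed(self):
        t = pd.DataFrame(
            [
                ("ICD-9", "diagnosis", "10", "A"),
                ("ICD-9", "procedure", "10", "B"),
            ],
            columns=["coding_system", "axis", "code", "chapter"],
        )
        assert CodeMap(t).chapters == ["A", "B"]

    def test_empty_file_is_schema_error(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("")
        with pytest.raises(SchemaError):
            load_code_map(empty)

    def test_header_only_file_is_schema_error(self, tmp_path):
        p = tmp_path / "hdr.csv"
        p.write_text("coding_system,axis,code,chapter\n")
        with pytest.raises(SchemaError):
            load_code_map(p)


class TestHarmonize:
    def test_cross_system_codes_collapse_to_single_indicator(self):
        cmap = CodeMap(
            pd.DataFrame(
                [
                    ("ICD-9", "diagnosis", "4019", "Circulatory"),
                    ("ICD-10", "diagnosis", "I10", "Circulatory"),
                ],
                columns=["coding_system", "axis", "code", "chapter"],
            )
        )
        table = _mini_table(
            [
                ("a1", "ICD-9", "diagnosis", "4019"),
                ("a1", "ICD-10", "diagnosis", "I10"),
            ]
        )
        feats = harmonize_codes(table, cmap)
        assert feats.loc[feats.admission_id == "a1", "chapter::Circulatory"].item() == 1

    def test_multiplicity_collapsed_to_binary(self, code_map):
        table = _mini_table(
            [
                ("a1", "ICD-9", "diagnosis", "1400"),
                ("a1", "ICD-9", "diagnosis", "1401"),
                ("a1", "ICD-9", "diagnosis", "1405"),
            ]
        )
        feats = harmonize_codes(table, code_map)
        chapter_cols = [c for c in feats.columns if c.startswith("chapter::")]
        assert feats[chapter_cols].to_numpy().max() == 1

    def test_longest_prefix_wins(self):
        cmap = CodeMap(
            pd.DataFrame(
                [
                    ("ICD-9", "diagnosis", "401", "Broad"),
                    ("ICD-9", "diagnosis", "4019", "Specific"),
                ],
                columns=["coding_system", "axis", "code", "chapter"],
            )
        )
        table = _mini_table([("a1", "ICD-9", "diagnosis", "40193")])
        feats = harmonize_codes(table, cmap)
        assert feats.loc[feats.admission_id == "a1", "chapter::Specific"].item() == 1
        assert feats.loc[feats.admission_id == "a1", "chapter::Broad"].item() == 0

    def test_unmapped_code_raises_and_names_code(self, code_map):
        table = _mini_table([("a1", "ICD-9", "diagnosis", "ZZZ9")])
        with pytest.raises(ValidationError, match="ZZZ9"):
            harmonize_codes(table, code_map, unmapped_policy="error")

    def test_unmapped_bucket_policy(self, code_map):
        table = _mini_table([("a1", "ICD-9", "diagnosis", "ZZZ9")])
        feats = harmonize_codes(table, code_map, unmapped_policy="bucket")
        assert feats.loc[feats.admission_id == "a1", "chapter::Unmapped"].item() == 1

    def test_identity_remap_is_idempotent_on_indicators(self, code_map, null_cohort):
        _, table = null_cohort
        once = harmonize_codes(table, code_map)
        twice = harmonize_codes(table, code_map)
        pd.testing.assert_frame_equal(once, twice)

    def test_demographics_one_hot_and_numeric_age(self, code_map, null_cohort):
        _, table = null_cohort
        feats = harmonize_codes(table, code_map)
        assert "age" in feature_columns(feats)
        gender_cols = [c for c in feats.columns if c.startswith("gender::")]
        assert gender_cols and set(np.unique(feats[gender_cols])) <= {0, 1}


class TestBatching:
    def test_batches_partition_the_cohort(self, null_features):
        batches = batch_by_year(null_features)
        assert len(batches) == 12
        assert sum(len(b) for _, b in batches) == len(null_features)
        assert [y for y, _ in batches] == sorted(y for y, _ in batches)

    def test_gap_years_produce_no_empty_batches(self):
        df = pd.DataFrame(
            {"admission_id": ["a", "b"], "year": [2008, 2010], "outcome": [0, 1],
             "age": [50.0, 60.0]}
        )
        batches = batch_by_year(df)
        assert [y for y, _ in batches] == [2008, 2010]

    def test_single_year_rejected(self):
        df = pd.DataFrame(
            {"admission_id": ["a"], "year": [2008], "outcome": [0], "age": [50.0]}
        )
        with pytest.raises(InsufficientBatchesError):
            batch_by_year(df)
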