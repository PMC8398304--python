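"""Summary-statistics I/O: parsing, validation, round-trip, packaged table."""

import hashlib
import math

import pytest

from snpmr import GwasAssociation, StudyTable, builtin_study_fixture, read_associations, write_associations
from snpmr.summary_io import ValidationWarning


def make_assoc(**overrides):
    base = dict(
        study_label="study",
        variant_id="rs1",
        effect_allele="T",
        other_allele="C",
        beta=0.1,
        se=0.05,
    )
    base.update(overrides)
    return GwasAssociation(**base)


class TestValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"se": 0.0},
            {"se": -1.0},
            {"effect_allele": "T", "other_allele": "T"},
            {"effect_allele": "N"},
            {"eaf": 1.5},
            {"p": 0.0},
            {"p": 1.2},
            {"n_cases": -1},
            {"beta": float("nan")},
        ],
    )
    def test_invalid_records_rejected(self, overrides):
        with pytest.raises(ValueError):
            make_assoc(**overrides)

    def test_inconsistent_p_warns_but_constructs(self):
        # |beta|/se = 2 but p implies z near 0: should warn, not raise
        with pytest.warns(ValidationWarning, match="disagree"):
            assoc = make_assoc(beta=0.1, se=0.05, p=0.9)
        assert assoc.p == 0.9

    def test_rounded_but_consistent_p_is_silent(self, recwarn):
        # p rounded to 3 significant digits stays consistent on the z scale
        make_assoc(beta=-0.063, se=0.020, p=1.97e-3)
        assert not [w for w in recwarn if issubclass(w.category, ValidationWarning)]

    def test_duplicate_study_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            StudyTable(records=(make_assoc(), make_assoc()))


class TestBuiltinFixture:
    def test_seven_records_all_t_vs_c(self, fixture_table):
        assert len(fixture_table) == 7
        assert all(r.effect_allele == "T" and r.other_allele == "C" for r in fixture_table)
        assert all(r.variant_id == "rs4988235" for r in fixture_table)
        assert all(r.eaf is None for r in fixture_table)

    @pytest.mark.parametrize(
        "label, beta, se, n_cases, n_controls",
        [
            ("MS GWAS", -0.054, 0.025, 14802, 26703),
            ("MS Immunochip", -0.063, 0.020, 14498, 24091),
            ("IGAP", -0.028, 0.016, 21982, 41944),
            ("FinnGen", -0.048, 0.029, 3060, 173839),
            ("PDWBS", 0.048, 0.021, 6476, 302042),
            ("PDGene", 0.117, 0.020, 13708, 95282),
            ("ALS GWAS", -0.028, 0.019, 20806, 59804),
        ],
    )
    def test_row_values(self, fixture_table, label, beta, se, n_cases, n_controls):
        record = fixture_table[label]
        assert record.beta == beta
        assert record.se == se
        assert record.n_cases == n_cases
        assert record.n_controls == n_controls

    def test_fixture_is_immutable_across_calls(self):
        digest = lambda t: hashlib.sha256(  # noqa: E731
            "|".join(f"{r.study_label},{r.beta!r},{r.se!r},{r.p!r},{r.n_cases},{r.n_controls}" for r in t).encode()
        ).hexdigest()
        assert digest(builtin_study_fixture()) == digest(builtin_study_fixture())
        assert digest(builtin_study_fixture()) == (
            "342c2b878b2160d5f84bc82e0d80473e52cf070ea965be943a9a389f27b26ed8"
        )


class TestReadWrite:
    def test_round_trip_identity(self, fixture_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_associations(fixture_table, path)
        back = read_associations(path)
        assert back.records == fixture_table.records

    def test_round_trip_with_all_optionals(self, tmp_path):
        table = StudyTable(
            records=(make_assoc(eaf=0.71234567890123, p=0.04550026389635842, n_cases=10, n_controls=20),)
        )
        path = tmp_path / "t.tsv"
        write_associations(table, path)
        back = read_associations(path)
        assert back.records == table.records  # full precision, not approximate

    def test_absent_optionals_written_as_empty_cells(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_associations(StudyTable(records=(make_assoc(),)), path)
        header, row = path.read_text().splitlines()
        assert row.count("\t") == header.count("\t")
        back = read_associations(path)
        assert back.records[0].eaf is None and back.records[0].p is None

    def test_header_only_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("study_label\tvariant_id\teffect_allele\tother_allele\tbeta\tse\n")
        with pytest.warns(ValidationWarning, match="no data rows"):
            table = read_associations(path)
        assert len(table) == 0

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("study_label\tvariant_id\teffect_allele\tother_allele\tbeta\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            read_associations(path)

    def test_bad_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "study_label\tvariant_id\teffect_allele\tother_allele\tbeta\tse\n"
            "ok\trs1\tT\tC\t0.1\t0.05\n"
            "zero-se\trs1\tT\tC\t0.1\t0\n"
            "not-a-number\trs1\tT\tC\tabc\t0.05\n"
        )
        with pytest.raises(ValueError) as excinfo:
            read_associations(path)
        message = str(excinfo.value)
        assert "line 3" in message and "positive" in message
        assert "line 4" in message and "abc" in message

    def test_dialect_maps_foreign_headers(self, tmp_path):
        path = tmp_path / "plink.csv"
        path.write_text("ID,A1,A2,BETA,SE,label\nrs9,t,c,0.2,0.1,s1\n")
        table = read_associations(
            path,
            dialect={
                "ID": "variant_id",
                "A1": "effect_allele",
                "A2": "other_allele",
                "BETA": "beta",
                "SE": "se",
                "label": "study_label",
            },
        )
        record = table.records[0]
        assert record.variant_id == "rs9"
        assert record.effect_allele == "T"  # case-normalised
        assert record.beta == 0.2

    def test_or_column_log_transformed_with_warning(self, tmp_path):
        path = tmp_path / "or.tsv"
        path.write_text(
            "study_label\tvariant_id\teffect_allele\tother_allele\tor\tse\ns1\trs1\tT\tC\t1.5\t0.1\n"
        )
        with pytest.warns(ValidationWarning, match="log-transformed"):
            table = read_associations(path, or_column="or")
        assert table.records[0].beta == pytest.approx(math.log(1.5), rel=1e-12)

    def test_unicode_minus_parsed(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "study_label\tvariant_id\teffect_allele\tother_allele\tbeta\tse\ns1\trs1\tT\tC\t−0.054\t0.025\n"
        )
        assert read_associations(path).records[0].beta == -0.054
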