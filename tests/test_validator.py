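"""Structural, template and vocabulary validation rules."""

import pytest

from sdrfkit.design import generate_design
from sdrfkit.model import Category, ColumnKey, SdrfParseError
from sdrfkit.sdrf import SdrfTable, read_sdrf
from sdrfkit.validate import (
    Severity,
    load_template,
    validate,
    validate_structure,
    validate_template,
    validate_terms,
)

from conftest import random_design_specs


def drop_column(table, key):
    idx = table.column_index(key)
    assert idx is not None, f"column {key} not present"
    return SdrfTable(
        columns=[k for i, k in enumerate(table.columns) if i != idx],
        rows=[[c for i, c in enumerate(row) if i != idx] for row in table.rows],
    )


def set_cell(table, row, key, value):
    out = table.copy()
    out.rows[row][out.column_index(key)] = value
    return out


def errors(findings):
    return [f for f in findings if f.severity is Severity.ERROR]


def rule_ids(findings):
    return [f.rule_id for f in findings]


ORGANISM = ColumnKey(Category.CHARACTERISTICS, "organism")
DISEASE = ColumnKey(Category.CHARACTERISTICS, "disease")
FRACTION = ColumnKey(Category.COMMENT, "fraction identifier")
LABEL = ColumnKey(Category.COMMENT, "label")


class TestStructuralRules:
    def test_generated_table_has_zero_errors(self, fig1_table):
        assert errors(validate_structure(fig1_table)) == []

    def test_deleting_organism_fires_s3(self, fig1_table):
        findings = validate_structure(drop_column(fig1_table, ORGANISM))
        assert [f.rule_id for f in errors(findings)] == ["S3"]
        assert errors(findings)[0].column == "characteristics[organism]"

    def test_non_integer_fraction_fires_s6_at_row(self, fig2_table):
        findings = validate_structure(set_cell(fig2_table, 4, FRACTION, "a"))
        s6 = [f for f in findings if f.rule_id == "S6"]
        assert len(s6) == 1 and s6[0].row == 5 and s6[0].severity is Severity.ERROR

    def test_conflicting_fraction_for_one_file_fires_s8(self):
        table = read_sdrf(
            "source name\tassay name\tcharacteristics[organism]\t"
            "characteristics[organism part]\tcharacteristics[biological replicate]\t"
            "comment[label]\tcomment[fraction identifier]\tcomment[technical replicate]\t"
            "comment[data file]\n"
            "s1\trun 1\tHomo sapiens\tliver\t1\tTMT126\t1\t1\ta.raw\n"
            "s2\trun 1\tHomo sapiens\tliver\t2\tTMT127N\t2\t1\ta.raw\n"
        )
        s8 = [f for f in validate_structure(table) if f.rule_id == "S8"]
        assert len(s8) == 1
        assert s8[0].column == "comment[fraction identifier]"

    def test_sample_characteristic_conflict_fires_s7(self, fig2_table):
        # rows 0 and 3 belong to sample 1 (fractions 1 and 2)
        table = set_cell(fig2_table, 3, ORGANISM, "Mus musculus")
        s7 = [f for f in validate_structure(table) if f.rule_id == "S7"]
        assert len(s7) == 1
        assert s7[0].column == "characteristics[organism]"

    def test_channel_claimed_twice_fires_s9(self, fig2_table):
        table = set_cell(fig2_table, 1, LABEL, fig2_table.rows[0][fig2_table.column_index(LABEL)])
        assert "S9" in rule_ids(errors(validate_structure(table)))

    def test_missing_label_column_fires_s14(self, fig1_table):
        findings = validate_structure(drop_column(fig1_table, LABEL))
        assert "S14" in [f.rule_id for f in errors(findings)]

    def test_empty_required_cell_fires_s5(self, fig1_table):
        table = set_cell(fig1_table, 2, ORGANISM, "  ")
        s5 = [f for f in validate_structure(table) if f.rule_id == "S5"]
        # the blank also conflicts with the sample's other rows (S7)
        assert len(s5) == 1 and s5[0].row == 3

    def test_unknown_label_value_fires_s11_warning(self, fig1_table):
        table = set_cell(fig1_table, 0, LABEL, "TMT999")
        s11 = [f for f in validate_structure(table) if f.rule_id == "S11"]
        assert len(s11) == 1 and s11[0].severity is Severity.WARNING
        # the bogus label also breaks per-sample/per-file consistency rules,
        # but S11 itself is only a warning

    def test_duplicate_rows_fire_s12_warning(self, fig1_table):
        table = fig1_table.copy()
        table.rows.append(list(table.rows[0]))
        s12 = [f for f in validate_structure(table) if f.rule_id == "S12"]
        assert len(s12) == 1 and s12[0].severity is Severity.WARNING

    def test_constant_factor_value_fires_s13_info(self, fig1_spec):
        from dataclasses import replace

        table = generate_design(replace(fig1_spec, factor_levels=("normal",)))
        s13 = [f for f in validate_structure(table) if f.rule_id == "S13"]
        assert len(s13) == 1 and s13[0].severity is Severity.INFO

    def test_empty_table_is_invalid(self):
        report = validate(SdrfTable(columns=[], rows=[]))
        assert not report.valid
        assert {"S1", "S2", "S3", "S4", "S14"} <= set(rule_ids(errors(report.findings)))

    @pytest.mark.parametrize(
        "header",
        [
            "source name",
            "assay name",
            "characteristics[organism]",
            "characteristics[organism part]",
            "characteristics[biological replicate]",
            "comment[fraction identifier]",
            "comment[technical replicate]",
            "comment[data file]",
            "comment[label]",
        ],
    )
    def test_monotonicity_deleting_any_required_column_adds_errors(self, fig2_table, header):
        from sdrfkit.model import parse_column_header

        base = len(errors(validate_structure(fig2_table)))
        damaged = drop_column(fig2_table, parse_column_header(header))
        assert len(errors(validate_structure(damaged))) > base

    def test_reports_are_deterministic(self, fig2_table, cv_store):
        a = validate(fig2_table, "default", cv_store)
        b = validate(fig2_table, "default", cv_store)
        assert a.to_text() == b.to_text()
        assert a.to_json() == b.to_json()

    def test_report_counts_match_findings(self, fig2_table):
        report = validate(drop_column(fig2_table, ORGANISM))
        c = report.counts
        assert sum(c.values()) == len(report.findings)
        assert report.valid == (c["ERROR"] == 0)


def with_disease(table, values):
    out = table.copy()
    out.columns.append(DISEASE)
    for row, v in zip(out.rows, values):
        row.append(v)
    return out


class TestTemplates:
    def test_human_table_with_normal_control_is_clean(self, fig1_table):
        table = with_disease(fig1_table, ["normal", "normal", "cancer", "cancer"])
        template = load_template("human")
        findings = validate_template(table, template)
        assert errors(findings) == []
        assert "H4" not in rule_ids(findings)

    def test_human_template_requires_disease(self, fig1_table):
        findings = validate_template(fig1_table, load_template("human"))
        assert [f.rule_id for f in errors(findings)] == ["H1"]

    def test_adding_disease_column_removes_the_error(self, fig1_table):
        table = with_disease(fig1_table, ["normal"] * 4)
        findings = validate_template(table, load_template("human"))
        assert errors(findings) == []

    def test_human_template_flags_non_human_organism(self, fig1_spec):
        from dataclasses import replace

        table = generate_design(replace(fig1_spec, organism="Mus musculus"))
        table = with_disease(table, ["normal"] * 4)
        findings = validate_template(table, load_template("human"))
        assert {f.rule_id for f in errors(findings)} == {"H3"}

    def test_missing_normal_control_is_info_only(self, fig1_table):
        table = with_disease(fig1_table, ["cancer"] * 4)
        findings = validate_template(table, load_template("human"))
        h4 = [f for f in findings if f.rule_id == "H4"]
        assert len(h4) == 1 and h4[0].severity is Severity.INFO

    def test_ancestry_is_a_warning(self, fig1_table):
        table = with_disease(fig1_table, ["normal"] * 4)
        h2 = [f for f in validate_template(table, load_template("human")) if f.rule_id == "H2"]
        assert len(h2) == 1 and h2[0].severity is Severity.WARNING

    def test_cell_line_template_requires_cell_line(self, fig1_table):
        findings = validate_template(fig1_table, load_template("cell-line"))
        assert [f.rule_id for f in errors(findings)] == ["C1"]

    def test_default_template_adds_nothing(self, fig1_table):
        assert validate_template(fig1_table, load_template("default")) == []

    def test_unknown_template_lists_available(self):
        with pytest.raises(SdrfParseError, match="human"):
            load_template("nonexistent")


class TestVocabulary:
    def make_table(self, cell):
        return read_sdrf(
            "source name\tcomment[modification parameters]\n" f"s1\t{cell}\n"
        )

    def test_matching_accession_and_label_is_clean(self, cv_store):
        table = self.make_table("AC=UNIMOD:35;NT=Oxidation;MT=Variable;TA=M")
        assert validate_terms(table, cv_store) == []

    def test_label_mismatch_is_warned(self, cv_store):
        table = self.make_table("AC=UNIMOD:35;NT=Phospho;MT=Variable;TA=M")
        findings = validate_terms(table, cv_store)
        assert [f.rule_id for f in findings] == ["V2"]
        assert findings[0].severity is Severity.WARNING

    def test_unknown_accession_is_warned(self, cv_store):
        findings = validate_terms(self.make_table("AC=UNIMOD:424242;NT=Mystery"), cv_store)
        assert [f.rule_id for f in findings] == ["V1"]

    def test_free_text_cells_produce_no_finding(self, cv_store):
        table = read_sdrf("source name\tcharacteristics[organism]\ns1\tHomo sapiens\n")
        assert validate_terms(table, cv_store) == []

    def test_unrecognized_key_is_info(self, cv_store):
        findings = validate_terms(self.make_table("NT=Oxidation;ZZ=1"), cv_store)
        assert [f.rule_id for f in findings] == ["V3"]
        assert findings[0].severity is Severity.INFO


class TestGeneratorValidatorConsistency:
    @pytest.mark.parametrize("spec", random_design_specs(25, seed=11),
                             ids=lambda s: f"{s.quant_method.value}-{s.n_biological}")
    def test_every_generated_design_validates_clean(self, spec, cv_store):
        report = validate(generate_design(spec), "default", cv_store)
        assert report.valid, report.to_text()
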