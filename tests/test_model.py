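"""Column-header and key/value micro-syntax parsers."""

import pytest
from hypothesis import given, strategies as st

from sdrfkit.model import (
    Category,
    ColumnKey,
    ModificationSpec,
    ModType,
    SdrfParseError,
    Tolerance,
    ToleranceUnit,
    format_column_header,
    parse_column_header,
    parse_enzyme,
    parse_key_value_cell,
    parse_modification,
    parse_tolerance,
    serialize_key_value_cell,
    serialize_modification,
)


class TestColumnHeader:
    @pytest.mark.parametrize(
        "header,expected",
        [
            ("characteristics [organism part]", (Category.CHARACTERISTICS, "organism part", 1)),
            ("characteristics[organism part]", (Category.CHARACTERISTICS, "organism part", 1)),
            ("source name", (Category.SOURCE_NAME, "", 1)),
            ("Source Name", (Category.SOURCE_NAME, "", 1)),
            ("assay name", (Category.ASSAY_NAME, "", 1)),
            ("factor value[tissue]", (Category.FACTOR_VALUE, "tissue", 1)),
            ("Factor Value[ Tissue ]", (Category.FACTOR_VALUE, "tissue", 1)),
            ("comment[instrument]", (Category.COMMENT, "instrument", 1)),
            ("COMMENT[Fraction Identifier]", (Category.COMMENT, "fraction identifier", 1)),
        ],
    )
    def test_parses_recognized_headers(self, header, expected):
        key = parse_column_header(header)
        assert (key.category, key.attribute, key.occurrence) == expected

    @pytest.mark.parametrize(
        "header",
        [
            "characteristics[phenotype",  # missing closing bracket
            "characteristics[]",  # empty attribute
            "characteristic[organism]",  # unknown prefix
            "factorvalue[tissue]",
            "",
            "   ",
        ],
    )
    def test_rejects_malformed_headers(self, header):
        with pytest.raises(SdrfParseError):
            parse_column_header(header)

    @pytest.mark.parametrize(
        "key,text",
        [
            (ColumnKey(Category.COMMENT, "fraction identifier"), "comment[fraction identifier]"),
            (ColumnKey(Category.ASSAY_NAME), "assay name"),
            (ColumnKey(Category.CHARACTERISTICS, "Organism"), "characteristics[organism]"),
        ],
    )
    def test_canonical_formatting(self, key, text):
        assert format_column_header(key) == text

    @given(
        category=st.sampled_from(list(Category)),
        attribute=st.text(
            alphabet=st.characters(
                whitelist_categories=("Ll", "Lu", "Nd"), whitelist_characters=" -_"
            ),
            min_size=1,
            max_size=25,
        ).filter(lambda s: s.strip()),
        spacing=st.sampled_from(["", " ", "  "]),
        shout=st.booleans(),
    )
    def test_parse_format_roundtrip(self, category, attribute, spacing, shout):
        """parse(format(key)) == key, and noisy dialect renderings
        (extra spaces, different case) parse to the same key."""
        if category in (Category.SOURCE_NAME, Category.ASSAY_NAME):
            key = ColumnKey(category)
            noisy = key.header.upper() if shout else key.header
        else:
            key = ColumnKey(category, attribute)
            prefix = category.value.upper() if shout else category.value
            noisy = f"{prefix}{spacing}[{key.attribute}]"
        assert parse_column_header(format_column_header(key)) == key
        assert parse_column_header(noisy) == key

    def test_occurrence_must_be_positive(self):
        with pytest.raises(ValueError):
            ColumnKey(Category.COMMENT, "label", occurrence=0)

    def test_bare_categories_take_no_attribute(self):
        with pytest.raises(ValueError):
            ColumnKey(Category.SOURCE_NAME, "organism")
        with pytest.raises(ValueError):
            ColumnKey(Category.COMMENT, "")


class TestKeyValueCell:
    def test_parses_printed_modification_cell(self):
        pairs = parse_key_value_cell("AC=UNIMOD:35;NT=Oxidation;MT=Variable;TA=M")
        assert pairs == {"AC": "UNIMOD:35", "NT": "Oxidation", "MT": "Variable", "TA": "M"}
        assert list(pairs) == ["AC", "NT", "MT", "TA"]  # order preserved

    def test_whitespace_and_case_normalization(self):
        assert parse_key_value_cell("ac = UNIMOD:35 ; nt = Oxidation") == {
            "AC": "UNIMOD:35",
            "NT": "Oxidation",
        }

    def test_bare_name_shorthand(self):
        assert parse_key_value_cell("Oxidation") == {"NT": "Oxidation"}

    def test_duplicate_key_rejected(self):
        with pytest.raises(SdrfParseError, match="NT"):
            parse_key_value_cell("NT=x;NT=y")

    def test_empty_cell_rejected(self):
        with pytest.raises(SdrfParseError):
            parse_key_value_cell("   ")

    @given(
        st.dictionaries(
            keys=st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ", min_size=1, max_size=3),
            values=st.text(
                alphabet=st.characters(
                    whitelist_categories=("Ll", "Lu", "Nd"), whitelist_characters=" :.,-"
                ),
                max_size=15,
            ).map(str.strip),
            min_size=1,
            max_size=6,
        )
    )
    def test_serializer_roundtrip_preserves_pairs_and_order(self, pairs):
        assert parse_key_value_cell(serialize_key_value_cell(pairs)) == pairs


class TestModification:
    def test_printed_oxidation_example(self):
        mod = parse_modification("AC=UNIMOD:35;NT=Oxidation;MT=Variable;TA=M")
        assert mod.name == "Oxidation"
        assert mod.accession == "UNIMOD:35"
        assert mod.mod_type is ModType.VARIABLE
        assert mod.target_amino_acids == ("M",)

    def test_fixed_carbamidomethyl(self):
        mod = parse_modification("NT=Carbamidomethyl;MT=Fixed;TA=C")
        assert mod.name == "Carbamidomethyl"
        assert mod.accession is None
        assert mod.mod_type is ModType.FIXED
        assert mod.target_amino_acids == ("C",)

    def test_mt_defaults_to_variable(self):
        assert parse_modification("Oxidation").mod_type is ModType.VARIABLE

    @pytest.mark.parametrize(
        "cell",
        [
            "MT=Variable",  # neither NT nor AC
            "NT=Oxidation;MT=Sometimes",  # MT outside the enumeration
            "NT=Oxidation;MM=heavy",  # non-numeric mass
            "NT=Oxidation;TA=Met",  # multi-letter residue
        ],
    )
    def test_invalid_modifications_rejected(self, cell):
        with pytest.raises(SdrfParseError):
            parse_modification(cell)

    @given(
        name=st.sampled_from(["Oxidation", "Phospho", "Acetyl", "TMT6plex", "GG"]),
        accession=st.one_of(st.none(), st.integers(1, 3000).map(lambda i: f"UNIMOD:{i}")),
        mod_type=st.sampled_from(list(ModType)),
        targets=st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), unique=True, max_size=4),
        mass=st.one_of(st.none(), st.floats(0.1, 3000).map(lambda x: round(x, 4))),
    )
    def test_serialize_parse_roundtrip(self, name, accession, mod_type, targets, mass):
        mod = ModificationSpec(
            name=name,
            accession=accession,
            mod_type=mod_type,
            target_amino_acids=tuple(targets),
            monoisotopic_mass=mass,
        )
        assert parse_modification(serialize_modification(mod)) == mod


class TestEnzymeAndTolerance:
    def test_enzyme_with_accession_and_site(self):
        enz = parse_enzyme("NT=Trypsin;AC=MS:1001251;CS=(?<=[KR])(?!P)")
        assert enz.name == "Trypsin"
        assert enz.accession == "MS:1001251"
        assert enz.cleavage_site == "(?<=[KR])(?!P)"

    def test_bare_enzyme_name(self):
        assert parse_enzyme("Trypsin").name == "Trypsin"

    @pytest.mark.parametrize(
        "cell,value,unit",
        [
            ("20 ppm", 20.0, ToleranceUnit.PPM),
            ("0.5 Da", 0.5, ToleranceUnit.DA),
            ("10ppm", 10.0, ToleranceUnit.PPM),
            ("0.02 DA", 0.02, ToleranceUnit.DA),
        ],
    )
    def test_tolerance_grammar(self, cell, value, unit):
        tol = parse_tolerance(cell)
        assert tol == Tolerance(value, unit)

    @pytest.mark.parametrize("cell", ["20", "-5 ppm", "0 Da", "20 mmu", "ppm", ""])
    def test_invalid_tolerances_rejected(self, cell):
        with pytest.raises(SdrfParseError):
            parse_tolerance(cell)
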