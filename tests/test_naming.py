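"""The designator grammar: formatting, vocabulary-driven parsing,
derivations, aliases, and well validation."""

import datetime as dt
import warnings as warnings_mod

import pytest
from hypothesis import given, strategies as st

from clonetrack import errors
from clonetrack.naming import (
    PLATE_DIMENSIONS,
    SampleName,
    WellAddress,
    derive_clone_name,
    derive_sort_name,
    format_name,
    is_filesystem_safe,
    parse_name,
    parse_well,
    short_alias,
)
from clonetrack.vocab import amend_vocabulary, default_vocabulary


def name(date=dt.date(2020, 1, 13), fp="mCh", gene="OCT4", guide="sg2",
         well=None, sort=None):
    w = parse_well(well) if well else None
    return SampleName(date, fp, gene, guide, w, sort)


class TestFormat:
    @pytest.mark.parametrize(
        "sample,text",
        [
            (name(), "20200113mChOCT4sg2"),
            (name(well="C6"), "20200113mChOCT4sg2_C6"),
            (name(well="C6", sort=4), "20200113mChOCT4sg2_C6_Sort4"),
            (name(date=dt.date(2020, 2, 20)), "20200220mChOCT4sg2"),
        ],
    )
    def test_canonical_rendering(self, sample, text):
        assert format_name(sample) == text

    def test_date_fields_zero_padded(self):
        assert format_name(name(date=dt.date(2021, 3, 5))).startswith("20210305")

    @pytest.mark.parametrize("bad", ["m_Ch", "", "a/b", "x y"])
    def test_unsafe_tokens_rejected(self, bad):
        with pytest.raises(errors.NameFormatError):
            SampleName(dt.date(2020, 1, 1), bad, "OCT4", "sg2")

    def test_sort_requires_well(self):
        with pytest.raises(errors.NameFormatError):
            SampleName(dt.date(2020, 1, 1), "mCh", "OCT4", "sg2", None, 1)


class TestParse:
    def test_printed_designators(self, vocab):
        parsed = parse_name("20200220mChOCT4sg2", vocab)
        assert parsed == name(date=dt.date(2020, 2, 20))

    def test_fp_casing_preserved_as_entered(self, vocab):
        parsed = parse_name("20200120mCHOCT4sg2", vocab)
        assert parsed.fp == "mCH"
        assert format_name(parsed) == "20200120mCHOCT4sg2"

    def test_suffixes(self, vocab):
        parsed = parse_name("20200113mChOCT4sg2_C6_Sort4", vocab)
        assert parsed.well.label == "C6"
        assert parsed.sort_index == 4

    def test_unknown_fp_unparseable(self, vocab):
        with pytest.raises(errors.NameParseError):
            parse_name("20200113xyOCT4sg2", vocab)

    def test_invalid_date_digits(self, vocab):
        with pytest.raises(errors.NameParseError):
            parse_name("20201350mChOCT4sg2", vocab)

    def test_malformed_sort_suffix(self, vocab):
        with pytest.raises(errors.NameParseError):
            parse_name("20200113mChOCT4sg2_C6_Sort0", vocab)

    def test_guide_pattern_fallback_warns(self, vocab):
        with pytest.warns(UserWarning, match="pattern"):
            parsed = parse_name("20200113mChNANOGsg7", vocab)
        assert parsed.gene == "NANOG"
        assert parsed.guide == "sg7"

    def test_longest_guide_match_wins(self, vocab):
        extended = amend_vocabulary(vocab, "guide_rna", "add", "Asg2")
        with warnings_mod.catch_warnings():
            warnings_mod.simplefilter("error")
            parsed = parse_name("20200113mChOCT4Asg2", extended)
        assert (parsed.gene, parsed.guide) == ("OCT4", "Asg2")


class TestDerivations:
    def test_clone_derivation(self, base_name, vocab):
        clone = derive_clone_name(base_name, parse_well("B9"))
        assert format_name(clone) == "20200113mChOCT4sg2_B9"
        with pytest.raises(errors.DerivationError):
            derive_clone_name(clone, parse_well("A1"))

    def test_sort_chain_increments_by_one(self, base_name):
        current = derive_clone_name(base_name, parse_well("C6"))
        for k in range(1, 6):
            current = derive_sort_name(current)
            assert current.sort_index == k

    def test_sort_requires_clone_level(self, base_name):
        with pytest.raises(errors.DerivationError):
            derive_sort_name(base_name)

    @pytest.mark.parametrize(
        "well,expected",
        [("C6", "200113_C6"), ("C10", "200113_C10")],
    )
    def test_short_alias(self, base_name, well, expected):
        assert short_alias(derive_clone_name(base_name, parse_well(well))) == expected

    def test_alias_needs_well(self, base_name):
        with pytest.raises(errors.AliasError):
            short_alias(base_name)


class TestWells:
    def test_accepts_exactly_96_labels_for_96_well_format(self):
        accepted = set()
        for row in "ABCDEFGHIJ":
            for col in range(0, 15):
                try:
                    accepted.add(parse_well(f"{row}{col}", 96).label)
                except errors.WellError:
                    pass
        assert len(accepted) == 96

    @pytest.mark.parametrize(
        "fmt,rows,cols",
        [(fmt, dims[0], dims[1]) for fmt, dims in sorted(PLATE_DIMENSIONS.items())],
    )
    def test_plate_bounds(self, fmt, rows, cols):
        assert rows * cols == fmt
        parse_well(f"{chr(ord('A') + rows - 1)}{cols}", fmt)  # corner accepted
        with pytest.raises(errors.WellError):
            parse_well(f"{chr(ord('A') + rows)}1", fmt)
        with pytest.raises(errors.WellError):
            parse_well(f"A{cols + 1}", fmt)

    @pytest.mark.parametrize("label", ["", "6C", "I1", "A0", "A13", "AA1"])
    def test_malformed_or_out_of_bounds(self, label):
        with pytest.raises(errors.WellError):
            parse_well(label, 96)


# --- properties ---------------------------------------------------------

_vocab_for_props = amend_vocabulary(
    amend_vocabulary(default_vocabulary(), "fluorescent_protein", "add", "GFP"),
    "guide_rna",
    "add",
    "sgRNA12",
)

_token = st.text(
    alphabet=st.sampled_from("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789+"),
    min_size=1,
    max_size=8,
)

_names = st.builds(
    SampleName,
    date=st.dates(dt.date(1990, 1, 1), dt.date(2099, 12, 31)),
    fp=st.sampled_from(_vocab_for_props.terms("fluorescent_protein")),
    gene=_token.filter(lambda t: not t[-1].isdigit()),
    guide=st.sampled_from(_vocab_for_props.terms("guide_rna")),
    well=st.one_of(
        st.none(),
        st.builds(
            WellAddress,
            row=st.sampled_from("ABCDEFGH"),
            column=st.integers(1, 12),
        ),
    ),
    sort_index=st.none(),
)


@given(_names, st.integers(0, 5))
def test_parse_format_round_trip(sample, sorts):
    """parse(format(x)) == x for any name constructible from the vocabulary."""
    if sample.well is not None:
        for _ in range(sorts):
            sample = derive_sort_name(sample)
    text = format_name(sample)
    assert is_filesystem_safe(text)
    assert parse_name(text, _vocab_for_props) == sample
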