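"""ENZYME flat-file parsing, name normalization and the name index."""

import pytest
from hypothesis import given, settings, strategies as st

from enzymome.enzyme_db import (
    EC_PATTERN,
    EnzymeRecord,
    build_name_index,
    ec_sort_key,
    lookup_ec,
    normalize_name,
    parse_enzyme_dat,
    serialize_enzyme_dat,
)

MINI_FIVE = """\
ID   1.1.1.1
DE   Alcohol dehydrogenase.
AN   Aldehyde reductase.
CA   A primary alcohol + NAD(+) = an aldehyde + NADH.
//
ID   4.4.1.1
DE   Cystathionine gamma-lyase.
CA   L-cystathionine + H2O = L-cysteine + NH3 + 2-oxobutanoate.
//
ID   1.8.99.1
DE   Transferred entry: 1.8.1.2 and 1.8.7.1.
//
ID   1.1.1.70
DE   Deleted entry.
//
ID   6.3.2.3
DE   Glutathione synthase.
CA   ATP + gamma-L-glutamyl-L-cysteine + glycine = ADP + phosphate +
CA   glutathione.
//
"""


class TestParsing:
    def test_empty_stream_yields_no_records(self):
        assert parse_enzyme_dat([]) == []

    def test_single_active_entry_fields(self):
        block = ("ID   4.4.1.1\n"
                 "DE   Cystathionine gamma-lyase.\n"
                 "CA   L-cystathionine + H2O = L-cysteine + NH3 + "
                 "2-oxobutanoate.\n//\n")
        (rec,) = parse_enzyme_dat(block.splitlines(True))
        assert rec.ec_number == "4.4.1.1"
        assert rec.status == "active"
        assert rec.recommended_name == "Cystathionine gamma-lyase."
        assert rec.catalytic_activity.startswith("L-cystathionine + H2O")

    def test_five_record_mini_file(self):
        # hand-parsed oracle: 5 blocks, of which exactly 3 are active
        records = parse_enzyme_dat(MINI_FIVE.splitlines(True))
        assert len(records) == 5
        by_status = {}
        for r in records:
            by_status.setdefault(r.status, []).append(r.ec_number)
        assert sorted(by_status["active"]) == ["1.1.1.1", "4.4.1.1", "6.3.2.3"]
        assert by_status["transferred"] == ["1.8.99.1"]
        assert by_status["deleted"] == ["1.1.1.70"]

    def test_transferred_targets_parsed(self):
        records = parse_enzyme_dat(MINI_FIVE.splitlines(True))
        trans = next(r for r in records if r.status == "transferred")
        assert trans.transfer_targets == {"1.8.1.2", "1.8.7.1"}

    def test_multiline_ca_joined_with_single_spaces(self):
        records = parse_enzyme_dat(MINI_FIVE.splitlines(True))
        gsh = next(r for r in records if r.ec_number == "6.3.2.3")
        assert gsh.catalytic_activity == (
            "ATP + gamma-L-glutamyl-L-cysteine + glycine = ADP + "
            "phosphate + glutathione.")

    def test_malformed_id_skipped_parsing_continues(self, caplog):
        text = ("ID   not-an-ec\nDE   Bogus.\n//\n"
                "ID   1.1.1.1\nDE   Alcohol dehydrogenase.\n//\n")
        with caplog.at_level("ERROR"):
            records = parse_enzyme_dat(text.splitlines(True))
        assert [r.ec_number for r in records] == ["1.1.1.1"]
        assert any("malformed ID" in m for m in caplog.messages)

    def test_truncated_final_record_dropped(self, caplog):
        text = "ID   1.1.1.1\nDE   Alcohol dehydrogenase.\n"
        with caplog.at_level("WARNING"):
            assert parse_enzyme_dat(text.splitlines(True)) == []
        assert any("truncated" in m for m in caplog.messages)

    def test_header_comment_lines_ignored(self):
        text = "CC   banner line\nCC   more banner\n" + MINI_FIVE
        assert len(parse_enzyme_dat(text.splitlines(True))) == 5


class TestNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("Cystathionine gamma-lyase.", "cystathionine gamma-lyase"),
        ("  Spaced   name  ", "spaced name"),
        ('"Quoted name."', "quoted name"),
        ("Homocysteine S-methyltransferase.",
         "homocysteine s-methyltransferase"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected

    @given(st.text(max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, s):
        once = normalize_name(s)
        assert normalize_name(once) == once


class TestNameIndex:
    def test_empty(self):
        assert len(build_name_index([])) == 0

    def test_collision_maps_to_both_ecs_ascending(self):
        records = [
            EnzymeRecord("1.1.1.21", "Aldose reductase.",
                         ("Alcohol dehydrogenase (acceptor).",)),
            EnzymeRecord("1.1.1.1", "Alcohol dehydrogenase.",
                         ("Alcohol dehydrogenase (acceptor).",)),
        ]
        idx = build_name_index(records)
        assert idx.get("alcohol dehydrogenase (acceptor)") == \
            ("1.1.1.1", "1.1.1.21")

    def test_recommended_name_indexed(self):
        records = [EnzymeRecord("2.1.1.10",
                                "Homocysteine S-methyltransferase.")]
        idx = build_name_index(records)
        assert idx.get("homocysteine s-methyltransferase") == ("2.1.1.10",)

    def test_no_inactive_leakage(self, bundled_records, bundled_index):
        inactive = {r.ec_number for r in bundled_records
                    if r.status != "active"}
        assert inactive  # the bundled file does carry tombstones
        indexed = {ec for ecs in bundled_index.entries.values() for ec in ecs}
        assert not (inactive & indexed)

    def test_index_completeness(self, bundled_records, bundled_index):
        for rec in bundled_records:
            if rec.status != "active":
                continue
            for name in rec.names():
                assert rec.ec_number in bundled_index.get(name), name

    def test_alt_names_excludable(self, bundled_records):
        idx = build_name_index(bundled_records, include_alt_names=False)
        assert idx.get("aldehyde reductase") == ()
        assert idx.get("aldose reductase") == ("1.1.1.21",)

    def test_keys_are_normalized_fixed_points(self, bundled_index):
        for key in bundled_index.entries:
            assert normalize_name(key) == key


class TestLookup:
    def test_known_ec(self, bundled_records):
        rec = lookup_ec("6.3.2.3", bundled_records)
        assert rec.recommended_name == "Glutathione synthase."
        assert rec.catalytic_activity == (
            "ATP + gamma-L-glutamyl-L-cysteine + glycine = ADP + "
            "phosphate + glutathione.")

    def test_transferred_entry_visible_with_targets(self, bundled_records):
        rec = lookup_ec("1.8.99.1", bundled_records)
        assert rec.status == "transferred"
        assert "1.8.1.2" in rec.transfer_targets

    def test_unknown_ec_not_found(self, bundled_records):
        assert lookup_ec("9.9.9.9", bundled_records) is None


_word = st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789-()",
                min_size=1, max_size=10).filter(
                    lambda w: w.strip("-") == w and not w.endswith("."))
_name = st.lists(_word, min_size=1, max_size=5).map(
    lambda ws: " ".join(ws).capitalize() + ".")
_ec = st.tuples(*(st.integers(1, 300),) * 4).map(
    lambda t: ".".join(map(str, t)))


@st.composite
def _active_records(draw):
    n = draw(st.integers(1, 6))
    ecs = draw(st.lists(_ec, min_size=n, max_size=n, unique=True))
    return [
        EnzymeRecord(
            ec_number=ec,
            recommended_name=draw(_name),
            alt_names=tuple(draw(st.lists(_name, max_size=2))),
            catalytic_activity=draw(_name),
        )
        for ec in ecs
    ]


@given(_active_records())
@settings(max_examples=60, deadline=None)
def test_flatfile_round_trip(records):
    """Serialize → reparse is field-identical for active records."""
    text = serialize_enzyme_dat(records)
    assert parse_enzyme_dat(text.splitlines(True)) == records


def test_ec_sort_key_orders_numerically_with_dash_last():
    ecs = ["1.10.1.1", "1.2.7.3", "1.2.7.-", "10.1.1.1", "1.2.7.10"]
    assert sorted(ecs, key=ec_sort_key) == [
        "1.2.7.3", "1.2.7.10", "1.2.7.-", "1.10.1.1", "10.1.1.1"]


def test_ec_pattern_accepts_partials_rejects_junk():
    assert EC_PATTERN.match("1.2.3.-")
    assert EC_PATTERN.match("1.2.3.4")
    assert not EC_PATTERN.match("1.2.3")
    assert not EC_PATTERN.match("1.2.3.4.5")
    assert not EC_PATTERN.match("a.b.c.d")
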