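"""Labeling algebra: render/parse, sequence reconstruction, inference, classes."""

import pytest
from hypothesis import given, settings, strategies as st

from isomirkit.nomenclature import (
    IsomirIdentity,
    LabelError,
    classify,
    infer_identity,
    parse_label,
    render_label,
    render_sequence,
    to_dna,
    to_rna,
)
from isomirkit.reference import EnumerationBounds, HairpinRecord, MatureArm, hairpin_from_isoforms


@pytest.mark.parametrize(
    "identity, label",
    [
        (IsomirIdentity("hsa-miR-203a-3p", 1, 0, "U"), "hsa-miR-203a-3p|+1|0(+1U)"),
        (IsomirIdentity("hsa-miR-100-5p", 0, -1, "UU"), "hsa-miR-100-5p|0|-1(+2U)"),
        (IsomirIdentity("X", 0, 0, ""), "X|0|0"),
        (IsomirIdentity("m", -1, -2, "UA"), "m|-1|-2(+UA)"),
        (IsomirIdentity("m", 0, 0, "", "GG"), "m|0|0(5p+2G)"),
    ],
)
def test_render_label(identity, label):
    assert render_label(identity) == label


@pytest.mark.parametrize(
    "label, expected",
    [
        ("hsa-miR-584-5p|−1|−2", IsomirIdentity("hsa-miR-584-5p", -1, -2)),
        ("hsa-miR-24-3p|0|−3(+1U)", IsomirIdentity("hsa-miR-24-3p", 0, -3, "U")),
        ("hsa-miR-30d-5p|0|+2", IsomirIdentity("hsa-miR-30d-5p", 0, 2)),
    ],
)
def test_parse_label(label, expected):
    assert parse_label(label) == expected


@pytest.mark.parametrize("bad", ["x|0|", "x|0", "x|a|0", "x|0|0(+)", "x|0|0(1U)", ""])
def test_parse_label_rejects_malformed(bad):
    with pytest.raises(LabelError) as err:
        parse_label(bad)
    assert err.value.position >= 0


identities = st.builds(
    IsomirIdentity,
    mature_name=st.from_regex(r"[a-z]{1,4}-miR-[0-9]{1,3}-[35]p", fullmatch=True),
    start_offset=st.integers(-5, 5),
    end_offset=st.integers(-5, 5),
    nta3=st.text(alphabet="ACGU", max_size=3),
    nta5=st.text(alphabet="ACGU", max_size=2),
)


@given(identities)
@settings(max_examples=300, deadline=None)
def test_parse_render_roundtrip(identity):
    assert parse_label(render_label(identity)) == identity


@given(identities)
@settings(max_examples=300, deadline=None)
def test_classification_is_a_partition(identity):
    cat = classify(identity)
    # exactly one category; mixed iff >= 2 deviations recorded
    if cat.category == "mixed":
        assert len(cat.mixed_detail) >= 2
    else:
        assert cat.mixed_detail == frozenset()


@pytest.mark.parametrize(
    "identity, category, detail",
    [
        (IsomirIdentity("m", 0, -2), "end-site", set()),
        (IsomirIdentity("m", -1, -1, "U"), "mixed", {"shifted", "3p-nta"}),
        (IsomirIdentity("m", -1, -2), "mixed", {"start-site", "end-site"}),
        (IsomirIdentity("m", -1, -1), "shifted", set()),
        (IsomirIdentity("m", 0, 0, "UU"), "3p-nta", set()),
        (IsomirIdentity("m", 0, 0), "canonical", set()),
        (IsomirIdentity("m", 2, 0), "start-site", set()),
        (IsomirIdentity("m", 0, 0, "", "A"), "5p-nta", set()),
        (IsomirIdentity("m", 1, -1, "U"), "mixed", {"start-site", "end-site", "3p-nta"}),
    ],
)
def test_classify(identity, category, detail):
    cat = classify(identity)
    assert cat.category == category
    assert cat.mixed_detail == frozenset(detail)


@pytest.fixture(scope="module")
def mir100_record():
    canonical = "AACCCGUAGAUCCGAACUUGUG"
    return hairpin_from_isoforms("hsa-miR-100-5p", {"hsa-miR-100-5p|0|0": canonical})


class TestRenderSequence:
    """The miR-100-5p family: canonical AACCCGUAGAUCCGAACUUGUG."""

    @pytest.fixture
    def record(self, mir100_record):
        return mir100_record

    @pytest.mark.parametrize(
        "label, expected",
        [
            ("hsa-miR-100-5p|0|0", "AACCCGUAGAUCCGAACUUGUG"),
            ("hsa-miR-100-5p|0|-1", "AACCCGUAGAUCCGAACUUGU"),
            ("hsa-miR-100-5p|+1|-1", "ACCCGUAGAUCCGAACUUGU"),
            ("hsa-miR-100-5p|0|-1(+2U)", "AACCCGUAGAUCCGAACUUGUUU"),
        ],
    )
    def test_family_sequences(self, record, label, expected):
        assert to_rna(render_sequence(parse_label(label), record)) == expected

    def test_out_of_bounds_window_raises(self, record):
        with pytest.raises(ValueError, match="outside hairpin"):
            render_sequence(IsomirIdentity("hsa-miR-100-5p", -30, 0), record)

    def test_templated_nta_raises(self, record):
        arm = record.arms[0]
        template_next = record.sequence[arm.end]
        with pytest.raises(ValueError, match="templated extension"):
            render_sequence(
                IsomirIdentity("hsa-miR-100-5p", 0, 0, template_next), record
            )


class TestInferIdentity:
    def test_canonical_maps_to_zero_offsets(self, flat_hairpin, bounds):
        arm = flat_hairpin.arms[0]
        seq = flat_hairpin.canonical_sequence(arm.mature_name)
        assert infer_identity(seq, flat_hairpin, arm, bounds) == IsomirIdentity(
            arm.mature_name
        )

    def test_trimmed_end(self, flat_hairpin, bounds):
        arm = flat_hairpin.arms[0]
        seq = flat_hairpin.canonical_sequence(arm.mature_name)[:-1]
        got = infer_identity(seq, flat_hairpin, arm, bounds)
        assert (got.start_offset, got.end_offset, got.nta3) == (0, -1, "")

    def test_templated_precedence_over_nta(self, bounds):
        """Appending a base that matches the hairpin is an end-site extension."""
        # hairpin engineered so that the base after the arm is T (=U)
        seq = "G" * 12 + "ACGTACGTACGTACGTACGTAC" + "T" + "G" * 12
        rec = HairpinRecord("hp", seq, (MatureArm("m", 12, 34),))
        read = rec.canonical_sequence("m") + "T"
        got = infer_identity(read, rec, rec.arms[0], bounds)
        assert got == IsomirIdentity("m", 0, 1)

    def test_matches_brute_force_decomposition(self, flat_hairpin, small_bounds):
        """The greedy inference agrees with exhaustive decomposition search."""
        arm = flat_hairpin.arms[0]
        hp = flat_hairpin.sequence
        reads = set()
        for a in range(-2, 3):
            for b in range(-2, 3):
                lo, hi = arm.start + a, arm.end + b
                if 18 <= hi - lo <= 26:
                    reads.add(hp[lo:hi])
                    reads.add(hp[lo:hi] + "A")
                    reads.add(hp[lo:hi] + "T")
        for read in sorted(reads):
            got = infer_identity(read, flat_hairpin, arm, small_bounds)
            brute = self._brute_force(read, flat_hairpin, arm, small_bounds)
            assert got == brute, read

    @staticmethod
    def _brute_force(read, record, arm, bounds):
        """Enumerate every decomposition; rank by (|nta3|, |nta5|, |a|, a)."""
        hp = record.sequence
        if not (bounds.min_len <= len(read) <= bounds.max_len):
            return None
        best = None
        for n3 in range(0, bounds.max_nta_len + 1):
            for a in range(-bounds.max_start_shift, bounds.max_start_shift + 1):
                core = read[: len(read) - n3] if n3 else read
                lo, hi = arm.start + a, arm.start + a + len(core)
                b = hi - arm.end
                if lo < 0 or hi > len(hp) or abs(b) > bounds.max_end_shift:
                    continue
                if hp[lo:hi] != core:
                    continue
                if n3 and hi < len(hp) and read[len(read) - n3] == hp[hi]:
                    continue
                cand = (n3, abs(a), a)
                if best is None or cand < best[0]:
                    best = (cand, IsomirIdentity(arm.mature_name, a, b, read[len(read) - n3:] if n3 else ""))
        return best[1] if best else None

    def test_unmatchable_sequence_returns_none(self, flat_hairpin, bounds):
        assert infer_identity("A" * 22, flat_hairpin, flat_hairpin.arms[0], bounds) is None


def test_dna_rna_normalisation_roundtrip():
    assert to_dna("acguACGU") == "ACGTACGT"
    assert to_rna(to_dna("ACGU")) == "ACGU"
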