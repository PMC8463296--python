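"""Record classification, edit-distance extraction, and CIGAR accounting."""

import pytest
from hypothesis import given, settings, strategies as st

from dualmap.alignment_model import (
    Category,
    ReadRecordGroup,
    cigar_to_string,
    classify,
    edit_distance_of,
    parse_cigar,
    query_alignment_length,
    reverse_complement,
)
from dualmap.errors import (
    DuplicatePrimary,
    EmptyAlignment,
    MalformedTag,
    MissingEvidence,
)

from conftest import record


@pytest.mark.parametrize(
    "flag, expected",
    [
        (0, Category.PRIMARY),
        (16, Category.PRIMARY),  # reverse strand is still primary
        (4, Category.UNMAPPED),
        (256, Category.SECONDARY),
        (2048, Category.SUPPLEMENTARY),
        (4 | 256, Category.UNMAPPED),  # unmapped wins over flag bits
        (4 | 2048, Category.UNMAPPED),
        (256 | 2048, Category.SECONDARY),  # never interpreted as primary
    ],
)
def test_classify_flag_semantics(flag, expected):
    assert classify(record(flag=flag)) is expected


@pytest.mark.parametrize(
    "cigar, expected",
    [
        ("100M", 100),
        ("10S80M5I5D10S", 85),  # soft clips and deletions excluded
        ("50H50M", 50),  # hard clips consume no aligned query
        ("30=10X10I", 50),  # extended ops count like M
        ("10M100N10M", 20),  # skipped regions consume no query
    ],
)
def test_query_alignment_length(cigar, expected):
    assert query_alignment_length(record(cigar=cigar)) == expected


def test_query_alignment_length_empty_alignment():
    with pytest.raises(EmptyAlignment):
        query_alignment_length(record(cigar="10S"))


@pytest.mark.parametrize(
    "cigar, md, expected",
    [
        ("10M", "10", 0),  # zero mismatches
        ("10M", "4A5", 1),  # one substitution
        ("5M1I4M", "9", 1),  # insertion counted from CIGAR
        ("10M2D10M", "10^AC10", 2),  # 2-base deletion, no mismatches
        ("8M1I2M2D5M", "4T5^GG2A2", 5),  # 2 subs + 1 ins + 2 del
    ],
)
def test_edit_distance_reconstruction_from_md(cigar, md, expected):
    rec = record(cigar=cigar, md=md)
    assert edit_distance_of(rec) == expected


def test_nm_takes_precedence_over_md():
    rec = record(cigar="10M", nm=3, md="10")
    assert edit_distance_of(rec) == 3


def test_missing_evidence_and_malformed_md():
    with pytest.raises(MissingEvidence):
        edit_distance_of(record(cigar="10M"))
    with pytest.raises(MalformedTag):
        edit_distance_of(record(cigar="10M2D10M", md="10^A10"))  # del length off
    with pytest.raises(MalformedTag):
        edit_distance_of(record(cigar="10M", md="9"))  # coverage off


@st.composite
def _alignment_with_md(draw):
    """A consistent (CIGAR, MD, NM) triple built edit-by-edit."""
    segments = draw(
        st.lists(
            st.sampled_from(["match", "sub", "ins", "del"]),
            min_size=1,
            max_size=12,
        )
    )
    cigar, md_parts, nm = [], [], 0
    match_run = 0
    bases = "ACGT"
    rng = draw(st.randoms(use_true_random=False))

    def flush():
        nonlocal match_run
        md_parts.append(str(match_run))
        match_run = 0

    for seg in segments:
        n = draw(st.integers(min_value=1, max_value=5))
        if seg == "match":
            cigar.append((0, n))
            match_run += n
        elif seg == "sub":
            cigar.append((0, n))
            for _ in range(n):
                flush()
                md_parts.append(rng.choice(bases))
            nm += n
        elif seg == "ins":
            cigar.append((1, n))
            nm += n
        else:
            flush()
            md_parts.append("^" + "".join(rng.choice(bases) for _ in range(n)))
            cigar.append((2, n))
            nm += n
    flush()
    if not any(op in (0, 1, 7, 8) for op, _ in cigar):
        cigar.append((0, 1))
        match_run = 1
        md_parts[-1] = str(int(md_parts[-1]) + 1)
    return cigar_to_string(cigar), "".join(md_parts), nm


@settings(deadline=None, max_examples=200)
@given(_alignment_with_md())
def test_md_reconstruction_matches_nm(triple):
    """Dropping NM and reconstructing from MD+CIGAR round-trips exactly."""
    cigar, md, nm = triple
    with_nm = record(cigar=cigar, nm=nm, md=md)
    without_nm = record(cigar=cigar, md=md)
    assert edit_distance_of(without_nm) == edit_distance_of(with_nm) == nm


@settings(deadline=None, max_examples=100)
@given(st.lists(st.tuples(st.sampled_from([0, 1, 2, 4]), st.integers(1, 20)), min_size=1))
def test_aligned_length_bounded_by_sequence(ops):
    """query_alignment_length <= stored sequence length."""
    from dualmap.alignment_model import QUERY_CONSUMING, ALIGNED_QUERY_OPS

    if not any(op in ALIGNED_QUERY_OPS for op, _ in ops):
        ops = ops + [(0, 1)]
    seq_len = sum(n for op, n in ops if op in QUERY_CONSUMING)
    rec = record(cigar=cigar_to_string(ops), seq="A" * seq_len)
    assert query_alignment_length(rec) <= len(rec.query_sequence)


def test_read_group_requires_unique_primary():
    good = ReadRecordGroup("r", [record(flag=0), record(flag=2048)])
    assert good.primary.flag == 0
    with pytest.raises(DuplicatePrimary):
        ReadRecordGroup("r", [record(flag=0), record(flag=0)]).primary
    with pytest.raises(DuplicatePrimary):
        ReadRecordGroup("r", [record(flag=256)]).primary


def test_cigar_and_revcomp_helpers():
    assert parse_cigar("3M1I2D") == [(0, 3), (1, 1), (2, 2)]
    assert cigar_to_string([(0, 3), (1, 1)]) == "3M1I"
    assert reverse_complement("AACG") == "CGTT"
    with pytest.raises(ValueError):
        parse_cigar("3Q")
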