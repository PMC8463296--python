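"""Domain model over SAM/BAM alignment records.

The pipeline's unit of evidence is a single SAM record: its flag bits decide
whether it is the read's primary alignment, and its NM tag (or, failing
that, MD + CIGAR) yields the edit distance *e* between the aligned portion
of the read and the reference.  The aligned query length *l* is the number
of read bases the aligner actually placed (CIGAR M/I/=/X; clips excluded),
so e/l is a well-defined per-alignment error rate.

All functions here are duck-typed over the attribute surface shared by
:class:`pysam.AlignedSegment` and the lightweight :class:`AlignmentRecord`
dataclass, so the same code paths serve both real BAM streams and in-memory
fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

from .errors import (
    DuplicatePrimary,
    EmptyAlignment,
    MalformedTag,
    MissingEvidence,
)

# SAM flag bits (SAM v1)
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

# Numeric CIGAR operation codes, as used by pysam cigartuples.
CIGAR_OPS = "MIDNSHP=X"
_OP_CODE = {op: i for i, op in enumerate(CIGAR_OPS)}
QUERY_CONSUMING = frozenset({0, 1, 4, 7, 8})  # M I S = X
ALIGNED_QUERY_OPS = frozenset({0, 1, 7, 8})  # M I = X
REFERENCE_CONSUMING = frozenset({0, 2, 3, 7, 8})  # M D N = X

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, int]]:
    """Parse a CIGAR string into pysam-style (op_code, length) tuples."""
    if cigar in ("", "*"):
        return []
    tuples: list[tuple[int, int]] = []
    for m in re.finditer(r"(\d+)([MIDNSHP=X])", cigar):
        tuples.append((_OP_CODE[m.group(2)], int(m.group(1))))
    reconstructed = "".join(f"{n}{CIGAR_OPS[op]}" for op, n in tuples)
    if reconstructed != cigar:
        raise ValueError(f"invalid CIGAR string: {cigar!r}")
    return tuples


def cigar_to_string(cigartuples: Iterable[tuple[int, int]]) -> str:
    return "".join(f"{n}{CIGAR_OPS[op]}" for op, n in cigartuples)


class Category(str, Enum):
    """SAM record category; ``unmapped`` takes precedence over flag bits."""

    PRIMARY = "primary"
    SECONDARY = "secondary"
    SUPPLEMENTARY = "supplementary"
    UNMAPPED = "unmapped"


@dataclass
class AlignmentRecord:
    """In-memory SAM record mirroring pysam's attribute names.

    ``query_qualities_str`` is the Phred+33 string form (``None`` for "*"),
    matching what the SAM text field carries.
    """

    query_name: str
    flag: int = 0
    reference_name: Optional[str] = None
    reference_start: Optional[int] = None  # 0-based leftmost
    mapping_quality: int = 0
    cigartuples: list[tuple[int, int]] = field(default_factory=list)
    query_sequence: Optional[str] = None
    query_qualities_str: Optional[str] = None
    tags: dict[str, object] = field(default_factory=dict)

    def has_tag(self, tag: str) -> bool:
        return tag in self.tags

    def get_tag(self, tag: str):
        try:
            return self.tags[tag]
        except KeyError:
            raise KeyError(f"tag {tag!r} not present") from None

    @classmethod
    def from_pysam(cls, rec) -> "AlignmentRecord":
        import pysam

        qual = rec.query_qualities
        return cls(
            query_name=rec.query_name,
            flag=rec.flag,
            reference_name=rec.reference_name if rec.reference_id >= 0 else None,
            reference_start=rec.reference_start if rec.reference_start >= 0 else None,
            mapping_quality=rec.mapping_quality,
            cigartuples=list(rec.cigartuples or []),
            query_sequence=rec.query_sequence,
            query_qualities_str=(
                pysam.qualities_to_qualitystring(qual) if qual is not None else None
            ),
            tags=dict(rec.get_tags()),
        )


def _flag(record) -> int:
    return record.flag


def classify(record) -> Category:
    """Categorize a SAM record; unmapped wins over secondary/supplementary."""
    flag = _flag(record)
    if flag & FLAG_UNMAPPED:
        return Category.UNMAPPED
    if flag & FLAG_SECONDARY:
        return Category.SECONDARY
    if flag & FLAG_SUPPLEMENTARY:
        return Category.SUPPLEMENTARY
    return Category.PRIMARY


def is_primary(record) -> bool:
    return classify(record) is Category.PRIMARY


def _cigartuples(record) -> list[tuple[int, int]]:
    return list(record.cigartuples or [])


def query_alignment_length(record) -> int:
    """Number of query bases consumed by aligned ops (M, I, =, X).

    Soft and hard clips are excluded: NM counts edits only within the
    aligned region, so this is the denominator that makes e/l a rate.
    """
    tuples = _cigartuples(record)
    length = sum(n for op, n in tuples if op in ALIGNED_QUERY_OPS)
    if length == 0:
        raise EmptyAlignment(
            f"record {record.query_name!r} has no aligned query bases"
        )
    return length


def full_read_length(record) -> int:
    """Query length including soft and hard clips (the sequenced read)."""
    tuples = _cigartuples(record)
    return sum(n for op, n in tuples if op in QUERY_CONSUMING or op == 5)


def _parse_md(md: str) -> tuple[int, int, int]:
    """Return (matched_bases, mismatches, deleted_bases) encoded by MD."""
    matched = mismatches = deleted = 0
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise MalformedTag(f"unparseable MD tag: {md!r}")
        pos = m.end()
        if m.group(1) is not None:
            matched += int(m.group(1))
        elif m.group(2) is not None:
            deleted += len(m.group(2)) - 1
        else:
            mismatches += 1
    if pos != len(md):
        raise MalformedTag(f"unparseable MD tag: {md!r}")
    return matched, mismatches, deleted


def edit_distance_of(record) -> int:
    """Edit distance e: NM tag if present, else reconstructed from MD+CIGAR.

    Reconstruction counts the mismatches encoded in MD plus the total
    inserted and deleted bases from the CIGAR. MD is validated against the
    CIGAR: its deletion run lengths must sum to the CIGAR's D total, and
    matches+mismatches must cover the CIGAR's aligned M/=/X span.
    """
    if record.has_tag("NM"):
        return int(record.get_tag("NM"))
    if not record.has_tag("MD"):
        raise MissingEvidence(
            f"record {record.query_name!r} carries neither NM nor MD"
        )
    tuples = _cigartuples(record)
    ins = sum(n for op, n in tuples if op == 1)
    dels = sum(n for op, n in tuples if op == 2)
    m_span = sum(n for op, n in tuples if op in (0, 7, 8))
    matched, mismatches, md_dels = _parse_md(str(record.get_tag("MD")))
    if md_dels != dels:
        raise MalformedTag(
            f"MD deletes {md_dels} bases but CIGAR deletes {dels}"
        )
    if matched + mismatches != m_span:
        raise MalformedTag(
            f"MD covers {matched + mismatches} aligned bases but CIGAR has {m_span}"
        )
    return mismatches + ins + dels


@dataclass
class ReadRecordGroup:
    """All SAM records sharing one read name; exactly one must be primary."""

    read_name: str
    records: list

    @property
    def primary(self):
        primaries = [r for r in self.records if is_primary(r)]
        if len(primaries) != 1:
            raise DuplicatePrimary(
                f"read {self.read_name!r} has {len(primaries)} primary records"
            )
        return primaries[0]


def group_by_read(records: Iterable) -> Iterator[ReadRecordGroup]:
    """Group an arbitrary-order record stream by read name (in memory)."""
    groups: dict[str, list] = {}
    for rec in records:
        groups.setdefault(rec.query_name, []).append(rec)
    for name, recs in groups.items():
        yield ReadRecordGroup(read_name=name, records=recs)
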