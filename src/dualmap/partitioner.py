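"""Split the fast mapper's output into keep-set records and realign-set reads.

Partitioning is by *read*, not by record: if a read's primary E exceeds the
threshold, all of its records (primary, secondary, supplementary) leave the
keep stream and the read itself is re-extracted as FASTQ for the sensitive
mapper, which will regenerate its own placements.

Extraction restores original sequencing orientation: SAM stores a
reverse-strand read as the reverse complement of what the sequencer
emitted, so reverse-flagged primaries are complemented back and their
qualities reversed.  Primaries that cannot be extracted (hard-clipped or
sequence "*") are reported and their read falls back to the keep stream
rather than aborting the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .alignment_model import (
    Category,
    ReadRecordGroup,
    classify,
    reverse_complement,
)
from .ed_profile import EditDistanceProfile
from .errors import OrphanRecord

FLAG_REVERSE = 0x10


@dataclass
class PartitionResult:
    threshold: float
    keep_names: set[str]
    realign_names: set[str]
    n_eligible: int
    n_unmapped: int = 0

    @property
    def realign_fraction(self) -> float:
        return len(self.realign_names) / self.n_eligible if self.n_eligible else 0.0


@dataclass
class FastqRecord:
    name: str
    sequence: str
    qualities: str

    def format(self) -> str:
        qual = self.qualities if self.qualities else "I" * len(self.sequence)
        return f"@{self.name}\n{self.sequence}\n+\n{qual}\n"


def partition_reads(
    profile: EditDistanceProfile, threshold: float
) -> PartitionResult:
    """Flag reads with E strictly greater than the threshold.

    Ties at the threshold stay in the keep-set, so with the nearest-rank
    threshold the realigned fraction never exceeds (100 - p)%.
    """
    realign = {name for name, e in profile.entries if e > threshold}
    keep = profile.read_names - realign
    return PartitionResult(
        threshold=threshold,
        keep_names=keep,
        realign_names=realign,
        n_eligible=len(profile),
        n_unmapped=profile.n_unmapped,
    )


def split_alignments(
    records: Iterable,
    realign_names: set[str],
    profiled_names: Optional[set[str]] = None,
    realign_unmapped: bool = False,
):
    """Route records by read: returns (keep_records, realign_groups).

    All records of a flagged read are grouped for extraction; all records of
    a kept read pass through unchanged.  Unmapped records pass through to
    the keep stream by default, or are grouped for realignment when
    ``realign_unmapped`` is set.  If ``profiled_names`` is given, a mapped
    record whose name is outside that universe raises :class:`OrphanRecord`.
    """
    keep: list = []
    grouped: dict[str, list] = {}
    for rec in records:
        name = rec.query_name
        cat = classify(rec)
        if cat is Category.UNMAPPED:
            if realign_unmapped and name not in realign_names:
                grouped.setdefault(name, []).append(rec)
            elif name in realign_names:
                grouped.setdefault(name, []).append(rec)
            else:
                keep.append(rec)
            continue
        if profiled_names is not None and name not in profiled_names:
            raise OrphanRecord(f"mapped record {name!r} was never profiled")
        if name in realign_names:
            grouped.setdefault(name, []).append(rec)
        else:
            keep.append(rec)
    groups = [ReadRecordGroup(read_name=n, records=r) for n, r in grouped.items()]
    return keep, groups


def _extract_record(record, name: str) -> FastqRecord:
    seq = record.query_sequence
    if seq is None or seq == "*":
        raise ValueError("sequence not stored")
    if any(op == 5 for op, _ in (record.cigartuples or [])):
        raise ValueError("hard-clipped primary")
    qual = getattr(record, "query_qualities_str", None)
    if qual is None:
        import pysam

        q = record.query_qualities
        qual = pysam.qualities_to_qualitystring(q) if q is not None else ""
    if record.flag & FLAG_REVERSE:
        seq = reverse_complement(seq)
        qual = qual[::-1]
    return FastqRecord(name=name, sequence=seq, qualities=qual)


def extract_reads(groups: Iterable[ReadRecordGroup]):
    """Materialize flagged reads as FASTQ records in sequencing orientation.

    Unmapped-only groups are extracted from their unmapped record (which
    stores the read verbatim).  Returns (fastq_records, unextractable),
    where ``unextractable`` lists groups that must fall back to the keep
    stream (fail-soft on hard-clipped or sequence-less primaries).
    """
    fastq: list[FastqRecord] = []
    unextractable: list[ReadRecordGroup] = []
    for group in groups:
        mapped = [r for r in group.records if classify(r) is not Category.UNMAPPED]
        try:
            if mapped:
                fastq.append(_extract_record(group.primary, group.read_name))
            else:
                fastq.append(_extract_record(group.records[0], group.read_name))
        except ValueError:
            unextractable.append(group)
    return fastq, unextractable


def write_fastq(records: Iterable[FastqRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.format())
            n += 1
    return n
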