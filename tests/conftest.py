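"""Shared fixtures: in-memory alignment records and a hermetic end-to-end
mock-mapper scenario built entirely from the synthetic-fixtures module."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from dualmap.alignment_model import AlignmentRecord, parse_cigar
from dualmap.backends import MockBackend, MockPlacement
from dualmap.fixtures import (
    make_reference_sequence,
    simulate_reads,
    write_fasta,
    write_fastq,
)


def record(
    name="r1",
    flag=0,
    cigar="100M",
    nm=None,
    md=None,
    seq=None,
    qual=None,
    ref="chrS",
    pos=0,
    mapq=60,
) -> AlignmentRecord:
    """Terse builder for an in-memory SAM record."""
    tags = {}
    if nm is not None:
        tags["NM"] = nm
    if md is not None:
        tags["MD"] = md
    unmapped = bool(flag & 0x4)
    return AlignmentRecord(
        query_name=name,
        flag=flag,
        reference_name=None if unmapped else ref,
        reference_start=None if unmapped else pos,
        mapping_quality=mapq,
        cigartuples=[] if unmapped else parse_cigar(cigar),
        query_sequence=seq,
        query_qualities_str=qual,
        tags=tags,
    )


@dataclass
class E2ECase:
    """A complete mock-mapper pipeline scenario."""

    reference: Path
    reads_fastq: Path
    fast_backend: MockBackend
    sensitive_backend: MockBackend
    read_names: list[str]
    fast_nm: dict[str, int]
    sensitive_nm: dict[str, int]
    read_length: int
    truths: list


def build_e2e_case(
    tmp_path: Path,
    n_reads: int = 100,
    read_length: int = 500,
    ref_length: int = 20_000,
    seed: int = 11,
    fast_nm=None,
    sensitive_nm=None,
    name_prefix: str = "read",
) -> E2ECase:
    """Error-free reads from a random reference; the mock fast mapper places
    each read at its true origin but with a *prescribed* NM (default:
    distinct values 0..n-1 so E values are all distinct), and the mock
    sensitive mapper re-places flagged reads with NM 0."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    ref_seq = make_reference_sequence(ref_length, 0.45, seed)
    ref_path = write_fasta({"chrS": ref_seq}, tmp_path / "ref.fasta")
    reads, truths = simulate_reads(
        ref_seq, n_reads, read_length, sub_rate=0.0, indel_rate=0.0,
        seed=seed + 1, name_prefix=name_prefix,
    )
    fastq = write_fastq(reads, tmp_path / "reads.fastq")
    names = [name for name, _, _ in reads]
    if fast_nm is None:
        fast_nm = {name: i for i, name in enumerate(names)}
    if sensitive_nm is None:
        sensitive_nm = {name: 0 for name in names}
    fast_manifest = {
        t.name: [
            MockPlacement(
                reference_name="chrS",
                position=t.start,
                cigar=t.cigar,
                nm=fast_nm[t.name],
                reverse=(t.strand == "-"),
            )
        ]
        for t in truths
    }
    sens_manifest = {
        t.name: [
            MockPlacement(
                reference_name="chrS",
                position=t.start,
                cigar=t.cigar,
                nm=sensitive_nm[t.name],
                reverse=(t.strand == "-"),
            )
        ]
        for t in truths
    }
    return E2ECase(
        reference=ref_path,
        reads_fastq=fastq,
        fast_backend=MockBackend(fast_manifest),
        sensitive_backend=MockBackend(sens_manifest),
        read_names=names,
        fast_nm=fast_nm,
        sensitive_nm=sensitive_nm,
        read_length=read_length,
        truths=truths,
    )


@pytest.fixture
def e2e_case(tmp_path):
    return build_e2e_case(tmp_path)
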