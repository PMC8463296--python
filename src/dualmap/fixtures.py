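"""Synthetic inputs for tests and desk-scale experiments.

Everything the pipeline consumes can be generated here, deterministically
from a seed: a random reference contig, an alternative haplotype with
implanted structural variants (>= 50 bp deletions, insertions, inversions,
tandem duplications, and balanced translocations), error-bearing long reads
sampled from a reference, and SAM files whose records carry prescribed
flags, CIGARs and NM values.

The read error model is intentionally simple — i.i.d. substitutions plus
geometric-length indels — because these fixtures exercise pipeline
mechanics (profiling, partitioning, merging), not mapper accuracy.  Each
simulated read carries a truth record with its origin interval, strand,
reference-orientation CIGAR and exact edit count, which lets tests recover
generator parameters from the profiler's output.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .alignment_model import cigar_to_string, parse_cigar, reverse_complement
from .errors import InconsistentManifest, OutOfBounds, OverlapError

BASES = np.array(list("ACGT"))

SV_KINDS = ("DEL", "INS", "INV", "DUP", "TRA")
MIN_SV_LEN = 50


# ---------------------------------------------------------------------------
# reference generation


def make_reference_sequence(length: int, gc: float, seed: int) -> str:
    """Random single-contig sequence with expected GC fraction ``gc``."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=probs))


def write_fasta(sequences: dict[str, str], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, 60))
            fh.write("\n")
    return path


def make_reference(
    length: int, gc: float, seed: int, path: Union[str, Path], name: str = "chrS"
) -> Path:
    """Write a seeded random reference FASTA (60-column wrapped)."""
    return write_fasta({name: make_reference_sequence(length, gc, seed)}, path)


# ---------------------------------------------------------------------------
# structural variant implanting


@dataclass
class SvSpec:
    """One structural variant to implant, in original-reference coordinates."""

    kind: str
    position: int
    length: int
    payload: Optional[str] = None  # INS only
    partner_position: Optional[int] = None  # TRA only

    def __post_init__(self) -> None:
        if self.kind not in SV_KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.length < MIN_SV_LEN:
            raise ValueError(f"SV length must be >= {MIN_SV_LEN} bp")
        if self.kind == "INS":
            if self.payload is None or len(self.payload) != self.length:
                raise ValueError("INS requires a payload of the stated length")
        if self.kind == "TRA" and self.partner_position is None:
            raise ValueError("TRA requires partner_position")

    def intervals(self) -> list[tuple[int, int]]:
        if self.kind == "INS":
            return [(self.position, self.position)]
        if self.kind == "TRA":
            return [
                (self.position, self.position + self.length),
                (self.partner_position, self.partner_position + self.length),
            ]
        return [(self.position, self.position + self.length)]


def implant_svs(
    reference: str, svs: Sequence[SvSpec]
) -> tuple[str, list[dict]]:
    """Apply SVs to a sequence; returns (alt sequence, truth records).

    DEL removes [pos, pos+len); INS inserts the payload at pos; INV
    reverse-complements the interval; DUP inserts a tandem copy; TRA swaps
    two equal-length blocks.  Truth coordinates are 0-based on the original
    reference.  Raises on overlapping or out-of-range intervals.
    """
    edits: list[tuple[int, int, str]] = []  # (start, end, replacement)
    truth: list[dict] = []
    for sv in svs:
        for start, end in sv.intervals():
            if start < 0 or end > len(reference) or start > end:
                raise OutOfBounds(
                    f"{sv.kind} interval [{start}, {end}) outside reference "
                    f"of length {len(reference)}"
                )
        if sv.kind == "DEL":
            edits.append((sv.position, sv.position + sv.length, ""))
        elif sv.kind == "INS":
            edits.append((sv.position, sv.position, sv.payload))
        elif sv.kind == "INV":
            segment = reference[sv.position : sv.position + sv.length]
            edits.append(
                (sv.position, sv.position + sv.length, reverse_complement(segment))
            )
        elif sv.kind == "DUP":
            segment = reference[sv.position : sv.position + sv.length]
            edits.append((sv.position, sv.position + sv.length, segment * 2))
        elif sv.kind == "TRA":
            a, b = sv.position, sv.partner_position
            seg_a = reference[a : a + sv.length]
            seg_b = reference[b : b + sv.length]
            edits.append((a, a + sv.length, seg_b))
            edits.append((b, b + sv.length, seg_a))
        truth.append(
            {
                "kind": sv.kind,
                "position": sv.position,
                "length": sv.length,
                "end": sv.position + (0 if sv.kind == "INS" else sv.length),
                "partner_position": sv.partner_position,
            }
        )
    ordered = sorted(edits, key=lambda e: e[0])
    for (s1, e1, _), (s2, _, _) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise OverlapError(f"implant intervals overlap at {s2}")
    alt = reference
    for start, end, replacement in sorted(edits, key=lambda e: e[0], reverse=True):
        alt = alt[:start] + replacement + alt[end:]
    return alt, truth


def write_sv_truth_bed(truth: Iterable[dict], path: Union[str, Path], contig: str) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in truth:
            fh.write(
                f"{contig}\t{rec['position']}\t{rec['end']}\t"
                f"{rec['kind']}\t{rec['length']}\n"
            )
    return path


def write_sv_truth_vcf(
    truth: Iterable[dict], path: Union[str, Path], contig: str, contig_length: int
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, rec in enumerate(truth, start=1):
            svlen = -rec["length"] if rec["kind"] == "DEL" else rec["length"]
            fh.write(
                f"{contig}\t{rec['position'] + 1}\tsv{i}\tN\t<{rec['kind']}>\t.\t.\t"
                f"SVTYPE={rec['kind']};SVLEN={svlen};END={rec['end'] + 1}\n"
            )
    return path


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadTruth:
    """Where a simulated read came from and what errors it carries.

    ``cigar`` is the read-vs-reference alignment in reference (forward)
    orientation; ``nm`` is its exact edit count (subs + inserted bases +
    deleted bases).
    """

    name: str
    contig: str
    start: int
    end: int  # 0-based half-open on the reference
    strand: str  # "+" or "-"
    cigar: str
    nm: int
    read_length: int


def _sample_read(
    rng: np.random.Generator,
    reference: str,
    start: int,
    target_len: int,
    sub_rate: float,
    indel_rate: float,
) -> Optional[tuple[str, list[tuple[int, int]], int, int]]:
    """Generate one read from ``start``; returns (seq, cigartuples, nm, ref_end)
    or None if the reference ran out before the read was complete."""
    seq: list[str] = []
    ops: list[tuple[int, int]] = []  # numeric cigar, merged as we go
    nm = 0
    ref_pos = start

    def push(op: int, n: int) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    while len(seq) < target_len:
        if indel_rate > 0 and rng.random() < indel_rate:
            g = rng.geometric(0.5)
            if rng.random() < 0.5:  # insertion into the read
                g = min(g, target_len - len(seq))
                seq.extend(rng.choice(BASES, size=g))
                push(1, g)
                nm += g
            else:  # deletion from the reference
                if ref_pos + g > len(reference):
                    return None
                push(2, g)
                nm += g
                ref_pos += g
            continue
        if ref_pos >= len(reference):
            return None
        base = reference[ref_pos]
        if sub_rate > 0 and rng.random() < sub_rate:
            base = str(rng.choice(BASES[BASES != base]))
            nm += 1
        seq.append(base)
        push(0, 1)
        ref_pos += 1
    return "".join(seq), ops, nm, ref_pos


def simulate_reads(
    reference: str,
    n: int,
    read_len: Union[int, tuple[int, int]],
    sub_rate: float,
    indel_rate: float,
    seed: int,
    contig: str = "chrS",
    name_prefix: str = "read",
) -> tuple[list[tuple[str, str, str]], list[ReadTruth]]:
    """Sample ``n`` error-bearing reads uniformly from a reference sequence.

    ``read_len`` is either a fixed length or a (min, max) uniform range.
    Substitutions are i.i.d. per base at ``sub_rate``; indels start at
    ``indel_rate`` per base with geometric(0.5) lengths, insertions and
    deletions equally likely.  Strand is uniform; reverse-strand reads are
    reverse-complemented in the FASTQ while the truth CIGAR stays in
    reference orientation.  Returns ([(name, seq, qual)], [ReadTruth]).
    """
    if not (0 <= sub_rate < 0.5 and 0 <= indel_rate < 0.5):
        raise ValueError("error rates must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    truths: list[ReadTruth] = []
    for i in range(n):
        if isinstance(read_len, tuple):
            target = int(rng.integers(read_len[0], read_len[1] + 1))
        else:
            target = int(read_len)
        if target > len(reference):
            raise ValueError("read length exceeds reference length")
        while True:
            # leave head-room for deletions so the walk rarely falls off
            max_start = max(len(reference) - target - 1, 0)
            start = int(rng.integers(0, max_start + 1))
            sampled = _sample_read(rng, reference, start, target, sub_rate, indel_rate)
            if sampled is not None:
                break
        seq, ops, nm, ref_end = sampled
        strand = "-" if rng.random() < 0.5 else "+"
        out_seq = reverse_complement(seq) if strand == "-" else seq
        name = f"{name_prefix}{i:05d}"
        qual = "I" * len(out_seq)
        reads.append((name, out_seq, qual))
        truths.append(
            ReadTruth(
                name=name,
                contig=contig,
                start=start,
                end=ref_end,
                strand=strand,
                cigar=cigar_to_string(ops),
                nm=nm,
                read_length=len(out_seq),
            )
        )
    return reads, truths


def write_fastq(reads: Iterable[tuple[str, str, str]], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return path


def write_truth_tsv(truths: Iterable[ReadTruth], path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("name\tcontig\tstart\tend\tstrand\tcigar\tnm\tread_length\n")
        for t in truths:
            fh.write(
                f"{t.name}\t{t.contig}\t{t.start}\t{t.end}\t{t.strand}\t"
                f"{t.cigar}\t{t.nm}\t{t.read_length}\n"
            )
    return path


# ---------------------------------------------------------------------------
# SAM fixtures with prescribed edit distances


@dataclass
class SamSpec:
    """One prescribed SAM record for :func:`make_sam_fixture`."""

    name: str
    cigar: str
    nm: Optional[int] = None
    md: Optional[str] = None
    flag: int = 0
    reference_name: str = "chrS"
    position: int = 0
    mapq: int = 60
    sequence: Optional[str] = None  # generated to match the CIGAR if omitted


@dataclass
class FixtureManifest:
    """A reproducible recipe for a SAM fixture file."""

    seed: int
    records: list[SamSpec]
    references: dict[str, int] = field(default_factory=lambda: {"chrS": 100_000})


def make_sam_fixture(manifest: FixtureManifest, path: Union[str, Path]) -> Path:
    """Write a SAM file carrying exactly the manifest's flags/CIGAR/NM.

    Sequences are filled in deterministically from the manifest seed when
    not prescribed.  Raises :class:`InconsistentManifest` when a prescribed
    sequence length disagrees with its CIGAR.
    """
    import pysam

    rng = np.random.default_rng(manifest.seed)
    path = Path(path)
    header = pysam.AlignmentHeader.from_references(
        list(manifest.references), list(manifest.references.values())
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rs in manifest.records:
            rec = pysam.AlignedSegment(header)
            rec.query_name = rs.name
            rec.flag = rs.flag
            unmapped = bool(rs.flag & 0x4)
            if unmapped:
                seq_len = len(rs.sequence) if rs.sequence else 100
                rec.query_sequence = rs.sequence or "".join(
                    rng.choice(BASES, size=seq_len)
                )
                rec.query_qualities = pysam.qualitystring_to_array("I" * seq_len)
                out.write(rec)
                continue
            tuples = parse_cigar(rs.cigar)
            qlen = sum(n for op, n in tuples if op in (0, 1, 4, 7, 8))
            if rs.sequence is not None and len(rs.sequence) != qlen:
                raise InconsistentManifest(
                    f"record {rs.name!r}: sequence length {len(rs.sequence)} "
                    f"!= CIGAR query length {qlen}"
                )
            seq = rs.sequence or "".join(rng.choice(BASES, size=qlen))
            rec.reference_id = header.get_tid(rs.reference_name)
            if rec.reference_id < 0:
                raise InconsistentManifest(
                    f"reference {rs.reference_name!r} not in manifest header"
                )
            rec.reference_start = rs.position
            rec.mapping_quality = rs.mapq
            rec.cigarstring = rs.cigar
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            if rs.nm is not None:
                rec.set_tag("NM", rs.nm)
            if rs.md is not None:
                rec.set_tag("MD", rs.md)
            out.write(rec)
    return path


def distinct_e_manifest(n: int, seed: int = 0, ref_length: int = 100_000) -> FixtureManifest:
    """``n`` primary records with all-distinct E: nm_i = i over a ``n``M CIGAR."""
    records = [
        SamSpec(name=f"fx{i:05d}", cigar=f"{n}M", nm=i, position=i % max(ref_length - n, 1))
        for i in range(n)
    ]
    return FixtureManifest(seed=seed, records=records, references={"chrS": ref_length})
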