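"""Mapper backends: a uniform contract for the fast and sensitive aligners.

The pipeline never implements alignment itself; it invokes an external
long-read mapper through :class:`MapperBackend`.  Two subprocess flavors
are provided — ``minimap2`` (two-piece affine gap penalty, fast) and
``ngmlr`` (convex gap penalty, sensitive, better at SV breakpoints) — plus
a deterministic :class:`MockBackend` driven by an explicit manifest of
placements, which makes end-to-end tests exact and hermetic.

Any mapper that emits the NM tag (or an MD tag it can be reconstructed
from) satisfies the contract, so other fast/sensitive pairs can be slotted
in.
"""

from __future__ import annotations

import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pysam

from .alignment_model import (
    FLAG_REVERSE,
    cigar_to_string,
    parse_cigar,
    reverse_complement,
)
from .errors import (
    BackendFailure,
    InconsistentManifest,
    MissingNM,
    UnsupportedPreset,
)

PRESETS = ("ont", "pacbio_clr", "pacbio_hifi")

_MINIMAP2_PRESETS = {"ont": "map-ont", "pacbio_clr": "map-pb", "pacbio_hifi": "map-hifi"}
_NGMLR_PRESETS = {"ont": "ont", "pacbio_clr": "pacbio", "pacbio_hifi": "pacbio"}


@dataclass
class MapperSpec:
    """How to invoke one mapper: flavor, executable, platform preset."""

    name: str  # "minimap2", "ngmlr", or "mock"
    executable: str = ""
    preset: str = "ont"
    extra_args: list[str] = field(default_factory=list)
    threads: int = 1

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise UnsupportedPreset(
                f"preset {self.preset!r} not one of {PRESETS}"
            )
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if not self.executable and self.name != "mock":
            self.executable = self.name


@dataclass
class MapperResult:
    alignment_path: Path
    n_input_reads: int
    n_records: int
    elapsed: float
    command: list[str] = field(default_factory=list)
    version: str = ""


def preset_args(spec: MapperSpec) -> list[str]:
    """Backend-specific argument list for the platform preset.

    minimap2: ``-ax map-ont|map-pb|map-hifi``; ngmlr: ``-x ont|pacbio``;
    the mock ignores presets.  ``extra_args`` are appended last.
    """
    if spec.name == "mock":
        return []
    if spec.name == "minimap2":
        args = ["-a", "-x", _MINIMAP2_PRESETS[spec.preset], "--MD"]
    elif spec.name == "ngmlr":
        args = ["-x", _NGMLR_PRESETS[spec.preset]]
    else:
        raise UnsupportedPreset(f"no preset table for backend {spec.name!r}")
    return args + list(spec.extra_args)


def count_fastq_reads(path) -> int:
    n = 0
    with pysam.FastxFile(str(path)) as fh:
        for _ in fh:
            n += 1
    return n


def _validate_nm(bam_path: Path) -> None:
    """Require NM (or reconstructible MD) on mapped records."""
    n_mapped = n_tagged = 0
    with pysam.AlignmentFile(str(bam_path), "rb", check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped:
                continue
            n_mapped += 1
            if rec.has_tag("NM") or rec.has_tag("MD"):
                n_tagged += 1
    if n_mapped > 0 and n_tagged == 0:
        raise MissingNM(f"no mapped record in {bam_path} carries NM or MD")


class MapperBackend:
    """Contract: map a FASTQ against a FASTA, produce an unsorted BAM whose
    read-name set is a subset of the input's, with NM on mapped records."""

    spec: MapperSpec

    def map_reads(self, reads: Path, reference: Path, out_bam: Path) -> MapperResult:
        raise NotImplementedError

    def version(self) -> str:
        raise NotImplementedError


class SubprocessBackend(MapperBackend):
    """Invoke a real mapper executable; SAM on stdout is converted to BAM."""

    def __init__(self, spec: MapperSpec):
        self.spec = spec
        if shutil.which(spec.executable) is None:
            raise BackendFailure(f"executable {spec.executable!r} not found on PATH")

    def _command(self, reads: Path, reference: Path) -> list[str]:
        spec = self.spec
        args = [spec.executable] + preset_args(spec) + ["-t", str(spec.threads)]
        if spec.name == "ngmlr":
            args += ["-r", str(reference), "-q", str(reads)]
        else:
            args += [str(reference), str(reads)]
        return args

    def version(self) -> str:
        try:
            out = subprocess.run(
                [self.spec.executable, "--version"],
                capture_output=True,
                text=True,
                timeout=60,
            )
            return out.stdout.strip().splitlines()[0] if out.stdout else "unknown"
        except (OSError, subprocess.TimeoutExpired):
            return "unknown"

    def map_reads(self, reads: Path, reference: Path, out_bam: Path) -> MapperResult:
        cmd = self._command(reads, reference)
        t0 = time.monotonic()
        proc = subprocess.run(cmd, capture_output=True)
        if proc.returncode != 0:
            raise BackendFailure(
                f"{self.spec.name} exited {proc.returncode}",
                stderr=proc.stderr.decode(errors="replace"),
            )
        sam_path = Path(str(out_bam) + ".sam")
        sam_path.write_bytes(proc.stdout)
        try:
            with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam, \
                    pysam.AlignmentFile(str(out_bam), "wb", template=sam) as bam:
                n_records = 0
                for rec in sam:
                    bam.write(rec)
                    n_records += 1
        finally:
            sam_path.unlink(missing_ok=True)
        _validate_nm(out_bam)
        elapsed = time.monotonic() - t0
        return MapperResult(
            alignment_path=out_bam,
            n_input_reads=count_fastq_reads(reads),
            n_records=n_records,
            elapsed=elapsed,
            command=cmd,
            version=self.version(),
        )


@dataclass
class MockPlacement:
    """One scripted alignment for the mock backend.

    ``cigar`` must consume exactly the read length (in sequencing
    orientation).  ``reverse`` stores the record as SAM would: reverse
    complemented sequence, reversed qualities, reversed CIGAR.
    """

    reference_name: str
    position: int
    cigar: str
    nm: int
    reverse: bool = False
    mapq: int = 60
    secondary: bool = False
    supplementary: bool = False


class MockBackend(MapperBackend):
    """Script-driven mapper: manifest maps read name -> list of placements.

    Reads absent from the manifest (or mapped to ``None``) come back as
    unmapped records, mirroring `minimap2 -a` behavior.  Output is exact
    and seed-free, so end-to-end pipeline tests can assert equality.
    """

    def __init__(self, manifest: dict, preset: str = "ont", name: str = "mock"):
        self.spec = MapperSpec(name="mock", executable="", preset=preset)
        self.label = name
        self.manifest = manifest

    def version(self) -> str:
        return "mock-1.0"

    @staticmethod
    def _reference_header(reference: Path) -> pysam.AlignmentHeader:
        names, lengths = [], []
        with pysam.FastxFile(str(reference)) as fh:
            for entry in fh:
                names.append(entry.name)
                lengths.append(len(entry.sequence))
        return pysam.AlignmentHeader.from_references(names, lengths)

    def _build_record(
        self,
        header: pysam.AlignmentHeader,
        name: str,
        seq: str,
        qual: str,
        placement: Optional[MockPlacement],
    ) -> pysam.AlignedSegment:
        rec = pysam.AlignedSegment(header)
        rec.query_name = name
        if placement is None:
            rec.flag = 0x4
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array(qual)
            return rec
        tuples = parse_cigar(placement.cigar)
        consumed = sum(n for op, n in tuples if op in (0, 1, 4, 7, 8))
        if consumed != len(seq):
            raise InconsistentManifest(
                f"CIGAR {placement.cigar} consumes {consumed} bases but read "
                f"{name!r} has {len(seq)}"
            )
        flag = 0
        if placement.reverse:
            flag |= FLAG_REVERSE
            seq = reverse_complement(seq)
            qual = qual[::-1]
            tuples = tuples[::-1]
        if placement.secondary:
            flag |= 0x100
        if placement.supplementary:
            flag |= 0x800
        rec.flag = flag
        rec.reference_id = header.get_tid(placement.reference_name)
        if rec.reference_id < 0:
            raise InconsistentManifest(
                f"reference {placement.reference_name!r} not in header"
            )
        rec.reference_start = placement.position
        rec.mapping_quality = placement.mapq
        rec.cigarstring = cigar_to_string(tuples)
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array(qual)
        rec.set_tag("NM", placement.nm)
        return rec

    def map_reads(self, reads: Path, reference: Path, out_bam: Path) -> MapperResult:
        t0 = time.monotonic()
        header = self._reference_header(reference)
        n_reads = n_records = 0
        with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam, \
                pysam.FastxFile(str(reads)) as fq:
            for entry in fq:
                n_reads += 1
                qual = entry.quality or "I" * len(entry.sequence)
                placements = self.manifest.get(entry.name)
                if not placements:
                    bam.write(
                        self._build_record(header, entry.name, entry.sequence, qual, None)
                    )
                    n_records += 1
                    continue
                for placement in placements:
                    bam.write(
                        self._build_record(
                            header, entry.name, entry.sequence, qual, placement
                        )
                    )
                    n_records += 1
        elapsed = time.monotonic() - t0
        return MapperResult(
            alignment_path=out_bam,
            n_input_reads=n_reads,
            n_records=n_records,
            elapsed=elapsed,
            command=["mock"],
            version=self.version(),
        )


def make_backend(spec: MapperSpec, manifest: Optional[dict] = None) -> MapperBackend:
    if spec.name == "mock":
        return MockBackend(manifest or {}, preset=spec.preset)
    return SubprocessBackend(spec)
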