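"""End-to-end orchestration of the dual-mode mapping pipeline.

Four stages: (1) map all reads with the fast backend, (2) profile the
normalized edit distance of every primary alignment and place a percentile
cut-off (default 90th), (3) extract the reads above the cut-off and realign
them with the sensitive backend, (4) merge the keep-set records with the
realignments into one coordinate-sorted indexed BAM, ready for downstream
SV calling.  A JSON stats report records per-stage durations, fractions,
the threshold, and before/after E distributions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pysam

from .backends import MapperBackend, MapperSpec, make_backend
from .ed_profile import (
    DistributionSummary,
    EditDistanceProfile,
    build_profile,
    percentile_threshold,
    summarize,
)
from .errors import DualmapError
from .merger import MergePlan, merge_bams, verify_merge
from .partitioner import (
    PartitionResult,
    partition_reads,
    split_alignments,
    write_fastq,
)

logger = logging.getLogger("dualmap")


@dataclass
class PipelineConfig:
    reads: Optional[Path] = None
    reference: Optional[Path] = None
    from_bam: Optional[Path] = None  # skip stage 1, profile this BAM instead
    out_bam: Path = Path("dualmap.bam")
    percentile: float = 90.0
    preset: str = "ont"
    backend_fast: Optional[MapperSpec] = None
    backend_sensitive: Optional[MapperSpec] = None
    workdir: Path = Path("dualmap_work")
    threads: int = 1
    keep_intermediates: bool = False
    realign_unmapped: bool = False
    denominator: str = "aligned"

    def __post_init__(self) -> None:
        if not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")
        if self.reads is None and self.from_bam is None:
            raise ValueError("either reads or from_bam must be given")
        if self.backend_fast is None:
            self.backend_fast = MapperSpec(
                name="minimap2", preset=self.preset, threads=self.threads
            )
        if self.backend_sensitive is None:
            self.backend_sensitive = MapperSpec(
                name="ngmlr", preset=self.preset, threads=self.threads
            )


@dataclass
class StatsReport:
    n_reads: int
    n_profiled: int
    n_realigned: int
    realigned_fraction: float
    threshold: float
    percentile: float
    n_unmapped: int
    n_unextractable: int
    summary_before: Optional[DistributionSummary]
    summary_after: Optional[DistributionSummary]
    per_stage_seconds: dict[str, float] = field(default_factory=dict)
    backend_versions: dict[str, str] = field(default_factory=dict)
    denominator: str = "aligned"
    violations: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_profiled": self.n_profiled,
            "n_realigned": self.n_realigned,
            "realigned_fraction": self.realigned_fraction,
            "threshold": self.threshold,
            "percentile": self.percentile,
            "n_unmapped": self.n_unmapped,
            "n_unextractable": self.n_unextractable,
            "denominator": self.denominator,
            "summary_before": self.summary_before.to_dict() if self.summary_before else None,
            "summary_after": self.summary_after.to_dict() if self.summary_after else None,
            "per_stage_seconds": self.per_stage_seconds,
            "backend_versions": self.backend_versions,
            "violations": self.violations,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def profile_bam(
    bam_path: Union[str, Path], source_label: str = "", denominator: str = "aligned"
) -> EditDistanceProfile:
    """Build an edit-distance profile from a BAM/SAM on disk."""
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        return build_profile(bam, source_label=source_label, denominator=denominator)


def _write_keep_bam(
    src_bam: Path,
    keep_path: Path,
    effective_realign: set[str],
    realign_unmapped: bool,
    realigned_unmapped_names: set[str],
) -> set[str]:
    """Second pass: write every record not routed to realignment; returns
    the set of read names written."""
    written: set[str] = set()
    with pysam.AlignmentFile(str(src_bam), check_sq=False) as src, \
            pysam.AlignmentFile(str(keep_path), "wb", template=src) as out:
        for rec in src:
            name = rec.query_name
            if name in effective_realign:
                continue
            if rec.is_unmapped and realign_unmapped and name in realigned_unmapped_names:
                continue
            out.write(rec)
            written.add(name)
    return written


def run_pipeline(
    config: PipelineConfig,
    backend_fast: Optional[MapperBackend] = None,
    backend_sensitive: Optional[MapperBackend] = None,
) -> tuple[Path, StatsReport]:
    """Execute map -> profile -> partition -> extract -> realign -> merge.

    Backend objects may be passed directly (e.g. mocks); otherwise they are
    constructed from the config's MapperSpecs.  Returns the final BAM path
    and the stats report (also written as ``<out>.stats.json``).
    """
    cfg = config
    workdir = Path(cfg.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    versions: dict[str, str] = {}
    intermediates: list[Path] = []

    if backend_fast is None and cfg.from_bam is None:
        backend_fast = make_backend(cfg.backend_fast)

    # stage 1: fast mapping (skipped with --from-bam)
    t0 = time.monotonic()
    if cfg.from_bam is not None:
        bam_a = Path(cfg.from_bam)
        n_reads = None
        logger.info("stage map_fast skipped; profiling %s", bam_a)
    else:
        bam_a = workdir / "fast.bam"
        result_a = backend_fast.map_reads(Path(cfg.reads), Path(cfg.reference), bam_a)
        n_reads = result_a.n_input_reads
        versions[backend_fast.spec.name] = result_a.version
        intermediates.append(bam_a)
        logger.info(
            "stage map_fast: %d reads -> %d records", n_reads, result_a.n_records
        )
    timings["map_fast"] = time.monotonic() - t0

    # stage 2: profile + threshold + partition
    t0 = time.monotonic()
    profile = profile_bam(bam_a, source_label="fast", denominator=cfg.denominator)
    if len(profile) == 0:
        raise DualmapError("no primary mapped records to profile")
    threshold = percentile_threshold(profile, cfg.percentile)
    partition = partition_reads(profile, threshold)
    if n_reads is None:
        n_reads = len(profile) + profile.n_unmapped
    logger.info(
        "stage profile: %d profiled, threshold E=%.4g, %d flagged (%.1f%%)",
        len(profile),
        threshold,
        len(partition.realign_names),
        100 * partition.realign_fraction,
    )
    timings["profile"] = time.monotonic() - t0

    # stage 3a: collect flagged groups and extract FASTQ
    t0 = time.monotonic()
    with pysam.AlignmentFile(str(bam_a), check_sq=False) as bam:
        _, groups = split_alignments(
            (r for r in bam if r.query_name in partition.realign_names
             or (r.is_unmapped and cfg.realign_unmapped)),
            partition.realign_names,
            profiled_names=None,
            realign_unmapped=cfg.realign_unmapped,
        )
    from .partitioner import extract_reads

    fastq_records, unextractable = extract_reads(groups)
    unextractable_names = {g.read_name for g in unextractable}
    effective_realign = {r.name for r in fastq_records}
    realigned_unmapped_names = effective_realign - partition.realign_names
    if unextractable_names:
        logger.warning(
            "%d flagged read(s) unextractable; retained in keep set",
            len(unextractable_names),
        )
    realign_fastq = workdir / "realign.fastq"
    write_fastq(fastq_records, realign_fastq)
    intermediates.append(realign_fastq)

    keep_bam = workdir / "keep.bam"
    keep_names_written = _write_keep_bam(
        bam_a, keep_bam, effective_realign, cfg.realign_unmapped, realigned_unmapped_names
    )
    intermediates.append(keep_bam)
    timings["partition_extract"] = time.monotonic() - t0

    # stage 3b: sensitive realignment
    t0 = time.monotonic()
    realigned_bam: Optional[Path] = None
    pg_lines: list[dict] = []
    if fastq_records:
        realigned_bam = workdir / "realigned.bam"
        if cfg.reference is None:
            raise DualmapError("a reference FASTA is required to realign reads")
        if backend_sensitive is None:
            # constructed lazily: a p=100 run never needs the sensitive mapper
            backend_sensitive = make_backend(cfg.backend_sensitive)
        result_b = backend_sensitive.map_reads(
            realign_fastq, Path(cfg.reference), realigned_bam
        )
        sens_name = backend_sensitive.spec.name
        versions[sens_name] = result_b.version
        pg_lines.append(
            {"ID": sens_name, "PN": sens_name, "CL": " ".join(result_b.command)}
        )
        intermediates.append(realigned_bam)
        logger.info(
            "stage realign: %d reads -> %d records",
            result_b.n_input_reads,
            result_b.n_records,
        )
    timings["realign"] = time.monotonic() - t0

    # stage 4: merge + verify
    t0 = time.monotonic()
    plan = MergePlan(
        keep_bam=keep_bam,
        realigned_bam=realigned_bam,
        expected_keep_names=keep_names_written,
        expected_realign_names=effective_realign,
        out_path=Path(cfg.out_bam),
        pg_lines=pg_lines,
    )
    final_bam = merge_bams(plan)
    violations = verify_merge(final_bam, plan)
    if violations:
        logger.warning("merge verification violations: %s", violations)
    timings["merge"] = time.monotonic() - t0

    # stats
    summary_before = summarize(profile) if len(profile) else None
    profile_after = profile_bam(final_bam, source_label="final", denominator=cfg.denominator)
    summary_after = summarize(profile_after) if len(profile_after) else None
    report = StatsReport(
        n_reads=n_reads,
        n_profiled=len(profile),
        n_realigned=len(fastq_records),
        realigned_fraction=(len(fastq_records) / len(profile) if len(profile) else 0.0),
        threshold=threshold,
        percentile=cfg.percentile,
        n_unmapped=profile.n_unmapped,
        n_unextractable=len(unextractable_names),
        summary_before=summary_before,
        summary_after=summary_after,
        per_stage_seconds=timings,
        backend_versions=versions,
        denominator=cfg.denominator,
        violations=violations,
    )
    report.to_json(Path(str(final_bam) + ".stats.json"))

    if not cfg.keep_intermediates:
        for p in intermediates:
            if p != bam_a or cfg.from_bam is None:
                p.unlink(missing_ok=True)
    return final_bam, report


def compare_profiles(
    bam_a: Union[str, Path],
    bam_b: Union[str, Path, None],
    bam_final: Union[str, Path],
    denominator: str = "aligned",
    bins: int = 50,
) -> dict:
    """Per-source E distribution summaries plus a medians table.

    Emits the distribution comparison used to check that selective
    realignment lowers the final median E relative to the fast mapper
    alone.  Warns (in the returned dict) when read universes differ.
    """
    out: dict = {"sources": {}, "medians": {}, "warnings": []}
    profiles = {}
    labelled = [("fast", bam_a), ("sensitive", bam_b), ("final", bam_final)]
    for label, path in labelled:
        if path is None:
            continue
        prof = profile_bam(path, source_label=label, denominator=denominator)
        profiles[label] = prof
        if len(prof):
            out["sources"][label] = summarize(prof, bins=bins).to_dict()
            out["medians"][label] = out["sources"][label]["median_E"]
        else:
            out["sources"][label] = None
            out["warnings"].append(f"{label}: empty profile")
    if "fast" in profiles and "final" in profiles:
        universe_a = profiles["fast"].read_names
        universe_f = profiles["final"].read_names
        if not (universe_a & universe_f):
            out["warnings"].append("fast and final profiles share no reads")
    return out
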