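"""Merge the keep-set BAM with the sensitive mapper's realignments.

The final artifact is a single coordinate-sorted, indexed BAM: every record
of the keep-set plus every record the sensitive mapper produced for the
flagged reads.  Reads the sensitive mapper failed to map are emitted as
unmapped records rather than dropped, so primary-read counts are conserved
and downstream accounting stays honest.  The @PG chain records both mappers
and this tool.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pysam

from .alignment_model import classify, Category
from .errors import CrossContamination, DuplicatePrimary, HeaderMismatch

_TOOL_NAME = "dualmap"


@dataclass
class MergePlan:
    keep_bam: Path
    realigned_bam: Optional[Path]
    expected_keep_names: set[str]
    expected_realign_names: set[str]
    out_path: Path
    pg_lines: list[dict] = field(default_factory=list)


def _sq_dict(header: pysam.AlignmentHeader) -> list[tuple[str, int]]:
    return [(sq["SN"], sq["LN"]) for sq in header.to_dict().get("SQ", [])]


def _names_in(path: Path) -> set[str]:
    names: set[str] = set()
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for rec in bam:
            names.add(rec.query_name)
    return names


def _extend_pg_chain(header_dict: dict, extra_pg: list[dict]) -> dict:
    """Append @PG entries (tool + sensitive mapper) onto the existing chain."""
    pgs = list(header_dict.get("PG", []))
    used_ids = {pg.get("ID") for pg in pgs}
    prev = pgs[-1]["ID"] if pgs else None
    for entry in extra_pg:
        pg = dict(entry)
        base = pg.get("ID", _TOOL_NAME)
        pg_id, i = base, 1
        while pg_id in used_ids:
            pg_id = f"{base}.{i}"
            i += 1
        pg["ID"] = pg_id
        if prev is not None:
            pg["PP"] = prev
        used_ids.add(pg_id)
        pgs.append(pg)
        prev = pg_id
    header_dict["PG"] = pgs
    return header_dict


def merge_bams(plan: MergePlan) -> Path:
    """Concatenate keep and realigned records, coordinate-sort, and index.

    Raises :class:`HeaderMismatch` on differing @SQ dictionaries and
    :class:`CrossContamination` if any read name occurs in both inputs.
    Flagged reads with no record in the realigned BAM get an unmapped
    placeholder record.
    """
    keep = pysam.AlignmentFile(str(plan.keep_bam), "rb", check_sq=False)
    realigned = None
    if plan.realigned_bam is not None:
        realigned = pysam.AlignmentFile(str(plan.realigned_bam), "rb", check_sq=False)
        if _sq_dict(keep.header) != _sq_dict(realigned.header):
            keep.close()
            realigned.close()
            raise HeaderMismatch("@SQ dictionaries differ between merge inputs")
        overlap = _names_in(plan.keep_bam) & _names_in(plan.realigned_bam)
        if overlap:
            keep.close()
            realigned.close()
            raise CrossContamination(
                f"{len(overlap)} read name(s) present in both inputs, "
                f"e.g. {sorted(overlap)[:3]}"
            )

    header_dict = keep.header.to_dict()
    header_dict = _extend_pg_chain(
        header_dict,
        plan.pg_lines + [{"ID": _TOOL_NAME, "PN": _TOOL_NAME, "CL": "merge"}],
    )
    header = pysam.AlignmentHeader.from_dict(header_dict)

    unsorted = Path(str(plan.out_path) + ".unsorted.bam")
    seen_realigned: set[str] = set()
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as out:
        for rec in keep:
            out.write(rec)
        if realigned is not None:
            for rec in realigned:
                seen_realigned.add(rec.query_name)
                moved = pysam.AlignedSegment.from_dict(rec.to_dict(), header)
                out.write(moved)
            # conserve flagged reads the sensitive mapper dropped entirely
            for name in sorted(plan.expected_realign_names - seen_realigned):
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.flag = 0x4
                out.write(rec)
    keep.close()
    if realigned is not None:
        realigned.close()

    pysam.sort("-o", str(plan.out_path), str(unsorted))
    os.unlink(unsorted)
    pysam.index(str(plan.out_path))
    return plan.out_path


def verify_merge(final_bam: Path, plan: MergePlan) -> list[str]:
    """Post-merge audit; returns a list of violations (empty = pass)."""
    violations: list[str] = []
    if not (Path(str(final_bam) + ".bai").exists() or Path(str(final_bam) + ".csi").exists()):
        violations.append("missing index")
    primaries: set[str] = set()
    all_names: set[str] = set()
    last_key = None
    with pysam.AlignmentFile(str(final_bam), "rb", check_sq=False) as bam:
        sort_order = bam.header.to_dict().get("HD", {}).get("SO")
        if sort_order != "coordinate":
            violations.append("header does not declare coordinate sort")
        for rec in bam:
            all_names.add(rec.query_name)
            if rec.is_unmapped:
                continue
            key = (rec.reference_id, rec.reference_start)
            if last_key is not None and key < last_key:
                violations.append("not coordinate-sorted")
                break
            last_key = key
            if classify(rec) is Category.PRIMARY:
                if rec.query_name in primaries:
                    violations.append(
                        f"duplicate primary for read {rec.query_name!r}"
                    )
                primaries.add(rec.query_name)
    expected = plan.expected_keep_names | plan.expected_realign_names
    missing = expected - all_names
    extra = all_names - expected
    if missing:
        violations.append(f"missing read(s): {sorted(missing)[:5]}")
    if extra:
        violations.append(f"unexpected read(s): {sorted(extra)[:5]}")
    return violations
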