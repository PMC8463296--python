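"""Per-read normalized edit-distance profiles and percentile thresholds.

For each read we keep one number, E = e / l: the edit distance of its
primary alignment divided by that alignment's aligned query length.  Only
primary records contribute — secondary placements typically carry larger
edit distances and would inflate the tail of the profile, and supplementary
records describe split segments rather than whole-read quality.

The percentile cut-off uses the nearest-rank estimator so that the
threshold is always an observed E value; a read is flagged for realignment
iff its E is *strictly greater* than the threshold, which guarantees the
flagged fraction never exceeds (100 - p)%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .alignment_model import (
    Category,
    classify,
    edit_distance_of,
    full_read_length,
    query_alignment_length,
)
from .errors import DuplicatePrimary, EmptyProfile

#: Sentinel threshold strictly below every possible E (E is always >= 0).
SENTINEL_BELOW_MIN = float("-inf")


def normalized_edit_distance(record, denominator: str = "aligned") -> float:
    """E = e / l for one mapped record.

    ``denominator`` selects l: ``"aligned"`` (default) uses the aligned
    query length (CIGAR M/I/=/X); ``"read"`` uses the full read length
    including clips.
    """
    e = edit_distance_of(record)
    if denominator == "aligned":
        l = query_alignment_length(record)
    elif denominator == "read":
        l = full_read_length(record)
        if l == 0:
            l = query_alignment_length(record)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return e / l


@dataclass
class EditDistanceProfile:
    """One E value per read, from its primary mapped record."""

    entries: list[tuple[str, float]] = field(default_factory=list)
    source_label: str = ""
    n_secondary: int = 0
    n_supplementary: int = 0
    n_unmapped: int = 0
    denominator: str = "aligned"

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def read_names(self) -> set[str]:
        return {name for name, _ in self.entries}

    def values(self) -> np.ndarray:
        return np.array([e for _, e in self.entries], dtype=float)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_name\tE\tsource\n")
            for name, e in self.entries:
                fh.write(f"{name}\t{e:.6g}\t{self.source_label}\n")


@dataclass
class DistributionSummary:
    n: int
    median_E: float
    quartiles: tuple[float, float]
    histogram: list[tuple[float, float, int]]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "median_E": self.median_E,
            "q1": self.quartiles[0],
            "q3": self.quartiles[1],
            "histogram": [
                {"left": left, "right": right, "count": count}
                for left, right, count in self.histogram
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_profile(
    alignments: Iterable,
    source_label: str = "",
    denominator: str = "aligned",
) -> EditDistanceProfile:
    """Profile a record stream: one E entry per read, primaries only.

    Secondary, supplementary, and unmapped records are counted but
    contribute no entries.  Raises :class:`DuplicatePrimary` if two primary
    records share a read name.
    """
    profile = EditDistanceProfile(source_label=source_label, denominator=denominator)
    seen: set[str] = set()
    for rec in alignments:
        cat = classify(rec)
        if cat is Category.UNMAPPED:
            profile.n_unmapped += 1
            continue
        if cat is Category.SECONDARY:
            profile.n_secondary += 1
            continue
        if cat is Category.SUPPLEMENTARY:
            profile.n_supplementary += 1
            continue
        name = rec.query_name
        if name in seen:
            raise DuplicatePrimary(f"read {name!r} has more than one primary record")
        seen.add(name)
        profile.entries.append(
            (name, normalized_edit_distance(rec, denominator=denominator))
        )
    return profile


def percentile_threshold(profile: EditDistanceProfile, p: float) -> float:
    """Nearest-rank percentile of the profile's E values.

    Sort E ascending; rank k = ceil(p * n / 100); return E_(k) for k >= 1.
    p = 0 returns :data:`SENTINEL_BELOW_MIN`, which sits strictly below
    every E, so every profiled read is flagged.
    """
    if not 0 <= p <= 100:
        raise ValueError(f"percentile must be in [0, 100], got {p}")
    n = len(profile)
    if n == 0:
        raise EmptyProfile("cannot take a percentile of an empty profile")
    k = math.ceil(p * n / 100)
    if k == 0:
        return SENTINEL_BELOW_MIN
    values = np.sort(profile.values())
    return float(values[k - 1])


def summarize(profile: EditDistanceProfile, bins: int = 50) -> DistributionSummary:
    """Median, quartiles (linear interpolation) and an equal-width histogram
    over [0, max E]; bins are half-open, the last bin closed."""
    if len(profile) == 0:
        raise EmptyProfile("cannot summarize an empty profile")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    values = profile.values()
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    top = float(values.max())
    if top == 0.0:
        top = 1.0  # degenerate all-zero profile: any width works
    counts, edges = np.histogram(values, bins=bins, range=(0.0, top))
    histogram = [
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(bins)
    ]
    return DistributionSummary(
        n=len(profile),
        median_E=float(med),
        quartiles=(float(q1), float(q3)),
        histogram=histogram,
    )
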