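"""Paired-end fragment ingest, length filtering and dyad calling.

Mononucleosome core fragments are reconstructed from properly paired
alignments (or read directly from a 3+-column "fragment BED"), capped at
the aligner's 200 bp insert limit at ingest, restricted to the 136–158 bp
retention window for analysis, and reduced to dyads — the fragment
midpoint, taken as ``start + (length − 1) // 2`` so that even-length
fragments resolve to the left-of-center base.  Dyads are accumulated into
per-position integer count tracks, the substrate for all profile
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

__all__ = [
    "FragmentRecord",
    "FilterPolicy",
    "DyadTrack",
    "IngestReport",
    "read_fragments",
    "filter_by_length",
    "fragment_dyad",
    "build_dyad_track",
    "pool_tracks",
    "write_bedgraph",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment as a 0-based half-open reference interval."""

    reference_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid fragment [{self.start}, {self.end}) on {self.reference_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FilterPolicy:
    """Fragment-length retention policy (all bounds inclusive).

    Defaults: analysis keeps mononucleosome-sized fragments of
    136–158 bp; anything longer than 200 bp is already discarded at
    ingest, mirroring the aligner's insert-size cap.
    """

    min_length: int = 136
    max_length: int = 158
    max_ingest_length: int = 200

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length <= self.max_ingest_length):
            raise ValueError(
                "require 1 <= min_length <= max_length <= max_ingest_length, got "
                f"{self.min_length}/{self.max_length}/{self.max_ingest_length}"
            )


@dataclass
class IngestReport:
    """Counts logged while reading an alignment/fragment file."""

    total_pairs: int = 0
    dropped_overlong: int = 0
    dropped_improper: int = 0
    dropped_cross_reference: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class DyadTrack:
    """Integer dyad counts per reference position for one sample."""

    reference_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if (self.counts < 0).any():
            raise ValueError("dyad counts must be non-negative")

    @property
    def n_dyads(self) -> int:
        return int(self.counts.sum())

    @property
    def reference_length(self) -> int:
        return self.counts.size


def fragment_dyad(fragment: FragmentRecord) -> int:
    """Dyad (midpoint) position of a fragment.

    Even-length fragments have no central base; the convention here
    floors to the left-of-center base, ``start + (length − 1) // 2``.
    The map is translation-equivariant: shifting the fragment by ``k``
    shifts the dyad by ``k``.
    """
    return fragment.start + (fragment.length - 1) // 2


def filter_by_length(
    fragments: Sequence[FragmentRecord], policy: FilterPolicy | None = None
) -> tuple[list[FragmentRecord], list[FragmentRecord]]:
    """Partition fragments into (retained, dropped) by the retention window.

    Retains exactly those with ``min_length <= length <= max_length``,
    preserving input order in both lists.
    """
    policy = policy or FilterPolicy()
    retained: list[FragmentRecord] = []
    dropped: list[FragmentRecord] = []
    for frag in fragments:
        if policy.min_length <= frag.length <= policy.max_length:
            retained.append(frag)
        else:
            dropped.append(frag)
    logger.info(
        "length filter [%d, %d]: retained %d, dropped %d",
        policy.min_length, policy.max_length, len(retained), len(dropped),
    )
    return retained, dropped


def build_dyad_track(
    fragments: Iterable[FragmentRecord] | np.ndarray,
    reference_length: int,
    reference_id: str = "ref",
) -> DyadTrack:
    """Accumulate fragment dyads (or raw dyad positions) into a count track."""
    if isinstance(fragments, np.ndarray):
        dyads = np.asarray(fragments, dtype=np.int64)
    else:
        fragments = list(fragments)
        if fragments:
            reference_id = fragments[0].reference_id
        dyads = np.array([fragment_dyad(f) for f in fragments], dtype=np.int64)
    if dyads.size and (dyads.min() < 0 or dyads.max() >= reference_length):
        raise ValueError("dyad position outside [0, reference_length)")
    counts = np.bincount(dyads, minlength=reference_length)
    return DyadTrack(reference_id, counts)


def pool_tracks(tracks: Sequence[DyadTrack], reference_id: str | None = None) -> DyadTrack:
    """Pool samples by count-wise summation (explicit, never implicit)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    length = tracks[0].reference_length
    if any(t.reference_length != length for t in tracks):
        raise ValueError("cannot pool tracks of differing reference length")
    counts = np.sum([t.counts for t in tracks], axis=0)
    return DyadTrack(reference_id or tracks[0].reference_id, counts)


# ---------------------------------------------------------------------------
# Readers


def read_fragments(
    path: str | Path,
    format: str = "auto",
    policy: FilterPolicy | None = None,
) -> tuple[list[FragmentRecord], IngestReport]:
    """Read fragments from SAM/BAM or fragment BED.

    SAM/BAM: one record per properly paired, mapped pair on a single
    reference, spanning leftmost mate start to rightmost mate end;
    secondary/supplementary alignments are ignored; pairs longer than
    ``policy.max_ingest_length`` are dropped at ingest; mates on
    different references are counted and dropped, not fatal.

    Fragment BED: 3+ whitespace-separated columns, 0-based half-open,
    one fragment per line (the ingest-length cap applies here too).
    """
    policy = policy or FilterPolicy()
    path = Path(path)
    if format == "auto":
        format = "sam_bam" if path.suffix.lower() in {".sam", ".bam", ".cram"} else "fragment_bed"
    if format == "sam_bam":
        return _read_sam(path, policy)
    if format == "fragment_bed":
        return _read_bed(path, policy)
    raise ValueError(f"unknown fragment format {format!r}")


def _read_sam(path: Path, policy: FilterPolicy) -> tuple[list[FragmentRecord], IngestReport]:
    report = IngestReport()
    fragments: list[FragmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            # one visit per pair: count it from the first-in-pair mate
            if read.is_secondary or read.is_supplementary or not read.is_paired:
                continue
            if not read.is_read1:
                continue
            report.total_pairs += 1
            if read.is_unmapped or read.mate_is_unmapped or not read.is_proper_pair:
                report.dropped_improper += 1
                continue
            if read.reference_id != read.next_reference_id:
                report.dropped_cross_reference += 1
                continue
            tlen = abs(read.template_length)
            if tlen == 0:
                report.dropped_improper += 1
                continue
            if tlen > policy.max_ingest_length:
                report.dropped_overlong += 1
                continue
            start = min(read.reference_start, read.next_reference_start)
            fragments.append(
                FragmentRecord(read.reference_name, start, start + tlen)
            )
            report.retained += 1
    _log_report(path, report)
    return fragments, report


def _read_bed(path: Path, policy: FilterPolicy) -> tuple[list[FragmentRecord], IngestReport]:
    report = IngestReport()
    fragments: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                ref, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            report.total_pairs += 1
            frag = FragmentRecord(ref, start, end)
            if frag.length > policy.max_ingest_length:
                report.dropped_overlong += 1
                continue
            fragments.append(frag)
            report.retained += 1
    _log_report(path, report)
    return fragments, report


def _log_report(path: Path, report: IngestReport) -> None:
    logger.info(
        "%s: %d pairs read, %d retained, %d >max ingest length, "
        "%d improper, %d cross-reference",
        path, report.total_pairs, report.retained, report.dropped_overlong,
        report.dropped_improper, report.dropped_cross_reference,
    )


# ---------------------------------------------------------------------------
# Track export


def write_bedgraph(
    path: str | Path,
    reference_id: str,
    values: np.ndarray,
    name: str = "track",
    comments: Sequence[str] = (),
) -> None:
    """Write a per-position track as bedGraph, run-length merging equal values."""
    values = np.asarray(values)
    lines = [f"# {c}" for c in comments]
    lines.append(f'track type=bedGraph name="{name}"')
    n = values.size
    i = 0
    while i < n:
        j = i + 1
        while j < n and values[j] == values[i]:
            j += 1
        v = values[i]
        out = int(v) if float(v).is_integer() else f"{float(v):.6g}"
        lines.append(f"{reference_id}\t{i}\t{j}\t{out}")
        i = j
    Path(path).write_text("\n".join(lines) + "\n")
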