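"""Transgene construct modelling.

A construct is a plasmid-derived reference sequence carrying a minimal
(90 bp) *unc-54* enhancer with two flanking single-insert cloning points
(HindIII upstream, NheI downstream) into which nucleosome-positioning or
-repelling elements are placed, in either orientation.  All downstream
profile reporting uses a signed coordinate axis whose origin is the
enhancer center, so this module also owns the coordinate conventions:

* internally every interval is 0-based, half-open;
* report offset = position − enhancer_center (negative = upstream);
* the center of an interval of length ``L`` starting at ``s`` is
  ``s + L//2``.  For even ``L`` this is the upper-median base, chosen so
  that the 90 bp enhancer spans exactly [−45, +45) on the report axis.
  Where a "no true center" dual report is wanted (even-length elements),
  both flanking positions ``s + L//2 − 1`` and ``s + L//2`` are used.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import numpy as np

__all__ = [
    "Interval",
    "Element",
    "Site",
    "Orientation",
    "ElementInsert",
    "Backbone",
    "ConstructSpec",
    "reverse_complement",
    "assemble_construct",
    "to_report_coordinates",
    "from_report_coordinates",
    "interval_center_positions",
    "homopolymer_element",
    "synthetic_element",
    "placeholder_backbone",
    "minimal_removed_interval",
    "write_construct_fasta",
    "write_elements_bed",
    "read_element_fasta",
    "KNOWN_ELEMENT_LENGTHS",
    "MINIMAL_ENHANCER_LENGTH",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Element lengths that are fixed by definition and enforced on use.
KNOWN_ELEMENT_LENGTHS: dict[str, int] = {
    "PRS-322": 70,
    "Trifonov": 166,
    "polyA20": 20,
    "polyT5": 5,
    "A5cA5": 11,
}

MINIMAL_ENHANCER_LENGTH = 90

HINDIII_SITE = "AAGCTT"
NHEI_SITE = "GCTAGC"


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an ACGT string.

    Raises ``ValueError`` naming the offending position for any
    character outside {A, C, G, T}.
    """
    for i, ch in enumerate(seq):
        if ch not in _DNA:
            raise ValueError(
                f"non-ACGT character {ch!r} at position {i} in sequence"
            )
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, what: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in _DNA:
            raise ValueError(f"non-ACGT character {ch!r} at position {i} in {what}")


@dataclass(frozen=True)
class Interval:
    """0-based, half-open reference interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, k: int) -> "Interval":
        return Interval(self.start + k, self.end + k)

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


def interval_center_positions(interval: Interval) -> list[int]:
    """Center position(s) of an interval.

    Odd length: the single central base.  Even length: the two bases
    flanking the (inter-base) center, lower first.
    """
    L = len(interval)
    if L == 0:
        raise ValueError("empty interval has no center")
    c = interval.start + L // 2
    if L % 2 == 1:
        return [c]
    return [c - 1, c]


@dataclass(frozen=True)
class Element:
    """A named DNA element to be inserted into a construct."""

    name: str
    sequence: str
    declared_length: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _validate_dna(self.sequence, f"element {self.name!r}")
        if self.declared_length is not None and len(self.sequence) != self.declared_length:
            raise ValueError(
                f"element {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared_length {self.declared_length}"
            )
        known = KNOWN_ELEMENT_LENGTHS.get(self.name)
        if known is not None and len(self.sequence) != known:
            raise ValueError(
                f"element {self.name!r} must be {known} bp, got {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def homopolymer_element(name: str) -> Element:
    """Build one of the literal homopolymeric repelling elements."""
    sequences = {
        "polyA20": "A" * 20,
        "polyT5": "T" * 5,
        "A5cA5": "AAAAA" + "C" + "AAAAA",
    }
    if name not in sequences:
        raise ValueError(f"unknown homopolymer element {name!r}")
    return Element(name, sequences[name])


def synthetic_element(name: str, length: int, seed: int = 0) -> Element:
    """A synthetic stand-in element: a seeded random ACGT sequence.

    Used by the simulator presets for elements (e.g. Widom 601,
    PRS-322) whose true sequence must otherwise be supplied as a FASTA
    config input; only the length and position of the element matter to
    the dyad statistics, not its base composition.
    """
    name_key = zlib.crc32(name.encode("utf-8"))
    rng = np.random.default_rng(np.random.SeedSequence([seed, length, name_key]))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Element(name, seq, declared_length=length)


class Site(str, Enum):
    """Single-insert cloning site relative to the minimal enhancer."""

    UPSTREAM_HINDIII = "upstream_HindIII"
    DOWNSTREAM_NHEI = "downstream_NheI"


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class ElementInsert:
    element: Element
    site: Site
    orientation: Orientation

    @property
    def inserted_sequence(self) -> str:
        if self.orientation is Orientation.REVERSE:
            return reverse_complement(self.element.sequence)
        return self.element.sequence


@dataclass(frozen=True)
class Backbone:
    """Backbone sequence with two marked insertion points flanking the enhancer."""

    sequence: str
    upstream_point: int
    downstream_point: int
    enhancer_interval: Interval

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _validate_dna(self.sequence, "backbone")
        n = len(self.sequence)
        if not (0 <= self.upstream_point <= self.enhancer_interval.start):
            raise ValueError("upstream insertion point must lie at or before the enhancer")
        if not (self.enhancer_interval.end <= self.downstream_point <= n):
            raise ValueError("downstream insertion point must lie at or after the enhancer")


@dataclass(frozen=True)
class AnnotatedElement:
    """An element as placed on an assembled construct."""

    interval: Interval
    orientation: Orientation
    element: Element


@dataclass(frozen=True)
class ConstructSpec:
    """A fully assembled construct with element annotations.

    ``element_intervals`` maps an element label to its placement.  The
    label is the element name, disambiguated with ``.upstream`` /
    ``.downstream`` suffixes when the same element occupies both sites.
    """

    name: str
    sequence: str
    enhancer_interval: Interval
    inserts: tuple[ElementInsert, ...]
    element_intervals: Mapping[str, AnnotatedElement]

    def __post_init__(self) -> None:
        intervals = [a.interval for a in self.element_intervals.values()]
        intervals.append(self.enhancer_interval)
        for i, a in enumerate(intervals):
            for b in intervals[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"overlapping annotated intervals {a} and {b}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def enhancer_center(self) -> int:
        return self.enhancer_interval.start + len(self.enhancer_interval) // 2

    def element_labels(self, element_name: str) -> list[str]:
        """All labels referring to ``element_name`` (one per placement)."""
        labels = [
            lbl
            for lbl in self.element_intervals
            if lbl == element_name or lbl.rsplit(".", 1)[0] == element_name
        ]
        if not labels:
            raise KeyError(f"element {element_name!r} not annotated on {self.name}")
        return labels


def assemble_construct(
    name: str, backbone: Backbone, inserts: Sequence[ElementInsert]
) -> ConstructSpec:
    """Place element inserts into the backbone's cloning points.

    Reverse-oriented inserts are reverse-complemented before insertion.
    At most one insert per site.  The assembled length equals the
    backbone length plus the summed insert lengths, and every recorded
    element interval slices out of the assembled sequence exactly.
    """
    by_site: dict[Site, ElementInsert] = {}
    for ins in inserts:
        if ins.site in by_site:
            raise ValueError(f"two inserts at site {ins.site.value!r}")
        by_site[ins.site] = ins

    up = by_site.get(Site.UPSTREAM_HINDIII)
    down = by_site.get(Site.DOWNSTREAM_NHEI)
    up_seq = up.inserted_sequence if up else ""
    down_seq = down.inserted_sequence if down else ""
    p, q = backbone.upstream_point, backbone.downstream_point

    sequence = (
        backbone.sequence[:p]
        + up_seq
        + backbone.sequence[p:q]
        + down_seq
        + backbone.sequence[q:]
    )

    lu = len(up_seq)
    placements: dict[Site, AnnotatedElement] = {}
    if up:
        placements[Site.UPSTREAM_HINDIII] = AnnotatedElement(
            Interval(p, p + lu), up.orientation, up.element
        )
    if down:
        placements[Site.DOWNSTREAM_NHEI] = AnnotatedElement(
            Interval(q + lu, q + lu + len(down_seq)), down.orientation, down.element
        )

    names = [ins.element.name for ins in by_site.values()]
    need_suffix = len(names) == 2 and names[0] == names[1]
    suffix = {Site.UPSTREAM_HINDIII: ".upstream", Site.DOWNSTREAM_NHEI: ".downstream"}
    element_intervals = {
        (ann.element.name + suffix[site] if need_suffix else ann.element.name): ann
        for site, ann in placements.items()
    }

    return ConstructSpec(
        name=name,
        sequence=sequence,
        enhancer_interval=backbone.enhancer_interval.shift(lu),
        inserts=tuple(inserts),
        element_intervals=element_intervals,
    )


def to_report_coordinates(spec: ConstructSpec, position: int) -> int:
    """Signed enhancer-centered offset of an internal reference position."""
    if not (0 <= position < len(spec)):
        raise ValueError(
            f"position {position} outside [0, {len(spec)}) on {spec.name}"
        )
    return position - spec.enhancer_center


def from_report_coordinates(spec: ConstructSpec, offset: int) -> int:
    """Inverse of :func:`to_report_coordinates`."""
    position = offset + spec.enhancer_center
    if not (0 <= position < len(spec)):
        raise ValueError(f"offset {offset} maps outside {spec.name}")
    return position


def minimal_removed_interval(spec: ConstructSpec) -> Interval:
    """Smallest contiguous interval covering the enhancer and all inserts.

    This is the default interval excised for flank-aligned comparisons
    between constructs carrying different-length inserts.
    """
    intervals = [spec.enhancer_interval] + [
        a.interval for a in spec.element_intervals.values()
    ]
    return Interval(min(i.start for i in intervals), max(i.end for i in intervals))


# ---------------------------------------------------------------------------
# Placeholder backbone


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def placeholder_backbone(
    upstream_flank: int = 1200,
    downstream_flank: int = 1200,
    upstream_gap: int = 3,
    downstream_gap: int = 3,
) -> Backbone:
    """A synthetic ~2.5 kb backbone with marked HindIII/NheI points.

    The full pPD151.79-derived plasmid sequence is not public in a
    machine-readable form, so the package ships this deterministic
    synthetic stand-in: a seeded random sequence with an AAGCTT
    (HindIII) site, a synthetic 90 bp minimal-enhancer placeholder, and
    a GCTAGC (NheI) site.  Insertion points sit ``upstream_gap`` /
    ``downstream_gap`` bases from the enhancer edges (distances in the
    real plasmid are not published and are therefore configurable).
    """
    rng = np.random.default_rng(20221129)
    enhancer = _random_dna(rng, MINIMAL_ENHANCER_LENGTH)
    up = _random_dna(rng, upstream_flank)
    gap_up = _random_dna(rng, upstream_gap)
    gap_down = _random_dna(rng, downstream_gap)
    down = _random_dna(rng, downstream_flank)

    prefix = up + HINDIII_SITE
    upstream_point = len(prefix)
    enh_start = upstream_point + upstream_gap
    enh = Interval(enh_start, enh_start + MINIMAL_ENHANCER_LENGTH)
    downstream_point = enh.end + downstream_gap
    sequence = prefix + gap_up + enhancer + gap_down + NHEI_SITE + down
    return Backbone(sequence, upstream_point, downstream_point, enh)


# ---------------------------------------------------------------------------
# FASTA / BED I/O


def read_element_fasta(path: str | Path, name: str | None = None) -> Element:
    """Read a single-record FASTA as an Element (name defaults to record id)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    return Element(name or rec.id, str(rec.seq))


def write_construct_fasta(spec: ConstructSpec, path: str | Path) -> None:
    rec = SeqRecord(Seq(spec.sequence), id=spec.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_elements_bed(spec: ConstructSpec, path: str | Path) -> None:
    """Element + enhancer annotations as 6-column BED (strand = orientation)."""
    lines = []
    rows: list[tuple[Interval, str, str]] = [
        (spec.enhancer_interval, "unc-54_minimal_enhancer", "+")
    ]
    for label, ann in spec.element_intervals.items():
        strand = "+" if ann.orientation is Orientation.FORWARD else "-"
        rows.append((ann.interval, label, strand))
    rows.sort(key=lambda r: r[0].start)
    for iv, label, strand in rows:
        lines.append(f"{spec.name}\t{iv.start}\t{iv.end}\t{label}\t0\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")
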