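"""Synthetic MNase-seq data generator for transgene arrays.

Generates everything the pipeline ingests, with full statistical
control and a single seed: a construct reference (FASTA), paired-end
mononucleosome fragments (fragment BED and a minimal valid SAM), and a
JSON manifest of every parameter.

The generative model is an explicit invention for testing, not a
biophysical model: dyads are drawn from a mixture of

* **positioned sites** — discretized-normal jitter around a fixed dyad
  position (a strong-positioning element such as Widom 601 behaves like
  a high-weight, low-jitter site);
* **background** — uniform over the reference, with per-position
  density multiplied by the factor of any covering **depletion zone**
  (a repelling element behaves like a near-zero factor zone);

and fragment lengths follow a discrete law on [130, 210] bp (default: a
rounded normal, mean 147 sd 6) that deliberately spans beyond the
136–158 bp retention window so the length filter is always exercised.
The in vivo array's 70–300 tandem copies collapse onto a single probe
reference during hybridization, so the simulator models one copy and
scales ``n_fragments`` instead.

All randomness flows from the one seed through per-operation stream
splits, so dyad simulation and fragment-length assignment are
independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from scipy.stats import norm

from .constructs import (
    ConstructSpec,
    ElementInsert,
    Interval,
    Orientation,
    Site,
    assemble_construct,
    homopolymer_element,
    minimal_removed_interval,
    placeholder_backbone,
    synthetic_element,
    write_construct_fasta,
)
from .fragments import FragmentRecord, fragment_dyad

__all__ = [
    "PositionedSite",
    "DepletionZone",
    "FragmentLengthLaw",
    "SimulationParams",
    "simulate_dyads",
    "dyads_to_fragments",
    "write_dataset",
    "preset_experiment",
    "PRESET_NAMES",
]

# stream-split codes: one sub-stream per stochastic operation
_STREAM_DYADS = 0
_STREAM_LENGTHS = 1


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class PositionedSite:
    """A preferred dyad position with Gaussian (discretized) jitter."""

    dyad_position: int
    weight: float
    jitter_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError("site weight must be finite and >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class DepletionZone:
    """An interval whose background dyad density is multiplied by ``factor``."""

    interval: Interval
    factor: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.factor <= 1.0):
            raise ValueError("depletion factor must lie in [0, 1]")


@dataclass(frozen=True)
class FragmentLengthLaw:
    """Discrete fragment-length distribution on a contiguous support."""

    lengths: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.probs) or not self.lengths:
            raise ValueError("lengths and probs must be equal-length and non-empty")
        p = np.asarray(self.probs)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("probs must be non-negative and sum to 1")

    @classmethod
    def truncated_normal(
        cls, mean: float = 147.0, sd: float = 6.0, low: int = 130, high: int = 210
    ) -> "FragmentLengthLaw":
        """Rounded normal truncated to [low, high] (the default MNase-like law)."""
        lengths = np.arange(low, high + 1)
        p = norm.cdf(lengths + 0.5, mean, sd) - norm.cdf(lengths - 0.5, mean, sd)
        p /= p.sum()
        return cls(tuple(int(l) for l in lengths), tuple(float(x) for x in p))

    @classmethod
    def constant(cls, length: int) -> "FragmentLengthLaw":
        return cls((length,), (1.0,))

    def mass(self, low: int, high: int) -> float:
        """Probability mass on lengths in [low, high] (inclusive)."""
        return float(
            sum(p for l, p in zip(self.lengths, self.probs) if low <= l <= high)
        )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(np.asarray(self.lengths), size=n, p=np.asarray(self.probs))

    @property
    def mean(self) -> float:
        return float(np.dot(self.lengths, self.probs))


@dataclass(frozen=True)
class SimulationParams:
    """Complete specification of one synthetic sample."""

    construct: ConstructSpec
    sites: tuple[PositionedSite, ...] = ()
    zones: tuple[DepletionZone, ...] = ()
    background_weight: float = 1.0
    n_fragments: int = 10_000
    length_law: FragmentLengthLaw = field(
        default_factory=FragmentLengthLaw.truncated_normal
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")
        if self.background_weight < 0:
            raise ValueError("background_weight must be >= 0")
        total = self.background_weight + sum(s.weight for s in self.sites)
        if total <= 0:
            raise ValueError("background_weight + site weights must be positive")
        n = len(self.construct)
        for s in self.sites:
            if not (0 <= s.dyad_position < n):
                raise ValueError(f"site dyad position {s.dyad_position} out of range")
        for z in self.zones:
            if z.interval.end > n:
                raise ValueError(f"zone {z.interval} extends past the reference")

    @property
    def reference_length(self) -> int:
        return len(self.construct)

    def as_dict(self) -> dict:
        return {
            "construct": self.construct.name,
            "reference_length": self.reference_length,
            "sites": [
                {"dyad_position": s.dyad_position, "weight": s.weight,
                 "jitter_sd": s.jitter_sd}
                for s in self.sites
            ],
            "zones": [
                {"start": z.interval.start, "end": z.interval.end, "factor": z.factor}
                for z in self.zones
            ],
            "background_weight": self.background_weight,
            "n_fragments": self.n_fragments,
            "length_law": {
                "lengths": [self.length_law.lengths[0], self.length_law.lengths[-1]],
                "mean": self.length_law.mean,
            },
            "seed": self.seed,
        }


def _background_density(params: SimulationParams) -> np.ndarray:
    density = np.ones(params.reference_length)
    for zone in params.zones:
        density[zone.interval.start:zone.interval.end] *= zone.factor
    return density


def simulate_dyads(params: SimulationParams) -> np.ndarray:
    """Draw ``n_fragments`` dyad positions from the mixture model.

    Each dyad independently comes from a positioned site (probability
    proportional to its weight; discretized-normal jitter, resampled if
    it falls off the reference) or from the zone-modulated uniform
    background (probability proportional to ``background_weight``;
    rejection sampling against the per-position density).  Fully
    reproducible from ``params.seed``.
    """
    rng = _rng(params.seed, _STREAM_DYADS)
    n = params.n_fragments
    ref_len = params.reference_length
    weights = np.array([s.weight for s in params.sites] + [params.background_weight])
    components = rng.choice(weights.size, size=n, p=weights / weights.sum())

    out = np.empty(n, dtype=np.int64)
    for i, site in enumerate(params.sites):
        idx = np.flatnonzero(components == i)
        if idx.size == 0:
            continue
        # sd=0 still flows through the normal draw (scale is applied after
        # the underlying standard-normal variates), so simulations that
        # differ only in jitter_sd share all other randomness for a seed.
        pos = np.rint(
            site.dyad_position + rng.normal(0.0, site.jitter_sd, size=idx.size)
        ).astype(np.int64)
        bad = (pos < 0) | (pos >= ref_len)
        while bad.any():  # resample off-reference jitter draws
            pos[bad] = np.rint(
                site.dyad_position + rng.normal(0.0, site.jitter_sd, size=int(bad.sum()))
            ).astype(np.int64)
            bad = (pos < 0) | (pos >= ref_len)
        out[idx] = pos

    bg_idx = np.flatnonzero(components == len(params.sites))
    if bg_idx.size:
        density = _background_density(params)
        if density.max() <= 0:
            raise ValueError("background requested but density is zero everywhere")
        accepted = np.empty(bg_idx.size, dtype=np.int64)
        need = np.arange(bg_idx.size)
        while need.size:  # rejection sampling against the zone-modulated density
            cand = rng.integers(0, ref_len, size=need.size)
            keep = rng.random(need.size) < density[cand]
            accepted[need[keep]] = cand[keep]
            need = need[~keep]
        out[bg_idx] = accepted
    return out


def dyads_to_fragments(
    dyads: np.ndarray, params: SimulationParams
) -> tuple[list[FragmentRecord], int]:
    """Wrap each dyad in a fragment drawn from the length law.

    The fragment is laid out as ``[d − (L−1)//2, d − (L−1)//2 + L)`` so
    that :func:`nucprofile.fragments.fragment_dyad` inverts the
    construction exactly for every length.  Fragments extending past
    either reference end are discarded; the discard count is returned.
    """
    rng = _rng(params.seed, _STREAM_LENGTHS)
    dyads = np.asarray(dyads, dtype=np.int64)
    lengths = params.length_law.sample(rng, dyads.size)
    starts = dyads - (lengths - 1) // 2
    ends = starts + lengths
    ok = (starts >= 0) & (ends <= params.reference_length)
    name = params.construct.name
    fragments = [
        FragmentRecord(name, int(s), int(e))
        for s, e in zip(starts[ok], ends[ok])
    ]
    return fragments, int((~ok).sum())


# ---------------------------------------------------------------------------
# Dataset writer


def write_dataset(
    construct: ConstructSpec,
    fragments: Sequence[FragmentRecord],
    out_prefix: str | Path,
    read_length: int = 25,
    params: SimulationParams | None = None,
) -> dict[str, Path]:
    """Write reference FASTA, fragment BED, minimal SAM and a manifest.

    The SAM holds one properly paired record pair per fragment with
    fixed-length reads (default 25 bp, mirroring short paired-end
    sequencing) at the fragment ends and template length ± the fragment
    length, so BED and SAM ingest to identical fragment multisets.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_prefix.with_suffix(".fasta"),
        "bed": out_prefix.with_suffix(".bed"),
        "sam": out_prefix.with_suffix(".sam"),
    }
    write_construct_fasta(construct, paths["fasta"])

    with open(paths["bed"], "w") as bed:
        for frag in fragments:
            bed.write(f"{frag.reference_id}\t{frag.start}\t{frag.end}\n")

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": construct.name, "LN": len(construct)}],
    }
    seq = construct.sequence
    with pysam.AlignmentFile(str(paths["sam"]), "w", header=header) as sam:
        for i, frag in enumerate(fragments):
            rl = min(read_length, frag.length)
            r1 = pysam.AlignedSegment(sam.header)
            r1.query_name = f"frag{i:07d}"
            r1.flag = 99  # paired, proper, mate reverse, first in pair
            r1.reference_id = 0
            r1.reference_start = frag.start
            r1.mapping_quality = 60
            r1.cigartuples = [(0, rl)]
            r1.next_reference_id = 0
            r1.next_reference_start = frag.end - rl
            r1.template_length = frag.length
            r1.query_sequence = seq[frag.start:frag.start + rl]
            r2 = pysam.AlignedSegment(sam.header)
            r2.query_name = r1.query_name
            r2.flag = 147  # paired, proper, reverse, second in pair
            r2.reference_id = 0
            r2.reference_start = frag.end - rl
            r2.mapping_quality = 60
            r2.cigartuples = [(0, rl)]
            r2.next_reference_id = 0
            r2.next_reference_start = frag.start
            r2.template_length = -frag.length
            r2.query_sequence = seq[frag.end - rl:frag.end]
            sam.write(r1)
            sam.write(r2)

    if params is not None:
        manifest = paths["manifest"] = out_prefix.with_suffix(".json")
        manifest.write_text(json.dumps(params.as_dict(), indent=2) + "\n")
    return paths


# ---------------------------------------------------------------------------
# Presets


PRESET_NAMES = ("control", "positioning_601_like", "repelling_PRS_like", "deboer_like")


def preset_experiment(
    name: str, n_fragments: int = 50_000, seed: int = 0
) -> SimulationParams:
    """Fully specified simulation over the placeholder construct.

    * ``control`` — uniform background only, no sites or zones (an
      insert-free enhancer-only construct).
    * ``positioning_601_like`` — a 147 bp synthetic "601" stand-in at
      both cloning sites, each a strong low-jitter positioned site over
      50% background (both-sites forward positioning layout).
    * ``repelling_PRS_like`` — a 70 bp synthetic "PRS-322" stand-in
      forward upstream / reverse downstream, with a factor-0.01
      depletion zone over elements + enhancer (near-complete
      exclusion).
    * ``deboer_like`` — the 11 bp A5cA5 homopolymer downstream only,
      with a moderate (factor 0.5) depletion zone reaching ~150 bp
      upstream across the enhancer (one-sided depletion).

    Element sequences other than the homopolymers are seeded synthetic
    stand-ins; only their lengths and placements shape the statistics.
    """
    backbone = placeholder_backbone()
    if name == "control":
        construct = assemble_construct("control", backbone, [])
        return SimulationParams(
            construct, background_weight=1.0, n_fragments=n_fragments, seed=seed
        )
    if name == "positioning_601_like":
        el = synthetic_element("601", 147)
        construct = assemble_construct(
            "positioning_601_like",
            backbone,
            [
                ElementInsert(el, Site.UPSTREAM_HINDIII, Orientation.FORWARD),
                ElementInsert(el, Site.DOWNSTREAM_NHEI, Orientation.FORWARD),
            ],
        )
        sites = tuple(
            PositionedSite(
                dyad_position=ann.interval.start + len(ann.interval) // 2,
                weight=0.25,
                jitter_sd=3.0,
            )
            for _, ann in sorted(
                construct.element_intervals.items(),
                key=lambda kv: kv[1].interval.start,
            )
        )
        return SimulationParams(
            construct, sites=sites, background_weight=0.5,
            n_fragments=n_fragments, seed=seed,
        )
    if name == "repelling_PRS_like":
        el = synthetic_element("PRS-322", 70)
        construct = assemble_construct(
            "repelling_PRS_like",
            backbone,
            [
                ElementInsert(el, Site.UPSTREAM_HINDIII, Orientation.FORWARD),
                ElementInsert(el, Site.DOWNSTREAM_NHEI, Orientation.REVERSE),
            ],
        )
        zone = DepletionZone(minimal_removed_interval(construct), factor=0.01)
        return SimulationParams(
            construct, zones=(zone,), background_weight=1.0,
            n_fragments=n_fragments, seed=seed,
        )
    if name == "deboer_like":
        el = homopolymer_element("A5cA5")
        construct = assemble_construct(
            "deboer_like",
            backbone,
            [ElementInsert(el, Site.DOWNSTREAM_NHEI, Orientation.REVERSE)],
        )
        ann = construct.element_intervals["A5cA5"]
        zone = DepletionZone(
            Interval(max(0, ann.interval.start - 150), ann.interval.end), factor=0.5
        )
        return SimulationParams(
            construct, zones=(zone,), background_weight=1.0,
            n_fragments=n_fragments, seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
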