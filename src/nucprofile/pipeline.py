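"""End-to-end analysis pipeline: alignments in, tables and tracks out.

For every sample: ingest → length filter → dyad track → raw and
normalized occupancy → positioning profile.  Then, across samples:
enhancer-region total occupancy with ratio to the control construct,
per-element positioning scores at element centers, flank-aligned
occupancy for cross-construct comparison, and the array coverage
estimate.  The pipeline is a pure function of (config, input files):
identical inputs give byte-identical outputs, and every table carries a
provenance header (parameters, package version, input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, DataError, RunConfig, validate_config
from .constructs import ConstructSpec, minimal_removed_interval, to_report_coordinates
from .fragments import (
    DyadTrack,
    FragmentRecord,
    IngestReport,
    build_dyad_track,
    filter_by_length,
    pool_tracks,
    read_fragments,
    write_bedgraph,
)
from .profiles import (
    OccupancyProfile,
    PositioningProfile,
    align_flanking_profiles,
    estimate_array_coverage,
    normalize_occupancy,
    occupancy_from_dyads,
    positioning_at_element,
    positioning_scores,
    ratio_to_control,
    region_total_occupancy,
)

__all__ = ["PipelineResult", "run_pipeline", "read_table"]

logger = logging.getLogger(__name__)


@dataclass
class UnitResult:
    """Profiles for one analysis unit (a sample, or a pooled construct)."""

    unit_id: str
    construct: ConstructSpec
    track: DyadTrack
    occupancy_raw: OccupancyProfile
    occupancy_norm: OccupancyProfile
    positioning: PositioningProfile
    mapped_pairs: int
    mean_fragment_length: float


@dataclass
class PipelineResult:
    output_dir: Path
    units: dict[str, UnitResult]
    occupancy_summary: pd.DataFrame
    element_positioning: pd.DataFrame
    flank_comparison: pd.DataFrame
    coverage: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _provenance(config: RunConfig) -> list[str]:
    lines = [
        f"nucprofile {__version__}",
        f"filter: min={config.filter_policy.min_length} "
        f"max={config.filter_policy.max_length} "
        f"ingest_cap={config.filter_policy.max_ingest_length}",
        f"windows: half_footprint={config.windows.half_footprint} "
        f"inner_half={config.windows.inner_half} outer_half={config.windows.outer_half}",
        f"normalization: {config.normalization_method}",
        f"control: {config.control}",
    ]
    for s in config.samples:
        lines.append(f"input {s.sample_id}: {s.alignments.name} sha256={_sha256(s.alignments)}")
    return lines


def _write_table(df: pd.DataFrame, path: Path, provenance: list[str]) -> None:
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Re-read a pipeline TSV (skipping its provenance header)."""
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Raises :class:`ConfigError` for configuration problems and
    :class:`DataError` for unusable inputs.
    """
    fatal = [f for f in validate_config(config) if f.fatal]
    if fatal:
        raise ConfigError("; ".join(f.message for f in fatal))

    out_dir = config.output_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = _provenance(config)

    # --- per-sample ingest ------------------------------------------------
    per_sample: dict[str, tuple[DyadTrack, IngestReport, float]] = {}
    ingest_rows = []
    for s in config.samples:
        spec = config.constructs[s.construct]
        try:
            fragments, report = read_fragments(s.alignments, policy=config.filter_policy)
        except (OSError, ValueError) as exc:
            raise DataError(f"sample {s.sample_id!r}: cannot ingest {s.alignments}: {exc}")
        retained, dropped = filter_by_length(fragments, config.filter_policy)
        mean_len = float(np.mean([f.length for f in fragments])) if fragments else 0.0
        track = build_dyad_track(retained, len(spec), spec.name)
        per_sample[s.sample_id] = (track, report, mean_len)
        ingest_rows.append({
            "sample": s.sample_id,
            "construct": s.construct,
            "total_pairs": report.total_pairs,
            "dropped_overlong": report.dropped_overlong,
            "dropped_improper": report.dropped_improper,
            "dropped_cross_reference": report.dropped_cross_reference,
            "ingested": report.retained,
            "retained_in_window": len(retained),
            "dropped_by_window": len(dropped),
            "dyads": track.n_dyads,
        })

    # --- analysis units (optionally pooled by construct) ------------------
    units: dict[str, UnitResult] = {}
    if config.pool_by_construct:
        by_construct: dict[str, list[str]] = {}
        for s in config.samples:
            by_construct.setdefault(s.construct, []).append(s.sample_id)
        groups = [(cname, sids) for cname, sids in by_construct.items()]
    else:
        groups = [(s.construct, [s.sample_id]) for s in config.samples]
        if len({sid for _, sids in groups for sid in sids}) != len(groups):
            raise ConfigError("duplicate sample ids in manifest")

    for label, sids in groups:
        unit_id = label if config.pool_by_construct else sids[0]
        spec = config.constructs[label]
        track = pool_tracks([per_sample[sid][0] for sid in sids], spec.name)
        if track.n_dyads == 0:
            raise DataError(f"unit {unit_id!r}: no dyads after filtering")
        occ_raw = occupancy_from_dyads(track, config.windows.half_footprint)
        occ_norm = normalize_occupancy(occ_raw, config.normalization_method)
        posi = positioning_scores(
            track, config.windows.inner_half, config.windows.outer_half
        )
        units[unit_id] = UnitResult(
            unit_id=unit_id,
            construct=spec,
            track=track,
            occupancy_raw=occ_raw,
            occupancy_norm=occ_norm,
            positioning=posi,
            mapped_pairs=sum(per_sample[sid][1].retained for sid in sids),
            mean_fragment_length=float(
                np.mean([per_sample[sid][2] for sid in sids])
            ),
        )

    # --- control resolution ----------------------------------------------
    control_unit: UnitResult | None = None
    if config.control is not None:
        ctrl_samples = config.control_samples()
        key = (
            ctrl_samples[0].construct
            if config.pool_by_construct
            else ctrl_samples[0].sample_id
        )
        control_unit = units[key]

    # --- Table 2 analogue: enhancer totals + ratio to control -------------
    control_total = None
    if control_unit is not None:
        control_total = region_total_occupancy(
            control_unit.occupancy_norm, control_unit.construct.enhancer_interval
        )
    occ_rows = []
    for unit in units.values():
        enh = unit.construct.enhancer_interval
        total = region_total_occupancy(unit.occupancy_norm, enh)
        row = {
            "unit": unit.unit_id,
            "construct": unit.construct.name,
            "region": "enhancer",
            "region_start_report": to_report_coordinates(unit.construct, enh.start),
            "region_end_report": to_report_coordinates(unit.construct, enh.end - 1) + 1,
            "total_occupancy": total,
        }
        if control_total is not None:
            row["ratio_to_control"] = ratio_to_control(total, control_total)
        occ_rows.append(row)
    occupancy_summary = pd.DataFrame(occ_rows)

    # --- Table 3 analogue: positioning at element centers -----------------
    el_rows = []
    for unit in units.values():
        names = sorted({
            ann.element.name for ann in unit.construct.element_intervals.values()
        })
        for el_name in names:
            for pos, score in positioning_at_element(
                unit.positioning, unit.construct, el_name
            ):
                el_rows.append({
                    "unit": unit.unit_id,
                    "construct": unit.construct.name,
                    "element": el_name,
                    "report_position": pos,
                    "positioning_score": score,
                })
    element_positioning = pd.DataFrame(
        el_rows,
        columns=["unit", "construct", "element", "report_position", "positioning_score"],
    )

    # --- Fig 4 analogue: flank-aligned occupancy --------------------------
    flanks = align_flanking_profiles(
        {uid: u.occupancy_norm for uid, u in units.items()},
        {uid: minimal_removed_interval(u.construct) for uid, u in units.items()},
    )
    flank_frames = []
    for uid, df in flanks.items():
        df = df.copy()
        df.insert(0, "unit", uid)
        flank_frames.append(df)
    flank_comparison = pd.concat(flank_frames, ignore_index=True)

    # --- Table 5 analogue: array coverage ---------------------------------
    cov_rows = []
    for unit in units.values():
        if unit.mapped_pairs == 0 or unit.mean_fragment_length <= 0:
            continue
        est = estimate_array_coverage(
            unit.mapped_pairs,
            unit.mean_fragment_length,
            len(unit.construct),
            config.copies_low,
            config.copies_high,
        )
        cov_rows.append({
            "unit": unit.unit_id,
            "mapped_pairs": est.mapped_pairs,
            "probe_length": est.probe_length,
            "copies_low": est.copies_low,
            "copies_high": est.copies_high,
            "coverage_low": est.coverage_low,
            "coverage_high": est.coverage_high,
        })
    coverage = pd.DataFrame(cov_rows)

    # --- outputs ----------------------------------------------------------
    paths: dict[str, Path] = {}
    for uid, unit in units.items():
        ref = unit.construct.name
        comments = provenance + [f"unit: {uid}"]
        for tag, values in [
            ("dyads", unit.track.counts),
            ("occupancy_raw", unit.occupancy_raw.values),
            ("occupancy_norm", unit.occupancy_norm.values),
            ("positioning", unit.positioning.scores),
        ]:
            p = out_dir / f"{uid}.{tag}.bedgraph"
            write_bedgraph(p, ref, values, name=f"{uid}.{tag}", comments=comments)
            paths[f"{uid}.{tag}"] = p
    for name, df in [
        ("ingest_report", pd.DataFrame(ingest_rows)),
        ("occupancy_summary", occupancy_summary),
        ("element_positioning", element_positioning),
        ("flank_comparison", flank_comparison),
        ("coverage", coverage),
    ]:
        p = out_dir / f"{name}.tsv"
        _write_table(df, p, provenance)
        paths[name] = p
    manifest = {
        "version": __version__,
        "control": config.control,
        "pool_by_construct": config.pool_by_construct,
        "units": sorted(units),
        "outputs": {k: v.name for k, v in sorted(paths.items())},
    }
    mpath = out_dir / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = mpath

    return PipelineResult(
        output_dir=out_dir,
        units=units,
        occupancy_summary=occupancy_summary,
        element_positioning=element_positioning,
        flank_comparison=flank_comparison,
        coverage=coverage,
        paths=paths,
    )
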