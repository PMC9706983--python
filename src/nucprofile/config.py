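"""Run configuration: parsing, validation and construct resolution.

A single YAML file names the constructs (backbone + inserts), the
sample manifest (sample id → alignment file + construct), the filter
policy and window parameters, the control, and the output directory.
Every analysis constant (136/158/200 bp filter, 73 bp half-footprint,
10/150 bp positioning half-windows, 70–300 array copies) lives here
with its default — never hard-coded in the pipeline logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .constructs import (
    Backbone,
    ConstructSpec,
    Element,
    ElementInsert,
    Interval,
    Orientation,
    Site,
    assemble_construct,
    homopolymer_element,
    placeholder_backbone,
    read_element_fasta,
)
from .fragments import FilterPolicy

__all__ = [
    "RunConfig",
    "SampleSpec",
    "WindowParams",
    "Finding",
    "ConfigError",
    "DataError",
    "load_config",
    "validate_config",
    "construct_from_config",
]


class ConfigError(ValueError):
    """Fatal problem with the run configuration."""


class DataError(RuntimeError):
    """Fatal problem with input data during a pipeline run."""


@dataclass(frozen=True)
class WindowParams:
    half_footprint: int = 73
    inner_half: int = 10
    outer_half: int = 150

    def __post_init__(self) -> None:
        if min(self.half_footprint, self.inner_half, self.outer_half) < 1:
            raise ConfigError("window parameters must be positive")
        if self.inner_half > self.outer_half:
            raise ConfigError(
                f"inner_half ({self.inner_half}) must not exceed "
                f"outer_half ({self.outer_half})"
            )


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    construct: str
    alignments: Path


@dataclass
class RunConfig:
    constructs: dict[str, ConstructSpec]
    samples: list[SampleSpec]
    control: str | None = None
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    windows: WindowParams = field(default_factory=WindowParams)
    normalization_method: str = "max"
    copies_low: int = 70
    copies_high: int = 300
    pool_by_construct: bool = False
    output_dir: Path = Path("nucprofile_out")
    seed: int = 0

    def control_samples(self) -> list[SampleSpec]:
        """Samples acting as control (matched by sample id, then construct)."""
        if self.control is None:
            return []
        by_id = [s for s in self.samples if s.sample_id == self.control]
        if by_id:
            return by_id
        return [s for s in self.samples if s.construct == self.control]


def construct_from_config(
    name: str, cfg: Mapping[str, Any], base_dir: Path
) -> ConstructSpec:
    """Build a ConstructSpec from its config stanza.

    ``backbone`` is either the string ``"placeholder"`` (optionally a
    mapping with gap overrides) or a mapping with ``fasta``,
    ``upstream_point``, ``downstream_point`` and ``enhancer: [start,
    end]``.  Each insert names its element sequence via ``sequence``
    (literal), ``fasta`` (path) or ``builtin`` (a homopolymer name).
    """
    bb_cfg = cfg.get("backbone", "placeholder")
    if bb_cfg == "placeholder":
        backbone = placeholder_backbone()
    elif isinstance(bb_cfg, Mapping) and bb_cfg.get("type", "placeholder") == "placeholder":
        backbone = placeholder_backbone(
            upstream_gap=int(bb_cfg.get("upstream_gap", 3)),
            downstream_gap=int(bb_cfg.get("downstream_gap", 3)),
        )
    elif isinstance(bb_cfg, Mapping):
        seq = read_element_fasta(base_dir / bb_cfg["fasta"], name="backbone").sequence
        enh = bb_cfg["enhancer"]
        backbone = Backbone(
            seq,
            int(bb_cfg["upstream_point"]),
            int(bb_cfg["downstream_point"]),
            Interval(int(enh[0]), int(enh[1])),
        )
    else:
        raise ConfigError(f"construct {name!r}: unrecognised backbone spec {bb_cfg!r}")

    inserts = []
    for ins in cfg.get("inserts", []):
        el_name = ins["element"]
        if "sequence" in ins:
            element = Element(el_name, ins["sequence"])
        elif "fasta" in ins:
            element = read_element_fasta(base_dir / ins["fasta"], name=el_name)
        elif "builtin" in ins:
            element = homopolymer_element(ins["builtin"])
        else:
            element = homopolymer_element(el_name)  # homopolymers need no sequence
        inserts.append(
            ElementInsert(element, Site(ins["site"]), Orientation(ins["orientation"]))
        )
    return assemble_construct(name, backbone, inserts)


def load_config(path: str | Path) -> RunConfig:
    """Parse and materialise a YAML run configuration."""
    path = Path(path)
    base_dir = path.parent
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: unparseable YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")

    constructs = {
        name: construct_from_config(name, cfg or {}, base_dir)
        for name, cfg in (raw.get("constructs") or {}).items()
    }
    samples = [
        SampleSpec(
            sample_id=str(s["id"]),
            construct=str(s["construct"]),
            alignments=base_dir / s["alignments"],
        )
        for s in raw.get("samples") or []
    ]
    filt = raw.get("filter") or {}
    windows = raw.get("windows") or {}
    coverage = raw.get("coverage") or {}
    norm = raw.get("normalization") or {}
    return RunConfig(
        constructs=constructs,
        samples=samples,
        control=raw.get("control"),
        filter_policy=FilterPolicy(
            min_length=int(filt.get("min_length", 136)),
            max_length=int(filt.get("max_length", 158)),
            max_ingest_length=int(filt.get("max_ingest_length", 200)),
        ),
        windows=WindowParams(
            half_footprint=int(windows.get("half_footprint", 73)),
            inner_half=int(windows.get("inner_half", 10)),
            outer_half=int(windows.get("outer_half", 150)),
        ),
        normalization_method=str(norm.get("method", "max")),
        copies_low=int(coverage.get("copies_low", 70)),
        copies_high=int(coverage.get("copies_high", 300)),
        pool_by_construct=bool(raw.get("pool_by_construct", False)),
        output_dir=base_dir / raw.get("output_dir", "nucprofile_out"),
        seed=int(raw.get("seed", 0)),
    )


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    message: str

    @property
    def fatal(self) -> bool:
        return self.severity == "error"


_DEFAULT_WINDOWS = WindowParams()
_DEFAULT_FILTER = FilterPolicy()


def validate_config(config: RunConfig | str | Path) -> list[Finding]:
    """Check a configuration without running the pipeline.

    Returns fatal errors (missing files, unknown constructs, absent
    control when summaries need one) and non-fatal warnings (non-default
    windows or filter bounds).  Parse failures surface as a single
    error finding.
    """
    findings: list[Finding] = []
    if not isinstance(config, RunConfig):
        try:
            config = load_config(config)
        except (ConfigError, OSError, KeyError, ValueError) as exc:
            return [Finding("error", f"config does not parse: {exc}")]

    if not config.samples:
        findings.append(Finding("error", "no samples in manifest"))
    for s in config.samples:
        if s.construct not in config.constructs:
            findings.append(
                Finding("error", f"sample {s.sample_id!r}: unknown construct {s.construct!r}")
            )
        if not s.alignments.exists():
            findings.append(
                Finding("error", f"sample {s.sample_id!r}: missing alignment file {s.alignments}")
            )
    if config.control is not None and not config.control_samples():
        findings.append(
            Finding("error", f"control {config.control!r} matches no sample or construct")
        )
    if config.control is None:
        findings.append(
            Finding("warning", "no control named: summaries will omit ratio_to_control")
        )
    if len(config.control_samples()) > 1 and not config.pool_by_construct:
        findings.append(
            Finding("error",
                    f"control {config.control!r} matches several samples; "
                    "set pool_by_construct to merge them")
        )
    if config.windows != _DEFAULT_WINDOWS:
        findings.append(Finding("warning", f"non-default windows: {config.windows}"))
    if config.filter_policy != _DEFAULT_FILTER:
        findings.append(Finding("warning", f"non-default filter: {config.filter_policy}"))
    for s in config.samples:
        spec = config.constructs.get(s.construct)
        if spec is not None and config.windows.outer_half * 2 + 1 > len(spec):
            findings.append(
                Finding("error",
                        f"outer window exceeds reference length for {s.construct!r}")
            )
    return findings
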