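"""Run configuration: validated YAML with every threshold surfaced.

All geometric cutoffs and tolerances used by the pipeline live here with
their defaults, so a run is fully specified by (inputs, config, seed).
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .crosslink import BACKGROUND_WARN_A, LINKER_TOLERANCE_A, LinkerSpec
from .domains import DomainDefinition

#: Approximate actin-fold subdomain boundaries for FtsA (author numbering,
#: VmFtsA 1-396 scale).  The IC subdomain replaces actin's IB and sits on
#: the opposite side of the fold; IA carries both termini.  These are
#: starting points meant to be edited per structure — every report records
#: the boundary set actually used.
DEFAULT_FTSA_DOMAINS = {
    "IA": [(1, 87), (373, 396)],
    "IC": [(88, 163)],
    "IIA": [(164, 245), (309, 372)],
    "IIB": [(246, 308)],
}


def default_domains() -> DomainDefinition:
    return DomainDefinition(
        {k: list(v) for k, v in DEFAULT_FTSA_DOMAINS.items()},
        provenance="approximate actin-fold subdomain boundaries for FtsA "
                   "(editable; not structure-refined)")


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline command needs besides the input files."""
    inputs: list[str] = dataclasses.field(default_factory=list)
    output_dir: str = "."
    seed: int = 0
    # contact / interface
    contact_cutoff: float = 4.5
    min_residue_pairs: int = 5
    polar_cutoff: float = 3.5
    # classification
    longitudinal_twist_max: float = 60.0
    lateral_twist_min: float = 150.0
    tight_min_pairs: int = 3
    # C2
    c2_tol_angle_deg: float = 5.0
    c2_tol_rise: float = 1.5
    c2_tol_rmsd: float = 2.0
    # helical / ring / curvature
    ring_tol_angle_deg: float = 3.0
    ring_tol_rise: float = 5.0
    ring_n_max: int = 100
    # cross-linking
    max_crosslink_distance: float = 20.0
    linker_tolerance: float = LINKER_TOLERANCE_A
    background_warn: float = BACKGROUND_WARN_A
    linkers: dict = dataclasses.field(default_factory=lambda: {"BMOE": 8.0})
    endogenous_cysteines: list[int] = dataclasses.field(default_factory=list)
    # domains
    domains: dict = dataclasses.field(
        default_factory=lambda: {k: [list(r) for r in v]
                                 for k, v in DEFAULT_FTSA_DOMAINS.items()})
    hinge_fixed: list[str] = dataclasses.field(
        default_factory=lambda: ["IA", "IIA", "IIB"])
    hinge_mobile: str = "IC"

    def domain_definition(self) -> DomainDefinition:
        return DomainDefinition({k: [tuple(r) for r in v]
                                 for k, v in self.domains.items()},
                                provenance="run configuration")

    def linker_specs(self) -> list[LinkerSpec]:
        return [LinkerSpec(name, float(span), self.linker_tolerance)
                for name, span in self.linkers.items()]

    def digest(self) -> str:
        """Stable hash of the full configuration (embedded in reports)."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class ConfigError(ValueError):
    pass


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config file; unknown keys are an error, not a warning."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)} "
                          f"(known: {sorted(known)})")
    cfg = RunConfig(**data)
    cfg.domain_definition()   # validates ranges
    cfg.linker_specs()        # validates spans
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def ensure_outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out
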