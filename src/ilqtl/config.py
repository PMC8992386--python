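"""Structured run configuration (YAML) for the pipeline and simulator."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .io_core import CONTROL_ID, GenomeSpec, SchemaError
from .simulate import QTLEffect, SimConfig


@dataclass
class RunConfig:
    seed: int = 0
    simulate: bool = True
    output_dir: str = "results/run"
    genome: dict[str, int] = field(default_factory=dict)
    marker_spacing_bp: int = 2_500_000
    n_backcrosses: int = 2
    n_selfs: int = 2
    n_lines: int = 100
    population_size: int = 200
    selection_threshold_sd: float | None = None
    qtls: list[dict] = field(default_factory=list)
    trait: str = "GL"
    baseline: float = 7.0
    residual_sd: float = 0.2
    n_replicates: int = 3
    n_control_replicates: int = 10
    environment_effects: dict[str, float] = field(default_factory=lambda: {"E1": 0.0, "E2": 0.15})
    genotyping_error_rate: float = 0.0
    donor: str = "sim_donor"
    het: str = "donor"
    control_id: str = CONTROL_ID
    alpha: float = 1e-4
    variance_model: str = "pooled"
    p0_mode: str = "empirical_locus"
    scan_threshold: float = 1e-3
    novelty_window_bp: int = 2_500_000
    merge_adjacent: bool = False
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise SchemaError(f"alpha {self.alpha} outside (0, 1)")
        if not 0 < self.scan_threshold < 1:
            raise SchemaError(f"scan threshold {self.scan_threshold} outside (0, 1)")
        if self.het not in ("donor", "ignore"):
            raise SchemaError(f"het policy must be 'donor' or 'ignore', got {self.het!r}")
        if self.p0_mode not in ("empirical_locus", "empirical_genome", "theoretical"):
            raise SchemaError(f"unknown p0 mode {self.p0_mode!r}")
        if self.simulate and not self.genome:
            raise SchemaError("simulate=true requires a genome block")
        if not self.simulate:
            for key in ("genome", "marker_map", "genotypes", "phenotypes"):
                if key not in self.inputs:
                    raise SchemaError(f"simulate=false requires inputs.{key}")

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec({str(c): int(l) for c, l in self.genome.items()})

    def sim_config(self) -> SimConfig:
        return SimConfig(
            genome=self.genome_spec(),
            marker_spacing_bp=self.marker_spacing_bp,
            n_backcrosses=self.n_backcrosses,
            n_selfs=self.n_selfs,
            n_lines=self.n_lines,
            population_size=self.population_size,
            selection_threshold_sd=self.selection_threshold_sd,
            qtls=[QTLEffect(**q) for q in self.qtls],
            trait=self.trait,
            baseline=self.baseline,
            environment_effects=dict(self.environment_effects),
            residual_sd=self.residual_sd,
            n_replicates=self.n_replicates,
            n_control_replicates=self.n_control_replicates,
            genotyping_error_rate=self.genotyping_error_rate,
            donor=self.donor,
            seed=self.seed,
        )


_NESTED = {
    "markers": {"spacing_bp": "marker_spacing_bp"},
    "scheme": {"n_backcrosses": "n_backcrosses", "n_selfs": "n_selfs"},
    "phenotype": {
        "trait": "trait",
        "baseline": "baseline",
        "residual_sd": "residual_sd",
        "n_replicates": "n_replicates",
        "n_control_replicates": "n_control_replicates",
        "environment_effects": "environment_effects",
    },
    "screen": {"alpha": "alpha", "variance_model": "variance_model"},
    "scan": {
        "p0_mode": "p0_mode",
        "threshold": "scan_threshold",
        "window_bp": "novelty_window_bp",
        "merge_adjacent": "merge_adjacent",
    },
}


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run config; ``overrides`` (flat keys) win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    flat: dict = {}
    for key, value in raw.items():
        if key in _NESTED and isinstance(value, dict):
            for sub, target in _NESTED[key].items():
                if sub in value:
                    flat[target] = value[sub]
            extra = set(value) - set(_NESTED[key])
            if extra:
                raise SchemaError(f"{path}: unknown key {key}.{sorted(extra)[0]}")
        else:
            flat[key] = value
    if overrides:
        flat.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(flat) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config key {sorted(unknown)[0]!r}")
    return RunConfig(**flat)
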