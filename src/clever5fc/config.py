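"""Calling thresholds and run configuration.

The defaults in :class:`CallingConfig` are the published scheme's gates: a
CpG enters the candidate (treated) or noise (untreated) pool when its C-to-T
ratio is >= 0.65 in at least two cells of that group; per-cell calls require
depth >= 3; unmodified-C calls require ratio <= 0.25 at depth >= 3; the
lambda background rate uses C sites covered >= 4 times; and final 5fCpG
calls need a Holm-Bonferroni adjusted binomial p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError, InvalidParameterError


@dataclass(frozen=True)
class CallingConfig:
    ratio_min: float = 0.65
    ratio_unmod_max: float = 0.25
    min_depth_call: int = 3
    min_depth_lambda: int = 4
    min_cells_pool: int = 2
    adj_p_max: float = 0.01

    def __post_init__(self):
        if not 0 <= self.ratio_unmod_max < self.ratio_min <= 1:
            raise InvalidParameterError(
                "require 0 <= ratio_unmod_max < ratio_min <= 1"
            )
        if self.min_depth_call < 1 or self.min_depth_lambda < 1:
            raise InvalidParameterError("depth thresholds must be >= 1")
        if self.min_cells_pool < 1:
            raise InvalidParameterError("min_cells_pool must be >= 1")
        if not 0 < self.adj_p_max <= 1:
            raise InvalidParameterError("adj_p_max must be in (0, 1]")


@dataclass
class CellSpec:
    """One row of the sample manifest."""

    cell_id: str
    treatment: str  # "treated" | "untreated"
    stage: str | None = None
    pair_id: str | None = None
    pair_role: str | None = None  # e.g. "male" / "female", "A" / "B"


@dataclass
class RunConfig:
    """Everything a full synthetic run needs, loadable from YAML."""

    seed: int = 1
    # genome
    n_chrom: int = 1
    chrom_len: int = 1_000_000
    cpg_density: float = 10.0  # CpG sites per kb
    annotation_spec: dict[str, float] | None = None
    # truth / generative model
    class_rates: dict[str, float] | None = None
    base_rate: float = 3e-4
    conversion_eff: float = 0.8
    background_rate: float = 0.0115
    coverage_mean: float = 5.0
    # cells
    manifest: list[CellSpec] = field(default_factory=list)
    # analysis
    calling: CallingConfig = field(default_factory=CallingConfig)
    window_size: int = 1000
    snp_mask_path: str | None = None
    outdir: str = "clever5fc_run"

    def __post_init__(self):
        ids = [c.cell_id for c in self.manifest]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate cell ids in manifest")

    @property
    def treated(self) -> list[CellSpec]:
        return [c for c in self.manifest if c.treatment == "treated"]

    @property
    def untreated(self) -> list[CellSpec]:
        return [c for c in self.manifest if c.treatment == "untreated"]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        manifest = [CellSpec(**row) for row in raw.pop("manifest", [])]
        calling = CallingConfig(**raw.pop("calling", {}))
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(manifest=manifest, calling=calling, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def default_manifest(n_treated: int, n_untreated: int,
                     stages: list[str] | None = None) -> list[CellSpec]:
    """Simple manifest: treated cells split evenly across ``stages``."""
    stages = stages or ["stage1"]
    manifest = []
    per_stage = max(1, n_treated // len(stages))
    for i in range(n_treated):
        stage = stages[min(i // per_stage, len(stages) - 1)]
        manifest.append(CellSpec(cell_id=f"t{i:02d}", treatment="treated", stage=stage))
    for i in range(n_untreated):
        manifest.append(CellSpec(cell_id=f"u{i:02d}", treatment="untreated"))
    return manifest
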