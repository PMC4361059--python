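"""Pipeline configuration: every tunable threshold in one validated object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from polyclone.errors import ConfigError
from polyclone.simulate import SimParams


def _rng(lo, hi, lo_open=False, hi_open=False):
    return (lo, hi, lo_open, hi_open)


#: Legal range per threshold: (lo, hi, lo_open, hi_open).
_RANGES: dict[str, tuple] = {
    "min_depth": _rng(1, 10_000),
    "strand_bias_alpha": _rng(0.0, 1.0, lo_open=True),
    "tail_bias_alpha": _rng(0.0, 1.0, lo_open=True),
    "het_min": _rng(0.0, 1.0, lo_open=True, hi_open=True),
    "hom_alt_min": _rng(0.0, 1.0, lo_open=True, hi_open=True),
    "min_mutant_reads": _rng(1, 1000),
    "min_baseq": _rng(0, 60),
    "end_exclusion_bp": _rng(0, 100),
    "repeat_flank_bp": _rng(0, 1000),
    "val_min_coverage": _rng(1, 100_000),
    "val_min_mutant_reads": _rng(1, 100_000),
    "val_min_mutant_fraction": _rng(0.0, 1.0, lo_open=True),
    "mp_threshold": _rng(0.0, 1.0, hi_open=True),
    "clonal_vaf_threshold": _rng(0.0, 1.0, lo_open=True, hi_open=True),
    "target_mb": _rng(0.0, 10_000.0, lo_open=True),
    "seed": _rng(0, 2**31 - 1),
}


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds, with their documented defaults.

    Primary caller: genotype thresholds plus the filter cascade (depth
    minimum 10, strand-bias alpha 0.001). Subclonal caller: minimum
    evidence 2, base quality 20, end exclusion 5 bp, repeat flank 10 bp.
    Validation: coverage 20, 5 mutant reads, 1% mutant fraction, MP
    threshold 0.15. Reporting: clonality threshold 0.25, target 30 Mb.
    """

    min_depth: int = 10
    strand_bias_alpha: float = 0.001
    tail_bias_alpha: float = 0.005
    het_min: float = 0.10
    hom_alt_min: float = 0.85
    min_mutant_reads: int = 2
    min_baseq: int = 20
    end_exclusion_bp: int = 5
    repeat_flank_bp: int = 10
    val_min_coverage: int = 20
    val_min_mutant_reads: int = 5
    val_min_mutant_fraction: float = 0.01
    mp_threshold: float = 0.15
    clonal_vaf_threshold: float = 0.25
    target_mb: float = 30.0
    seed: int = 0
    sim: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        for name, (lo, hi, lo_open, hi_open) in _RANGES.items():
            v = getattr(self, name)
            ok = (v > lo if lo_open else v >= lo) and (v < hi if hi_open else v <= hi)
            if not ok:
                lo_b = "(" if lo_open else "["
                hi_b = ")" if hi_open else "]"
                raise ConfigError(
                    f"{name}={v} outside legal range {lo_b}{lo}, {hi}{hi_b}"
                )
        if self.het_min >= self.hom_alt_min:
            raise ConfigError(
                f"het_min ({self.het_min}) must be below hom_alt_min ({self.hom_alt_min})"
            )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["sim"]["subclonal_vaf_range"] = list(self.sim.subclonal_vaf_range)
        return d


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a YAML key-value config; absent keys take the defaults.

    Unknown keys are rejected; out-of-range values raise a ConfigError
    naming the key and its legal range. ``overrides`` (e.g. CLI flags)
    take precedence over the file.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    sim_data = data.pop("sim", None)
    if sim_data is not None:
        if not isinstance(sim_data, dict):
            raise ConfigError("sim must be a mapping of SimParams fields")
        sim_known = {f.name for f in dataclasses.fields(SimParams)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(sim_unknown)}")
        if "subclonal_vaf_range" in sim_data:
            sim_data["subclonal_vaf_range"] = tuple(sim_data["subclonal_vaf_range"])
        sim_data.setdefault("seed", int(data.get("seed", 0)))
        sim = SimParams(**sim_data)
    else:
        sim = SimParams(seed=int(data.get("seed", 0)))
    return PipelineConfig(sim=sim, **data)
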