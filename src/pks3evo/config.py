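"""Pipeline configuration: a flat, range-validated YAML namespace."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


def _rng(lo, hi):
    return {"lo": lo, "hi": hi}


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end analysis, with validated ranges.

    The reconciliation costs (1.5 / 1 / 6 / 0), the weak-edge threshold
    (98), the network weights (0.22 / 0.76 / 0.02, anchors doubled) and
    the family cutoff (0.5) default to the published study constants;
    simulation sizes and rates default to the package's standard synthetic
    conditions.
    """

    # global
    seed: int = 1
    out_dir: str = "pks3evo_run"

    # simulation
    n_species: int = 16
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_families: int = 8
    n_clades: int = 4
    dup_rate: float = 0.08
    transfer_rate: float = 0.06
    loss_rate: float = 0.05
    weak_fraction: float = 0.25
    support_low: float = 50.0
    support_high: float = 100.0
    n_bgc_per_clade: int = 10
    similarity_noise: float = 0.1

    # classification
    evalue_cutoff: float = 1e-5
    max_gap_bp: int = 20000

    # trees / reconciliation
    collapse_threshold: float = 98.0
    clade_support_threshold: float = 95.0
    min_clade_size: int = 2
    cost_duplication: float = 1.5
    cost_loss: float = 1.0
    cost_transfer: float = 6.0
    cost_codivergence: float = 0.0

    # HGT screening
    hgt_dominance: float = 0.9
    hgt_min_identity: float = 50.0
    hgt_max_evalue: float = 1e-20

    # networks / statistics
    weight_jaccard: float = 0.22
    weight_dss: float = 0.76
    weight_adjacency: float = 0.02
    anchor_multiplier: float = 2.0
    distance_cutoff: float = 0.5
    alpha: float = 0.05
    bonferroni: bool = False

    _RANGES = {
        "n_species": _rng(2, 10_000),
        "birth_rate": _rng(1e-9, 1e6),
        "death_rate": _rng(0.0, 1e6),
        "n_families": _rng(1, 100_000),
        "n_clades": _rng(1, 1_000),
        "dup_rate": _rng(0.0, 1e3),
        "transfer_rate": _rng(0.0, 1e3),
        "loss_rate": _rng(0.0, 1e3),
        "weak_fraction": _rng(0.0, 1.0),
        "support_low": _rng(0.0, 100.0),
        "support_high": _rng(0.0, 100.0),
        "n_bgc_per_clade": _rng(1, 100_000),
        "similarity_noise": _rng(0.0, 1.0),
        "evalue_cutoff": _rng(0.0, 1e6),
        "max_gap_bp": _rng(0, 1_000_000_000),
        "collapse_threshold": _rng(0.0, 100.0),
        "clade_support_threshold": _rng(0.0, 100.0),
        "min_clade_size": _rng(1, 1_000_000),
        "cost_duplication": _rng(0.0, 1e6),
        "cost_loss": _rng(0.0, 1e6),
        "cost_transfer": _rng(0.0, 1e6),
        "cost_codivergence": _rng(0.0, 1e6),
        "hgt_dominance": _rng(0.0, 1.0),
        "hgt_min_identity": _rng(0.0, 100.0),
        "hgt_max_evalue": _rng(0.0, 1e6),
        "weight_jaccard": _rng(0.0, 1.0),
        "weight_dss": _rng(0.0, 1.0),
        "weight_adjacency": _rng(0.0, 1.0),
        "anchor_multiplier": _rng(1.0, 1e3),
        "distance_cutoff": _rng(0.0, 1.0),
        "alpha": _rng(0.0, 1.0),
    }

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, bounds in self._RANGES.items():
            value = getattr(self, name)
            if not (bounds["lo"] <= value <= bounds["hi"]):
                raise ValueError(
                    f"config field {name}={value!r} outside "
                    f"[{bounds['lo']}, {bounds['hi']}]"
                )
        total = self.weight_jaccard + self.weight_dss + self.weight_adjacency
        if abs(total - 1.0) > 1e-12:
            raise ValueError("distance component weights must sum to 1")
        if self.support_low > self.support_high:
            raise ValueError("support_low must be <= support_high")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
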