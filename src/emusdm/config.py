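"""Pipeline configuration: a versioned YAML schema with validated defaults.

Defaults encode the standard protocol: 5-km coordinate-uncertainty cut,
1970-present time frame, 30-km thinning and pseudo-absence spacing, VIF
threshold 10, a 9-algorithm roster with 6 repeats and a 70/30 split, and
skill gates TSS >= 0.7 / AUC >= 0.9 / Kappa >= 0.7.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ensemble import GateThresholds
from .occurrences import CleaningRules

__all__ = ["SyntheticConfig", "PipelineConfig", "ConfigError"]

CONFIG_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Synthetic-landscape study conditions (used when no files are given)."""

    n_rows: int = 100
    n_cols: int = 100
    cell_size_km: float = 10.0
    layer_names: tuple[str, ...] = ("bio13", "bio15", "bio18", "bio19", "bio1")
    autocorr_length_km: tuple[float, ...] | float = (150.0, 120.0, 100.0, 80.0, 60.0)
    niche_intercept: float = -1.0
    niche_coefficients: dict = field(
        default_factory=lambda: {"bio13": 4.0, "bio15": -3.0, "bio18": 2.0}
    )
    niche_quadratic: dict = field(default_factory=lambda: {"bio13": -1.5})
    n_presences: int = 500
    n_analogues: int = 1500
    dirty_fraction: float = 0.1
    bias_hotspots: int = 6
    bias_floor: float = 0.05
    scenario_shifts: dict = field(
        default_factory=lambda: {
            "past": {"additive_delta": {"bio15": 0.8}, "multiplicative_factor": {}},
            "future": {"additive_delta": {"bio13": -0.6}, "multiplicative_factor": {}},
        }
    )


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results/run"
    # data sources: synthetic generation, or paths to files
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    occurrences_csv: str | None = None
    analogues_csv: str | None = None
    stack_dir: str | None = None
    scenario_stack_dirs: dict = field(default_factory=dict)
    city_points: list = field(default_factory=list)
    # stage parameters
    cleaning: CleaningRules = field(default_factory=CleaningRules)
    thin_km: float = 30.0
    pseudoabsence_min_dist_km: float = 30.0
    bias_bandwidth_km: float = 100.0
    kernel_components: int | None = None
    vif_threshold: float = 10.0
    roster: list | None = None
    n_repeats: int = 6
    calib_fraction: float = 0.7
    gates: GateThresholds = field(default_factory=GateThresholds)
    compute_importance: bool = True
    compute_boyce: bool = True
    n_importance_shuffles: int = 3
    write_artifacts: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.calib_fraction < 1.0:
            raise ConfigError("calib_fraction must be in (0, 1)")
        if self.thin_km <= 0 or self.pseudoabsence_min_dist_km <= 0:
            raise ConfigError("distances must be positive")
        if self.vif_threshold <= 1.0:
            raise ConfigError("vif_threshold must exceed 1")
        for g in ("tss_min", "kappa_min"):
            if not -1.0 <= getattr(self.gates, g) <= 1.0:
                raise ConfigError(f"{g} out of range")
        if not 0.0 <= self.gates.auc_min <= 1.0:
            raise ConfigError("auc_min out of range")
        if self.synthetic is None and (
            self.occurrences_csv is None or self.stack_dir is None
        ):
            raise ConfigError(
                "either synthetic mode or occurrence/stack paths are required"
            )

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = CONFIG_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        version = d.pop("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {version}")
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], SyntheticConfig):
            syn = dict(d["synthetic"])
            if "layer_names" in syn:
                syn["layer_names"] = tuple(syn["layer_names"])
            if isinstance(syn.get("autocorr_length_km"), (list, tuple)):
                syn["autocorr_length_km"] = tuple(syn["autocorr_length_km"])
            d["synthetic"] = SyntheticConfig(**syn)
        if d.get("cleaning") is not None and not isinstance(d["cleaning"], CleaningRules):
            c = dict(d["cleaning"])
            c.pop("excluded_region_masks", None)  # polygons are not YAML-round-tripped
            d["cleaning"] = CleaningRules(**c)
        if d.get("gates") is not None and not isinstance(d["gates"], GateThresholds):
            d["gates"] = GateThresholds(**d["gates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        if d.get("cleaning"):
            d["cleaning"].pop("excluded_region_masks", None)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
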