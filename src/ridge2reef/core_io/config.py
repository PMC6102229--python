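"""Pipeline configuration.

Every numeric parameter of the downstream stages appears here with its
published default, so a YAML file only needs to override what differs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Cover-management factors per land-cover class.  Literature defaults for
#: humid tropical high islands; user-overridable through the config file.
DEFAULT_C_FACTORS: dict[str, float] = {
    "native_forest": 0.003,
    "secondary_forest": 0.008,
    "shrubland": 0.05,
    "pine_plantation": 0.08,
    "monoculture": 0.34,
    "bare": 0.45,
    "water": 0.0,
}

#: Integer codes used on class rasters for the land-cover classes above.
LAND_COVER_CODES: dict[str, int] = {
    "water": 0,
    "native_forest": 1,
    "secondary_forest": 2,
    "shrubland": 3,
    "pine_plantation": 4,
    "monoculture": 5,
    "bare": 6,
}


@dataclass
class SdrParams:
    """Connectivity → delivery-ratio calibration."""

    ic0: float = 0.5
    k_borselli: float = 2.0
    sdr_max: float = 0.8
    flow_accum_threshold: int = 40
    k_fill: float = 0.002
    slope_floor: float = 0.005
    ls_cap: float = 122.0

    def __post_init__(self) -> None:
        if not 0 < self.sdr_max <= 1:
            raise ValueError("sdr_max must be in (0, 1]")
        if self.k_borselli <= 0:
            raise ValueError("k_borselli must be > 0")


@dataclass
class PlumeParams:
    """Cost-composite weights and decay geometry for plume dispersal."""

    w_depth: float = 1.0 / 3.0
    w_dist: float = 1.0 / 3.0
    w_wind: float = 1.0 / 3.0
    max_distance: float = 3000.0
    cost_floor: float = 1e-3
    d_c: float | None = None  # auto-calibrated per pour point when None

    def __post_init__(self) -> None:
        w = (self.w_depth, self.w_dist, self.w_wind)
        if any(x < 0 for x in w):
            raise ValueError("plume weights must be nonnegative")
        total = sum(w)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"plume weights must sum to 1, got {total}")


@dataclass
class BrtConfig:
    """Boosted-tree hyperparameter search space and CV settings."""

    learning_rates: tuple[float, ...] = (0.01, 0.005, 0.001)
    tree_complexities: tuple[int, ...] = (1, 2, 3, 5)
    bag_fractions: tuple[float, ...] = (0.5, 0.75)
    max_trees: int = 10_000
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for b in self.bag_fractions:
            if not 0 < b <= 1:
                raise ValueError("bag fraction must be in (0, 1]")


#: Proportional coral-cover reductions per bleaching level, keyed by depth
#: band (min_depth_m, max_depth_m).
BLEACHING_REDUCTIONS: dict[str, dict[tuple[float, float], float]] = {
    "none": {},
    "low": {(0.0, 5.0): 0.10},
    "moderate": {(0.0, 5.0): 0.30},
    "high": {(0.0, 5.0): 0.30, (5.0, 10.0): 0.10},
}


@dataclass
class SynthParams:
    size: int = 200
    n_sites: int = 163
    #: None selects the per-indicator calibrated noise levels
    noise_sd: float | None = None
    n_valleys: int = 3


@dataclass
class PipelineConfig:
    """All knobs of the full pipeline, with published defaults."""

    seed: int = 0
    scenario: str = "current"
    bleaching: str = "none"
    land_cell_size: float = 30.0
    marine_cell_size: float = 60.0
    erosivity_mode: str = "monthly"
    max_predict_depth: float = 22.0
    r_max: float = 0.7
    alpha: float = 0.10
    linkage_threshold: float = 0.90
    priority_export_fraction: float = 0.66
    buffer_distance: float = 100.0
    c_factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_C_FACTORS))
    sdr: SdrParams = field(default_factory=SdrParams)
    plume: PlumeParams = field(default_factory=PlumeParams)
    brt: BrtConfig = field(default_factory=BrtConfig)
    synth: SynthParams = field(default_factory=SynthParams)
    inputs: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.scenario not in ("current", "deforestation", "restoration"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.bleaching not in BLEACHING_REDUCTIONS:
            raise ValueError(f"unknown bleaching level {self.bleaching!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    # -- YAML --------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if f.name == "sdr":
                value = SdrParams(**value)
            elif f.name == "plume":
                value = PlumeParams(**value)
            elif f.name == "brt":
                value = BrtConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in value.items()})
            elif f.name == "synth":
                value = SynthParams(**value)
            kwargs[f.name] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        def _plain(obj: Any) -> Any:
            if isinstance(obj, tuple):
                return [_plain(v) for v in obj]
            if isinstance(obj, list):
                return [_plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            return obj

        return _plain(dataclasses.asdict(self))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
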