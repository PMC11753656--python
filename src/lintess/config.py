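"""Run configuration and the package's per-mode defaults.

The defaults table links each travel mode's accessibility time standard to
its network step threshold (one-second isochronous units) and to the planar
bandwidth it implies (average speed × time standard):

====== ============ ============= ============== ==================
mode   speed (m/s)  standard      τ (steps ≡ s)  planar bandwidth (m)
====== ============ ============= ============== ==================
walk   0.8          30 min        1800           1440
bicycle 3.6         15 min        900            3240
taxi   4.3          10 min        600            2580
metro  1.1          20 min        1200           1320
====== ============ ============= ============== ==================
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .economics import IncomeConfig
from .synth import MODE_SPEEDS, SyntheticCityConfig

__all__ = [
    "MODE_SPEEDS",
    "STEP_THRESHOLDS",
    "PLANAR_BANDWIDTHS",
    "TIME_STANDARDS_MIN",
    "RunConfig",
]

#: accessibility time standards per mode, minutes
TIME_STANDARDS_MIN = {"walk": 30, "bicycle": 15, "taxi": 10, "metro": 20}

#: network step thresholds (one-second units)
STEP_THRESHOLDS = {m: t * 60 for m, t in TIME_STANDARDS_MIN.items()}

#: planar KDE bandwidths (m) = mode speed × time standard
PLANAR_BANDWIDTHS = {
    m: MODE_SPEEDS[m] * STEP_THRESHOLDS[m] for m in MODE_SPEEDS
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either file inputs (network/amenities/prices, optionally trajectories)
    or a synthetic-city block must be given.  All randomness derives from
    ``seed``.
    """

    out_dir: str = "lintess_out"
    seed: int = 0
    log_level: str = "INFO"

    # inputs: files ...
    network_path: str | None = None
    amenities_path: str | None = None
    trajectories_path: str | None = None
    prices_path: str | None = None
    # ... or a synthetic city
    synthetic: SyntheticCityConfig | None = None

    modes: list[str] = field(default_factory=lambda: ["walk"])
    defined_length: float = 100.0
    min_speed: float = 0.8
    tau_steps: dict = field(default_factory=lambda: dict(STEP_THRESHOLDS))
    planar_bandwidths: dict = field(default_factory=lambda: dict(PLANAR_BANDWIDTHS))
    run_planar: bool = False
    grid_cell_m: float = 100.0

    kfunction_n_sim: int = 99
    kfunction_n_h: int = 20
    kfunction_significance: float = 0.05

    income: IncomeConfig = field(default_factory=IncomeConfig)
    variogram_family: str = "spherical"
    variogram_n_lags: int = 12

    def __post_init__(self) -> None:
        for mode in self.modes:
            if mode not in self.tau_steps:
                raise ValueError(f"no step threshold configured for mode {mode!r}")
        if self.synthetic is None and self.network_path is None:
            raise ValueError("either network_path or a synthetic block is required")
        for p in (self.network_path, self.amenities_path,
                  self.trajectories_path, self.prices_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        if "synthetic" in doc and doc["synthetic"] is not None:
            doc["synthetic"] = SyntheticCityConfig(**doc["synthetic"])
        if "income" in doc and doc["income"] is not None:
            doc["income"] = IncomeConfig(**doc["income"])
        return cls(**doc)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
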