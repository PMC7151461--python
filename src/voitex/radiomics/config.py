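"""Engine configuration for discretization and texture-matrix construction."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from ..errors import ConfigError

__all__ = ["EngineConfig"]


@dataclass(frozen=True)
class EngineConfig:
    """Knobs shared by all feature computations.

    ``n_bins`` is the fixed gray-level count for equal-width discretization
    over the ROI's own intensity range; ``epsilon`` is added inside every
    log2; ``energy_offset`` is the constant c in the energy sums;
    ``gldm_alpha`` is the level-difference tolerance defining dependence;
    ``coarseness_cap`` bounds the coarseness statistic when its
    denominator vanishes.
    """

    n_bins: int = 32
    glcm_distance: int = 1
    epsilon: float = 2.22e-16
    energy_offset: float = 0.0
    gldm_alpha: int = 0
    coarseness_cap: float = 1e6

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.glcm_distance < 1:
            raise ConfigError(f"glcm_distance must be >= 1, got {self.glcm_distance}")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EngineConfig":
        return cls(**json.loads(text))
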