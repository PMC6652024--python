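"""Conventional anomaly-detection (CAD) baselines.

Two global-threshold comparators: flagging values more than a multiple of
the sample standard deviation from the mean (default 6 SD), and flagging
values whose Mahalanobis distance exceeds a critical value (default
3.717526, the square root of 13.82).  In one dimension the Mahalanobis
distance reduces to |v - mean| / SD, so the two baselines are the same rule
with different default cutoffs; both are computed on the full series, not
per fold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ConfigurationError

__all__ = [
    "SD_MULTIPLIER_DEFAULT",
    "MAHALANOBIS_CRITICAL_DEFAULT",
    "CadConfig",
    "sd_flags",
    "mahalanobis_flags",
    "cad_flags",
]

SD_MULTIPLIER_DEFAULT = 6.0
#: sqrt(13.82), kept as the printed constant rather than a recomputed
#: chi-square quantile.
MAHALANOBIS_CRITICAL_DEFAULT = 3.717526


@dataclass(frozen=True)
class CadConfig:
    method: str = "sd"
    sd_multiplier: float = SD_MULTIPLIER_DEFAULT
    mahalanobis_critical: float = MAHALANOBIS_CRITICAL_DEFAULT

    def __post_init__(self) -> None:
        if self.method not in ("sd", "mahalanobis"):
            raise ConfigurationError(
                f"method must be 'sd' or 'mahalanobis', got {self.method!r}"
            )
        if self.sd_multiplier <= 0 or self.mahalanobis_critical <= 0:
            raise ConfigurationError("CAD multipliers must be positive")


def _distance_flags(values, cutoff: float) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) / sd > cutoff  # strict at the cutoff


def sd_flags(values, multiplier: float = SD_MULTIPLIER_DEFAULT) -> np.ndarray:
    """Flag v iff |v - mean| > multiplier * sample SD (strict)."""
    if multiplier <= 0:
        raise ConfigurationError("multiplier must be positive")
    return _distance_flags(values, multiplier)


def mahalanobis_flags(
    values, critical: float = MAHALANOBIS_CRITICAL_DEFAULT
) -> np.ndarray:
    """Flag v iff its (1-D) Mahalanobis distance exceeds the critical value."""
    if critical <= 0:
        raise ConfigurationError("critical value must be positive")
    return _distance_flags(values, critical)


def cad_flags(values, config: CadConfig) -> np.ndarray:
    if config.method == "sd":
        return sd_flags(values, config.sd_multiplier)
    return mahalanobis_flags(values, config.mahalanobis_critical)
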