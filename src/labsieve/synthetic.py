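"""Synthetic lab-like observation series with ground-truth labels.

The generator emulates the structure the detector assumes: a heavy-bodied,
right-skewed plausible distribution (lognormal by default, as lab analytes
are non-negative and long-tailed) confined to a plausibility interval
[low, high], plus sparse implausible contamination in the tails — the
default rate of 0.0576% matches the average implausibility prevalence the
silver standards reveal in large EHR extracts.  Contaminant magnitudes are
drawn uniformly between 2x and 50x beyond the violated bound: clearly
outside, but not trivially infinite.  An optional systematic-error mode
multiplies a fixed fraction of rows by a constant (default 100), emulating
a unit error — e.g. a troponin of 0.41 recorded as 41 — which violates the
sparsity assumption that the flagger relies on.

Truth labels are always computed from the final values with the same rule
the evaluation uses (outside [low, high] strictly), so labels and silver
standard can never disagree by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import ConfigurationError, ObservationSeries, SilverStandard

__all__ = [
    "CONTAMINATION_RATE_DEFAULT",
    "BodySpec",
    "SystematicError",
    "GeneratorConfig",
    "generate",
    "benchmark_series",
    "benchmark_suite",
]

CONTAMINATION_RATE_DEFAULT = 0.000576  # 0.0576%
_MAGNITUDE_RANGE = (2.0, 50.0)


@dataclass(frozen=True)
class BodySpec:
    """Distribution of plausible values before interval truncation.

    For ``lognormal``, location/scale are the log-space mean/SD; for
    ``normal`` the mean/SD; for ``mixture`` two normals with tuple
    location/scale and mixing weight on the first component.
    """

    family: str = "lognormal"
    location: float | tuple = 4.0
    scale: float | tuple = 0.5
    weight: float = 0.5  # mixture only

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal", "mixture"):
            raise ConfigurationError(f"unknown body family {self.family!r}")


@dataclass(frozen=True)
class SystematicError:
    """Multiply a random fraction of rows by a constant (unit-error mode)."""

    fraction: float
    multiplier: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ConfigurationError("systematic fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 100_000
    body: BodySpec = field(default_factory=BodySpec)
    standard: SilverStandard = field(
        default_factory=lambda: SilverStandard("SYN-LOGNORM", 0.0, 1000.0)
    )
    contamination_rate: float = CONTAMINATION_RATE_DEFAULT
    contamination_placement: str = "upper"
    systematic_error: SystematicError | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0.0 <= self.contamination_rate < 1.0):
            raise ConfigurationError("contamination_rate must be in [0, 1)")
        if self.contamination_placement not in ("upper", "lower", "both"):
            raise ConfigurationError(
                "contamination_placement must be upper/lower/both"
            )


def _draw_body(rng: np.random.Generator, body: BodySpec, size: int) -> np.ndarray:
    if body.family == "lognormal":
        return rng.lognormal(body.location, body.scale, size)
    if body.family == "normal":
        return rng.normal(body.location, body.scale, size)
    loc1, loc2 = body.location
    sc1, sc2 = body.scale
    first = rng.random(size) < body.weight
    out = np.where(
        first, rng.normal(loc1, sc1, size), rng.normal(loc2, sc2, size)
    )
    return out


def _draw_plausible(
    rng: np.random.Generator, body: BodySpec, std: SilverStandard, size: int
) -> np.ndarray:
    """Rejection-sample the body until every draw lies inside [low, high]."""
    out = _draw_body(rng, body, size)
    for _ in range(1000):
        bad = (out < std.low) | (out > std.high)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out[bad] = _draw_body(rng, body, n_bad)
    raise ConfigurationError(
        "body distribution has negligible mass inside [low, high]"
    )


def _draw_contaminants(
    rng: np.random.Generator, std: SilverStandard, placement: str, size: int
) -> np.ndarray:
    """Values strictly outside [low, high], 2x-50x beyond the violated bound."""
    f = rng.uniform(*_MAGNITUDE_RANGE, size)
    width = std.high - std.low
    ref = width if width > 0 else max(abs(std.high), abs(std.low), 1.0)
    if std.high > 0:
        upper = std.high * f
    else:
        upper = std.high + f * ref
    if std.low < 0:
        lower = std.low * f
    elif std.low > 0:
        lower = std.low / f
    else:
        lower = -f * ref
    if placement == "upper":
        return upper
    if placement == "lower":
        return lower
    side = rng.random(size) < 0.5
    return np.where(side, upper, lower)


def generate(config: GeneratorConfig) -> tuple[ObservationSeries, np.ndarray]:
    """Generate one labelled series; deterministic given ``config.seed``.

    Returns the series (row ids ``r0000000`` ...) and a boolean truth vector
    that is true exactly for rows whose final value falls outside the
    config's plausibility interval.
    """
    rng = np.random.default_rng(config.seed)
    std = config.standard
    n = config.n
    values = _draw_plausible(rng, config.body, std, n)
    contaminated = rng.random(n) < config.contamination_rate
    n_cont = int(contaminated.sum())
    if n_cont:
        values[contaminated] = _draw_contaminants(
            rng, std, config.contamination_placement, n_cont
        )
    if config.systematic_error is not None:
        sys_rows = rng.random(n) < config.systematic_error.fraction
        values[sys_rows] *= config.systematic_error.multiplier
    truth = (values < std.low) | (values > std.high)
    series = ObservationSeries(
        concept_code=std.concept_code,
        values=values,
        row_ids=np.array([f"r{i:07d}" for i in range(n)], dtype=object),
    )
    return series, truth


def benchmark_series(
    seed: int, n: int = 100_000
) -> tuple[ObservationSeries, SilverStandard, np.ndarray]:
    """The default sparse-contamination benchmark.

    Lognormal body (log-mean 4, log-SD 0.5) inside [0, 1000] with 0.0576%
    upper-tail contaminants 2x-50x beyond the upper bound.
    """
    cfg = GeneratorConfig(n=n, seed=seed)
    series, truth = generate(cfg)
    return series, cfg.standard, truth


def benchmark_suite(seed: int) -> list[tuple]:
    """Fixed, seeded scenario battery: (name, series, standard, truth).

    Scenarios cover the sparse regime the method targets (upper tail and
    both tails), the no-contamination control, a non-sparse systematic
    unit-error series that deliberately violates the sparsity assumption,
    and a small-n series.
    """
    def child(i: int) -> int:
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    troponin_like = SilverStandard("SYN-TROPONIN", 0.0, 20.0)
    scenarios = [
        ("sparse-upper-tail", GeneratorConfig(n=20_000, seed=child(0))),
        (
            "sparse-both-tails",
            GeneratorConfig(
                n=20_000, contamination_placement="both", seed=child(1)
            ),
        ),
        (
            "zero-contamination",
            GeneratorConfig(n=20_000, contamination_rate=0.0, seed=child(2)),
        ),
        (
            "heavy-systematic-error",
            GeneratorConfig(
                n=20_000,
                body=BodySpec(
                    family="lognormal", location=math.log(0.2), scale=0.35
                ),
                standard=troponin_like,
                systematic_error=SystematicError(fraction=0.5, multiplier=100.0),
                seed=child(3),
            ),
        ),
        ("small-n", GeneratorConfig(n=5_000, seed=child(4))),
    ]
    out = []
    for name, cfg in scenarios:
        series, truth = generate(cfg)
        out.append((name, series, cfg.standard, truth))
    return out
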