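"""Per-observation-type flagging pipeline.

For one observation type the procedure is: shuffle the rows to destroy any
source ordering, partition them into folds of at most ``fold_size`` points,
and process each fold independently — standardise and cube the values to
stretch the distribution tails, approximate the number of clusters, run
HK-means, take a census of cluster populations, and flag every point whose
cluster population is at most floor(alpha * fold_length).  Folds are
embarrassingly parallel; results are identical whether they run serially or
concurrently because each fold derives its own sub-seed from the pipeline
seed and its fold index.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from joblib import Parallel, delayed

from . import cluster
from .types import ConfigurationError, FlagReport, ObservationSeries

__all__ = [
    "ALPHA_GRID",
    "FlagConfig",
    "FoldSpec",
    "shuffle_observations",
    "partition_folds",
    "scale_and_cube",
    "run_fold",
    "run_pipeline",
]

log = logging.getLogger(__name__)

#: The eight pre-wired sparsity ratios, most liberal first.  Other values
#: are permitted.
ALPHA_GRID = (
    1 / 500,
    1 / 1000,
    1 / 2000,
    1 / 3000,
    1 / 4000,
    1 / 5000,
    1 / 6000,
    1 / 10000,
)

_TRANSFORMS = ("scale_cube", "none")


@dataclass
class FlagConfig:
    """Settings for one pipeline run.

    alpha is the sparsity ratio: the population fraction at or below which a
    cluster counts as implausible.  fold_size defaults to round(1/alpha),
    reproducing the coupled setting alpha = 1/n, but the two may be set
    independently because the flag rule is expressed as a fraction of the
    fold.  The single seed drives the shuffle and fans out deterministically
    to per-fold sub-seeds.
    """

    alpha: float = 1 / 1000
    fold_size: int | None = None
    seed: int = 0
    k_max: int = 10
    transform: str = "scale_cube"
    n_subsamples: int = 10
    subsample_size: int = 500
    init_max_points: int = 2000
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError("alpha must be in (0, 1]")
        if self.fold_size is None:
            self.fold_size = max(2, round(1.0 / self.alpha))
        if self.fold_size < 2:
            raise ConfigurationError("fold_size must be >= 2")
        if self.k_max < 1:
            raise ConfigurationError("k_max must be >= 1")
        if self.transform not in _TRANSFORMS:
            raise ConfigurationError(
                f"transform must be one of {_TRANSFORMS}, got {self.transform!r}"
            )

    @classmethod
    def from_json(cls, path) -> "FlagConfig":
        """Load from a JSON file; every field optional."""
        with open(path) as fh:
            raw = json.load(fh)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FoldSpec:
    """One fold of the shuffled series: a contiguous index range."""

    fold_index: int
    start: int
    stop: int
    member_row_ids: tuple

    def __len__(self) -> int:
        return self.stop - self.start


def shuffle_observations(series: ObservationSeries, seed: int) -> ObservationSeries:
    """Seeded random permutation of the series (rows stay paired)."""
    if len(series) == 0:
        raise ValueError("cannot shuffle an empty series")
    perm = np.random.default_rng(seed).permutation(len(series))
    return ObservationSeries(
        concept_code=series.concept_code,
        values=series.values[perm],
        row_ids=series.row_ids[perm],
        n_excluded=series.n_excluded,
    )


def partition_folds(series: ObservationSeries, fold_size: int) -> list[FoldSpec]:
    """Split the (already shuffled) series into folds of <= fold_size points.

    Every fold except possibly the last has exactly fold_size members; folds
    are disjoint, exhaustive and order-preserving.
    """
    if fold_size < 2:
        raise ConfigurationError("fold_size must be >= 2")
    n = len(series)
    folds = []
    for j, start in enumerate(range(0, n, fold_size)):
        stop = min(start + fold_size, n)
        folds.append(
            FoldSpec(
                fold_index=j,
                start=start,
                stop=stop,
                member_row_ids=tuple(series.row_ids[start:stop]),
            )
        )
    return folds


def scale_and_cube(values) -> np.ndarray:
    """Centre, scale to unit sample SD, then raise to the 3rd power.

    Cubing a z-score is strictly monotone, so it reorders nothing, but it
    stretches both distribution tails relative to the bulk — the feature
    transform that lets the clustering focus on tail points.  A zero-SD
    (constant) input maps to all zeros.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("scale_and_cube needs at least 2 values")
    centred = x - x.mean()
    # normalise by the max deviation first so the variance can neither
    # underflow nor overflow for extreme-magnitude inputs
    m = np.abs(centred).max()
    if m == 0.0:
        return np.zeros_like(x)
    centred /= m
    sd = centred.std(ddof=1)
    if sd == 0.0:
        return np.zeros_like(x)
    return (centred / sd) ** 3


def _fold_seed(seed: int, fold_index: int) -> int:
    """Deterministic per-fold sub-seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(fold_index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_fold(
    values, config: FlagConfig, fold_seed: int = 0
) -> tuple[cluster.ClusterModel, np.ndarray]:
    """Transform, cluster and flag one fold.

    Returns the fitted ClusterModel (on transformed values) and a boolean
    flag per point, aligned with the fold's original (untransformed) order.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("run_fold needs at least 2 values")
    feat = scale_and_cube(x) if config.transform == "scale_cube" else x
    k = cluster.approximate_k(
        feat,
        k_max=config.k_max,
        seed=fold_seed,
        n_subsamples=config.n_subsamples,
        subsample_size=config.subsample_size,
    )
    model = cluster.hkmeans(
        feat,
        k,
        seed=fold_seed,
        max_iter=config.max_iter,
        init_max_points=config.init_max_points,
    )
    threshold = cluster.flag_threshold(x.size, config.alpha)
    flags = np.zeros(x.size, dtype=bool)
    flags[cluster.flag_sparse(model, threshold)] = True
    return model, flags


def _fold_result(values, config, fold_index):
    model, flags = run_fold(values, config, _fold_seed(config.seed, fold_index))
    return model, flags


def run_pipeline(
    series: ObservationSeries, config: FlagConfig, n_jobs: int = 1
) -> FlagReport:
    """Full per-observation-type run: shuffle, partition, flag, aggregate.

    The report covers every input row exactly once, in shuffled fold order.
    Deterministic given (series, config): parallel execution (n_jobs != 1,
    via joblib) yields the same report as sequential because every fold is a
    pure function of its values and sub-seed.  A trailing fold of a single
    point cannot be clustered; it is carried into the report unflagged, with
    a warning.
    """
    import pandas as pd

    if len(series) == 0:
        raise ValueError("cannot run the pipeline on an empty series")
    shuffled = shuffle_observations(series, config.seed)
    folds = partition_folds(shuffled, config.fold_size)
    log.info(
        "%s: %d rows in %d folds (fold_size=%d, alpha=%g)",
        series.concept_code, len(series), len(folds), config.fold_size,
        config.alpha,
    )

    runnable = [f for f in folds if len(f) >= 2]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_fold_result)(
            shuffled.values[f.start : f.stop], config, f.fold_index
        )
        for f in runnable
    )
    by_index = {f.fold_index: r for f, r in zip(runnable, results)}

    frames = []
    for f in folds:
        vals = shuffled.values[f.start : f.stop]
        ids = shuffled.row_ids[f.start : f.stop]
        if f.fold_index in by_index:
            model, flags = by_index[f.fold_index]
            cluster_idx = model.assignments
            pops = model.populations[model.assignments]
            log.debug(
                "fold %d: k=%d, %d flagged", f.fold_index, model.k,
                int(flags.sum()),
            )
        else:
            warnings.warn(
                f"fold {f.fold_index} has fewer than 2 points; not clustered",
                stacklevel=2,
            )
            flags = np.zeros(len(f), dtype=bool)
            cluster_idx = np.zeros(len(f), dtype=int)
            pops = np.ones(len(f), dtype=int)
        frames.append(
            pd.DataFrame(
                {
                    "row_id": ids,
                    "value": vals,
                    "flagged": flags,
                    "fold_index": f.fold_index,
                    "cluster_index": cluster_idx,
                    "cluster_population": pops,
                }
            )
        )
    rows = pd.concat(frames, ignore_index=True)
    return FlagReport(concept_code=series.concept_code, rows=rows)
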