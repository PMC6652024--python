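"""Silver-standard evaluation of flaggers.

Labels come from the per-observation-type plausibility interval: a value is
truly implausible iff it lies strictly outside [low, high] (the bounds
themselves are plausible).  From labels and flags we compute the 2x2
confusion matrix and sensitivity, specificity and fallout; sensitivity is
undefined (NaN) when there are no truly implausible rows.  Two detectors
are compared on false positives with an exact two-sided binomial test on
the truly-plausible rows where exactly one of them flags (McNemar-style,
null proportion 1/2).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .pipeline import FlagConfig, run_pipeline
from .types import ConfusionCounts, ObservationSeries, SilverStandard

__all__ = [
    "EvaluationResult",
    "FalsePositiveComparison",
    "silver_labels",
    "confusion",
    "compare_false_positives",
    "sweep_alphas",
]


@dataclass(frozen=True)
class EvaluationResult:
    counts: ConfusionCounts
    sensitivity: float  # NaN when no positive labels
    specificity: float  # NaN when no negative labels
    fallout: float      # 1 - specificity

    def to_dict(self) -> dict:
        c = self.counts
        return {
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fallout": self.fallout,
        }


class FalsePositiveComparison(NamedTuple):
    fp_a: int
    fp_b: int
    p_value: float


def silver_labels(
    series: ObservationSeries, standard: SilverStandard
) -> np.ndarray:
    """True iff the value is strictly outside [low, high]."""
    if standard.concept_code != series.concept_code:
        warnings.warn(
            f"evaluating series {series.concept_code!r} against standard "
            f"for {standard.concept_code!r}",
            stacklevel=2,
        )
    v = series.values
    return (v < standard.low) | (v > standard.high)


def confusion(labels, flags) -> EvaluationResult:
    """Confusion counts and indices for one detector against the labels."""
    labels = np.asarray(labels, dtype=bool)
    flags = np.asarray(flags, dtype=bool)
    if labels.shape != flags.shape:
        raise ValueError("labels and flags must have equal length")
    tp = int(np.sum(labels & flags))
    fn = int(np.sum(labels & ~flags))
    fp = int(np.sum(~labels & flags))
    tn = int(np.sum(~labels & ~flags))
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    fallout = 1.0 - spec if not math.isnan(spec) else math.nan
    return EvaluationResult(
        counts=ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn),
        sensitivity=sens,
        specificity=spec,
        fallout=fallout,
    )


def compare_false_positives(labels, flags_a, flags_b) -> FalsePositiveComparison:
    """Paired false-positive comparison of two detectors.

    Counts each detector's false positives on the truly-plausible rows and
    tests, with an exact two-sided binomial on the rows where exactly one
    detector false-positives, whether the discordances split evenly
    (p = 1 when there are none).
    """
    labels = np.asarray(labels, dtype=bool)
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if not (labels.shape == a.shape == b.shape):
        raise ValueError("labels and both flag vectors must have equal length")
    plaus = ~labels
    fp_a = int(np.sum(a & plaus))
    fp_b = int(np.sum(b & plaus))
    only_a = int(np.sum(a & ~b & plaus))
    only_b = int(np.sum(b & ~a & plaus))
    n_disc = only_a + only_b
    if n_disc == 0:
        p = 1.0
    else:
        p = float(binomtest(only_a, n_disc, 0.5, alternative="two-sided").pvalue)
    return FalsePositiveComparison(fp_a=fp_a, fp_b=fp_b, p_value=p)


def sweep_alphas(
    series: ObservationSeries,
    standard: SilverStandard,
    alphas,
    config: FlagConfig | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """One pipeline run + evaluation per sparsity ratio.

    Returns a table ordered by alpha descending (most liberal first) with
    the confusion counts and indices per setting.  fold_size is re-coupled
    to each alpha as round(1/alpha).
    """
    alphas = sorted(alphas, reverse=True)
    if not alphas:
        raise ValueError("alphas must be non-empty")
    base = config.to_dict() if config is not None else FlagConfig().to_dict()
    labels = silver_labels(series, standard)
    records = []
    for alpha in alphas:
        cfg_dict = dict(base, alpha=alpha, fold_size=None)
        cfg = FlagConfig(**cfg_dict)
        report = run_pipeline(series, cfg, n_jobs=n_jobs)
        res = confusion(labels, report.flags_for(series))
        records.append(
            {"alpha": alpha, "fold_size": cfg.fold_size, **res.to_dict()}
        )
    return pd.DataFrame.from_records(records)
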