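"""Core domain types shared across the package.

The unit of analysis is a single observation type (one LOINC-style code):
a vector of numeric results ``x(1..n)`` carried together with stable row
identifiers so that every flag can be traced back to its source row.
Silver-standard plausibility intervals are evaluation-only labels; the
detector itself never sees them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "ObservationSeries",
    "SilverStandard",
    "FlagReport",
    "ConfusionCounts",
    "FLAG_REPORT_COLUMNS",
]


class ConfigurationError(Exception):
    """Bad user-supplied configuration (missing column, malformed option)."""


class ValidationError(Exception):
    """Input data violate a documented invariant (e.g. low > high)."""


@dataclass
class ObservationSeries:
    """Numeric results for one observation type, in source order.

    Parameters
    ----------
    concept_code:
        Observation-type identifier (LOINC-style string).
    values:
        Finite numeric results, units as recorded at source (never converted).
    row_ids:
        Stable provenance identifier per value; unique within the series.
    n_excluded:
        Count of source rows dropped before construction because their value
        did not parse to a finite number.
    """

    concept_code: str
    values: np.ndarray
    row_ids: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = np.asarray(self.row_ids, dtype=object)
        if self.values.ndim != 1:
            raise ValidationError("values must be one-dimensional")
        if self.values.shape != self.row_ids.shape:
            raise ValidationError("values and row_ids must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError(
                f"non-finite values in series {self.concept_code!r}"
            )
        if len(set(self.row_ids.tolist())) != self.row_ids.size:
            raise ValidationError(
                f"duplicate row_ids in series {self.concept_code!r}"
            )

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SilverStandard:
    """Per-observation-type plausibility interval ``[low, high]``.

    Values strictly below ``low`` or strictly above ``high`` are implausible;
    the bounds themselves are plausible (closed interval).  Used only to
    derive evaluation labels, never by the detector.
    """

    concept_code: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.high):
            raise ValidationError(
                f"silver standard for {self.concept_code!r}: "
                f"low ({self.low}) > high ({self.high})"
            )


FLAG_REPORT_COLUMNS = (
    "row_id",
    "value",
    "flagged",
    "fold_index",
    "cluster_index",
    "cluster_population",
)


@dataclass
class FlagReport:
    """Per-row flag decisions with fold/cluster provenance.

    ``rows`` is a DataFrame with columns ``row_id, value, flagged,
    fold_index, cluster_index, cluster_population``; every input row appears
    exactly once (the folds partition the series).
    """

    concept_code: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FLAG_REPORT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"flag report missing columns: {missing}")
        if self.rows["row_id"].duplicated().any():
            raise ValidationError("flag report contains duplicate row_ids")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def flags(self) -> np.ndarray:
        """Boolean flag per row, in report order."""
        return self.rows["flagged"].to_numpy(dtype=bool)

    @property
    def flagged_row_ids(self) -> list:
        return self.rows.loc[self.rows["flagged"], "row_id"].tolist()

    def flags_for(self, series: ObservationSeries) -> np.ndarray:
        """Boolean flags aligned to ``series`` order (joined on row_id)."""
        lookup = dict(
            zip(self.rows["row_id"].tolist(), self.rows["flagged"].tolist())
        )
        return np.array([bool(lookup[r]) for r in series.row_ids], dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion-matrix cell counts (positive class = implausible)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn
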