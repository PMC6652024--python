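"""Readers and writers for observation tables, silver standards and reports.

Observation tables are delimited text with a header; the default column
names (``concept_cd``, ``nval_num``) echo the i2b2 ``observation_fact``
star schema that large clinical data warehouses expose.  Values that do not
parse to a finite number are excluded with a logged count rather than
raising — warehouse extracts routinely interleave textual results.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import (
    FLAG_REPORT_COLUMNS,
    ConfigurationError,
    FlagReport,
    ObservationSeries,
    SilverStandard,
    ValidationError,
)

__all__ = [
    "read_observations",
    "read_silver_standards",
    "write_flag_report",
    "read_flag_report",
    "write_observations",
]

log = logging.getLogger(__name__)


def read_observations(
    path,
    concept_column: str = "concept_cd",
    value_column: str = "nval_num",
    id_column: str | None = None,
    delimiter: str = ",",
) -> dict[str, ObservationSeries]:
    """Read a delimited observation table into one series per concept code.

    Row order within each concept follows the file.  Provenance row ids are
    taken from ``id_column`` when given, else synthesised from the file row
    number.  Rows whose value is missing or non-numeric are excluded and
    counted on the series (``n_excluded``).
    """
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"observation file {path} is empty", stacklevel=2)
        return {}
    for col in (concept_column, value_column):
        if col not in frame.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} "
                f"(available: {list(frame.columns)})"
            )
    if id_column is not None and id_column not in frame.columns:
        raise ConfigurationError(f"id column {id_column!r} not found in {path}")
    numeric = pd.to_numeric(frame[value_column], errors="coerce")
    numeric[~np.isfinite(numeric)] = np.nan
    if id_column is not None:
        row_ids = frame[id_column].astype(str)
    else:
        row_ids = pd.Series(
            [f"row{i}" for i in range(len(frame))], index=frame.index
        )
    out: dict[str, ObservationSeries] = {}
    for code, idx in frame.groupby(concept_column, sort=False).groups.items():
        vals = numeric.loc[idx]
        ok = vals.notna()
        n_excluded = int((~ok).sum())
        if n_excluded:
            log.info(
                "%s: excluded %d non-numeric rows", code, n_excluded
            )
        out[str(code)] = ObservationSeries(
            concept_code=str(code),
            values=vals[ok].to_numpy(dtype=float),
            row_ids=row_ids.loc[idx][ok].to_numpy(dtype=object),
            n_excluded=n_excluded,
        )
    return out


def write_observations(
    series: ObservationSeries,
    path,
    concept_column: str = "concept_cd",
    value_column: str = "nval_num",
    id_column: str = "row_id",
    delimiter: str = ",",
) -> None:
    """Write one series back to a delimited observation table."""
    pd.DataFrame(
        {
            id_column: series.row_ids,
            concept_column: series.concept_code,
            value_column: series.values,
        }
    ).to_csv(path, sep=delimiter, index=False)


def read_silver_standards(path, delimiter: str = ",") -> dict[str, SilverStandard]:
    """Read the silver-standard table (columns concept_code, low, high)."""
    frame = pd.read_csv(path, sep=delimiter)
    for col in ("concept_code", "low", "high"):
        if col not in frame.columns:
            raise ConfigurationError(
                f"column {col!r} not found in silver-standard table {path}"
            )
    out: dict[str, SilverStandard] = {}
    for rec in frame.itertuples(index=False):
        code = str(rec.concept_code)
        low, high = float(rec.low), float(rec.high)
        if low > high:
            raise ValidationError(
                f"silver standard for {code!r}: low ({low}) > high ({high})"
            )
        out[code] = SilverStandard(concept_code=code, low=low, high=high)
    return out


def write_flag_report(report: FlagReport, path, delimiter: str = ",") -> None:
    """Write the flag report as delimited text; round-trips losslessly."""
    report.rows.loc[:, list(FLAG_REPORT_COLUMNS)].to_csv(
        path, sep=delimiter, index=False
    )


def read_flag_report(path, concept_code: str = "", delimiter: str = ",") -> FlagReport:
    rows = pd.read_csv(
        path,
        sep=delimiter,
        dtype={
            "row_id": str,
            "value": float,
            "flagged": bool,
            "fold_index": int,
            "cluster_index": int,
            "cluster_population": int,
        },
    )
    rows["row_id"] = rows["row_id"].astype(object)
    return FlagReport(concept_code=concept_code, rows=rows)
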