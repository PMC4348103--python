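"""Marker quality control and column standardization.

QC follows the conventional pipeline for dominant presence/absence markers:
drop markers with minor allele frequency below a threshold, then drop one of
each pair of near-duplicate markers (squared Pearson correlation above a
threshold), scanning left to right and keeping the earlier column.  Covariate
columns are then rescaled to mean zero, variance one, and missing entries are
set to zero *after* rescaling — i.e. imputed at the column mean.

Standardization statistics are kept separate from the data so that scaling
fitted on a training fold can be applied without leakage to held-out samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import NotBinaryError, ShapeMismatchError, TooFewRowsError
from .tabular_io import SampleTable


@dataclass
class DroppedFeature:
    name: str
    reason: str  # "maf" or "r2"
    partner: Optional[str] = None  # retained near-duplicate, for reason "r2"


@dataclass
class StandardizationStats:
    """Column means/SDs (and optional trait mean) from a reference sample set."""

    column_means: np.ndarray
    column_sds: np.ndarray
    constant_mask: np.ndarray  # columns with zero or undefined spread
    trait_mean: Optional[float] = None
    source: str = "training-fold"  # or "full-data"

    @property
    def n_features(self) -> int:
        return self.column_means.shape[0]


@dataclass
class CovariateSet:
    """A named, standardized covariate block plus its provenance."""

    name: str
    matrix: np.ndarray
    stats: StandardizationStats
    kept_features: list[str]
    dropped_features: list[DroppedFeature] = field(default_factory=list)


def _check_binary_marker(table: SampleTable) -> None:
    if table.role != "marker":
        raise ValueError("operation requires a marker-role table")
    observed = table.values[np.isfinite(table.values)]
    if np.any((observed != 0.0) & (observed != 1.0)):
        raise NotBinaryError("marker table contains a value outside {0, 1, missing}")


def filter_maf(
    table: SampleTable, maf_min: float = 0.01
) -> tuple[SampleTable, list[DroppedFeature]]:
    """Drop markers with minor allele frequency below ``maf_min``.

    The frequency is computed over non-missing calls only; a marker with no
    calls at all is dropped.  Returns the filtered table and the drop log.
    """
    _check_binary_marker(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(table.values, axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= maf_min  # NaN compares False: all-missing columns drop
    dropped = [
        DroppedFeature(name, "maf")
        for name, k in zip(table.feature_names, keep)
        if not k
    ]
    kept_names = [f for f, k in zip(table.feature_names, keep) if k]
    return table.subset_columns(kept_names), dropped


def dedup_correlated(
    table: SampleTable, r2_max: float = 0.95
) -> tuple[SampleTable, list[DroppedFeature]]:
    """Drop one of each marker pair with squared correlation above ``r2_max``.

    Greedy left-to-right scan in column order: a column is dropped as soon
    as its pairwise-complete squared Pearson correlation with any *retained*
    earlier column exceeds the threshold; the earlier column is kept.
    Constant columns have undefined correlations and are never dropped here.
    """
    _check_binary_marker(table)
    corr = table.to_frame().corr(min_periods=2).to_numpy()
    r2 = corr**2
    kept_idx: list[int] = []
    dropped: list[DroppedFeature] = []
    for j in range(table.n_features):
        partner = None
        if kept_idx:
            with np.errstate(invalid="ignore"):
                hits = np.asarray(kept_idx)[
                    np.where(r2[j, kept_idx] > r2_max)[0]
                ]
            if hits.size:
                partner = int(hits[0])
        if partner is None:
            kept_idx.append(j)
        else:
            dropped.append(
                DroppedFeature(
                    table.feature_names[j], "r2", table.feature_names[partner]
                )
            )
    kept_names = [table.feature_names[j] for j in kept_idx]
    return table.subset_columns(kept_names), dropped


def qc_markers(
    table: SampleTable, maf_min: float = 0.01, r2_max: float = 0.95
) -> tuple[SampleTable, list[DroppedFeature]]:
    """Full marker QC in fixed order: MAF filter, then near-duplicate removal."""
    filtered, dropped_maf = filter_maf(table, maf_min)
    deduped, dropped_r2 = dedup_correlated(filtered, r2_max)
    return deduped, dropped_maf + dropped_r2


def qc_report_frame(dropped: list[DroppedFeature], kept: list[str]) -> pd.DataFrame:
    """Tabulate QC outcomes: one row per input feature, kept or dropped."""
    rows = [
        {"feature": f, "status": "kept", "reason": "", "partner": ""} for f in kept
    ]
    rows += [
        {
            "feature": d.name,
            "status": "dropped",
            "reason": d.reason,
            "partner": d.partner or "",
        }
        for d in dropped
    ]
    return pd.DataFrame(rows, columns=["feature", "status", "reason", "partner"])


def standardize_fit(
    matrix: np.ndarray,
    trait: Optional[np.ndarray] = None,
    ddof: int = 1,
    source: str = "training-fold",
) -> tuple[np.ndarray, StandardizationStats]:
    """Rescale each column to mean 0, variance 1; then set missing entries to 0.

    Sample statistics use an ``n - 1`` denominator by default.  Columns with
    zero (or undefined) spread are flagged constant and zeroed entirely.  The
    trait, if given, contributes only its mean (it is centered, not scaled).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise TooFewRowsError("standardization needs a 2-D matrix with >= 2 rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(matrix, axis=0)
        sds = np.nanstd(matrix, axis=0, ddof=ddof)
    constant = ~np.isfinite(sds) | (sds == 0.0) | ~np.isfinite(means)
    stats = StandardizationStats(
        column_means=np.where(np.isfinite(means), means, 0.0),
        column_sds=np.where(constant, 0.0, sds),
        constant_mask=constant,
        trait_mean=float(np.mean(trait)) if trait is not None else None,
        source=source,
    )
    return standardize_apply(matrix, stats), stats


def standardize_apply(
    matrix: np.ndarray, stats: StandardizationStats
) -> np.ndarray:
    """Apply stored means/SDs to new rows; missing and constant columns -> 0."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != stats.n_features:
        raise ShapeMismatchError(
            f"matrix has {matrix.shape[-1]} columns, stats expect {stats.n_features}"
        )
    safe_sds = np.where(stats.constant_mask, 1.0, stats.column_sds)
    z = (matrix - stats.column_means) / safe_sds
    z[:, stats.constant_mask] = 0.0
    z[~np.isfinite(z)] = 0.0  # missing entries impute to the column mean
    return z


def standardize_table(
    name: str, table: SampleTable, dropped: Optional[list[DroppedFeature]] = None
) -> CovariateSet:
    """Standardize a whole table at once (full-data statistics)."""
    z, stats = standardize_fit(table.values, source="full-data")
    return CovariateSet(
        name=name,
        matrix=z,
        stats=stats,
        kept_features=list(table.feature_names),
        dropped_features=dropped or [],
    )
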