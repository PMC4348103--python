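"""Reading, writing and aligning sample-by-feature tables.

The on-disk convention is a delimited text file with a header row; the
first column holds sample IDs and every other column one feature.  Missing
values are written as a configurable token (``"NA"`` by default).  All
downstream modules work on :class:`AlignedDataset`, so files are read
exactly once per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateIdError,
    EmptyIntersectionError,
    EmptyTableError,
    NonNumericCellError,
    NotBinaryError,
)

logger = logging.getLogger(__name__)

ROLES = ("trait", "marker", "metabolite")
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN")


@dataclass
class SampleTable:
    """A rectangular samples x features table with explicit missing values.

    ``values`` is a float matrix in which ``NaN`` marks a missing entry.
    Marker-role tables are validated to contain only {0, 1, missing}.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.role not in ROLES:
            raise ValueError(f"unknown table role {self.role!r}; expected one of {ROLES}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n == 0:
            raise EmptyTableError("table has no samples")
        # m == 0 is permitted in memory: QC can legitimately drop every column
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match column count")
        if len(set(self.sample_ids)) != n:
            raise DuplicateIdError("duplicate sample IDs")
        if len(set(self.feature_names)) != m:
            raise DuplicateIdError("duplicate feature names")
        if self.role == "marker":
            observed = self.values[np.isfinite(self.values)]
            bad = observed[(observed != 0.0) & (observed != 1.0)]
            if bad.size:
                raise NotBinaryError(
                    f"marker table contains non-binary value {bad.flat[0]!r}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def subset_rows(self, sample_ids: Sequence[str]) -> "SampleTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return SampleTable(
            list(sample_ids), list(self.feature_names), self.values[rows], self.role
        )

    def subset_columns(self, feature_names: Sequence[str]) -> "SampleTable":
        index = {f: j for j, f in enumerate(self.feature_names)}
        cols = [index[f] for f in feature_names]
        return SampleTable(
            list(self.sample_ids), list(feature_names), self.values[:, cols], self.role
        )


@dataclass
class AlignedDataset:
    """A trait table plus covariate blocks restricted to common samples.

    Every member table carries identical sample IDs in identical order, so
    row i always refers to the same variety across blocks.
    """

    sample_ids: list[str]
    trait_table: SampleTable
    covariate_blocks: list[tuple[str, SampleTable]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.covariate_blocks:
            raise ValueError("at least one covariate block is required")
        for name, table in [("trait", self.trait_table)] + list(self.covariate_blocks):
            if table.sample_ids != self.sample_ids:
                raise ValueError(f"block {name!r} sample IDs are not aligned")

    def block(self, name: str) -> SampleTable:
        for bname, table in self.covariate_blocks:
            if bname == name:
                return table
        raise KeyError(name)


def _read_header(path: Path, delimiter: str) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\r\n")
    return first.split(delimiter)


def read_table(
    path: str | Path,
    role: str,
    delimiter: str = ",",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> SampleTable:
    """Read a delimited table (header row, first column = sample ID).

    Any cell that is not parseable as a number and is not one of
    ``missing_tokens`` raises :class:`NonNumericCellError` naming the
    offending row and column.  Duplicate sample IDs or feature names raise
    :class:`DuplicateIdError`.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    header = _read_header(path, delimiter)
    features = header[1:]
    if len(set(features)) != len(features):
        raise DuplicateIdError(f"duplicate feature names in header of {path}")

    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, index_col=0
    )
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise EmptyTableError(f"{path} has no data rows or columns")
    ids = [str(s) for s in raw.index]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"duplicate sample IDs in {path}")

    tokens = set(missing_tokens)
    cells = raw.to_numpy(dtype=object)
    stripped = np.vectorize(lambda c: str(c).strip(), otypes=[object])(cells)
    missing_mask = np.isin(stripped, list(tokens))
    # exact float() conversion (pandas' fast parser is not round-trip safe)
    try:
        values = np.where(missing_mask, "nan", stripped).astype(float)
    except ValueError:
        for (i, j), cell in np.ndenumerate(stripped):
            if missing_mask[i, j]:
                continue
            try:
                float(cell)
            except ValueError:
                raise NonNumericCellError(
                    f"non-numeric cell {cell!r} at sample {ids[i]!r}, "
                    f"feature {features[j]!r} in {path}"
                ) from None
        raise  # pragma: no cover - conversion failed but no cell identified
    values[missing_mask] = np.nan
    return SampleTable(ids, features, values, role)


def write_table(
    table: SampleTable,
    path: str | Path,
    delimiter: str = ",",
    missing_token: str = "NA",
) -> None:
    """Write a table in the same delimited convention ``read_table`` expects.

    Floats are written with ``repr`` precision so a write/read round-trip
    reproduces values exactly.
    """
    frame = table.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=delimiter, na_rep=missing_token)


def align(
    trait: SampleTable, blocks: Mapping[str, SampleTable]
) -> AlignedDataset:
    """Restrict all tables to their common samples, in trait-table order.

    The trait table's ordering is the canonical one; rows present in some
    tables but not others are dropped (and the counts logged).
    """
    if not blocks:
        raise ValueError("at least one covariate block is required")
    common = set(trait.sample_ids)
    for table in blocks.values():
        common &= set(table.sample_ids)
    if not common:
        raise EmptyIntersectionError("no sample IDs shared by all tables")
    ordered = [s for s in trait.sample_ids if s in common]

    dropped = len(trait.sample_ids) - len(ordered)
    if dropped:
        logger.info("align: dropped %d samples from trait table", dropped)
    aligned_blocks = []
    for name, table in blocks.items():
        d = table.n_samples - len(ordered)
        if d:
            logger.info("align: dropped %d samples from block %r", d, name)
        aligned_blocks.append((name, table.subset_rows(ordered)))
    return AlignedDataset(ordered, trait.subset_rows(ordered), aligned_blocks)


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
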