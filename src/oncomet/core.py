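"""Core containers shared by every stage of the pipeline.

The two central objects are :class:`AbundanceMatrix` — a features × samples
grid of positive measurements (metabolite intensities or gene expression)
carrying a ``scale_tag`` that records how far along the normalization chain
the values are — and :class:`SampleAnnotation`, a per-sample table of
histology, group labels, genotype flags, run-day block, and freeze time.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Allowed normalization states, in pipeline order.  Operations in
#: :mod:`oncomet.preprocess` only accept inputs strictly earlier in this
#: order than their own output state, so running the chain out of order
#: raises instead of silently producing nonsense.
SCALE_ORDER = ("raw", "block_corrected", "imputed", "pqn", "log2")


class ConfigError(ValueError):
    """A configuration field is missing or invalid."""


class DataError(ValueError):
    """Input data violate a precondition of the requested operation."""


class ScaleOrderError(DataError):
    """An operation was applied at the wrong point of the normalization chain."""


@dataclasses.dataclass
class AbundanceMatrix:
    """Features × samples measurement grid.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.  Missing measurements are NaN.
    scale_tag
        Position in the normalization chain; one of :data:`SCALE_ORDER`.
    """

    data: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_ORDER:
            raise ScaleOrderError(
                f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_ORDER}"
            )
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicated feature identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataError(f"duplicated sample identifier: {dup!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    # -- invariant helpers ----------------------------------------------
    def require_scale(self, *allowed: str) -> None:
        if self.scale_tag not in allowed:
            raise ScaleOrderError(
                f"operation requires scale_tag in {allowed}, got {self.scale_tag!r}"
            )

    def require_complete(self) -> None:
        if self.data.isna().any().any():
            n = int(self.data.isna().sum().sum())
            raise DataError(f"matrix contains {n} missing values; impute first")

    def require_positive(self) -> None:
        if (self.data <= 0).any().any():
            raise DataError("matrix contains non-positive values")

    # -- derived matrices ------------------------------------------------
    def with_data(self, data: pd.DataFrame, scale_tag: str) -> "AbundanceMatrix":
        return AbundanceMatrix(data=data, scale_tag=scale_tag)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"samples not in matrix: {missing[:5]}")
        return AbundanceMatrix(self.data.loc[:, list(sample_ids)].copy(), self.scale_tag)

    def subset_features(self, feature_ids: Sequence[str]) -> "AbundanceMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise DataError(f"features not in matrix: {missing[:5]}")
        return AbundanceMatrix(self.data.loc[list(feature_ids)].copy(), self.scale_tag)

    def unlogged(self) -> pd.DataFrame:
        """Values on the linear scale regardless of the current tag."""
        if self.scale_tag == "log2":
            return np.exp2(self.data)
        return self.data


#: Columns :class:`SampleAnnotation` understands.  Only ``group`` is
#: mandatory; the rest are used by specific stages when present.
ANNOTATION_COLUMNS = (
    "group",        # tumor / normal
    "histology",    # HMIN / HWIDE / HA / PDTC / TCV-PTC / normal
    "recurrence",   # bool
    "gLOH",         # bool — genome-wide loss of heterozygosity
    "mtDNA",        # bool — truncating mtDNA mutation
    "mTOR",         # bool — mTOR-pathway alteration
    "TERT",         # bool — TERT promoter mutation
    "block",        # run-day batch identifier
    "freeze_time",  # hours from resection to freezing
)


@dataclasses.dataclass
class SampleAnnotation:
    """Per-sample metadata table, indexed by sample identifier."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataError(f"duplicated sample identifier in annotation: {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise DataError(f"annotation column {name!r} not present")
        return self.table[name]

    def blocks(self) -> pd.Series:
        return self.column("block")

    def freeze_time(self) -> pd.Series:
        return self.column("freeze_time").astype(float)

    def samples_in_group(self, label: str, column: str = "group") -> list[str]:
        col = self.column(column)
        return list(col.index[col == label])

    def aggressive(self) -> pd.Series:
        """Clinical-aggressiveness indicator: widely invasive or recurrent.

        Used to order integrated clusters from least to most aggressive.
        """
        hist = self.column("histology").astype(str)
        agg = hist.str.upper() == "HWIDE"
        if "recurrence" in self.table.columns:
            agg = agg | self.table["recurrence"].astype(bool)
        return agg

    def subset(self, sample_ids: Iterable[str]) -> "SampleAnnotation":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.table.index]
        if missing:
            raise DataError(f"samples not in annotation: {missing[:5]}")
        return SampleAnnotation(self.table.loc[ids].copy())
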