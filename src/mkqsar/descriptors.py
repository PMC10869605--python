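"""Compound-by-descriptor matrix container.

A :class:`DescriptorMatrix` holds the numeric feature table a QSAR model is
fitted on: one row per compound, one named column per molecular descriptor.
Values are stored as a float array with ``NaN`` marking missing cells, so the
container stays a thin, labelled wrapper over NumPy that converts losslessly
to and from :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DescriptorMatrix"]


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors table with row/column labels.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_compounds, n_descriptors)``.  Missing
        entries are ``NaN``.
    row_ids
        Compound identifiers, one per row.  Kept as strings so integer ids
        and designed-compound labels ("44a") coexist.
    col_names
        Descriptor names, one per column, unique.
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if not self.row_ids:
            self.row_ids = [str(i + 1) for i in range(n)]
        if not self.col_names:
            self.col_names = [f"d{j}" for j in range(p)]
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_names = [str(c) for c in self.col_names]
        if len(self.row_ids) != n:
            raise ValueError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.col_names) != p:
            raise ValueError(f"{len(self.col_names)} column names for {p} columns")
        if len(set(self.col_names)) != p:
            dupes = sorted({c for c in self.col_names if self.col_names.count(c) > 1})
            raise ValueError(f"duplicate descriptor names: {dupes}")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True where a cell is missing."""
        return np.isnan(self.values)

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.col_names.index(name)]

    def subset(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Restrict to the given descriptor columns, in the given order."""
        idx = [self.col_names.index(n) for n in names]
        return DescriptorMatrix(
            self.values[:, idx].copy(), list(self.row_ids), [self.col_names[i] for i in idx]
        )

    def drop(self, names: Sequence[str]) -> "DescriptorMatrix":
        keep = [c for c in self.col_names if c not in set(names)]
        return self.subset(keep)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.col_names)
        df.insert(0, "compound_id", self.row_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str = "compound_id") -> "DescriptorMatrix":
        cols = [c for c in df.columns if c != id_column]
        row_ids = [str(r) for r in df[id_column]] if id_column in df.columns else []
        values = df[cols].to_numpy(dtype=float)
        return cls(values, row_ids, cols)

    def equals(self, other: "DescriptorMatrix", atol: float = 0.0) -> bool:
        return (
            self.row_ids == other.row_ids
            and self.col_names == other.col_names
            and np.allclose(self.values, other.values, atol=atol, equal_nan=True)
        )
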