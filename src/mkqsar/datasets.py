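"""Packaged PARP1-inhibitor activity data and table I/O.

The package ships the published activity table for 57 fused tetracyclic /
pentacyclic dihydrodiazepinoindolone derivatives (FTPDDs): measured
lg(IC50) against PARP1, the predictions of six fitted models (heuristic
multilinear regression, gene expression programming, random forest, and
epsilon-SVR with single / double / triple kernels), and the train/test split
flag.  Substituent labels are stored as the literal text printed for each
compound; positions drawn as structure images carry the token ``figure``.

Also shipped: the eight-descriptor multilinear model (symbol, meaning,
regression coefficient) and the designed-compound list (parent compound 44
plus six derivatives with predicted IC50 and docking score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix

__all__ = [
    "CompoundRecord",
    "ActivityTable",
    "HmDescriptorFixture",
    "MODEL_NAMES",
    "load_activity_table",
    "load_hm_descriptors",
    "load_new_compounds",
    "read_descriptor_csv",
    "write_descriptor_csv",
    "write_predictions_csv",
    "read_predictions_csv",
]

#: Prediction columns present for every compound, in report order.
MODEL_NAMES = ("HM", "GEP", "RF", "SVR1", "SVR2", "SVR3")

_CSV_MODEL_COLS = {
    "HM": "hm",
    "GEP": "gep",
    "RF": "rf",
    "SVR1": "svr_single",
    "SVR2": "svr_double",
    "SVR3": "svr_triple",
}


@dataclass
class CompoundRecord:
    """One compound: substituents, measured activity, model predictions."""

    compound_id: int
    substituents: dict[str, str]
    measured_lg_ic50: float
    predictions: dict[str, float]
    is_test: bool

    def __post_init__(self) -> None:
        if self.compound_id <= 0:
            raise ValueError("compound_id must be positive")
        if not math.isfinite(self.measured_lg_ic50):
            raise ValueError(f"non-finite measured value for compound {self.compound_id}")
        missing = [m for m in MODEL_NAMES if m not in self.predictions]
        if missing:
            raise ValueError(f"compound {self.compound_id} lacks predictions for {missing}")


@dataclass
class ActivityTable:
    """Ordered collection of :class:`CompoundRecord` with a provenance note."""

    records: list[CompoundRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate compound ids")
        flags = {r.is_test for r in self.records}
        if self.records and flags != {True, False} and len(self.records) > 1:
            raise ValueError("test flags must partition records into two non-empty groups")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, compound_id: int) -> CompoundRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    @property
    def train_records(self) -> list[CompoundRecord]:
        return [r for r in self.records if not r.is_test]

    @property
    def test_records(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.is_test]

    def measured(self, subset: str = "all") -> np.ndarray:
        recs = {"all": self.records, "train": self.train_records, "test": self.test_records}[subset]
        return np.array([r.measured_lg_ic50 for r in recs])

    def predicted(self, model: str, subset: str = "all") -> np.ndarray:
        recs = {"all": self.records, "train": self.train_records, "test": self.test_records}[subset]
        return np.array([r.predictions[model] for r in recs])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"compound_id": r.compound_id, "measured_lg_ic50": r.measured_lg_ic50}
            row.update({m: r.predictions[m] for m in MODEL_NAMES})
            row["is_test"] = r.is_test
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class HmDescriptorFixture:
    """The eight selected descriptors with meaning and regression slope."""

    entries: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        symbols = [e[0] for e in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("descriptor symbols must be unique")
        if any(not math.isfinite(e[2]) for e in self.entries):
            raise ValueError("coefficients must be finite")

    @property
    def symbols(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries])


def _fixture_path(name: str):
    return resources.files("mkqsar.data").joinpath(name)


# Measured vs model columns cannot be reconciled exactly with every summary
# statistic published alongside them; two printed test-set RMSE figures for
# the triple-kernel model (0.0288 and 0.0228) are both recorded here.
_PROVENANCE = (
    "57 FTPDD PARP1 inhibitors, measured lg(IC50) with six model prediction "
    "columns and starred test-set flags, transcribed at 4-decimal precision. "
    "Source reports triple-kernel test RMSE as 0.0288 (abstract) and 0.0228 "
    "(results section); both retained verbatim, unadjudicated."
)


def load_activity_table() -> ActivityTable:
    """Load the packaged 57-compound activity table.

    Returns a table with 45 training and 12 starred test compounds.

    Raises
    ------
    RuntimeError
        If the packaged CSV is missing or fails validation.
    """
    path = _fixture_path("activity_table.csv")
    try:
        df = pd.read_csv(path, dtype={"r1": str, "r2": str, "r3": str, "ring": str})
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise RuntimeError(f"corrupt or missing activity fixture {path}: {exc}") from exc
    records = []
    for _, row in df.iterrows():
        subs = {
            k: str(row[k])
            for k in ("r1", "r2", "r3", "ring")
            if isinstance(row[k], str) and row[k] != ""
        }
        preds = {m: float(row[c]) for m, c in _CSV_MODEL_COLS.items()}
        records.append(
            CompoundRecord(
                compound_id=int(row["compound_id"]),
                substituents=subs,
                measured_lg_ic50=float(row["measured_lg_ic50"]),
                predictions=preds,
                is_test=bool(int(row["is_test"])),
            )
        )
    table = ActivityTable(records, provenance=_PROVENANCE)
    ids = sorted(r.compound_id for r in table.records)
    if ids != list(range(1, 58)):
        raise RuntimeError(f"activity fixture {path} does not cover compounds 1-57")
    return table


def load_hm_descriptors() -> HmDescriptorFixture:
    """Load the eight-descriptor multilinear-model fixture."""
    path = _fixture_path("hm_descriptors.csv")
    try:
        df = pd.read_csv(path)
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise RuntimeError(f"corrupt or missing descriptor fixture {path}: {exc}") from exc
    return HmDescriptorFixture(
        [(str(r.symbol), str(r.meaning), float(r.coefficient)) for r in df.itertuples()]
    )


def load_new_compounds() -> pd.DataFrame:
    """Designed compounds: parent 44 plus six derivatives (predicted IC50, docking score)."""
    path = _fixture_path("new_compounds.csv")
    try:
        return pd.read_csv(path, dtype={"compound_id": str})
    except (FileNotFoundError, pd.errors.ParserError) as exc:
        raise RuntimeError(f"corrupt or missing designed-compound fixture {path}: {exc}") from exc


def read_descriptor_csv(path: str | Path) -> DescriptorMatrix:
    """Read a compounds x descriptors CSV.

    Expects a header row of descriptor names with a leading compound-id
    column; blank cells become missing values (NaN).
    """
    # pandas silently renames duplicate header fields, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    names = [str(c) for c in header[1:]]
    if len(set(names)) != len(names):
        dupes = sorted({c for c in names if names.count(c) > 1})
        raise ValueError(f"duplicate descriptor names in {path}: {dupes}")
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed descriptor CSV {path}: {exc}") from exc
    return DescriptorMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], names
    )


def write_descriptor_csv(m: DescriptorMatrix, path: str | Path) -> None:
    """Write a descriptor matrix as CSV (inverse of :func:`read_descriptor_csv`)."""
    df = pd.DataFrame(m.values, index=m.row_ids, columns=m.col_names)
    df.index.name = "compound_id"
    df.to_csv(path)


def write_predictions_csv(table: ActivityTable, path: str | Path) -> None:
    """Write one row per compound: id, measured, six model columns, test flag."""
    df = table.to_dataframe()
    df["is_test"] = df["is_test"].astype(int)
    df.to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> ActivityTable:
    """Read a predictions CSV written by :func:`write_predictions_csv`."""
    df = pd.read_csv(path)
    records = [
        CompoundRecord(
            compound_id=int(row["compound_id"]),
            substituents={},
            measured_lg_ic50=float(row["measured_lg_ic50"]),
            predictions={m: float(row[m]) for m in MODEL_NAMES},
            is_test=bool(int(row["is_test"])),
        )
        for _, row in df.iterrows()
    ]
    return ActivityTable(records, provenance=f"read from {path}")
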