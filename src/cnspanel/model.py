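"""In-memory data model shared by every pipeline stage.

Bulk expression is held as a pandas DataFrame (rows = probes or genes,
columns = samples) wrapped in :class:`ExpressionMatrix` so that the row kind
travels with the values. Sample metadata is a DataFrame with one row per
sample; marker panels are small ordered containers of gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROW_KINDS = ("probe", "gene")
GROUPS = ("disease", "control")

#: metadata columns every SampleMetadata frame carries
META_COLUMNS = ("sample_id", "group", "age", "sex", "cohort")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass
class ExpressionMatrix:
    """Nonnegative linear-scale intensities, probes-or-genes x samples.

    Parameters
    ----------
    data:
        DataFrame indexed by probe or gene identifier, one column per
        sample. Values are linear-scale (never log) intensities.
    row_kind:
        ``"probe"`` before collapsing, ``"gene"`` after.
    """

    data: pd.DataFrame
    row_kind: str = "probe"

    def __post_init__(self) -> None:
        if self.row_kind not in ROW_KINDS:
            raise ValueError(f"row_kind must be one of {ROW_KINDS}, got {self.row_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        if values.size and (values < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        """Restrict to the given samples, preserving their order."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy(), self.row_kind)


def make_metadata(records) -> pd.DataFrame:
    """Build a validated sample-metadata frame.

    ``records`` is any DataFrame-constructible object with columns
    sample_id, group, and optionally age, sex, cohort. Missing ages become
    NaN and missing sex becomes ``"unknown"``.
    """
    meta = pd.DataFrame(records)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata requires sample_id and group columns")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups[:5]}")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"group must be one of {GROUPS}, got {sorted(bad)}")
    if "age" not in meta.columns:
        meta["age"] = np.nan
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    if (meta["age"].dropna() < 0).any():
        raise ValueError("ages must be nonnegative")
    if "sex" not in meta.columns:
        meta["sex"] = "unknown"
    meta["sex"] = meta["sex"].fillna("unknown")
    if "cohort" not in meta.columns:
        meta["cohort"] = ""
    return meta.loc[:, list(META_COLUMNS)].reset_index(drop=True)


@dataclass
class CellTypePanel:
    """A named cell type with its ordered marker-gene list.

    Symbols are upper-cased on construction so panel membership matching is
    case-insensitive everywhere downstream.
    """

    cell_type: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = [g.upper() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"panel {self.cell_type!r} has duplicate genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in set(self.genes)
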