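"""The central samples × lipid-features container and its CSV round trip.

A :class:`FeatureTable` is a wide peak-area matrix (features as rows, samples
as columns — the orientation vendor exports use) plus a sample → group map.
``QC`` is a reserved group label for pooled quality-control injections.
Missing cells (below detection) are ``NaN`` and serialize as empty strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

QC_GROUP = "QC"

__all__ = ["FeatureTable", "QC_GROUP", "read_feature_table", "write_feature_table"]


@dataclass
class FeatureTable:
    """Peak-area matrix with group labels.

    Parameters
    ----------
    values
        DataFrame, index = feature ids, columns = sample ids, cells = peak
        areas (arbitrary cps-scaled units); NaN marks an undetected cell.
    groups
        Mapping sample id → group label covering every column; the label
        ``"QC"`` marks pooled QC injections.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("peak areas must be non-negative")
        self.groups = self.groups.loc[self.values.columns]

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def qc_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == QC_GROUP]

    @property
    def biological_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g != QC_GROUP]

    @property
    def biological_groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.biological_samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def qc_matrix(self) -> pd.DataFrame:
        return self.values[self.qc_samples]

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(feature_ids)], self.groups.copy())

    def group_columns(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]


def read_feature_table(path: str | Path, groups_path: str | Path | None = None,
                       sep: str = ",") -> FeatureTable:
    """Read a wide CSV/TSV (features × samples) plus its group sidecar.

    The sidecar (default ``<path stem>.groups.csv``) has columns
    ``sample,group``. Empty cells and ``NA`` read as missing. If the matrix
    arrives transposed (sample ids in the index), it is auto-transposed.
    """
    path = Path(path)
    if groups_path is None:
        groups_path = path.with_suffix("").with_suffix(".groups.csv")
    groups_path = Path(groups_path)
    if not groups_path.exists():
        raise FileNotFoundError(f"group sidecar not found: {groups_path}")

    with open(path) as fh:
        header_cells = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dupes = [c for c in header_cells if c in seen or seen.add(c)]
    if dupes:
        raise ValueError(f"duplicate sample column(s) in header: {dupes}")
    values = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    meta = pd.read_csv(groups_path)
    groups = pd.Series(meta["group"].values, index=meta["sample"].astype(str))

    # transposed input: sample ids found in the row index instead of columns
    index_ids = set(map(str, values.index))
    col_ids = set(map(str, values.columns))
    known = set(groups.index)
    if index_ids <= known and not col_ids <= known:
        values = values.T
    values.index = values.index.map(str)
    values.columns = values.columns.map(str)
    return FeatureTable(values, groups)


def write_feature_table(table: FeatureTable, path: str | Path,
                        groups_path: str | Path | None = None,
                        sep: str = ",") -> None:
    """Write the matrix and its group sidecar; missing cells become ''."""
    path = Path(path)
    if groups_path is None:
        groups_path = path.with_suffix("").with_suffix(".groups.csv")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.values.to_csv(path, sep=sep, index_label="feature_id", na_rep="")
    pd.DataFrame({"sample": table.sample_ids,
                  "group": [table.groups[s] for s in table.sample_ids]}
                 ).to_csv(groups_path, index=False)
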