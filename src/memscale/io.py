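"""Site-table reading, validation and writing.

A site table is one CSV row per sampled field: an id column, planar
coordinates (projected km), environmental columns and per-species
abundance counts. The schema names the column groups so the pipeline can
split the table into its coordinate, explanatory and community blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import Coordinates
from .ordination import ExplanatoryMatrix
from .transform import CommunityMatrix

__all__ = ["SiteSchema", "SiteTable", "read_site_table", "write_site_table"]


@dataclass(frozen=True)
class SiteSchema:
    """Column-group declaration for a site-table CSV."""

    species_cols: tuple
    id_col: str = "site_id"
    x_col: str = "x_km"
    y_col: str = "y_km"
    env_cols: tuple = None  # None: every remaining column is environmental

    def __post_init__(self):
        object.__setattr__(self, "species_cols", tuple(self.species_cols))
        if self.env_cols is not None:
            object.__setattr__(self, "env_cols", tuple(self.env_cols))


@dataclass(frozen=True)
class SiteTable:
    """Row-aligned coordinates, environment and species counts."""

    coords: Coordinates
    env: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self):
        n = self.coords.n
        if len(self.env) != n or len(self.counts) != n:
            raise ValueError("coordinate, environment and species blocks have unequal row counts")

    @property
    def n(self) -> int:
        return self.coords.n

    @property
    def site_ids(self) -> tuple:
        return self.coords.site_ids

    def community(self) -> CommunityMatrix:
        return CommunityMatrix.from_frame(self.counts)

    def explanatory(self, columns=None) -> ExplanatoryMatrix:
        df = self.env if columns is None else self.env[list(columns)]
        return ExplanatoryMatrix.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"site_id": list(self.site_ids),
                           "x_km": self.coords.xy[:, 0],
                           "y_km": self.coords.xy[:, 1]})
        df = pd.concat([df, self.env.reset_index(drop=True),
                        self.counts.reset_index(drop=True)], axis=1)
        return df


def _require_columns(df: pd.DataFrame, needed, what: str):
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"site table is missing {what} column(s): {', '.join(missing)}")


def _numeric_block(df: pd.DataFrame, cols, what: str) -> pd.DataFrame:
    block = df[list(cols)].apply(pd.to_numeric, errors="coerce")
    bad = block.isna() & ~df[list(cols)].isna()
    if bad.any().any() or block.isna().any().any():
        rows = np.nonzero(block.isna().any(axis=1).to_numpy())[0]
        lines = ", ".join(str(r + 2) for r in rows[:10])  # +2: header + 1-based
        raise ValueError(f"non-numeric or missing {what} values at CSV line(s): {lines}")
    return block


def read_site_table(path, schema: SiteSchema) -> SiteTable:
    """Read and validate a site-table CSV against a schema."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, [schema.id_col, schema.x_col, schema.y_col], "identifier/coordinate")
    _require_columns(df, schema.species_cols, "species")
    ids = df[schema.id_col].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate site_id(s): {', '.join(map(str, dup[:10]))}")
    env_cols = schema.env_cols
    if env_cols is None:
        reserved = {schema.id_col, schema.x_col, schema.y_col, *schema.species_cols}
        env_cols = tuple(c for c in df.columns if c not in reserved)
    else:
        _require_columns(df, env_cols, "environmental")
    xy = _numeric_block(df, [schema.x_col, schema.y_col], "coordinate").to_numpy()
    env = _numeric_block(df, env_cols, "environmental")
    counts = _numeric_block(df, schema.species_cols, "species count")
    if (counts < 0).any().any():
        raise ValueError("negative species counts")
    index = pd.Index(ids, name="site_id")
    return SiteTable(
        coords=Coordinates(xy=xy, site_ids=tuple(ids)),
        env=env.set_axis(index, axis=0),
        counts=counts.set_axis(index, axis=0),
    )


def write_site_table(table: SiteTable, path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path
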