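"""Tip-level rate statistics and equal-area community grids.

The tip speciation-rate proxy is the DR statistic: the reciprocal of the
equal-splits (ES) measure, the root-to-tip sum of branch lengths with each
edge discounted by 2^(number of splits between it and the tip).  Tip age
is the age of a tip's parent node and serves as a species-level community
age proxy when aggregated as grid-cell medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trees import Phylogeny

__all__ = [
    "equal_splits",
    "dr_rate",
    "tip_age",
    "tip_rate_table",
    "EqualAreaGrid",
    "equal_area_grid",
    "grid_community_summaries",
    "community_age_contrast",
    "EARTH_RADIUS_KM",
    "EARTH_SURFACE_KM2",
]

EARTH_RADIUS_KM = 6371.0088
EARTH_SURFACE_KM2 = 4.0 * math.pi * EARTH_RADIUS_KM**2


def equal_splits(tree: Phylogeny) -> pd.Series:
    """Equal-splits measure per tip (Myr).

    For tip i with root-ward path edges e_1 (pendant), e_2, ..., e_m the
    measure is sum_j len(e_j) * 2**-(j-1); a root edge, if present, is
    excluded.  Raises if a tip's whole path has zero length.
    """
    a = tree.arrays
    es = np.zeros(a.n_tips)
    for tip in range(a.n_tips):
        v, w, acc = tip, 1.0, 0.0
        while a.parent[v] >= 0:
            acc += a.blen[v] * w
            w *= 0.5
            v = a.parent[v]
        if acc <= 0:
            raise ValueError(f"tip {a.tip_labels[tip]!r} has a zero-length root path")
        es[tip] = acc
    return pd.Series(es, index=list(a.tip_labels), name="ES")


def dr_rate(es: pd.Series) -> pd.Series:
    """DR tip speciation rate: the reciprocal of equal splits (/Myr)."""
    return (1.0 / es).rename("DR")


def tip_age(tree: Phylogeny) -> pd.Series:
    """Age (Myr) of each tip's parent node."""
    a = tree.arrays
    ages = tree.node_ages()
    vals = [ages.ages[int(a.parent[i])] for i in range(a.n_tips)]
    return pd.Series(vals, index=list(a.tip_labels), name="tip_age")


def tip_rate_table(tree: Phylogeny, require_ultrametric: bool = True) -> pd.DataFrame:
    """ES, DR and tip age for every tip of a dated ultrametric tree."""
    if require_ultrametric and not tree.node_ages().ultrametric:
        raise ValueError("tip metrics require an ultrametric (dated) tree")
    es = equal_splits(tree)
    return pd.DataFrame({"ES": es, "DR": dr_rate(es), "tip_age": tip_age(tree)})


# ---------------------------------------------------------------------------
# equal-area grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EqualAreaGrid:
    """Equal-area grid on the cylindrical (Lambert) equal-area projection.

    Cells are rectangles in (longitude, sin latitude) space, which makes
    every cell's spherical area identical by construction.  Cell ids are
    (row, column) integer pairs; assignment of boundary points is
    deterministic (the lexicographically smaller adjoining cell).
    """

    target_area: float
    n_rows: int
    n_cols: int
    cell_area: float

    @classmethod
    def build(cls, target_area: float = 322.0) -> "EqualAreaGrid":
        if target_area <= 0:
            raise ValueError("target_area must be positive")
        side = math.sqrt(target_area)
        n_cols = max(1, round(2 * math.pi * EARTH_RADIUS_KM / side))
        dx = 2 * math.pi * EARTH_RADIUS_KM / n_cols
        n_rows = max(1, round(2 * EARTH_RADIUS_KM / (target_area / dx)))
        dy = 2 * EARTH_RADIUS_KM / n_rows
        return cls(
            target_area=float(target_area),
            n_rows=n_rows,
            n_cols=n_cols,
            cell_area=dx * dy,
        )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def total_area(self) -> float:
        return self.cell_area * self.n_cells

    def assign(self, lon, lat) -> list:
        """Map points to (row, col) cell ids; boundary points go to the
        lexicographically smallest adjoining cell."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        u = (lon + 180.0) / 360.0 * self.n_cols
        v = (np.sin(np.radians(lat)) + 1.0) / 2.0 * self.n_rows
        col = np.floor(u).astype(np.int64)
        row = np.floor(v).astype(np.int64)
        col[(u == col) & (col > 0)] -= 1
        row[(v == row) & (row > 0)] -= 1
        np.clip(col, 0, self.n_cols - 1, out=col)
        np.clip(row, 0, self.n_rows - 1, out=row)
        return list(zip(row.tolist(), col.tolist()))

    def centroid(self, cell) -> tuple:
        row, col = cell
        lon = -180.0 + (col + 0.5) * 360.0 / self.n_cols
        y = -1.0 + (row + 0.5) * 2.0 / self.n_rows
        return lon, math.degrees(math.asin(y))


def equal_area_grid(target_area: float = 322.0) -> EqualAreaGrid:
    """Construct the default equal-area grid (~322 km^2 cells)."""
    return EqualAreaGrid.build(target_area)


def grid_community_summaries(
    occurrences: pd.DataFrame,
    tip_values: pd.DataFrame,
    grid: EqualAreaGrid,
) -> pd.DataFrame:
    """Per-cell species richness and median DR / tip age.

    Each species counts once per cell regardless of its record count
    there; cells with no kept records are absent from the output.  Only
    species present in ``tip_values`` contribute.
    """
    kept = (
        occurrences
        if "status" not in occurrences.columns
        else occurrences[occurrences["status"] == "kept"]
    )
    kept = kept[kept["species"].isin(tip_values.index)]
    if len(kept) == 0:
        return pd.DataFrame(
            columns=["cell_id", "centroid_lon", "centroid_lat", "richness", "median_dr", "median_age"]
        )
    cells = grid.assign(
        kept["decimalLongitude"].to_numpy(), kept["decimalLatitude"].to_numpy()
    )
    df = pd.DataFrame({"cell": cells, "species": kept["species"].to_numpy()})
    rows = []
    for cell, grp in df.groupby("cell", sort=True):
        species = grp["species"].unique()
        vals = tip_values.loc[species]
        lon, lat = grid.centroid(cell)
        rows.append(
            dict(
                cell_id=f"{cell[0]}_{cell[1]}",
                centroid_lon=lon,
                centroid_lat=lat,
                richness=len(species),
                median_dr=float(vals["DR"].median()),
                median_age=float(vals["tip_age"].median()),
            )
        )
    return pd.DataFrame(rows)


def community_age_contrast(ages_tropical, ages_non_tropical) -> tuple:
    """Welch two-sample two-tailed t-test on species tip ages by class.

    Returns ``(t_statistic, p_value)``; raises for classes with fewer
    than 2 values or with no variance in either sample.
    """
    a = np.asarray(ages_tropical, dtype=float)
    b = np.asarray(ages_non_tropical, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each tropicality class needs at least 2 ages")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both classes; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
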