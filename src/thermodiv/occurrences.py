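"""Occurrence-record cleaning and per-species climatic niche summaries.

The cleaning rules target the truncation artifacts common in aggregated
museum/observation records: coordinates that are exactly zero, pairs where
both latitude and longitude were reported only to the nearest integer
degree, and per-species geographic outliers far from the occurrence
centroid.  Niche summaries are the mean-annual-temperature (MAT) niche and
two binary tropicality classifications (geographic and climatic).
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "clean_occurrences",
    "remove_geographic_outliers",
    "species_mat",
    "classify_geographic",
    "classify_climatic",
    "species_niche_table",
    "TROPIC_LATITUDE",
    "REMOVAL_REASONS",
]

#: Latitude of the Tropics of Cancer/Capricorn used for the geographic
#: tropical/non-tropical split (boundary inclusive).
TROPIC_LATITUDE = 23.43677

#: Closed vocabulary of removal reasons written to the status column.
REMOVAL_REASONS = (
    "missing",
    "out_of_range",
    "zero_coordinate",
    "integer_pair",
    "geographic_outlier",
)

_LON, _LAT = "decimalLongitude", "decimalLatitude"


def _require_columns(table: pd.DataFrame) -> None:
    for col in ("species", _LON, _LAT):
        if col not in table.columns:
            raise ValueError(f"occurrence table lacks column {col!r}")


def clean_occurrences(table: pd.DataFrame) -> pd.DataFrame:
    """Flag coordinate artifacts; returns the table with a ``status`` column.

    Rows are marked ``removed:<reason>`` when coordinates are missing, out
    of range, exactly zero in either axis, or integer-valued in *both*
    axes (single-axis integral coordinates are kept: the targeted artifact
    is whole-degree truncation of the pair).  All other rows are ``kept``.
    The operation is idempotent and row-preserving.
    """
    _require_columns(table)
    if len(table) == 0:
        raise ValueError("occurrence table is empty")
    out = table.copy()
    lon = pd.to_numeric(out[_LON], errors="coerce").to_numpy(dtype=float)
    lat = pd.to_numeric(out[_LAT], errors="coerce").to_numpy(dtype=float)
    status = np.array(["kept"] * len(out), dtype=object)

    missing = ~np.isfinite(lon) | ~np.isfinite(lat)
    status[missing] = "removed:missing"
    ok = ~missing

    out_of_range = ok & ((np.abs(lon) > 180) | (np.abs(lat) > 90))
    status[out_of_range] = "removed:out_of_range"
    ok &= ~out_of_range

    zero = ok & ((lon == 0.0) | (lat == 0.0))
    status[zero] = "removed:zero_coordinate"
    ok &= ~zero

    integer_pair = ok & (lon == np.floor(lon)) & (lat == np.floor(lat))
    status[integer_pair] = "removed:integer_pair"

    prior = out["status"].to_numpy() if "status" in out.columns else None
    out["status"] = status
    if prior is not None:  # idempotence: earlier removals stay removed
        keep_prior = np.array([s != "kept" for s in prior])
        out.loc[keep_prior, "status"] = prior[keep_prior]
    return out


def remove_geographic_outliers(table: pd.DataFrame, k_sd: float = 3.0, min_records: int = 4) -> pd.DataFrame:
    """Single-pass per-species centroid outlier filter, in degrees.

    For each species with at least ``min_records`` kept records, compute
    the centroid (mean lon, mean lat) and Euclidean distances d_i; rows
    with ``d > mean(d) + k_sd * sd(d)`` (sample sd, n-1 denominator) are
    marked ``removed:geographic_outlier``.  Species with fewer records,
    or with zero distance spread, are left untouched.
    """
    _require_columns(table)
    out = table.copy()
    if "status" not in out.columns:
        out = clean_occurrences(out)
    status = out["status"].to_numpy(dtype=object)
    kept = status == "kept"
    lon = out[_LON].to_numpy(dtype=float)
    lat = out[_LAT].to_numpy(dtype=float)
    for idx in _group_indices(out):
        sel = idx[kept[idx]]
        if len(sel) < min_records:
            continue
        d = np.hypot(lon[sel] - lon[sel].mean(), lat[sel] - lat[sel].mean())
        sd = d.std(ddof=1)
        if sd == 0:
            continue
        cut = d.mean() + k_sd * sd
        status[sel[d > cut]] = "removed:geographic_outlier"
    out["status"] = status
    return out


def _group_indices(table: pd.DataFrame):
    species = table["species"].to_numpy()
    order = np.argsort(species, kind="stable")
    sp_sorted = species[order]
    breaks = np.flatnonzero(sp_sorted[1:] != sp_sorted[:-1]) + 1
    yield from np.split(order, breaks)


def species_mat(table: pd.DataFrame, temp_column: str = "temp_c") -> pd.DataFrame:
    """Per-species MAT: arithmetic mean of kept records' temperatures.

    Species with no kept temperature-bearing record get ``MAT = NaN`` and
    ``mat_excluded = True`` (they drop out of MAT-based analyses).
    """
    _require_columns(table)
    kept = table if "status" not in table.columns else table[table["status"] == "kept"]
    rows = []
    for species, grp in kept.groupby("species", sort=True):
        temps = (
            pd.to_numeric(grp[temp_column], errors="coerce").dropna()
            if temp_column in grp.columns
            else pd.Series(dtype=float)
        )
        rows.append((species, float(temps.mean()) if len(temps) else np.nan, len(temps) == 0))
    return pd.DataFrame(rows, columns=["species", "mat", "mat_excluded"]).set_index("species")


def classify_geographic(mean_lat: float, boundary: float = TROPIC_LATITUDE) -> str:
    """Tropical iff |mean latitude| <= the tropic boundary (inclusive)."""
    if not np.isfinite(mean_lat):
        raise ValueError("mean latitude is not finite")
    return "tropical" if abs(mean_lat) <= boundary else "non-tropical"


def default_tropical_mask(lon, lat) -> np.ndarray:
    """Synthetic stand-in climatic mask: tropical iff |lat| <= tropic line."""
    return np.abs(np.asarray(lat, dtype=float)) <= TROPIC_LATITUDE


def mask_from_csv_grid(grid: pd.DataFrame) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Build a tropical-mask function from a (lon, lat, is_tropical) grid.

    Each query point maps to its nearest grid cell center (Euclidean in
    degrees).  The grid is the plain-CSV mask dialect; any raster can be
    exported to it.
    """
    for col in ("lon", "lat", "is_tropical"):
        if col not in grid.columns:
            raise ValueError(f"mask grid lacks column {col!r}")
    glon = grid["lon"].to_numpy(dtype=float)
    glat = grid["lat"].to_numpy(dtype=float)
    gval = grid["is_tropical"].to_numpy(dtype=bool)

    def mask(lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        d2 = (lon[:, None] - glon[None, :]) ** 2 + (lat[:, None] - glat[None, :]) ** 2
        return gval[np.argmin(d2, axis=1)]

    return mask


def classify_climatic(
    records: pd.DataFrame,
    tropical_mask: Callable[[np.ndarray, np.ndarray], np.ndarray] = default_tropical_mask,
) -> str:
    """Majority classification against a tropical/non-tropical mask.

    Non-tropical iff strictly more than 50% of kept records fall outside
    tropical cells; ties classify as tropical.
    """
    kept = records if "status" not in records.columns else records[records["status"] == "kept"]
    if len(kept) == 0:
        raise ValueError("no kept records to classify")
    trop = np.asarray(
        tropical_mask(kept[_LON].to_numpy(dtype=float), kept[_LAT].to_numpy(dtype=float)),
        dtype=bool,
    )
    frac_outside = 1.0 - trop.mean()
    return "non-tropical" if frac_outside > 0.5 else "tropical"


def species_niche_table(
    table: pd.DataFrame,
    tropical_mask: Callable = default_tropical_mask,
    temp_column: str = "temp_c",
    boundary: float = TROPIC_LATITUDE,
) -> pd.DataFrame:
    """Combine MAT, mean latitude and both tropicality calls per species.

    Expects a cleaned table (``status`` column); species with zero kept
    records are omitted entirely.
    """
    if "status" not in table.columns:
        raise ValueError("run clean_occurrences (and optionally the outlier filter) first")
    kept = table[table["status"] == "kept"]
    mat = species_mat(table, temp_column=temp_column)
    rows = []
    for species, grp in kept.groupby("species", sort=True):
        mean_lat = float(grp[_LAT].mean())
        rows.append(
            dict(
                species=species,
                n_records=len(grp),
                mean_lat=mean_lat,
                mat=mat.loc[species, "mat"] if species in mat.index else np.nan,
                geo_tropicality=classify_geographic(mean_lat, boundary=boundary),
                clim_tropicality=classify_climatic(grp, tropical_mask),
            )
        )
    return pd.DataFrame(rows).set_index("species")
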