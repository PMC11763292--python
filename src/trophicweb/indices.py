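"""Catch-based trophic indicators: MTL, FiB, the region decomposition, and
spatial/effort summaries of purse-seine landings.

Landings are held as a tidy :class:`pandas.DataFrame` with one row per catch
record (columns documented in :data:`CATCH_COLUMNS`).  The yearly mean trophic
level of the catch is the catch-weighted mean of species trophic levels; the
Fishing-in-Balance index compares a year's catch, inflated to primary-
production equivalents through the transfer efficiency TE, against a
reference year.  When a fleet expands into new grounds, the region-based
decomposition (RMTL) splits each year's catch and MTL into the original
region — assumed to stay in trophic balance — and the expanded region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foodweb import TrophicLevelTable

__all__ = [
    "CATCH_COLUMNS",
    "IndexSeries",
    "ExpansionPartition",
    "QuadrantGrid",
    "mean_trophic_level",
    "index_series",
    "fishing_in_balance",
    "rmtl_decompose",
    "grid_quadrants",
    "biomass_by_year",
    "effort_indices",
]

#: canonical catch-table dialect (tonnes, decimal degrees with S/W negative)
CATCH_COLUMNS = [
    "year",
    "month",
    "fleet",
    "species_code",
    "lat",
    "lon",
    "depth_m",
    "catch_t",
    "days_at_sea",
    "fishing_days",
    "hauls",
]

FLEETS = ("VIC", "VRB")

#: kilometres per degree of latitude on the spherical Earth used for quadrant
#: areas (mean Earth radius convention)
KM_PER_DEGREE = 111.32
CELL_DEG = 0.5  # 30 arc-minutes


@dataclass
class IndexSeries:
    """Yearly catch, MTL and FiB relative to a reference year."""

    table: pd.DataFrame  # columns: year, Y, MTL, FiB, coverage
    reference_year: int
    te: float = 0.1

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    def row(self, year: int) -> pd.Series:
        return self.table.set_index("year").loc[year]


@dataclass
class ExpansionPartition:
    """Per-year, per-region estimated catch and MTL under fleet expansion."""

    table: pd.DataFrame  # columns: year, region, Y_hat, MTL_hat, flag
    breakpoints: list[int] = field(default_factory=list)

    def region(self, r: int) -> pd.DataFrame:
        return self.table[self.table["region"] == r].reset_index(drop=True)


def mean_trophic_level(
    records: pd.DataFrame, tl: TrophicLevelTable
) -> tuple[float, float]:
    """Catch-weighted mean trophic level of one year's records.

    Species without a trophic-level entry are excluded from numerator and
    denominator; the second return value is the coverage fraction (usable
    catch / total catch).  Raises ``ValueError`` when no usable catch exists.
    """
    catch = records["catch_t"].to_numpy(dtype=float)
    tls = np.array(
        [tl.get(code, np.nan) for code in records["species_code"]], dtype=float
    )
    usable = np.isfinite(tls) & (catch > 0)
    total = catch[catch > 0].sum()
    usable_catch = catch[usable].sum()
    if usable_catch <= 0:
        raise ValueError("no catch with a known trophic level")
    mtl = float((catch[usable] * tls[usable]).sum() / usable_catch)
    coverage = float(usable_catch / total) if total > 0 else 0.0
    return mtl, coverage


def fishing_in_balance(
    y: np.ndarray, mtl: np.ndarray, y0: float, mtl0: float, te: float = 0.1
) -> np.ndarray:
    """FiB_k = log10(Y_k·(1/TE)^MTL_k) − log10(Y_0·(1/TE)^MTL_0).

    Zero in the reference year by construction; positive values indicate
    geographic or bathymetric expansion of the fishery.
    """
    y = np.asarray(y, dtype=float)
    mtl = np.asarray(mtl, dtype=float)
    if not (0 < te < 1):
        raise ValueError("TE must lie in (0, 1)")
    if y0 <= 0 or np.any(y <= 0):
        raise ValueError("FiB requires positive catches")
    # both terms use the same log implementation so the reference year is
    # exactly zero
    log_inv = np.log10(np.float64(1.0 / te))
    return (np.log10(y) + mtl * log_inv) - (np.log10(np.float64(y0)) + mtl0 * log_inv)


def index_series(
    records: pd.DataFrame,
    tl: TrophicLevelTable,
    reference_year: int | None = None,
    te: float = 0.1,
) -> IndexSeries:
    """Yearly total catch, MTL and FiB from a full catch table."""
    rows = []
    for year, grp in records.groupby("year", sort=True):
        mtl, coverage = mean_trophic_level(grp, tl)
        rows.append(
            {
                "year": int(year),
                "Y": float(grp["catch_t"].sum()),
                "MTL": mtl,
                "coverage": coverage,
            }
        )
    table = pd.DataFrame(rows)
    if reference_year is None:
        reference_year = int(table["year"].min())
    ref = table.set_index("year").loc[reference_year]
    table["FiB"] = fishing_in_balance(
        table["Y"].to_numpy(), table["MTL"].to_numpy(), ref["Y"], ref["MTL"], te
    )
    return IndexSeries(table=table, reference_year=reference_year, te=te)


def rmtl_decompose(
    series: IndexSeries, breakpoints: list[int], te: float | None = None
) -> ExpansionPartition:
    """Split yearly catch and MTL into original and expanded fishing regions.

    ``breakpoints`` lists the last year of each region's pre-expansion span
    (n_1 < n_2 < ...).  For years after n_r the original-region catch is
    estimated by holding its fishery in trophic balance (FiB = 0 relative to
    the breakpoint year), the original-region MTL follows from the same
    balance using the reported total catch, and the expanded region takes the
    residual catch with its MTL recovered from the mass-weighted identity
    MTL_k·Y_k = Σ_r MTL̂_k^r·Ŷ_k^r.

    Negative residual catches are floored at zero and the year flagged
    ``assumption violated``; an empty expanded region leaves its MTL
    undefined (NaN) with flag ``undefined``.
    """
    if te is None:
        te = series.te
    if not breakpoints or sorted(breakpoints) != list(breakpoints):
        raise ValueError("breakpoints must be a non-empty increasing list of years")
    tab = series.table.set_index("year")
    for n in breakpoints:
        if n not in tab.index:
            raise ValueError(f"breakpoint year {n} not in series")
    log_inv_te = math.log10(1.0 / te)
    out = []
    # reference catch/MTL of each region at the moment the next region opens
    ref_y = {1: float(tab.loc[breakpoints[0], "Y"])}
    ref_m = {1: float(tab.loc[breakpoints[0], "MTL"])}
    for year in tab.index:
        yk = float(tab.loc[year, "Y"])
        mk = float(tab.loc[year, "MTL"])
        n_active = 1 + sum(year > n for n in breakpoints)
        if n_active == 1:
            out.append(
                {"year": year, "region": 1, "Y_hat": yk, "MTL_hat": mk, "flag": ""}
            )
            continue
        # regions 1..n_active-1 held in balance relative to their references
        y_used = 0.0
        my_used = 0.0
        for r in range(1, n_active):
            y_hat = ref_y[r] * (1.0 / te) ** (ref_m[r] - mk)
            m_hat = ref_m[r] - math.log10(yk / ref_y[r]) / log_inv_te
            flag = ""
            if y_used + y_hat > yk:
                y_hat = max(yk - y_used, 0.0)
                flag = "assumption violated"
            out.append(
                {"year": year, "region": r, "Y_hat": y_hat, "MTL_hat": m_hat, "flag": flag}
            )
            y_used += y_hat
            my_used += m_hat * y_hat
        y_res = yk - y_used
        if y_res <= 0:
            out.append(
                {
                    "year": year,
                    "region": n_active,
                    "Y_hat": 0.0,
                    "MTL_hat": float("nan"),
                    "flag": "undefined",
                }
            )
        else:
            m_res = (mk * yk - my_used) / y_res
            out.append(
                {
                    "year": year,
                    "region": n_active,
                    "Y_hat": y_res,
                    "MTL_hat": m_res,
                    "flag": "",
                }
            )
        if n_active < len(breakpoints) + 1 and year == breakpoints[n_active - 1]:
            # freeze the newest region's state as its own reference
            ref_y[n_active] = y_res if y_res > 0 else 0.0
            ref_m[n_active] = out[-1]["MTL_hat"]
    return ExpansionPartition(table=pd.DataFrame(out), breakpoints=list(breakpoints))


# --------------------------------------------------------------------------
# spatial gridding and effort
# --------------------------------------------------------------------------


@dataclass
class QuadrantGrid:
    """Catch aggregated on a 30-arc-minute lattice anchored at integer degrees."""

    cells: pd.DataFrame  # columns: lat_idx, lon_idx, catch_t, area_km2
    n_excluded: int = 0

    @property
    def total_area(self) -> float:
        return float(self.cells["area_km2"].sum())

    def n_quadrants(self) -> int:
        return len(self.cells)


def quadrant_cell(lat: float, lon: float) -> tuple[int, int]:
    """Signed-floor cell index of a position on the 30′ lattice."""
    return math.floor(lat / CELL_DEG), math.floor(lon / CELL_DEG)


def quadrant_area(lat_idx: int) -> float:
    """Spherical-Earth area (km²) of a 30′ cell, at the cell-centre latitude."""
    lat_centre = (lat_idx + 0.5) * CELL_DEG
    return (KM_PER_DEGREE * CELL_DEG) * (
        KM_PER_DEGREE * math.cos(math.radians(lat_centre)) * CELL_DEG
    )


def grid_quadrants(records: pd.DataFrame) -> QuadrantGrid:
    """Aggregate catch records onto the 30′ quadrant lattice.

    Records with missing coordinates are excluded and counted.
    """
    ok = records["lat"].notna() & records["lon"].notna()
    n_excluded = int((~ok).sum())
    sub = records[ok]
    if sub.empty:
        return QuadrantGrid(
            cells=pd.DataFrame(columns=["lat_idx", "lon_idx", "catch_t", "area_km2"]),
            n_excluded=n_excluded,
        )
    lat_idx = np.floor(sub["lat"].to_numpy() / CELL_DEG).astype(int)
    lon_idx = np.floor(sub["lon"].to_numpy() / CELL_DEG).astype(int)
    agg = (
        pd.DataFrame(
            {"lat_idx": lat_idx, "lon_idx": lon_idx, "catch_t": sub["catch_t"].to_numpy()}
        )
        .groupby(["lat_idx", "lon_idx"], as_index=False)["catch_t"]
        .sum()
    )
    agg["area_km2"] = [quadrant_area(i) for i in agg["lat_idx"]]
    return QuadrantGrid(cells=agg, n_excluded=n_excluded)


def quadrants_per_year_fleet(records: pd.DataFrame) -> pd.DataFrame:
    """Count of distinct 30′ quadrants visited, per year and fleet."""
    ok = records["lat"].notna() & records["lon"].notna()
    sub = records[ok].copy()
    sub["lat_idx"] = np.floor(sub["lat"] / CELL_DEG).astype(int)
    sub["lon_idx"] = np.floor(sub["lon"] / CELL_DEG).astype(int)
    return (
        sub.groupby(["year", "fleet"])[["lat_idx", "lon_idx"]]
        .apply(lambda g: len(g.drop_duplicates()))
        .rename("n_quadrants")
        .reset_index()
    )


def biomass_by_year(records: pd.DataFrame) -> pd.DataFrame:
    """Per-species yearly biomass (summed catch over visited quadrants) and
    density in t/km² over the total area of quadrants visited that year.

    Years with zero visited area get NaN density and an ``undefined`` flag.
    """
    out = []
    for year, grp in records.groupby("year", sort=True):
        grid = grid_quadrants(grp)
        area = grid.total_area
        for species, sgrp in grp.groupby("species_code"):
            ok = sgrp["lat"].notna() & sgrp["lon"].notna()
            biomass = float(sgrp.loc[ok, "catch_t"].sum())
            out.append(
                {
                    "year": int(year),
                    "species_code": species,
                    "biomass_t": biomass,
                    "density_t_km2": biomass / area if area > 0 else float("nan"),
                    "flag": "" if area > 0 else "undefined",
                }
            )
    return pd.DataFrame(out)


def effort_indices(records: pd.DataFrame, reference_year: int) -> pd.DataFrame:
    """Relative effort per year and fleet: days at sea, fishing days, hauls,
    each as the ratio of the yearly total to the reference-year total
    (reference year = 1).  Records missing all effort fields are excluded and
    counted in the ``n_excluded`` column.
    """
    effort_cols = ["days_at_sea", "fishing_days", "hauls"]
    rows = []
    for fleet, fgrp in records.groupby("fleet"):
        usable = fgrp.dropna(subset=effort_cols, how="all")
        totals = usable.groupby("year")[effort_cols].sum(min_count=1)
        if reference_year not in totals.index:
            raise ValueError(f"no effort data for fleet {fleet!r} in {reference_year}")
        ref = totals.loc[reference_year]
        if (ref.fillna(0) <= 0).any():
            raise ValueError(f"reference-year effort totals must be positive ({fleet})")
        for year, tot in totals.iterrows():
            rows.append(
                {
                    "year": int(year),
                    "fleet": fleet,
                    "days_at_sea_idx": float(tot["days_at_sea"] / ref["days_at_sea"]),
                    "fishing_days_idx": float(tot["fishing_days"] / ref["fishing_days"]),
                    "hauls_idx": float(tot["hauls"] / ref["hauls"]),
                    "n_excluded": int(len(fgrp[fgrp["year"] == year]) - len(usable[usable["year"] == year])),
                }
            )
    return pd.DataFrame(rows).sort_values(["fleet", "year"]).reset_index(drop=True)
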