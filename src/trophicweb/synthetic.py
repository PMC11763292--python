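"""Synthetic catch series, diet matrices and balanced food webs.

The monitoring database behind the real landings is not public, so every
stage of the pipeline is exercised on generated data with the same
statistical structure: a two-region, two-fleet purse-seine catch series in
which the refrigerated-brine fleet opens a new fishing region with a
distinct species mix partway through the span, and food webs whose
parameters bracket the magnitudes of the packaged model table and balance
with every ecotrophic efficiency inside (0, 1).

All generators are deterministic under a fixed integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .foodweb import CONSUMER, DETRITUS, PRODUCER, DietMatrix, TrophicLevelTable
from .massbalance import GroupParams

__all__ = [
    "ScenarioConfig",
    "generate_foodweb",
    "generate_catch_series",
    "generate_two_region_series",
    "load_fixture",
    "FIXTURES",
]

FIXTURES = ("table1_tl", "table2_original", "table2_expanded", "sardine_diet")

#: default species pools (code, trophic level, relative abundance weight);
#: the original (southern) grounds are sardine-dominated with low-TL pelagics,
#: the expanded (northern) grounds carry a different mix with higher-TL species
REGION1_POOL = [
    ("SV", 2.77, 0.45),
    ("SL", 2.61, 0.15),
    ("PA", 2.49, 0.12),
    ("CA", 2.99, 0.10),
    ("TA", 2.00, 0.08),
    ("CO", 3.11, 0.10),
]
REGION2_POOL = [
    ("SV", 2.77, 0.40),
    ("XI", 2.77, 0.15),
    ("GA", 3.28, 0.12),
    ("BL", 3.24, 0.13),
    ("ES", 3.21, 0.10),
    ("DO", 4.44, 0.10),
]

#: lat/lon boxes (decimal degrees, S/W negative) for the two fishing regions
REGION1_BOX = ((-28.5, -24.0), (-49.5, -45.5))
REGION2_BOX = ((-24.0, -21.5), (-44.5, -40.5))


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for the synthetic two-region, two-fleet catch series."""

    seed: int = 0
    start_year: int = 2000
    end_year: int = 2016
    expansion_year: int = 2008
    region1_pool: list = field(default_factory=lambda: list(REGION1_POOL))
    region2_pool: list = field(default_factory=lambda: list(REGION2_POOL))
    records_per_year: int = 120
    mean_catch_vic: float = 80.0  # tonnes per record
    mean_catch_vrb: float = 160.0
    catch_sd_log: float = 0.6  # lognormal sigma of per-record catch
    region1_box: tuple = REGION1_BOX
    region2_box: tuple = REGION2_BOX

    def __post_init__(self) -> None:
        if not (self.start_year < self.expansion_year <= self.end_year):
            raise ValueError("expansion year must fall inside the year span")
        if self.catch_sd_log < 0:
            raise ValueError("catch noise sd must be non-negative")
        if self.records_per_year < 1:
            raise ValueError("need at least one record per year")


# --------------------------------------------------------------------------
# balanced food webs
# --------------------------------------------------------------------------


def generate_foodweb(
    n_groups: int,
    seed: int,
    n_producers: int = 1,
    cannibalism: float = 0.0,
    ee_range: tuple[float, float] = (0.15, 0.9),
    max_resample: int = 100,
) -> tuple[DietMatrix, list[GroupParams]]:
    """Generate a fully parameterised, exactly balanced food web.

    Groups are ordered detritus, producers, then consumers by increasing
    trophic position; each consumer's diet is drawn (Dirichlet) over all
    strictly lower-indexed groups, optionally with a small cannibalism
    fraction on the diagonal.  P/B and Q/B are drawn from ranges bracketing
    the magnitudes of coastal pelagic models; each group's biomass is then
    back-solved from a drawn target ecotrophic efficiency in reverse trophic
    order, so every EE lies inside the requested range by construction.  The
    top consumer receives a catch so its production is used.  Deterministic
    per seed.
    """
    if n_groups < 3:
        raise ValueError("need at least detritus, one producer and one consumer")
    if not (0 <= cannibalism < 1):
        raise ValueError("cannibalism fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_cons = n_groups - 1 - n_producers
    if n_cons < 1:
        raise ValueError("at least one consumer required")
    codes = (
        ["DET"]
        + [f"P{i + 1}" for i in range(n_producers)]
        + [f"C{i + 1}" for i in range(n_cons)]
    )
    roles = {"DET": DETRITUS}
    roles.update({f"P{i + 1}": PRODUCER for i in range(n_producers)})
    roles.update({f"C{i + 1}": CONSUMER for i in range(n_cons)})

    n = n_groups
    for _ in range(max_resample):
        dc = np.zeros((n, n))
        first_consumer = 1 + n_producers
        for j in range(first_consumer, n):
            alpha = rng.uniform(0.5, 2.0, size=j)
            frac = rng.dirichlet(alpha)
            if cannibalism > 0:
                self_frac = rng.uniform(0, cannibalism)
                dc[:j, j] = frac * (1 - self_frac)
                dc[j, j] = self_frac
            else:
                dc[:j, j] = frac
        diet = DietMatrix(codes=list(codes), dc=dc, roles=dict(roles))

        pb = np.empty(n)
        qb = np.zeros(n)
        pb[0] = 0.0  # detritus: no production of its own
        pb[1 : first_consumer] = rng.uniform(20.0, 120.0, size=n_producers)
        pb[first_consumer:] = np.exp(rng.uniform(math.log(0.3), math.log(8.0), size=n_cons))
        pq = rng.uniform(0.1, 0.35, size=n_cons)
        qb[first_consumer:] = pb[first_consumer:] / pq
        ee = rng.uniform(*ee_range, size=n)

        # biomass back-solve, top predator first; catch keeps apex EE > 0
        b = np.zeros(n)
        catch = np.zeros(n)
        catch[n - 1] = rng.uniform(0.01, 0.1)
        ok = True
        for i in range(n - 1, -1, -1):
            demand = catch[i]
            for j in range(first_consumer, n):
                if dc[i, j] > 0 and j > i:
                    demand += b[j] * qb[j] * dc[i, j]
            if i == 0:  # detritus biomass is a free pool, not balanced here
                b[i] = 150.0
                continue
            # cannibalism: B_i·PB_i·EE_i = demand + B_i·QB_i·DC[i,i]
            denom = pb[i] * ee[i] - qb[i] * dc[i, i]
            if demand <= 0 or denom <= 0:
                ok = False
                break
            b[i] = demand / denom
        if not ok:
            continue
        groups = []
        for i, c in enumerate(codes):
            if roles[c] == DETRITUS:
                groups.append(GroupParams(code=c, role=DETRITUS, b=float(b[i])))
            elif roles[c] == PRODUCER:
                groups.append(
                    GroupParams(
                        code=c, role=PRODUCER, b=float(b[i]), pb=float(pb[i]), ee=float(ee[i])
                    )
                )
            else:
                groups.append(
                    GroupParams(
                        code=c,
                        role=CONSUMER,
                        b=float(b[i]),
                        pb=float(pb[i]),
                        qb=float(qb[i]),
                        ee=float(ee[i]),
                        catches={"VIC": float(catch[i])} if catch[i] > 0 else {},
                    )
                )
        return diet, groups
    raise RuntimeError("resampling budget exhausted while balancing the web")


# --------------------------------------------------------------------------
# catch series
# --------------------------------------------------------------------------


def _records_for(
    rng: np.random.Generator,
    year: int,
    fleet: str,
    pool: list,
    box: tuple,
    n: int,
    mean_catch: float,
    sd_log: float,
) -> pd.DataFrame:
    codes = [p[0] for p in pool]
    weights = np.array([p[2] for p in pool], dtype=float)
    weights /= weights.sum()
    choice = rng.choice(len(codes), size=n, p=weights)
    (lat_lo, lat_hi), (lon_lo, lon_hi) = box
    mu = math.log(mean_catch) - 0.5 * sd_log**2  # mean-preserving lognormal
    return pd.DataFrame(
        {
            "year": year,
            "month": rng.integers(1, 13, size=n),
            "fleet": fleet,
            "species_code": [codes[i] for i in choice],
            "lat": rng.uniform(lat_lo, lat_hi, size=n),
            "lon": rng.uniform(lon_lo, lon_hi, size=n),
            "depth_m": rng.uniform(20, 120, size=n),
            "catch_t": rng.lognormal(mu, sd_log, size=n),
            "days_at_sea": rng.integers(3, 15, size=n),
            "fishing_days": rng.integers(1, 8, size=n),
            "hauls": rng.integers(1, 12, size=n),
        }
    )


def generate_catch_series(config: ScenarioConfig) -> pd.DataFrame:
    """Two-region, two-fleet synthetic landings in the canonical dialect.

    Region 1 (ice fleet, southern grounds) is fished every year; from the
    expansion year onward the refrigerated-brine fleet opens region 2 with
    its own species pool and trophic-level mix, and the ice fleet also
    visits the new grounds.  Per-record catches are lognormal around the
    configured fleet means.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for year in range(config.start_year, config.end_year + 1):
        frames.append(
            _records_for(
                rng,
                year,
                "VIC",
                config.region1_pool,
                config.region1_box,
                config.records_per_year,
                config.mean_catch_vic,
                config.catch_sd_log,
            )
        )
        if year >= config.expansion_year:
            n2 = config.records_per_year // 2
            frames.append(
                _records_for(
                    rng,
                    year,
                    "VRB",
                    config.region2_pool,
                    config.region2_box,
                    n2,
                    config.mean_catch_vrb,
                    config.catch_sd_log,
                )
            )
            frames.append(
                _records_for(
                    rng,
                    year,
                    "VIC",
                    config.region2_pool,
                    config.region2_box,
                    n2 // 2,
                    config.mean_catch_vic,
                    config.catch_sd_log,
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_two_region_series(
    n1_year: int = 2007,
    start_year: int = 2000,
    end_year: int = 2016,
    y_ref: float = 60_000.0,
    mtl_ref: float = 3.0,
    region2_mtl: float = 2.8,
    region2_catch: float = 30_000.0,
    te: float = 0.1,
    growth: float = 0.02,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate yearly (Y, MTL) series whose post-expansion years satisfy the
    region-decomposition assumptions exactly.

    The original region is constructed to stay in trophic balance relative
    to its state in ``n1_year`` (its catch follows the FiB = 0 relation and
    its MTL the matching balance line), while region 2 contributes a fixed
    trophic level and a slowly growing catch.  The coupled constraints are
    resolved by fixed-point iteration per year.  Returns ``(series, truth)``
    where truth holds the per-year per-region catches and trophic levels the
    construction used.  Optional lognormal noise on the pre-expansion catches
    only (noise after expansion would break the construction).
    """
    rng = np.random.default_rng(seed)
    log_inv_te = math.log10(1.0 / te)
    rows = []
    truth = []
    for year in range(start_year, n1_year + 1):
        noise = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
        y = y_ref * (1 + growth) ** (year - n1_year) * noise
        mtl = mtl_ref
        if year == n1_year:
            y = y_ref
        rows.append({"year": year, "Y": y, "MTL": mtl})
        truth.append(
            {"year": year, "Y1": y, "MTL1": mtl, "Y2": 0.0, "MTL2": float("nan")}
        )
    for year in range(n1_year + 1, end_year + 1):
        y2 = region2_catch * (1 + growth) ** (year - n1_year - 1)
        mtl_k = mtl_ref  # initial guess
        for _ in range(200):
            y1 = y_ref * (1.0 / te) ** (mtl_ref - mtl_k)
            y_tot = y1 + y2
            mtl1 = mtl_ref - math.log10(y_tot / y_ref) / log_inv_te
            new_mtl = (mtl1 * y1 + region2_mtl * y2) / y_tot
            if abs(new_mtl - mtl_k) < 1e-13:
                mtl_k = new_mtl
                break
            mtl_k = new_mtl
        y1 = y_ref * (1.0 / te) ** (mtl_ref - mtl_k)
        y_tot = y1 + y2
        mtl1 = mtl_ref - math.log10(y_tot / y_ref) / log_inv_te
        rows.append({"year": year, "Y": y_tot, "MTL": mtl_k})
        truth.append(
            {"year": year, "Y1": y1, "MTL1": mtl1, "Y2": y2, "MTL2": region2_mtl}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


# --------------------------------------------------------------------------
# packaged reference tables
# --------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("trophicweb.data").joinpath(name)


def load_fixture(name: str):
    """Load a packaged reference table by name.

    - ``table1_tl``: species → trophic level catalogue
      (:class:`TrophicLevelTable` keyed by scientific name).
    - ``table2_original`` / ``table2_expanded``: functional-group parameter
      tables of the mass-balance model (:class:`pandas.DataFrame`).
    - ``sardine_diet``: the sardine diet column as an item → fraction dict.
    """
    if name == "table1_tl":
        frame = pd.read_csv(_data_path("table1_tl.csv"))
        return TrophicLevelTable(
            entries=dict(zip(frame["species"], frame["tl"].astype(float)))
        )
    if name in ("table2_original", "table2_expanded"):
        return pd.read_csv(_data_path(f"{name}.csv"))
    if name == "sardine_diet":
        frame = pd.read_csv(_data_path("sardine_diet.csv"))
        return dict(zip(frame["item"], frame["fraction"].astype(float)))
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
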