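"""Mixed trophic impacts and keystone-group classification.

The direct impact of group *j* on group *i* combines a positive bottom-up
term (how much *j* contributes to the diet of *i*) and a negative top-down
term (which share of the total predation and fishing removal on *i* is
exerted by *j*):

    q[i, j] = DC[i, j] − FC[j, i]

Indirect effects propagate along all interaction paths; the total (mixed)
impact matrix is the Leontief-style series

    m = q + q² + q³ + ... = (I − q)⁻¹ − I

which converges whenever the spectral radius of ``q`` is below one.
Keystone groups are those exerting a high overall impact
ε_i = sqrt(Σ_{j≠i} m[j, i]²) despite a low biomass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foodweb import CONSUMER, DietMatrix
from .massbalance import BalancedModel

__all__ = [
    "ImpactMatrix",
    "KeystoneResult",
    "direct_impacts",
    "mixed_trophic_impacts",
    "overall_effect",
    "keystone_classify",
]

CATEGORIES = (
    "keystone",
    "low-impact-low-biomass",
    "low-impact-high-biomass",
    "high-impact-high-biomass",
    "intermediate",
)


@dataclass
class ImpactMatrix:
    """Direct (q) and propagated total (m) impact matrices.

    Entry ``[i, j]`` is the impact of column group *j* on row group *i*.
    """

    codes: list[str]
    q: np.ndarray
    m: np.ndarray | None = None
    truncated: bool = False

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.codes, columns=self.codes)

    def m_frame(self) -> pd.DataFrame:
        if self.m is None:
            raise ValueError("total impacts not yet propagated")
        return pd.DataFrame(self.m, index=self.codes, columns=self.codes)


@dataclass
class KeystoneResult:
    """Per-group overall effect, biomass and keystone category."""

    table: pd.DataFrame  # columns: code, logB, logEps2, category
    thresholds: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def category(self, code: str) -> str:
        return self.table.set_index("code").loc[code, "category"]


def direct_impacts(
    diet: DietMatrix,
    model: BalancedModel,
    include_fleets: bool = False,
) -> ImpactMatrix:
    """Direct impact matrix q[i, j] = DC[i, j] − FC[j, i].

    ``DC[i, j]`` here is the fraction of predator *i*'s diet supplied by
    *j*; ``FC[j, i]`` is predator *i*'s share of the total predation and
    removal on prey *j*, computed from the B·QB·DC consumption flows (plus
    fleet catches).  With ``include_fleets`` each fleet becomes an extra
    impacting column exerting its share of removals (and an impacted row of
    zeros).
    """
    groups = {g.code: g for g in model.groups}
    codes = list(diet.codes)
    n = len(codes)
    cons = np.zeros((n, n))  # cons[i, j]: consumption of prey i by predator j
    for j, cj in enumerate(codes):
        g = groups[cj]
        if g.role == CONSUMER:
            cons[:, j] = (g.b or 0.0) * (g.qb or 0.0) * diet.dc[:, j]

    fleets: list[str] = []
    fleet_removals = np.zeros((n, 0))
    if include_fleets:
        fleets = sorted({f for g in model.groups for f in g.catches})
        fleet_removals = np.zeros((n, len(fleets)))
        for i, ci in enumerate(codes):
            for k, fl in enumerate(fleets):
                fleet_removals[i, k] = groups[ci].catches.get(fl, 0.0)

    total_removal = cons.sum(axis=1) + fleet_removals.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(total_removal[:, None] > 0, cons / total_removal[:, None], 0.0)
        fc_fleet = np.where(
            total_removal[:, None] > 0, fleet_removals / total_removal[:, None], 0.0
        )

    nf = len(fleets)
    q = np.zeros((n + nf, n + nf))
    # diet benefit: q[i, j] += fraction of i's diet supplied by j
    q[:n, :n] = diet.dc.T
    # predation cost: q[i, j] -= share of predation on i exerted by j
    q[:n, :n] -= fc
    if nf:
        q[:n, n:] -= fc_fleet  # fleets impact groups they remove
        # fleets are "fed" by what they catch: benefit of group j to fleet f
        catch_matrix = fleet_removals.T  # [fleet, group]
        totals = catch_matrix.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            q[n:, :n] = np.where(totals > 0, catch_matrix / totals, 0.0)
    all_codes = codes + [f"FLEET:{f}" for f in fleets]
    return ImpactMatrix(codes=all_codes, q=q)


def mixed_trophic_impacts(
    impact: ImpactMatrix, method: str = "leontief", max_order: int = 50
) -> ImpactMatrix:
    """Propagate direct impacts over all interaction paths.

    ``method="leontief"`` (default) computes m = (I − q)⁻¹ − I, the
    standard construction; it equals the path sum whenever the spectral
    radius of q is below one and extends it analytically otherwise (a
    warning notes when the formal series diverges).  ``method="series"``
    sums the powers q + q² + ... + q^max_order explicitly, flagged as
    truncated.  A singular (I − q) raises.
    """
    q = impact.q
    n = q.shape[0]
    eye = np.eye(n)
    if method == "series":
        m = np.zeros_like(q)
        power = q.copy()
        for _ in range(max_order):
            m += power
            power = power @ q
        return ImpactMatrix(codes=impact.codes, q=q, m=m, truncated=True)
    if method != "leontief":
        raise ValueError(f"unknown method {method!r}")
    radius = max(abs(np.linalg.eigvals(q))) if n else 0.0
    if radius >= 1.0 - 1e-9:
        if abs(np.linalg.det(eye - q)) < 1e-12:
            raise ValueError("non-convergent impact propagation: singular (I - q)")
        warnings.warn(
            f"impact series formally divergent (spectral radius {radius:.3f}); "
            "returning the Leontief inverse",
            stacklevel=2,
        )
    try:
        m = np.linalg.solve(eye - q, eye) - eye
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"non-convergent impact propagation: {exc}") from exc
    return ImpactMatrix(codes=impact.codes, q=q, m=m, truncated=False)


def overall_effect(m: np.ndarray) -> np.ndarray:
    """ε_i = sqrt(Σ_{j≠i} m[j, i]²): total impact exerted, diagonal excluded."""
    off = m.copy()
    np.fill_diagonal(off, 0.0)
    return np.sqrt((off**2).sum(axis=0))


def keystone_classify(
    impact: ImpactMatrix,
    biomasses: pd.Series,
    band_iqr_fraction: float = 0.25,
) -> KeystoneResult:
    """Classify groups on the (log biomass, log squared impact) plane.

    Axes are split at their medians, with an ``intermediate`` band of
    ±``band_iqr_fraction``·IQR around each split (default: total band width
    of half an interquartile range).  Quadrants map to: keystone (high
    impact, low biomass), high-impact-high-biomass, low-impact-low-biomass
    and low-impact-high-biomass.  Groups with zero biomass or zero effect
    are excluded with a warning (their logs are undefined).
    """
    if impact.m is None:
        impact = mixed_trophic_impacts(impact)
    eps = overall_effect(impact.m)
    rows = []
    excluded = []
    for code, e in zip(impact.codes, eps):
        if code.startswith("FLEET:"):
            continue
        b = float(biomasses.get(code, np.nan))
        if not np.isfinite(b) or b <= 0 or e <= 0:
            excluded.append(code)
            continue
        rows.append({"code": code, "logB": np.log10(b), "logEps2": np.log10(e**2)})
    if excluded:
        warnings.warn(f"excluded from keystone analysis: {excluded}", stacklevel=2)
    if len(rows) < 4:
        raise ValueError("keystone classification needs at least 4 usable groups")
    table = pd.DataFrame(rows)
    x = table["logB"].to_numpy()
    y = table["logEps2"].to_numpy()
    tx, ty = np.median(x), np.median(y)
    bx = band_iqr_fraction * (np.percentile(x, 75) - np.percentile(x, 25))
    by = band_iqr_fraction * (np.percentile(y, 75) - np.percentile(y, 25))

    def label(xi: float, yi: float) -> str:
        if abs(xi - tx) <= bx or abs(yi - ty) <= by:
            return "intermediate"
        if yi > ty:
            return "keystone" if xi < tx else "high-impact-high-biomass"
        return "low-impact-low-biomass" if xi < tx else "low-impact-high-biomass"

    table["category"] = [label(xi, yi) for xi, yi in zip(x, y)]
    return KeystoneResult(
        table=table,
        thresholds={"logB": float(tx), "logEps2": float(ty), "bandB": float(bx), "bandEps2": float(by)},
        excluded=excluded,
    )
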