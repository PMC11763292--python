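"""Ecopath-style static mass balance over functional groups.

Each group *i* obeys the balance

    B_i·PB_i·EE_i − Σ_j B_j·QB_j·DC[i, j] − Y_i − EX_i = 0

production used within the system (ecotrophic efficiency EE) equals what
predators consume plus what fisheries and exports remove.  For every
non-detritus group exactly one of {B, PB, EE} may be left unknown; because
each balance equation is linear in its group's single unknown, the whole
system assembles into one linear solve.  Derived per-group attributes —
predation mortality M2, P/Q, omnivory index, flow to detritus, net
efficiency, mortality partitions — and the primary production required to
sustain the catches (PPR) are computed from the balanced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .foodweb import CONSUMER, DETRITUS, PRODUCER, DietMatrix, TrophicLevelTable, compute_trophic_levels

__all__ = [
    "GroupParams",
    "BalancedModel",
    "solve_balance",
    "predation_mortality",
    "pq_ratio",
    "omnivory_index",
    "omnivory_from_diet",
    "flows",
    "ppr",
]

#: fraction of consumption not assimilated, routed to detritus (convention)
DEFAULT_UNASSIMILATED = 0.2

_BALANCE_TOL = 1e-9


@dataclass(frozen=True)
class GroupParams:
    """Input parameters of one functional group.

    ``None`` marks the single unknown to be solved (among B, PB, EE for
    non-detritus groups).  Units: B in t/km², PB and QB in yr⁻¹, catches
    and export in t/km²/yr.
    """

    code: str
    role: str = CONSUMER
    name: str = ""
    b: float | None = None
    pb: float | None = None
    qb: float | None = None
    ee: float | None = None
    catches: dict[str, float] = field(default_factory=dict)
    export: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in (PRODUCER, CONSUMER, DETRITUS):
            raise ValueError(f"unknown role {self.role!r}")
        for label, v in (("B", self.b), ("PB", self.pb), ("QB", self.qb)):
            if v is not None and v < 0:
                raise ValueError(f"{label} of {self.code!r} must be non-negative")
        if self.ee is not None and not (0.0 <= self.ee <= 1.0):
            raise ValueError(f"known EE of {self.code!r} must lie in [0, 1]")
        if self.role == CONSUMER and self.qb is not None and self.qb <= 0:
            raise ValueError(f"consumer {self.code!r} needs QB > 0")
        if self.role in (PRODUCER, DETRITUS) and self.qb not in (None, 0.0):
            raise ValueError(f"{self.role} {self.code!r} cannot have a QB")
        if any(v < 0 for v in self.catches.values()) or self.export < 0:
            raise ValueError(f"removals of {self.code!r} must be non-negative")

    @property
    def total_catch(self) -> float:
        return float(sum(self.catches.values()))

    def unknown(self) -> str | None:
        """Which of B / PB / EE is left for the solver (detritus: none)."""
        if self.role == DETRITUS:
            return None
        missing = [
            lab for lab, v in (("B", self.b), ("PB", self.pb), ("EE", self.ee)) if v is None
        ]
        if len(missing) > 1:
            raise ValueError(
                f"group {self.code!r} has {len(missing)} unknowns {missing}; at most one allowed"
            )
        return missing[0] if missing else None


@dataclass
class BalancedModel:
    """Solved mass-balance model with per-group derived attributes."""

    groups: list[GroupParams]  # all parameters filled in
    diet: DietMatrix
    tl: TrophicLevelTable
    residuals: dict[str, float]
    unbalanced: list[str] = field(default_factory=list)
    unassimilated: float = DEFAULT_UNASSIMILATED

    def __getitem__(self, code: str) -> GroupParams:
        for g in self.groups:
            if g.code == code:
                return g
        raise KeyError(code)

    @property
    def codes(self) -> list[str]:
        return [g.code for g in self.groups]

    def biomasses(self) -> pd.Series:
        return pd.Series({g.code: g.b for g in self.groups}, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        m2 = predation_mortality(self.groups, self.diet)
        flow = flows(self, self.diet)
        for g in self.groups:
            rows.append(
                {
                    "code": g.code,
                    "name": g.name,
                    "role": g.role,
                    "TL": self.tl[g.code],
                    "B": g.b,
                    "PB": g.pb,
                    "QB": g.qb,
                    "EE": g.ee,
                    "PQ": (g.pb / g.qb) if g.qb else float("nan"),
                    "OI": omnivory_index(g.code, self.diet, self.tl),
                    "M2": m2[g.code],
                    "catch": g.total_catch,
                    "flow_to_detritus": flow.set_index("code").loc[g.code, "flow_to_detritus"],
                    "residual": self.residuals.get(g.code, float("nan")),
                    "balanced": g.code not in self.unbalanced,
                }
            )
        return pd.DataFrame(rows)


def _consumption_matrix(groups: list[GroupParams], diet: DietMatrix) -> np.ndarray:
    """Flow matrix Q[i, j] = B_j·QB_j·DC[i, j] (consumption of prey i by j)."""
    codes = [g.code for g in groups]
    if codes != diet.codes:
        raise ValueError("group order must match diet matrix order")
    bq = np.array(
        [(g.b or 0.0) * (g.qb or 0.0) for g in groups], dtype=float
    )
    return diet.dc * bq[np.newaxis, :]


def solve_balance(
    groups: list[GroupParams],
    diet: DietMatrix,
    unassimilated: float = DEFAULT_UNASSIMILATED,
) -> BalancedModel:
    """Fill in the single unknown parameter of every group by mass balance.

    Groups with only an unknown EE reduce to one equation each; unknown B or
    PB couple groups through predation, so all unknowns are assembled into a
    single linear system and solved simultaneously.  Groups whose solved EE
    falls outside [0, 1] are flagged unbalanced but returned.  Any PB
    supplied for detritus is ignored with a warning (its balance follows
    from inflows).
    """
    groups = list(groups)
    codes = [g.code for g in groups]
    if codes != diet.codes:
        raise ValueError("group order must match diet matrix order")
    n = len(groups)
    idx = {c: i for i, c in enumerate(codes)}

    for g in groups:
        if g.role == DETRITUS and g.pb is not None:
            warnings.warn(
                f"detritus {g.code!r}: supplied PB ignored; balance follows from inflows",
                stacklevel=2,
            )

    unknowns = {g.code: g.unknown() for g in groups}
    unknown_codes = [c for c, u in unknowns.items() if u is not None]
    k = len(unknown_codes)
    col = {c: j for j, c in enumerate(unknown_codes)}

    # structural check: a group with unknown B (or PB/EE) whose balance
    # equation is vacuous cannot be solved
    a = np.zeros((k, k))
    rhs = np.zeros(k)
    dc = diet.dc
    for row, ci in enumerate(unknown_codes):
        i = idx[ci]
        gi = groups[i]
        ui = unknowns[ci]
        removals = gi.total_catch + gi.export
        rhs[row] = removals
        # production term B_i·PB_i·EE_i
        prod_parts = {"B": gi.b, "PB": gi.pb, "EE": gi.ee}
        coeff = 1.0
        for lab, v in prod_parts.items():
            if lab != ui:
                coeff *= v  # type: ignore[operator]
        a[row, col[ci]] += coeff
        # predation term −Σ_j B_j·QB_j·DC[i, j]
        for j, gj in enumerate(groups):
            if gj.role != CONSUMER or dc[i, j] == 0.0:
                continue
            if unknowns[gj.code] == "B":
                a[row, col[gj.code]] -= gj.qb * dc[i, j]
            else:
                rhs[row] += gj.b * gj.qb * dc[i, j]

    if k:
        # rows that are identically zero are structurally unsolvable
        for row, ci in enumerate(unknown_codes):
            if not a[row].any() and rhs[row] == 0.0:
                raise ValueError(
                    f"group {ci!r} is structurally unsolvable: nothing eats it "
                    "and it has no catch or export"
                )
        try:
            x = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular mass-balance system: {exc}") from exc
        solved = dict(zip(unknown_codes, x))
        filled: list[GroupParams] = []
        for g in groups:
            u = unknowns[g.code]
            if u is None:
                filled.append(g)
            else:
                value = float(solved[g.code])
                attr = {"B": "b", "PB": "pb", "EE": "ee"}[u]
                try:
                    filled.append(replace(g, **{attr: value}))
                except ValueError:
                    # solved value outside the input-validation range (e.g. an
                    # EE > 1 signalling an unbalanced group): keep it visible
                    ng = replace(g)
                    object.__setattr__(ng, attr, value)
                    filled.append(ng)
        groups = filled

    # clamp EE dataclass invariant: rebuild with raw values to keep flagged
    # out-of-range EE visible — bypass validation via object.__setattr__
    unbalanced: list[str] = []
    residuals: dict[str, float] = {}
    q = _consumption_matrix(groups, diet)
    predation = q.sum(axis=1)
    for i, g in enumerate(groups):
        if g.role == DETRITUS:
            continue
        prod = g.b * g.pb  # type: ignore[operator]
        res = prod * g.ee - predation[i] - g.total_catch - g.export
        residuals[g.code] = float(res)
        if not (0.0 <= g.ee <= 1.0):  # type: ignore[operator]
            unbalanced.append(g.code)

    tl = compute_trophic_levels(diet)
    return BalancedModel(
        groups=groups,
        diet=diet,
        tl=tl,
        residuals=residuals,
        unbalanced=unbalanced,
        unassimilated=unassimilated,
    )


def predation_mortality(
    groups: list[GroupParams], diet: DietMatrix
) -> dict[str, float]:
    """M2_i = Σ_j B_j·QB_j·DC[i, j] / B_i — per-biomass predation losses."""
    q = _consumption_matrix(groups, diet)
    consumed = q.sum(axis=1)
    out: dict[str, float] = {}
    for i, g in enumerate(groups):
        if g.b in (None, 0.0):
            if consumed[i] > 0:
                raise ValueError(
                    f"group {g.code!r} has zero biomass but non-zero predation"
                )
            out[g.code] = 0.0
        else:
            out[g.code] = float(consumed[i] / g.b)
    return out


def pq_ratio(group: GroupParams) -> float:
    """Gross food-conversion efficiency P/Q = PB/QB."""
    if not group.qb:
        raise ValueError(f"P/Q undefined for {group.code!r} (no consumption)")
    if group.pb is None:
        raise ValueError(f"P/Q needs a known PB for {group.code!r}")
    return group.pb / group.qb


def omnivory_index(code: str, diet: DietMatrix, tls: TrophicLevelTable) -> float:
    """Diet-weighted variance of prey trophic levels:

    OI_i = Σ_j DC[j, i]·(TL_j − (TL_i − 1))²

    Zero by convention for producers, detritus and single-prey consumers;
    import is counted as a TL-1 food item.
    """
    j = diet.index(code)
    if diet.roles[code] != CONSUMER:
        return 0.0
    fractions = diet.dc[:, j]
    prey_tl = np.array([tls[c] for c in diet.codes])
    mean_prey_tl = tls[code] - 1.0
    oi = float(fractions @ (prey_tl - mean_prey_tl) ** 2)
    imp = diet.import_frac.get(code, 0.0)
    if imp:
        oi += imp * (1.0 - mean_prey_tl) ** 2
    return oi


def omnivory_from_diet(
    diet_column: dict[str, float],
    tls: TrophicLevelTable,
    predator_tl: float | None = None,
) -> float:
    """Omnivory index of one consumer from its diet column and prey TLs.

    When ``predator_tl`` is omitted it is computed as 1 + Σ DC_j·TL_j.
    """
    from .foodweb import normalize_diet, trophic_level_from_diet

    fractions = normalize_diet(diet_column)
    if predator_tl is None:
        predator_tl = trophic_level_from_diet(fractions, tls)
    mean_prey_tl = predator_tl - 1.0
    return float(
        sum(f * (tls[item] - mean_prey_tl) ** 2 for item, f in fractions.items())
    )


def flows(model: BalancedModel, diet: DietMatrix) -> pd.DataFrame:
    """Per-group flow bookkeeping of a balanced model.

    flow to detritus = B·PB·(1−EE) + B·QB·u   (u = unassimilated fraction,
    consumers only); net efficiency = production / assimilated consumption
    = PB / (QB·(1−u)); F = catch/B, Z = PB, F/Z = catch/(B·PB); proportion
    natural mortality = 1 − F/Z (predation plus other natural losses).
    """
    u = model.unassimilated
    rows = []
    for g in model.groups:
        if g.role == DETRITUS:
            rows.append(
                {
                    "code": g.code,
                    "flow_to_detritus": 0.0,
                    "net_efficiency": float("nan"),
                    "F": 0.0,
                    "F_over_Z": 0.0,
                    "prop_natural_mortality": float("nan"),
                }
            )
            continue
        b, pb, ee = g.b, g.pb, g.ee
        non_pred = b * pb * (1.0 - ee)
        egestion = b * (g.qb or 0.0) * u if g.role == CONSUMER else 0.0
        if g.role == CONSUMER and g.qb:
            net_eff = pb / (g.qb * (1.0 - u))
        else:
            net_eff = float("nan")
        prod = b * pb
        f_over_z = g.total_catch / prod if prod > 0 else 0.0
        rows.append(
            {
                "code": g.code,
                "flow_to_detritus": non_pred + egestion,
                "net_efficiency": net_eff,
                "F": g.total_catch / b if b else 0.0,
                "F_over_Z": f_over_z,
                "prop_natural_mortality": 1.0 - f_over_z,
            }
        )
    return pd.DataFrame(rows)


def _paths_to_bottom(
    diet: DietMatrix, start: int
) -> list[list[int]]:
    """All simple diet paths from a consumer down to producers/detritus.

    A path follows predator → prey links; cycles are cut on the first
    repeated node.
    """
    bottom = {
        i for i, c in enumerate(diet.codes) if diet.roles[c] in (PRODUCER, DETRITUS)
    }
    paths: list[list[int]] = []
    stack: list[tuple[list[int], set[int]]] = [([start], {start})]
    while stack:
        path, seen = stack.pop()
        node = path[-1]
        if node in bottom:
            paths.append(path)
            continue
        prey = np.flatnonzero(diet.dc[:, node] > 0)
        for p in prey:
            if p in seen:
                continue  # cycle cut
            stack.append((path + [int(p)], seen | {int(p)}))
    return paths


def ppr(
    model: BalancedModel,
    diet: DietMatrix | None = None,
    catches: dict[str, float] | None = None,
    convention: str = "as_printed",
    prune: float = 1e-12,
) -> float:
    """Primary production (and detritus flow) required to sustain catches.

    Back-calculates along every diet path from each caught group down to
    producers/detritus.  Two conventions:

    - ``"as_printed"``: each path contributes
      (Y_i/P_i)·Π over path links of (Q_j/P_j · EE_j · DC_prey,j),
      the product taken over the predators j along the path.
    - ``"raising"``: the classic raising-factor form — catch Y_i raised by
      Π (Q_j/P_j)·DC along the path, without the EE factor or the
      production normalisation of the caught group.

    Contributions below ``prune`` are dropped.  Nonnegative, linear in the
    catches.
    """
    if diet is None:
        diet = model.diet
    if convention not in ("as_printed", "raising"):
        raise ValueError(f"unknown convention {convention!r}")
    groups = {g.code: g for g in model.groups}
    if catches is None:
        catches = {g.code: g.total_catch for g in model.groups}
    total = 0.0
    for code, y in catches.items():
        if y <= 0:
            continue
        g0 = groups[code]
        if diet.roles[code] in (PRODUCER, DETRITUS):
            # catch of a primary group requires itself only
            total += y
            continue
        start = diet.index(code)
        p0 = g0.b * g0.pb  # type: ignore[operator]
        for path in _paths_to_bottom(diet, start):
            contrib = y / p0 if convention == "as_printed" else y
            # links: predator path[k] eating prey path[k+1]
            for k in range(len(path) - 1):
                pred = groups[diet.codes[path[k]]]
                dc = diet.dc[path[k + 1], path[k]]
                qp = (pred.qb or 0.0) / pred.pb  # type: ignore[operator]
                if convention == "as_printed":
                    contrib *= qp * pred.ee * dc  # type: ignore[operator]
                else:
                    contrib *= qp * dc
                if contrib < prune:
                    break
            if contrib >= prune:
                total += contrib
    return float(total)
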