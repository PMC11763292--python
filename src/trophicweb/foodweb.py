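"""Diet-composition handling and trophic-level computation.

A food web is wired by its diet-composition matrix ``DC``, with ``DC[i, j]``
the fraction that prey *i* contributes to the diet of predator *j*.  Fractional
trophic levels follow from the fixed point

    TL_i = 1 + sum_j DC[j, i] * TL_j

with producers and detritus pinned at trophic level 1 and diet imported from
outside the system treated as trophic level 1 (its history is untracked).
Because real webs contain cycles (mutual predation, cannibalism) the fixed
point is obtained by a linear solve rather than by iterating the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "TrophicLevelTable",
    "DietMatrix",
    "normalize_diet",
    "pool_diets",
    "compute_trophic_levels",
    "trophic_level_from_diet",
]

# group roles
PRODUCER = "producer"
CONSUMER = "consumer"
DETRITUS = "detritus"
Role = str

_COLUMN_TOL = 1e-6
IMPORT_CODE = "IMPORT"


@dataclass(frozen=True)
class TrophicLevelTable:
    """Catalogue mapping species/group codes to fractional trophic levels."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        seen = set()
        for code, tl in self.entries.items():
            if code in seen:
                raise ValueError(f"duplicate code {code!r}")
            seen.add(code)
            if not np.isfinite(tl) or tl < 1.0:
                raise ValueError(f"trophic level of {code!r} must be >= 1, got {tl}")

    def __getitem__(self, code: str) -> float:
        return float(self.entries[code])

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def get(self, code: str, default: float | None = None) -> float | None:
        value = self.entries.get(code, default)
        return None if value is None else float(value)

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.entries), name="TL", dtype=float)

    @classmethod
    def from_series(cls, series: pd.Series) -> "TrophicLevelTable":
        return cls(entries={str(k): float(v) for k, v in series.items()})


@dataclass
class DietMatrix:
    """Prey-by-predator diet fractions plus group roles and import fractions.

    ``dc[i, j]`` is the fraction of prey ``codes[i]`` in the diet of predator
    ``codes[j]``.  Consumer columns sum to 1 together with the import
    fraction; producer and detritus columns are all zero.
    """

    codes: list[str]
    dc: np.ndarray
    roles: dict[str, Role]
    import_frac: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = list(self.codes)
        self.dc = np.asarray(self.dc, dtype=float)
        n = len(self.codes)
        if len(set(self.codes)) != n:
            raise ValueError("group codes must be unique")
        if self.dc.shape != (n, n):
            raise ValueError(f"DC must be {n}x{n}, got {self.dc.shape}")
        if np.any(self.dc < -1e-15) or np.any(self.dc > 1 + 1e-12):
            raise ValueError("diet fractions must lie in [0, 1]")
        missing = set(self.codes) - set(self.roles)
        if missing:
            raise ValueError(f"missing roles for {sorted(missing)}")
        for j, code in enumerate(self.codes):
            role = self.roles[code]
            col = self.dc[:, j].sum() + self.import_frac.get(code, 0.0)
            if role == CONSUMER:
                if abs(col - 1.0) > _COLUMN_TOL:
                    raise ValueError(
                        f"consumer column {code!r} sums to {col:.8f}, expected 1"
                    )
            elif role in (PRODUCER, DETRITUS):
                if self.dc[:, j].any():
                    raise ValueError(f"{role} column {code!r} must be all zero")
            else:
                raise ValueError(f"unknown role {role!r} for {code!r}")

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def role_mask(self, role: Role) -> np.ndarray:
        return np.array([self.roles[c] == role for c in self.codes])

    def consumers(self) -> list[str]:
        return [c for c in self.codes if self.roles[c] == CONSUMER]

    def column(self, code: str) -> pd.Series:
        return pd.Series(self.dc[:, self.index(code)], index=self.codes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dc, index=self.codes, columns=self.codes)

    # -- CSV dialect: first column prey code, remaining columns predators -----
    def to_csv(self, path) -> None:
        frame = self.to_frame()
        if self.import_frac:
            imp = pd.Series(
                {c: self.import_frac.get(c, 0.0) for c in self.codes},
                name=IMPORT_CODE,
            )
            frame = pd.concat([frame, imp.to_frame().T])
        frame.index.name = "prey"
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path, roles: Mapping[str, Role]) -> "DietMatrix":
        frame = pd.read_csv(path, index_col=0)
        import_frac: dict[str, float] = {}
        if IMPORT_CODE in frame.index:
            imp_row = frame.loc[IMPORT_CODE]
            import_frac = {c: float(v) for c, v in imp_row.items() if v > 0}
            frame = frame.drop(index=IMPORT_CODE)
        codes = list(frame.columns)
        frame = frame.reindex(index=codes, fill_value=0.0)
        return cls(
            codes=codes,
            dc=frame.to_numpy(dtype=float),
            roles={c: roles[c] for c in codes},
            import_frac=import_frac,
        )


def normalize_diet(raw_fractions: Mapping[str, float]) -> dict[str, float]:
    """Rescale non-negative diet weights so they sum to exactly 1.

    Raises ``ValueError`` on an all-zero (empty) diet; proportions between
    items are preserved.
    """
    items = list(raw_fractions.items())
    weights = np.array([w for _, w in items], dtype=float)
    if np.any(weights < 0):
        raise ValueError("diet weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("empty diet")
    return {k: float(w / total) for (k, _), w in zip(items, weights)}


def pool_diets(
    study_columns: Sequence[Mapping[str, float]],
    weights: Iterable[float] | None = None,
) -> dict[str, float]:
    """Pool several per-study diet columns into a single determination.

    Each study column is normalised, the (optionally weighted) mean taken over
    the union of food items — a study missing an item contributes 0 for it —
    and the result renormalised.  With equal weights this is the renormalised
    arithmetic mean.
    """
    studies = [normalize_diet(col) for col in study_columns]
    if not studies:
        raise ValueError("need at least one study")
    if weights is None:
        w = np.ones(len(studies))
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (len(studies),):
            raise ValueError("one weight per study required")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    items = sorted({item for s in studies for item in s})
    pooled = np.zeros(len(items))
    for wk, study in zip(w, studies):
        pooled += wk * np.array([study.get(item, 0.0) for item in items])
    pooled /= pooled.sum()
    return dict(zip(items, (float(v) for v in pooled)))


def trophic_level_from_diet(
    diet_column: Mapping[str, float],
    tls: TrophicLevelTable,
    import_frac: float = 0.0,
) -> float:
    """Trophic level of a single consumer from its diet column:

    TL = 1 + Σ_j DC_j·TL_j, with imported diet counted at TL 1.

    Useful when the prey trophic levels are already known (e.g. from a
    published catalogue) and no full-web solve is needed.
    """
    fractions = normalize_diet({**dict(diet_column), IMPORT_CODE: import_frac} if import_frac else diet_column)
    tl = 1.0
    for item, frac in fractions.items():
        tl += frac * (1.0 if item == IMPORT_CODE else tls[item])
    return tl


def compute_trophic_levels(diet: DietMatrix) -> TrophicLevelTable:
    """Solve TL_i = 1 + sum_j DC[j, i]·TL_j as a linear fixed point.

    Producers and detritus are pinned at TL 1; imported diet counts as TL 1.
    Exact for webs with cycles provided the consumer-on-consumer diet
    sub-matrix has spectral radius < 1 (guaranteed when no consumer column is
    fully cannibalistic).
    """
    is_consumer = diet.role_mask(CONSUMER)
    tl = np.ones(diet.n)
    idx = np.flatnonzero(is_consumer)
    if idx.size:
        # TL_c = 1 + import_c·1 + Σ_{fixed j} DC[j,c]·1 + Σ_{consumer j} DC[j,c]·TL_j
        a = diet.dc[np.ix_(idx, idx)].T  # rows: consumer equations
        radius = max(abs(np.linalg.eigvals(a))) if idx.size else 0.0
        if radius >= 1.0 - 1e-12:
            raise ValueError("degenerate diet cycle: spectral radius >= 1")
        fixed_contrib = diet.dc[:, idx].sum(axis=0) - diet.dc[np.ix_(idx, idx)].sum(axis=0)
        imports = np.array([diet.import_frac.get(diet.codes[c], 0.0) for c in idx])
        rhs = 1.0 + fixed_contrib + imports
        tl[idx] = np.linalg.solve(np.eye(idx.size) - a, rhs)
    return TrophicLevelTable(entries={c: float(t) for c, t in zip(diet.codes, tl)})
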