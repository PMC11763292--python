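"""Empirical life-history estimators feeding the mass-balance model.

These are the standard comparative relationships used to turn literature
growth parameters into the rate inputs of a trophic model: von Bertalanffy
growth, Pauly's (1980) natural-mortality regression, Hoenig's (1983)
longevity-based total mortality, and the Palomares–Pauly (1998) empirical
consumption/biomass regression.  Under equilibrium, production per biomass
P/B equals total mortality Z = M + F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrowthParams",
    "vbgf_length",
    "pauly_M",
    "hoenig_Z",
    "palomares_QB",
    "pb_from_Z",
    "fishing_mortality",
]

#: Hoenig (1983) ln Z = a + b·ln Tm coefficients per taxon
HOENIG_COEFS = {
    "fish": (1.46, -1.01),
    "mollusk": (1.23, -0.832),
}

DEFAULT_TEMPERATURE_C = 23.4  # study-system mean water temperature


@dataclass(frozen=True)
class GrowthParams:
    """Growth/longevity inputs for one species.

    Lengths in cm, weights in grams wet weight, ages and longevity in years,
    temperature in °C.  ``aspect_ratio`` is the caudal-fin shape index
    Ar = h²/S (fin height squared over fin surface area); ``herbivore`` and
    ``detritivore`` are the 0/1 food-type flags of the consumption
    regression — carnivores carry 0 for both.
    """

    linf: float
    k: float
    t0: float = 0.0
    winf: float | None = None
    tmax: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_C
    aspect_ratio: float | None = None
    fin_height_mm: float | None = None
    fin_area_mm2: float | None = None
    herbivore: int = 0
    detritivore: int = 0

    def __post_init__(self) -> None:
        if self.linf <= 0 or self.k <= 0:
            raise ValueError("L∞ and K must be positive")
        if self.winf is not None and self.winf <= 0:
            raise ValueError("W∞ must be positive")
        if self.tmax is not None and self.tmax <= 0:
            raise ValueError("longevity must be positive")
        if self.herbivore not in (0, 1) or self.detritivore not in (0, 1):
            raise ValueError("food-type flags must be 0 or 1")
        if self.herbivore and self.detritivore:
            raise ValueError("a group cannot be both herbivore and detritivore")
        if (
            self.aspect_ratio is not None
            and self.fin_height_mm is not None
            and self.fin_area_mm2 is not None
        ):
            implied = self.fin_height_mm**2 / self.fin_area_mm2
            if abs(implied - self.aspect_ratio) > 0.01 * abs(self.aspect_ratio):
                raise ValueError(
                    f"aspect ratio {self.aspect_ratio} inconsistent with "
                    f"h²/S = {implied:.4f}"
                )

    @property
    def ar(self) -> float:
        """Caudal-fin aspect ratio, from h²/S when not given directly."""
        if self.aspect_ratio is not None:
            return self.aspect_ratio
        if self.fin_height_mm is not None and self.fin_area_mm2 is not None:
            return self.fin_height_mm**2 / self.fin_area_mm2
        raise ValueError("no aspect-ratio information available")


def vbgf_length(t: float, p: GrowthParams) -> float:
    """von Bertalanffy length at age: L_t = L∞·(1 − e^(−K·(t − t0)))."""
    return p.linf * (1.0 - math.exp(-p.k * (t - p.t0)))


def pauly_M(k: float, linf: float, temperature: float) -> float:
    """Pauly's natural mortality (yr⁻¹):

    log10 M = 0.654·log10 K − 0.279·log10 L∞ + 0.463·log10 T
    """
    if k <= 0 or linf <= 0 or temperature <= 0:
        raise ValueError("K, L∞ and T must be positive")
    return 10.0 ** (
        0.654 * math.log10(k) - 0.279 * math.log10(linf) + 0.463 * math.log10(temperature)
    )


def hoenig_Z(tmax: float, taxon: str = "fish") -> float:
    """Hoenig's longevity-based total mortality: Z = exp(a + b·ln Tm)."""
    if tmax <= 0:
        raise ValueError("longevity must be positive")
    try:
        a, b = HOENIG_COEFS[taxon]
    except KeyError:
        raise ValueError(
            f"unknown taxon {taxon!r}; expected one of {sorted(HOENIG_COEFS)}"
        ) from None
    return math.exp(a + b * math.log(tmax))


def palomares_QB(
    winf: float,
    temperature: float = DEFAULT_TEMPERATURE_C,
    ar: float = 0.0,
    herbivore: int = 0,
    detritivore: int = 0,
) -> float:
    """Palomares–Pauly consumption/biomass (yr⁻¹):

    log10 Q/B = 7.964 − 0.204·log10 W∞ − 1.965·T′ + 0.083·Ar + 0.532·H + 0.398·D

    with T′ = 1000/(T°C + 273.15) the inverse absolute temperature.
    """
    if winf <= 0:
        raise ValueError("W∞ must be positive")
    t_prime = 1000.0 / (temperature + 273.15)
    return 10.0 ** (
        7.964
        - 0.204 * math.log10(winf)
        - 1.965 * t_prime
        + 0.083 * ar
        + 0.532 * herbivore
        + 0.398 * detritivore
    )


def pb_from_Z(z: float) -> float:
    """P/B under equilibrium equals total mortality Z (yr⁻¹)."""
    if z < 0:
        raise ValueError("Z must be non-negative")
    return z


def fishing_mortality(z: float, m: float) -> tuple[float, bool]:
    """F = Z − M, clamped at zero.

    Returns ``(F, flagged)`` where ``flagged`` is True when the supplied
    natural mortality exceeded total mortality (F clamped).
    """
    f = z - m
    if f < 0:
        return 0.0, True
    return f, False
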