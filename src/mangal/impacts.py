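"""Impact scenarios: single killing event plus reduced regrowth in a zone.

Each impact is summarised by two Delphi-elicited scores on [0, 1]: its
intensity I and its spatial scale S (the affected fraction of the stand).
An impact clears all trees from a strip covering fraction S of the sample
hectare (single killing event) and, during recovery, multiplies both the
recruitment rate and tree growth inside that strip by a reduction factor.

Two readings of the reduction factor are available.  The ``literal`` mode
uses ``1 - I*(1 - S)``, i.e. the printed scenario formula; because that
expression weakens the reduction as S grows, a ``zone_intensity`` mode
applying ``1 - I`` inside the zone is provided as the alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DEFAULT_RECRUITMENT, step_year
from .stand import (DEFAULT_RESOLUTION, SpeciesParams, Stand, ZoneModifiers,
                    stand_summary)

#: The ten canonical impact labels, most severe first.
IMPACT_NAMES = (
    "development", "tourism", "household uses", "aquaculture",
    "natural disasters", "climate change", "pests/disease",
    "extractive processes", "pollution", "war",
)

#: Recovery is declared when sample biomass re-enters this band (t/ha).
DEFAULT_BAND = (300.0, 400.0)

FORMULA_MODES = ("literal", "zone_intensity")


@dataclass(frozen=True)
class ImpactSpec:
    """A named impact with intensity and spatial scale on [0, 1]."""

    name: str
    intensity: float
    spatial_scale: float
    formula_mode: str = "literal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")
        if not 0.0 <= self.spatial_scale <= 1.0:
            raise ValueError("spatial_scale must lie in [0, 1]")
        if self.formula_mode not in FORMULA_MODES:
            raise ValueError(f"formula_mode must be one of {FORMULA_MODES}")


@dataclass(frozen=True)
class Strip:
    """Vertical strip ``x0 <= x < x1`` spanning the full domain height."""

    x0: float
    x1: float

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    def contains(self, x, y=None):
        x = np.asarray(x, dtype=float)
        return (x >= self.x0) & (x < self.x1)


def impacted_zone(spatial_scale: float, stand: Stand) -> Strip:
    """Strip covering fraction ``spatial_scale`` of the sample square.

    The strip starts at the sample origin and extends through the edge band
    (full y-range) at the same x-range.  S=0 yields an empty strip, S=1 the
    full sample width.
    """
    if not 0.0 <= spatial_scale <= 1.0:
        raise ValueError("spatial_scale must lie in [0, 1]")
    x0 = stand.sample_origin
    return Strip(x0, x0 + spatial_scale * stand.sample_side)


def zone_modifiers(spec: ImpactSpec) -> tuple[float, float]:
    """(recruit_factor, growth_factor) applied inside the impacted zone.

    ``literal`` mode: ``1 - I*(1 - S)``; ``zone_intensity`` mode: ``1 - I``.
    Both clipped to [0, 1]; both factors are equal because the scenario
    formulas reduce recruitment and growth identically.
    """
    if spec.formula_mode == "literal":
        f = 1.0 - spec.intensity * (1.0 - spec.spatial_scale)
    else:
        f = 1.0 - spec.intensity
    f = float(np.clip(f, 0.0, 1.0))
    return f, f


def apply_impact(stand: Stand, spec: ImpactSpec,
                 rng: np.random.Generator | None = None,
                 mode: str = "clear") -> Stand:
    """Impose a single killing event and install the zone modifiers.

    ``mode='clear'`` removes every tree inside the impacted strip;
    ``mode='thin'`` instead keeps each tree in the strip with probability
    ``1 - I*(1 - S)`` (the reduced-density reading of the scenario table).
    Trees outside the strip are never touched.
    """
    if mode not in ("clear", "thin"):
        raise ValueError("mode must be 'clear' or 'thin'")
    s = stand.copy()
    strip = impacted_zone(spec.spatial_scale, s)
    inside = strip.contains(s.x)
    if mode == "clear":
        keep = ~inside
    else:
        if rng is None:
            raise ValueError("thin mode needs a random generator")
        frac = 1.0 - spec.intensity * (1.0 - spec.spatial_scale)
        keep = ~inside | (rng.random(s.n) < frac)
    s.x, s.y = s.x[keep], s.y[keep]
    s.dbh, s.age = s.dbh[keep], s.age[keep]
    s.mem, s.mem_ptr = s.mem[keep], s.mem_ptr[keep]
    rf, gf = zone_modifiers(spec)
    s.zone = ZoneModifiers(strip.x0, strip.x1, rf, gf)
    return s


@dataclass(frozen=True)
class RecoveryOutcome:
    """Years until sample biomass re-entered the halting band."""

    years: int
    censored: bool

    @property
    def value(self) -> float:
        return float(self.years)


def recovery_time(stand: Stand, params: SpeciesParams,
                  rng: np.random.Generator,
                  band: tuple[float, float] = DEFAULT_BAND,
                  max_years: int = 200,
                  base_rate: float = DEFAULT_RECRUITMENT,
                  resolution: float = DEFAULT_RESOLUTION) -> RecoveryOutcome:
    """Run annual steps until sample biomass reaches the band's lower edge.

    Returns the elapsed years; if the band is not reached within
    ``max_years`` the result carries a censoring flag (never an exception).
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band lower edge must be below the upper edge")
    s = stand
    for elapsed in range(max_years + 1):
        if stand_summary(s, params).biomass >= lo:
            return RecoveryOutcome(elapsed, False)
        if elapsed == max_years:
            break
        s = step_year(s, params, rng, base_rate=base_rate,
                      resolution=resolution)
    return RecoveryOutcome(max_years, True)
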