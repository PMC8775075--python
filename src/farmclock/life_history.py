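"""Species life-history constants anchoring the age transformations.

Every age transformation in this package is parameterized by three
life-history traits of the sampled species: gestation length (GT), age at
sexual maturity (ASM) and maximum recorded lifespan (MaxAge).  Constants for
the four built-in ruminant species (red/wapiti deer, cattle, goat, sheep)
are vendored from the AnAge longevity database; custom species can be
supplied via a small YAML/key-value config so the multi-species workflow
extends beyond the built-ins.

All ages inside the package are measured in days.  Lifespans are commonly
tabulated in years, so conversion helpers using the Julian year
(365.25 days) are provided here and used everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import yaml

__all__ = [
    "DAYS_PER_YEAR",
    "SpeciesLifeHistory",
    "builtin_life_history",
    "builtin_species",
    "years_to_days",
    "days_to_years",
    "load_life_history_config",
]

#: Length of one year in days (Julian year).
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SpeciesLifeHistory:
    """Life-history constants for one species, all durations in days.

    Parameters
    ----------
    species_name
        Free-text species label, e.g. ``"goat"``.
    max_lifespan_days
        Maximum recorded lifespan (MaxAge).
    asm_days
        Average age at sexual maturity (ASM).
    gestation_days
        Average gestation length (GT).
    """

    species_name: str
    max_lifespan_days: float
    asm_days: float
    gestation_days: float

    def __post_init__(self) -> None:
        for field in ("max_lifespan_days", "asm_days", "gestation_days"):
            value = getattr(self, field)
            if not (value > 0):
                raise ValueError(f"{field} must be strictly positive, got {value!r}")
        if not (self.gestation_days < self.asm_days < self.max_lifespan_days):
            raise ValueError(
                "life-history ordering violated: require gestation < age at "
                f"sexual maturity < max lifespan, got GT={self.gestation_days}, "
                f"ASM={self.asm_days}, MaxAge={self.max_lifespan_days}"
            )


# AnAge-derived constants: (max lifespan in years, ASM in days, GT in days).
_BUILTIN: dict[str, tuple[float, float, float]] = {
    "deer": (31.5, 791.0, 245.0),
    "cattle": (20.0, 548.0, 277.0),
    "goat": (20.8, 545.5, 155.0),
    "sheep": (22.8, 731.0, 146.0),
}


def years_to_days(years: float) -> float:
    """Convert a duration in years to days (Julian year, 365.25 d).

    Raises
    ------
    ValueError
        If ``years`` is negative.
    """
    if years < 0:
        raise ValueError(f"duration must be non-negative, got {years!r}")
    return years * DAYS_PER_YEAR


def days_to_years(days: float) -> float:
    """Convert a duration in days to years (Julian year, 365.25 d)."""
    if days < 0:
        raise ValueError(f"duration must be non-negative, got {days!r}")
    return days / DAYS_PER_YEAR


def builtin_species() -> tuple[str, ...]:
    """Names of the vendored species."""
    return tuple(_BUILTIN)


def builtin_life_history(species_name: str) -> SpeciesLifeHistory:
    """Return the vendored life-history record for a built-in species.

    Lookup is case-insensitive.  Max lifespan is converted from years to
    days; ASM and gestation are tabulated in days already.

    Raises
    ------
    ValueError
        If ``species_name`` is not one of the vendored species.
    """
    key = species_name.strip().lower()
    if key not in _BUILTIN:
        supported = ", ".join(sorted(_BUILTIN))
        raise ValueError(
            f"unknown species {species_name!r}; built-in species are: {supported}. "
            "Use a life-history config file for other species."
        )
    max_years, asm, gt = _BUILTIN[key]
    return SpeciesLifeHistory(
        species_name=key,
        max_lifespan_days=years_to_days(max_years),
        asm_days=asm,
        gestation_days=gt,
    )


def load_life_history_config(
    path: Union[str, Path],
) -> Mapping[str, SpeciesLifeHistory]:
    """Load per-species life-history constants from a YAML config file.

    The file maps species names to the three constants::

        alpaca:
          max_lifespan_years: 25.8
          asm_days: 730
          gestation_days: 335

    ``max_lifespan_days`` may be given instead of ``max_lifespan_years``.

    Returns a dict keyed by lower-cased species name.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"life-history config {path} must be a mapping of species")
    table: dict[str, SpeciesLifeHistory] = {}
    for name, entry in raw.items():
        if not isinstance(entry, dict):
            raise ValueError(f"entry for species {name!r} must be a mapping")
        if "max_lifespan_days" in entry:
            max_days = float(entry["max_lifespan_days"])
        elif "max_lifespan_years" in entry:
            max_days = years_to_days(float(entry["max_lifespan_years"]))
        else:
            raise ValueError(
                f"species {name!r}: need max_lifespan_years or max_lifespan_days"
            )
        table[str(name).lower()] = SpeciesLifeHistory(
            species_name=str(name).lower(),
            max_lifespan_days=max_days,
            asm_days=float(entry["asm_days"]),
            gestation_days=float(entry["gestation_days"]),
        )
    return table
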