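"""Invertible age transformations used to define clocks 1-3.

An epigenetic clock is a sparse linear predictor of *transformed* age; the
transformation determines which scale the regression sees and how its
predictions are mapped back to calendar age (DNAm age).  Three transforms
are supported, each anchored on a species' life history (GT = gestation
days, ASM = age at sexual maturity, MaxAge = maximum lifespan, all in
days), with natural logarithms throughout:

clock 1 (log age)
    ``LogAge = ln(age + 2 GT)``.  Species-specific; the 2 GT offset keeps
    the log well-behaved near birth and leaves room for prenatal samples.
clock 2 (log-log relative age)
    ``RelativeAge = (age + 2 GT) / (MaxAge + 2 GT)`` in (0, 1], then
    ``LoglogAge = -ln(-ln(RelativeAge))``.  Lifespan-normalized, hence
    comparable across species with very different longevities.
clock 3 (log-linear age)
    ``r = (age + 2 GT) / (ASM + 2 GT)``; logarithmic below sexual maturity
    (``ln r``) and linear above (``r - 1``), continuously differentiable at
    ASM.  Uses ASM as a lifespan proxy, which is usually far better
    recorded in livestock than true maximum lifespan.

Each transform is strictly increasing in age and has an exact closed-form
inverse, so round trips are lossless to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .life_history import SpeciesLifeHistory

__all__ = ["AgeTransform", "relative_age", "CLOCK_NUMBERS"]

CLOCK_NUMBERS = (1, 2, 3)


def relative_age(lh: SpeciesLifeHistory, age_days) -> np.ndarray | float:
    """Lifespan-relative age ``(age + 2 GT) / (MaxAge + 2 GT)``, in (0, 1].

    Accepts a scalar or array of ages in days within ``[0, MaxAge]``.
    """
    age = np.asarray(age_days, dtype=float)
    if np.any(age < 0) or np.any(age > lh.max_lifespan_days):
        raise ValueError(
            f"age must lie in [0, MaxAge={lh.max_lifespan_days}] days for "
            f"{lh.species_name}; got values outside that range"
        )
    offset = 2.0 * lh.gestation_days
    out = (age + offset) / (lh.max_lifespan_days + offset)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AgeTransform:
    """One of the three invertible age <-> transformed-age mappings.

    Parameters
    ----------
    clock_number
        1 (log age), 2 (log-log relative age) or 3 (log-linear age).
    life_history
        Species constants parameterizing the transform.
    clamp_relative_age
        Clock 2 only: if True, ages at or beyond MaxAge are clamped so the
        relative age never reaches 1 (useful at prediction time for
        long-lived outliers); if False such ages raise.
    printed_inverse
        Clock 3 only: compatibility switch for the published form of the
        sub-ASM inverse, which subtracts 1.5 instead of 2 GT.  That form is
        not the algebraic inverse of the forward transform (the constant is
        dimensionally inconsistent with day units), so the default is the
        exact inverse; the flag reproduces the published behaviour.
    """

    clock_number: int
    life_history: SpeciesLifeHistory
    clamp_relative_age: bool = False
    printed_inverse: bool = False

    _REL_CLAMP: float = field(default=1.0 - 1e-6, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.clock_number not in CLOCK_NUMBERS:
            raise ValueError(
                f"clock_number must be one of {CLOCK_NUMBERS}, got {self.clock_number!r}"
            )

    # -- forward ---------------------------------------------------------

    def transform(self, age_days) -> np.ndarray | float:
        """Map chronological age (days) to the clock's transformed scale."""
        age = np.asarray(age_days, dtype=float)
        if not np.all(np.isfinite(age)):
            raise ValueError("age must be finite")
        if np.any(age < 0):
            raise ValueError(f"age must be non-negative, got min {age.min()}")
        lh = self.life_history
        offset = 2.0 * lh.gestation_days
        if self.clock_number == 1:
            out = np.log(age + offset)
        elif self.clock_number == 2:
            rel = (age + offset) / (lh.max_lifespan_days + offset)
            if np.any(rel >= 1.0):
                if self.clamp_relative_age:
                    rel = np.minimum(rel, self._REL_CLAMP)
                else:
                    raise ValueError(
                        f"clock 2 diverges at age >= MaxAge "
                        f"({lh.max_lifespan_days} d for {lh.species_name}); "
                        "set clamp_relative_age=True to clamp instead"
                    )
            out = -np.log(-np.log(rel))
        else:  # clock 3
            r = (age + offset) / (lh.asm_days + offset)
            out = np.where(r >= 1.0, r - 1.0, np.log(r))
        return out if out.ndim else float(out)

    # -- inverse ---------------------------------------------------------

    def inverse_transform(self, y) -> np.ndarray | float:
        """Map a transformed-age value back to DNAm age in days.

        Exact functional inverse of :meth:`transform` (up to floating
        point), except for clock 3 with ``printed_inverse=True``.
        """
        yv = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(yv)):
            raise ValueError("transformed age must be finite")
        lh = self.life_history
        offset = 2.0 * lh.gestation_days
        if self.clock_number == 1:
            out = np.exp(yv) - offset
        elif self.clock_number == 2:
            out = np.exp(-np.exp(-yv)) * (lh.max_lifespan_days + offset) - offset
        else:
            scale = lh.asm_days + offset
            sub = np.exp(yv) * scale - (1.5 if self.printed_inverse else offset)
            out = np.where(yv >= 0.0, lh.asm_days + yv * scale, sub)
        return out if out.ndim else float(out)
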