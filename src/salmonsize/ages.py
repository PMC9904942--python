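"""Salmon age codes in European notation and brood-year accounting.

An age code ``"f.o"`` gives the number of winters spent rearing in fresh
water (``f``) and the number of years spent at sea (``o``).  Total age adds
one year for incubation in the gravel, so a 2.3 fish is six years old.
Return year and brood year are linked through total age: a fish returning
in calendar year ``y`` with total age ``t`` hatched from eggs spawned in
``y - t``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["AgeGroup", "parse_age_code", "assign_brood_year", "AgeParseError"]

# Dominant Bristol Bay age groups: 1-2 freshwater years (0 for river-type
# Nushagak fish), 1-4 ocean years.
_AGE_RE = re.compile(r"^([0-3])\.([1-4])$")


class AgeParseError(ValueError):
    """Raised for an age code outside the accepted ``f.o`` grammar."""


@dataclass(frozen=True, order=True)
class AgeGroup:
    """Freshwater/ocean age pair, e.g. ``AgeGroup(1, 3)`` for a 1.3 fish."""

    fw_years: int
    ocean_years: int

    def __post_init__(self) -> None:
        if self.fw_years < 0:
            raise ValueError(f"freshwater age must be >= 0, got {self.fw_years}")
        if self.ocean_years < 1:
            raise ValueError(f"ocean age must be >= 1, got {self.ocean_years}")

    @property
    def total_age(self) -> int:
        """Total age in years: freshwater + ocean + 1 embryo year."""
        return self.fw_years + self.ocean_years + 1

    @property
    def code(self) -> str:
        return f"{self.fw_years}.{self.ocean_years}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


def parse_age_code(code: str) -> AgeGroup:
    """Parse an ``"f.o"`` age code string into an :class:`AgeGroup`.

    Only codes with f in 0-3 and o in 1-4 are accepted; anything else
    (including whitespace or comma separators) raises :class:`AgeParseError`.

    >>> parse_age_code("2.3").total_age
    6
    """
    if not isinstance(code, str):
        raise AgeParseError(f"age code must be a string, got {type(code).__name__}")
    m = _AGE_RE.match(code)
    if m is None:
        raise AgeParseError(f"unparseable age code {code!r} (expected 'f.o')")
    return AgeGroup(fw_years=int(m.group(1)), ocean_years=int(m.group(2)))


def assign_brood_year(return_year: int, age: AgeGroup | str) -> int:
    """Brood year of a fish returning in ``return_year`` at age ``age``.

    ``brood_year = return_year - total_age``; the inverse mapping
    ``return_year = brood_year + total_age`` is the identity round trip.
    """
    if isinstance(age, str):
        age = parse_age_code(age)
    return int(return_year) - age.total_age
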