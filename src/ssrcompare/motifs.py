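"""Motif algebra for microsatellite repeat units.

Two repeat units describe the same microsatellite if one is a cyclic rotation
of the other ("ACT", "CTA", "TAC" all tile the tract ACTACTACT...) or a
rotation of its reverse complement (the same tract read from the opposite
strand).  Units are restricted to *primitive* strings of length 1-6 nt --
"ATAT" is not a unit in its own right but two copies of "AT".  Partitioning
the primitive units under this relation yields exactly 501 equivalence
classes, the complete catalogue of distinct microsatellite patterns this
package recognizes.

Each class is represented by the lexicographically smallest member
(A < C < G < T); matching across species always happens at class level,
while reports may display whichever rotation was actually observed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

from .labels import RegionLabel, coerce_region

DNA_ALPHABET = "ACGT"
MAX_UNIT_LENGTH = 6

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidAlphabetError(ValueError):
    """A motif unit contained characters outside {A, C, G, T}."""


class NonPrimitiveUnitError(ValueError):
    """A unit was a power of a shorter unit where a primitive one is required."""


def _check_unit(unit: str) -> str:
    if not unit:
        raise InvalidAlphabetError("empty repeat unit")
    unit = unit.upper()
    if any(base not in DNA_ALPHABET for base in unit):
        raise InvalidAlphabetError(f"repeat unit {unit!r} contains non-ACGT characters")
    return unit


def rotations(unit: str) -> list[str]:
    """All cyclic rotations of ``unit``, starting from offset 0."""
    unit = _check_unit(unit)
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def reverse_complement(unit: str) -> str:
    """Watson-Crick complement, reversed. An involution on DNA strings."""
    return _check_unit(unit).translate(_COMPLEMENT)[::-1]


def primitive_root(unit: str) -> str:
    """Shortest string whose tandem repetition equals ``unit``."""
    unit = _check_unit(unit)
    n = len(unit)
    for d in range(1, n + 1):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return unit[:d]
    raise AssertionError("unreachable")  # pragma: no cover


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a concatenation of >=2 copies of a shorter string."""
    return len(primitive_root(unit)) == len(unit)


@dataclass(frozen=True)
class MotifClass:
    """Equivalence class of a repeat unit under rotation + reverse complement.

    ``representative`` is the lexicographic minimum over all rotations of any
    member and of its reverse complement; ``members`` holds every unit string
    in the class.
    """

    representative: str
    members: frozenset[str]

    @property
    def period(self) -> int:
        return len(self.representative)

    def __contains__(self, unit: str) -> bool:
        return unit.upper() in self.members

    def __str__(self) -> str:
        return self.representative


@lru_cache(maxsize=None)
def _class_of(unit: str) -> MotifClass:
    members = frozenset(rotations(unit)) | frozenset(rotations(reverse_complement(unit)))
    return MotifClass(representative=min(members), members=members)


def canonicalize(unit: str, *, reduce: bool = False) -> MotifClass:
    """Map a repeat unit to its canonical motif class.

    ``unit`` must be primitive unless ``reduce=True``, in which case it is
    first reduced to its primitive root (the behaviour the detector uses).
    """
    unit = _check_unit(unit)
    if len(unit) > MAX_UNIT_LENGTH:
        raise ValueError(f"repeat unit longer than {MAX_UNIT_LENGTH} nt: {unit!r}")
    root = primitive_root(unit)
    if len(root) != len(unit):
        if not reduce:
            raise NonPrimitiveUnitError(
                f"unit {unit!r} is {unit[: len(root)]!r} repeated; reduce to its "
                "primitive root first (or pass reduce=True)"
            )
        unit = root
    return _class_of(unit)


def enumerate_classes(max_unit: int = MAX_UNIT_LENGTH) -> list[MotifClass]:
    """Exhaustively enumerate all motif classes with period 1..``max_unit``.

    Returns one :class:`MotifClass` per equivalence class, ordered by period
    then representative.  For ``max_unit=6`` this yields the full catalogue
    of 501 distinct microsatellite patterns.
    """
    if not 1 <= max_unit <= MAX_UNIT_LENGTH:
        raise ValueError(f"max_unit must be in 1..{MAX_UNIT_LENGTH}, got {max_unit}")
    seen: dict[str, MotifClass] = {}
    for length in range(1, max_unit + 1):
        for bases in itertools.product(DNA_ALPHABET, repeat=length):
            unit = "".join(bases)
            if not is_primitive(unit):
                continue
            cls = canonicalize(unit)
            seen.setdefault(cls.representative, cls)
    return sorted(seen.values(), key=lambda c: (c.period, c.representative))


class ParsedTag(NamedTuple):
    unit: str
    region: RegionLabel
    ordinal: int | None


def format_tag(display_unit: str, region: "RegionLabel | str", ordinal: int | None = None) -> str:
    """Render the ``UNIT@Region`` tag, e.g. ``CAG@Coding`` or ``GAA@Intron 1``.

    ``display_unit`` is printed as given (it may be any rotation of the
    canonical representative); an optional ordinal qualifier is appended for
    introns numbered in transcription order.
    """
    unit = _check_unit(display_unit)
    if len(unit) > MAX_UNIT_LENGTH:
        raise ValueError(f"display unit longer than {MAX_UNIT_LENGTH} nt: {unit!r}")
    label = coerce_region(region)
    tag = f"{unit}@{label.value}"
    if ordinal is not None:
        tag += f" {int(ordinal)}"
    return tag


def parse_tag(tag: str) -> ParsedTag:
    """Inverse of :func:`format_tag`; ordinal suffixes become qualifiers."""
    try:
        unit, region_token = tag.split("@", 1)
    except ValueError:
        raise ValueError(f"malformed tag (no '@'): {tag!r}") from None
    unit = _check_unit(unit)
    parts = region_token.strip().split()
    ordinal: int | None = None
    if len(parts) == 2 and parts[1].isdigit():
        ordinal = int(parts[1])
    elif len(parts) != 1:
        raise ValueError(f"malformed region token in tag: {tag!r}")
    return ParsedTag(unit=unit, region=coerce_region(parts[0]), ordinal=ordinal)
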