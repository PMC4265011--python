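"""Gene-region vocabulary shared by tagging, annotation and reporting.

A microsatellite is assigned to exactly one of seven gene areas: the coding
region, non-coding exonic sequence, introns, the two untranslated regions,
and the upstream/downstream flanks (2,000 nt in transcription orientation).
"""
from __future__ import annotations

from enum import Enum


class UnknownRegionError(ValueError):
    """Raised when a region token cannot be mapped to one of the 7 labels."""


class RegionLabel(str, Enum):
    CODING = "Coding"
    FIVE_UTR = "5UTR"
    THREE_UTR = "3UTR"
    INTRON = "Intron"
    EXON = "Exon"
    UPSTREAM = "Upstream"
    DOWNSTREAM = "Downstream"

    def __str__(self) -> str:  # report dialect, e.g. "CAG@Coding"
        return self.value


#: Tie-break precedence for tracts straddling a region boundary: the more
#: gene-proximal / more specific label wins when overlap lengths are equal.
SPECIFICITY_ORDER = (
    RegionLabel.CODING,
    RegionLabel.FIVE_UTR,
    RegionLabel.THREE_UTR,
    RegionLabel.INTRON,
    RegionLabel.EXON,
    RegionLabel.UPSTREAM,
    RegionLabel.DOWNSTREAM,
)

_ALIASES = {
    "CODING": RegionLabel.CODING,
    "CDS": RegionLabel.CODING,
    "5UTR": RegionLabel.FIVE_UTR,
    "5'UTR": RegionLabel.FIVE_UTR,
    "5-UTR": RegionLabel.FIVE_UTR,
    "FIVE_PRIME_UTR": RegionLabel.FIVE_UTR,
    "3UTR": RegionLabel.THREE_UTR,
    "3'UTR": RegionLabel.THREE_UTR,
    "3-UTR": RegionLabel.THREE_UTR,
    "THREE_PRIME_UTR": RegionLabel.THREE_UTR,
    "INTRON": RegionLabel.INTRON,
    "EXON": RegionLabel.EXON,
    "UPSTREAM": RegionLabel.UPSTREAM,
    "DOWNSTREAM": RegionLabel.DOWNSTREAM,
}


def coerce_region(value: "RegionLabel | str") -> RegionLabel:
    """Normalize a region token (any common spelling) to its canonical label."""
    if isinstance(value, RegionLabel):
        return value
    token = str(value).strip().upper()
    try:
        return _ALIASES[token]
    except KeyError:
        raise UnknownRegionError(f"unknown gene region: {value!r}") from None
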