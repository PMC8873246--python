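"""Genomic intervals and region-string parsing.

All internal computation uses 0-based half-open coordinates. Printed,
browser-style coordinates ("chr11: 67,103,534–67,145,377") are 1-based
inclusive and are converted exactly once, at the parsing boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import RegionError, RegionParseError

ZERO_HALF_OPEN = "zero_half_open"
ONE_INCLUSIVE = "one_inclusive"
COORDINATE_SYSTEMS = (ZERO_HALF_OPEN, ONE_INCLUSIVE)

# hyphen, en dash, em dash, minus sign
_SEPARATORS = "-–—−"
_REGION_RE = re.compile(
    r"^(?P<chrom>[^:]+):(?P<start>\d+)[%s](?P<end>\d+)$" % _SEPARATORS
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """An interval stored in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise RegionError(
                f"invalid interval {self.chrom}:[{self.start}, {self.end}): "
                "require 0 <= start < end"
            )

    @classmethod
    def from_one_inclusive(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive endpoints (browser convention)."""
        return cls(chrom, start - 1, end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_one_inclusive(self) -> tuple[str, int, int]:
        return self.chrom, self.start + 1, self.end


def parse_region(text: str, coordinate_system: str = ONE_INCLUSIVE) -> GenomicInterval:
    """Parse a region string such as ``chr1:100-200`` or the printed style
    ``chr11: 67,103,534–67,145,377``.

    Commas and internal whitespace are stripped; hyphen and en/em dash both
    separate the endpoints. ``coordinate_system`` declares how the two
    numbers are to be read; the default is 1-based inclusive, matching
    genome-browser style strings. The result is always stored 0-based
    half-open.
    """
    if not isinstance(text, str) or not text.strip():
        raise RegionParseError("empty region string")
    if coordinate_system not in COORDINATE_SYSTEMS:
        raise RegionParseError(f"unknown coordinate system {coordinate_system!r}")
    cleaned = text.replace(",", "")
    cleaned = re.sub(r"\s+", "", cleaned)
    match = _REGION_RE.match(cleaned)
    if match is None:
        # name the offending token: whatever follows the first colon, or the
        # whole string if there is none
        offending = cleaned.split(":", 1)[1] if ":" in cleaned else cleaned
        raise RegionParseError(
            f"malformed region string {text!r}: cannot parse token {offending!r}"
        )
    chrom = match.group("chrom")
    start = int(match.group("start"))
    end = int(match.group("end"))
    if coordinate_system == ONE_INCLUSIVE:
        if start < 1 or end < start:
            raise RegionParseError(
                f"malformed 1-based region {text!r}: need 1 <= start <= end"
            )
        return GenomicInterval.from_one_inclusive(chrom, start, end)
    return GenomicInterval(chrom, start, end)


def format_region(
    interval: GenomicInterval, coordinate_system: str = ONE_INCLUSIVE
) -> str:
    """Format an interval so that :func:`parse_region` round-trips it."""
    if coordinate_system == ONE_INCLUSIVE:
        chrom, start, end = interval.to_one_inclusive()
        return f"{chrom}:{start}-{end}"
    if coordinate_system == ZERO_HALF_OPEN:
        return f"{interval.chrom}:{interval.start}-{interval.end}"
    raise RegionParseError(f"unknown coordinate system {coordinate_system!r}")
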