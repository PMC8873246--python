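"""In-silico restriction digestion and fragment-level bookkeeping.

A genome contig is partitioned into an ordered restriction-fragment map by
scanning every position for the first cutter's motif (cleavage at the
motif's 5' start, so the motif travels with the downstream fragment — the
^GATC convention). A secondary cutter marks "blind" fragments, those with
no internal secondary site. Count records and viewpoint intervals are then
resolved onto fragments.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InconsistencyError,
    InvalidAlphabetError,
    InvalidMotifError,
    RegulocusError,
    ViewpointResolutionError,
)
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


def _check_motif(motif: str) -> str:
    if not motif:
        raise InvalidMotifError("motif must be a non-empty DNA string")
    motif = motif.upper()
    if not set(motif) <= _DNA:
        raise InvalidAlphabetError(f"motif {motif!r} contains non-ACGT symbols")
    return motif


def find_motif_positions(sequence: str, motif: str) -> np.ndarray:
    """All (possibly overlapping) occurrence start positions of motif.

    N bases never match: the motif is a literal over {A,C,G,T}, so any
    window containing N fails the comparison.
    """
    motif = _check_motif(motif)
    pattern = re.compile("(?=" + re.escape(motif) + ")")
    return np.fromiter(
        (m.start() for m in pattern.finditer(sequence.upper())), dtype=np.int64
    )


@dataclass(frozen=True)
class RestrictionFragment:
    chrom: str
    start: int
    end: int
    index: int
    blind: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


class RestrictionFragmentMap:
    """Ordered fragments tiling one contig exactly.

    Stored as boundary arrays: fragment ``k`` spans ``[starts[k], ends[k])``
    with ``ends[k] == starts[k+1]``, ``starts[0] == 0`` and
    ``ends[-1] == contig length``.
    """

    def __init__(
        self,
        chrom: str,
        starts: Sequence[int],
        ends: Sequence[int],
        first_cutter: str,
        second_cutter: str | None = None,
        blind: Sequence[bool] | None = None,
    ) -> None:
        self.chrom = chrom
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.first_cutter = first_cutter
        self.second_cutter = second_cutter
        if blind is None:
            self.blind = np.zeros(len(self.starts), dtype=bool)
        else:
            self.blind = np.asarray(blind, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        if len(self.starts) != len(self.ends) or len(self.starts) != len(self.blind):
            raise InconsistencyError("fragment array lengths disagree")
        if len(self.starts) == 0:
            return
        if np.any(self.starts >= self.ends):
            raise InconsistencyError("zero or negative length fragment")
        if self.starts[0] != 0:
            raise InconsistencyError("first fragment must start at 0")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise InconsistencyError("fragments must tile the contig without gaps")

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, index: int) -> RestrictionFragment:
        return RestrictionFragment(
            self.chrom,
            int(self.starts[index]),
            int(self.ends[index]),
            int(index),
            bool(self.blind[index]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RestrictionFragmentMap):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    @property
    def contig_length(self) -> int:
        return int(self.ends[-1]) if len(self) else 0

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def fragment_at(self, position: int) -> int:
        """Index of the fragment whose half-open span contains position."""
        if len(self) == 0 or position < 0 or position >= self.contig_length:
            raise RegulocusError(
                f"position {position} outside contig [0, {self.contig_length})"
            )
        return int(np.searchsorted(self.starts, position, side="right") - 1)

    def overlapping(self, interval: GenomicInterval) -> np.ndarray:
        """Indices of fragments overlapping an interval."""
        if interval.chrom != self.chrom:
            return np.empty(0, dtype=np.int64)
        mask = (self.starts < interval.end) & (self.ends > interval.start)
        return np.flatnonzero(mask)

    def to_bed_rows(self) -> list[tuple]:
        rows = []
        for frag in self:
            name = f"frag{frag.index}" + ("_blind" if frag.blind else "")
            rows.append((frag.chrom, frag.start, frag.end, name))
        return rows


def digest(
    sequence: str, motif: str, chrom: str = "chr1"
) -> RestrictionFragmentMap:
    """Digest a contig at every occurrence of ``motif``.

    Cuts are placed at the 5' start of each occurrence; a cut at position 0
    would produce an empty leading fragment, which is dropped. Overlapping
    occurrences are all honoured (every position is scanned). An empty
    sequence yields an empty map; an empty motif is an error.
    """
    motif = _check_motif(motif)
    sequence = sequence.upper()
    if not set(sequence) <= _DNA_N:
        raise InvalidAlphabetError("sequence contains symbols outside {A,C,G,T,N}")
    if len(sequence) == 0:
        return RestrictionFragmentMap(chrom, [], [], motif)
    cuts = find_motif_positions(sequence, motif)
    boundaries = np.concatenate(([0], cuts, [len(sequence)]))
    boundaries = np.unique(boundaries)  # drops duplicate 0 => empty fragment
    starts = boundaries[:-1]
    ends = boundaries[1:]
    return RestrictionFragmentMap(chrom, starts, ends, motif)


def fragment_map_from_cuts(
    chrom: str, cut_positions: Sequence[int], contig_length: int, motif: str
) -> RestrictionFragmentMap:
    """Build a map directly from known cut positions (no sequence scan)."""
    boundaries = np.unique(
        np.concatenate(
            ([0], np.asarray(cut_positions, dtype=np.int64), [contig_length])
        )
    )
    return RestrictionFragmentMap(chrom, boundaries[:-1], boundaries[1:], motif)


def annotate_blind(
    fmap: RestrictionFragmentMap, sequence: str, secondary_motif: str
) -> RestrictionFragmentMap:
    """Flag fragments lacking any full secondary-motif occurrence inside
    their half-open span. Returns a new map; the input is unchanged."""
    secondary_motif = _check_motif(secondary_motif)
    if len(sequence) != fmap.contig_length:
        raise InconsistencyError(
            f"sequence length {len(sequence)} != contig length {fmap.contig_length}"
        )
    occ = find_motif_positions(sequence, secondary_motif)
    occ_end = occ + len(secondary_motif)
    blind = np.ones(len(fmap), dtype=bool)
    if len(occ):
        # occurrence fully inside fragment k iff starts[k] <= occ and
        # occ_end <= ends[k]; fragments tile, so locate by start position.
        frag_idx = np.searchsorted(fmap.starts, occ, side="right") - 1
        inside = occ_end <= fmap.ends[frag_idx]
        blind[np.unique(frag_idx[inside])] = False
    return RestrictionFragmentMap(
        fmap.chrom,
        fmap.starts,
        fmap.ends,
        fmap.first_cutter,
        secondary_motif,
        blind,
    )


def assign_counts(
    fmap: RestrictionFragmentMap,
    records: Iterable[tuple[str, int, float]] | pd.DataFrame,
) -> np.ndarray:
    """Sum per-position count records onto fragments.

    Each record ``(chrom, position, count)`` is added to the unique fragment
    whose half-open span contains ``position``. Records off the contig (or
    on another chromosome) are rejected with a logged warning; total
    assigned count equals total accepted input count exactly.
    """
    if isinstance(records, pd.DataFrame):
        records = list(
            zip(records.iloc[:, 0], records.iloc[:, 1], records.iloc[:, 2])
        )
    counts = np.zeros(len(fmap), dtype=float)
    n_rejected = 0
    for chrom, position, count in records:
        if chrom != fmap.chrom or position < 0 or position >= fmap.contig_length:
            n_rejected += 1
            logger.warning(
                "rejecting out-of-bounds record %s:%d (count %s)",
                chrom,
                position,
                count,
            )
            continue
        idx = np.searchsorted(fmap.starts, position, side="right") - 1
        counts[idx] += count
    if n_rejected:
        logger.warning("rejected %d out-of-bounds records", n_rejected)
    return counts


def locate_viewpoint(
    fmap: RestrictionFragmentMap, viewpoint: GenomicInterval
) -> int:
    """Index of the unique fragment containing the viewpoint midpoint."""
    if viewpoint.chrom != fmap.chrom:
        raise ViewpointResolutionError(
            f"viewpoint on {viewpoint.chrom}, map on {fmap.chrom}"
        )
    mid = viewpoint.midpoint
    if mid < 0 or mid >= fmap.contig_length:
        raise ViewpointResolutionError(
            f"viewpoint midpoint {mid} outside contig [0, {fmap.contig_length})"
        )
    return fmap.fragment_at(mid)


def resolve_viewpoint_fragment(
    fmap: RestrictionFragmentMap, viewpoint: GenomicInterval
) -> int:
    """Strict resolution: the viewpoint must overlap exactly one fragment."""
    hits = fmap.overlapping(viewpoint)
    if len(hits) != 1:
        raise ViewpointResolutionError(
            f"viewpoint {viewpoint.chrom}:{viewpoint.start}-{viewpoint.end} "
            f"overlaps {len(hits)} fragments (need exactly 1)"
        )
    return int(hits[0])


def fragment_map_from_bed(df: pd.DataFrame, first_cutter: str = "GATC") -> RestrictionFragmentMap:
    """Reconstruct a map from BED4 rows written by ``to_bed_rows``."""
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise InconsistencyError("fragment maps span exactly one contig")
    blind = None
    if "name" in df.columns:
        blind = df["name"].astype(str).str.endswith("_blind").to_numpy()
    return RestrictionFragmentMap(
        str(chroms[0]),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        first_cutter,
        blind=blind,
    )
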