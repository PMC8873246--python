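"""Super-enhancer calling: stitch, rank, hockey-stick cutoff.

Peaks closer than the stitching distance are merged transitively into
stitched enhancers whose signal is the sum of member signals. Stitched
enhancers are ranked by signal and separated into super / typical by the
geometric rule on the unit-scaled rank-vs-signal curve: sort ascending,
scale both axes to [0, 1], and take as threshold the signal at the first
index whose forward-difference slope exceeds 1; regions strictly above the
threshold are super-enhancers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateLandscapeWarning, ParameterError
from .intervals import GenomicInterval


@dataclass
class SignalPeak:
    interval: GenomicInterval
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ParameterError(f"peak signal must be >= 0, got {self.signal}")


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    member_peaks: list[SignalPeak]
    signal: float
    rank: int | None = None
    scaled_x: float | None = None
    scaled_y: float | None = None
    is_super: bool = False


def stitch(peaks: list[SignalPeak], distance: int = 12500) -> list[StitchedEnhancer]:
    """Merge peaks whose gap along the sorted order is <= distance
    (transitive closure; overlapping peaks always merge). Signal is summed,
    so total signal is conserved exactly."""
    if distance < 0:
        raise ParameterError(f"stitch distance must be >= 0, got {distance}")
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    clusters: list[list[SignalPeak]] = [[ordered[0]]]
    for peak in ordered[1:]:
        last = clusters[-1][-1]
        cluster_end = max(p.interval.end for p in clusters[-1])
        same_chrom = peak.interval.chrom == last.interval.chrom
        if same_chrom and peak.interval.start - cluster_end <= distance:
            clusters[-1].append(peak)
        else:
            clusters.append([peak])
    stitched = []
    for members in clusters:
        start = min(p.interval.start for p in members)
        end = max(p.interval.end for p in members)
        stitched.append(
            StitchedEnhancer(
                interval=GenomicInterval(members[0].interval.chrom, start, end),
                member_peaks=members,
                signal=float(sum(p.signal for p in members)),
            )
        )
    return stitched


def hockey_stick_cutoff(stitched: list[StitchedEnhancer]) -> float | None:
    """Assign scaled coordinates and is_super flags; return the signal
    threshold (None when the landscape is degenerate).

    Geometry: signals sorted ascending; x = rank index scaled to [0, 1];
    y = min-max scaled signal; cutoff = first index whose forward slope
    exceeds 1; threshold = the unscaled signal there; super iff signal >
    threshold. Invariant to uniform rescaling of all signals.
    """
    n = len(stitched)
    if n < 3:
        raise ParameterError(f"need >= 3 stitched enhancers, got {n}")
    order = sorted(range(n), key=lambda i: stitched[i].signal)
    signals = np.array([stitched[i].signal for i in order], dtype=float)
    lo, hi = signals[0], signals[-1]
    if hi == lo:
        warnings.warn(
            "all stitched signals equal; no hockey-stick cutoff exists, "
            "calling zero super-enhancers",
            DegenerateLandscapeWarning,
            stacklevel=2,
        )
        for enhancer in stitched:
            enhancer.is_super = False
        return None
    x = np.arange(n, dtype=float) / (n - 1)
    y = (signals - lo) / (hi - lo)
    for pos, idx in enumerate(order):
        stitched[idx].scaled_x = float(x[pos])
        stitched[idx].scaled_y = float(y[pos])
    slopes = np.diff(y) / np.diff(x)
    crossing = np.flatnonzero(slopes > 1.0)
    if len(crossing) == 0:
        # exactly linear curve: mean slope is 1 and none exceed it
        warnings.warn(
            "rank curve is exactly linear; no slope exceeds 1, "
            "calling zero super-enhancers",
            DegenerateLandscapeWarning,
            stacklevel=2,
        )
        for enhancer in stitched:
            enhancer.is_super = False
        return None
    threshold = float(signals[crossing[0]])
    for enhancer in stitched:
        enhancer.is_super = enhancer.signal > threshold
    return threshold


def rank_enhancers(stitched: list[StitchedEnhancer]) -> list[StitchedEnhancer]:
    """Rank 1 = highest signal; ties broken by earlier genomic coordinate."""
    ordered = sorted(
        stitched,
        key=lambda e: (-e.signal, e.interval.chrom, e.interval.start),
    )
    for rank, enhancer in enumerate(ordered, start=1):
        enhancer.rank = rank
    return ordered


def call_superenhancers(
    peaks: list[SignalPeak],
    distance: int = 12500,
    exclude_regions: list[GenomicInterval] | None = None,
    bed_path: str | None = None,
    tsv_path: str | None = None,
) -> pd.DataFrame:
    """stitch -> cutoff -> rank; returns the ranked table and optionally
    writes BED6 (name SE/TE, score = signal) and a TSV."""
    if exclude_regions:
        peaks = [
            p
            for p in peaks
            if not any(p.interval.overlaps(region) for region in exclude_regions)
        ]
    stitched = stitch(peaks, distance=distance)
    hockey_stick_cutoff(stitched)
    ordered = rank_enhancers(stitched)
    table = pd.DataFrame(
        {
            "chrom": [e.interval.chrom for e in ordered],
            "start": [e.interval.start for e in ordered],
            "end": [e.interval.end for e in ordered],
            "rank": [e.rank for e in ordered],
            "signal": [e.signal for e in ordered],
            "n_peaks": [len(e.member_peaks) for e in ordered],
            "is_super": [e.is_super for e in ordered],
        }
    )
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if bed_path is not None:
        from .genomeio import write_bed

        rows = [
            (
                e.interval.chrom,
                e.interval.start,
                e.interval.end,
                ("SE" if e.is_super else "TE") + f"_rank{e.rank}",
                e.signal,
                ".",
            )
            for e in ordered
        ]
        write_bed(bed_path, rows)
    return table
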