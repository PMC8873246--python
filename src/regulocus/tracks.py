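"""Viewpoint contact-profile processing.

Raw per-fragment counts are turned into display/test-ready tracks in a
fixed order: raw -> masked (viewpoint exclusion) -> normalized (single
multiplicative factor equalizing summed signal over a reference region)
-> smoothed (running mean in fragment-index space). The stage field
enforces the order; out-of-order calls are rejected. Masked fragments
carry NaN, never zero, and are excluded from every computation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateProfileError,
    InconsistencyError,
    ParameterError,
    PipelineOrderError,
)
from .fragmap import RestrictionFragmentMap, locate_viewpoint
from .intervals import GenomicInterval

STAGE_RAW = "raw"
STAGE_MASKED = "masked"
STAGE_NORMALIZED = "normalized"
STAGE_SMOOTHED = "smoothed"
_STAGE_ORDER = (STAGE_RAW, STAGE_MASKED, STAGE_NORMALIZED, STAGE_SMOOTHED)


@dataclass(frozen=True)
class FourCProfile:
    """Per-fragment signal for one viewpoint in one condition."""

    fragmap: RestrictionFragmentMap
    viewpoint: GenomicInterval
    viewpoint_index: int
    condition: str
    values: np.ndarray
    mask: np.ndarray  # True = excluded; values[mask] are NaN
    stage: str = STAGE_RAW

    def __post_init__(self) -> None:
        if len(self.values) != len(self.fragmap):
            raise InconsistencyError(
                f"values length {len(self.values)} != fragment count "
                f"{len(self.fragmap)}"
            )
        if len(self.mask) != len(self.values):
            raise InconsistencyError("mask length != values length")
        if self.stage not in _STAGE_ORDER:
            raise ParameterError(f"unknown stage {self.stage!r}")
        unmasked = self.values[~self.mask]
        if self.stage in (STAGE_RAW, STAGE_MASKED, STAGE_NORMALIZED) and np.any(
            unmasked < 0
        ):
            raise ParameterError(f"negative values at stage {self.stage!r}")

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def same_map(self, other: "FourCProfile") -> bool:
        return self.fragmap == other.fragmap


def make_raw_profile(
    fmap: RestrictionFragmentMap,
    viewpoint: GenomicInterval,
    counts: Sequence[float],
    condition: str,
) -> FourCProfile:
    values = np.asarray(counts, dtype=float).copy()
    return FourCProfile(
        fragmap=fmap,
        viewpoint=viewpoint,
        viewpoint_index=locate_viewpoint(fmap, viewpoint),
        condition=condition,
        values=values,
        mask=np.zeros(len(values), dtype=bool),
        stage=STAGE_RAW,
    )


def _require_stage(profile: FourCProfile, allowed: tuple[str, ...], op: str) -> None:
    if profile.stage not in allowed:
        raise PipelineOrderError(
            f"{op} requires stage in {allowed}, got {profile.stage!r}"
        )


def mask_viewpoint(profile: FourCProfile, margin_bp: int = 2000) -> FourCProfile:
    """Mask the viewpoint fragment and every fragment overlapping the
    viewpoint fragment's span widened by ``margin_bp`` on both sides.
    Idempotent: masking a masked profile with the same margin is a no-op."""
    if margin_bp < 0:
        raise ParameterError(f"margin must be >= 0, got {margin_bp}")
    _require_stage(profile, (STAGE_RAW, STAGE_MASKED), "mask_viewpoint")
    vp = profile.fragmap[profile.viewpoint_index]
    lo = vp.start - margin_bp
    hi = vp.end + margin_bp
    fmap = profile.fragmap
    masked = (fmap.starts < hi) & (fmap.ends > lo)
    mask = profile.mask | masked
    mask[profile.viewpoint_index] = True
    values = profile.values.copy()
    values[mask] = np.nan
    return replace(profile, values=values, mask=mask, stage=STAGE_MASKED)


def reference_membership(
    fmap: RestrictionFragmentMap, reference: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean membership: fragment midpoint inside any reference interval."""
    if not reference:
        raise ParameterError("reference region must contain at least one interval")
    mids = fmap.midpoints
    member = np.zeros(len(fmap), dtype=bool)
    for interval in reference:
        if interval.chrom != fmap.chrom:
            continue
        member |= (mids >= interval.start) & (mids < interval.end)
    return member


def normalize_to_region(
    profile: FourCProfile,
    reference: Sequence[GenomicInterval],
    scale: float = 1e6,
) -> FourCProfile:
    """Multiply all unmasked values by one factor so that the summed signal
    over reference-region fragments (midpoint rule) equals ``scale``."""
    _require_stage(profile, (STAGE_MASKED,), "normalize_to_region")
    if scale <= 0:
        raise ParameterError(f"scale must be > 0, got {scale}")
    member = reference_membership(profile.fragmap, reference)
    usable = member & ~profile.mask
    denom = float(np.sum(profile.values[usable])) if usable.any() else 0.0
    if denom <= 0:
        raise DegenerateProfileError(
            "no unmasked signal in the normalization reference region"
        )
    values = profile.values * (scale / denom)
    return replace(profile, values=values, stage=STAGE_NORMALIZED)


def running_mean(profile: FourCProfile, window: int = 11) -> FourCProfile:
    """Smooth by a running mean over fragment indices.

    Each unmasked value becomes the mean of the unmasked values in the
    window centred on it; at contig edges the window shrinks symmetrically
    to the available fragments. Masked fragments stay masked and never
    contribute to a neighbour's mean.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    _require_stage(profile, (STAGE_NORMALIZED,), "running_mean")
    n = len(profile.values)
    half = window // 2
    values = profile.values.copy()
    src = profile.values
    mask = profile.mask
    for i in range(n):
        if mask[i]:
            continue
        h = min(half, i, n - 1 - i)
        window_vals = src[i - h : i + h + 1]
        window_mask = mask[i - h : i + h + 1]
        values[i] = window_vals[~window_mask].mean()
    return replace(profile, values=values, stage=STAGE_SMOOTHED)


def profile_to_bedgraph(profile: FourCProfile, path: str) -> None:
    """Write a profile as bedGraph; masked fragments are omitted so the
    reader can reconstruct the mask from the fragment map."""
    from .genomeio import write_bedgraph

    keep = ~profile.mask
    fmap = profile.fragmap
    write_bedgraph(
        path, fmap.chrom, fmap.starts[keep], fmap.ends[keep], profile.values[keep]
    )


def profile_from_bedgraph(
    track: "np.ndarray | object",
    fmap: RestrictionFragmentMap,
    viewpoint: GenomicInterval,
    condition: str,
    stage: str = STAGE_NORMALIZED,
) -> FourCProfile:
    """Rebuild a profile from a bedGraph DataFrame (chrom/start/end/value)
    written by :func:`profile_to_bedgraph`. Lines must coincide with
    fragments of ``fmap``; fragments without a line are masked."""
    values = np.full(len(fmap), np.nan)
    mask = np.ones(len(fmap), dtype=bool)
    starts = fmap.starts
    for row in track.itertuples():
        if row.chrom != fmap.chrom:
            raise InconsistencyError(
                f"track line on {row.chrom!r} but fragment map on {fmap.chrom!r}"
            )
        idx = int(np.searchsorted(starts, row.start))
        if (
            idx >= len(fmap)
            or fmap.starts[idx] != row.start
            or fmap.ends[idx] != row.end
        ):
            raise InconsistencyError(
                f"track interval [{row.start}, {row.end}) does not match any "
                "fragment; track and fragment map disagree"
            )
        values[idx] = row.value
        mask[idx] = False
    return FourCProfile(
        fragmap=fmap,
        viewpoint=viewpoint,
        viewpoint_index=locate_viewpoint(fmap, viewpoint),
        condition=condition,
        values=values,
        mask=mask,
        stage=stage,
    )


def ratio_track(
    profile_a: FourCProfile,
    profile_b: FourCProfile,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-fragment log2((a + eps)/(b + eps)) on fragments unmasked in both
    profiles; NaN elsewhere. Both inputs must be smoothed tracks on the
    same fragment map."""
    if pseudocount <= 0:
        raise ParameterError(f"pseudocount must be > 0, got {pseudocount}")
    _require_stage(profile_a, (STAGE_SMOOTHED,), "ratio_track")
    _require_stage(profile_b, (STAGE_SMOOTHED,), "ratio_track")
    if not profile_a.same_map(profile_b):
        raise InconsistencyError("ratio_track requires identical fragment maps")
    both = ~(profile_a.mask | profile_b.mask)
    out = np.full(len(profile_a.values), np.nan)
    out[both] = np.log2(
        (profile_a.values[both] + pseudocount)
        / (profile_b.values[both] + pseudocount)
    )
    return out
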