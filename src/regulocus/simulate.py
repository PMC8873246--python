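"""Synthetic locus generator.

Produces every input the downstream stages consume, with known ground
truth: a single-contig genome whose first-cutter motif occurrences are
exactly the planted ones (background sequence is rejection-resampled until
no accidental occurrence remains), viewpoint contact counts with power-law
distance decay, negative-binomial overdispersion and a plantable loop
enrichment over the enhancer region in one condition, a peak-signal
landscape with one heavy 7-peak stitched cluster, and a nucleus x promoter
count matrix drawn from a mixture of fiber-type classes with QC covariates.

All draws go through one ``numpy.random.Generator``; a fixed seed gives
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidAlphabetError
from .fragmap import (
    RestrictionFragmentMap,
    find_motif_positions,
    fragment_map_from_cuts,
    resolve_viewpoint_fragment,
)
from .intervals import GenomicInterval
from .nucleus import QC_METRICS, QcThresholds
from .se_rank import SignalPeak
from .tracks import FourCProfile, STAGE_RAW
from .fragmap import locate_viewpoint

CHROM = "chrS"
_DNA = "ACGT"

# QC rule names paired with draw ranges: (passing low, passing high),
# (violating low, violating high). Violating draws are strictly outside
# the kept region so strict thresholds always reject them.
_QC_PASS = {
    "peak_region_fragments": (5000, 50000),
    "pct_reads_in_peaks": (30.0, 80.0),
    "blacklist_ratio": (0.0, 0.02),
    "nucleosome_signal": (0.2, 5.0),
    "tss_enrichment": (3.0, 12.0),
}
_QC_FAIL = [
    ("peak_region_fragments", (100, 3000)),  # includes boundary 3000 (strict >)
    ("peak_region_fragments", (100001, 200000)),
    ("pct_reads_in_peaks", (0.0, 15.0)),
    ("blacklist_ratio", (0.03, 0.2)),
    ("nucleosome_signal", (10.0, 20.0)),
    ("tss_enrichment", (0.0, 2.0)),
]


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 1_200_000
    cutter_motif: str = "GATC"
    secondary_motif: str = "CATG"
    motif_spacing_mean: float = 500.0
    n_genes: int = 4
    tad_boundaries: tuple[int, ...] = (200_000, 450_000, 700_000, 950_000)
    se_interval: GenomicInterval = field(
        default_factory=lambda: GenomicInterval(CHROM, 500_000, 542_000)
    )
    read_depth: int = 100_000
    decay_exponent: float = 1.0
    decay_offset: float = 1000.0
    loop_enrichment: float = 1.0
    loop_condition: str = "A"
    dispersion: float = 10.0
    n_nuclei_per_class: tuple[int, ...] = (64, 59, 249, 495)
    accessibility_effect: float = 10.0
    qc_fail_fraction: float = 0.1
    nucleus_depth_mean: float = 200.0
    n_background_peaks: int = 40
    background_signal_shape: float = 0.05
    background_signal_scale: float = 60.0
    peak_width: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be > 0")
        for motif in (self.cutter_motif, self.secondary_motif):
            if not motif or not set(motif.upper()) <= set(_DNA):
                raise InvalidAlphabetError(
                    f"motif {motif!r} must be a non-empty string over ACGT"
                )
        if self.decay_exponent <= 0:
            raise ConfigError("decay_exponent must be > 0")
        if self.decay_offset <= 0:
            raise ConfigError("decay_offset must be > 0")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.loop_enrichment < 0:
            raise ConfigError("loop_enrichment must be >= 0")
        if self.accessibility_effect < 1:
            raise ConfigError("accessibility_effect must be >= 1")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ConfigError("qc_fail_fraction must be in [0, 1)")
        bounds = self.tad_boundaries
        if list(bounds) != sorted(set(bounds)):
            raise ConfigError("tad_boundaries must be strictly increasing")
        if bounds and (bounds[0] <= 0 or bounds[-1] >= self.genome_length):
            raise ConfigError("tad_boundaries must lie strictly inside the genome")
        tads = self.tads()
        containing = [t for t in tads if t.contains_interval(self.se_interval)]
        if len(containing) != 1:
            raise ConfigError("se_interval must lie inside exactly one TAD")

    def tads(self) -> list[GenomicInterval]:
        edges = [0, *self.tad_boundaries, self.genome_length]
        return [
            GenomicInterval(self.se_interval.chrom, a, b)
            for a, b in zip(edges[:-1], edges[1:])
        ]

    def locus_tad(self) -> GenomicInterval:
        return next(
            t for t in self.tads() if t.contains_interval(self.se_interval)
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class LocusModel:
    """Annotation bundle for the synthetic locus."""

    chrom: str
    genome_length: int
    tads: tuple[GenomicInterval, ...]
    tad_region: GenomicInterval  # the TAD containing the enhancer region
    se_region: GenomicInterval
    reference_region: tuple[GenomicInterval, ...]  # normalization denominator
    genes: tuple[tuple[str, GenomicInterval], ...]
    promoters: tuple[tuple[str, GenomicInterval], ...]
    viewpoints: tuple[tuple[str, GenomicInterval], ...]

    def gene_names(self) -> list[str]:
        return [name for name, _ in self.genes]

    def viewpoint_for(self, gene: str) -> GenomicInterval:
        for name, interval in self.viewpoints:
            if name == gene:
                return interval
        raise KeyError(gene)


def make_locus(config: SimConfig) -> LocusModel:
    """Place a clustered gene array downstream of the enhancer region,
    inside the same TAD; promoters and 1-bp viewpoints at gene starts."""
    tad = config.locus_tad()
    gene_length = 8_000
    gene_spacing = 30_000
    first_start = config.se_interval.end + 20_000
    genes = []
    promoters = []
    viewpoints = []
    for i in range(config.n_genes):
        start = first_start + i * gene_spacing
        end = start + gene_length
        if end > tad.end:
            raise ConfigError(
                f"gene {i + 1} does not fit inside the locus TAD; "
                "enlarge the TAD or reduce n_genes"
            )
        name = f"gene{i + 1}"
        genes.append((name, GenomicInterval(config.se_interval.chrom, start, end)))
        promoters.append(
            (name, GenomicInterval(config.se_interval.chrom, start - 2000, start + 500))
        )
        viewpoints.append(
            (name, GenomicInterval(config.se_interval.chrom, start, start + 1))
        )
    return LocusModel(
        chrom=config.se_interval.chrom,
        genome_length=config.genome_length,
        tads=tuple(config.tads()),
        tad_region=tad,
        se_region=config.se_interval,
        reference_region=tuple(config.tads()),
        genes=tuple(genes),
        promoters=tuple(promoters),
        viewpoints=tuple(viewpoints),
    )


def plant_motif_positions(
    config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Cut-site start positions with mean spacing ~ motif_spacing_mean and
    a minimum gap that keeps planted motifs from overlapping."""
    motif_len = len(config.cutter_motif)
    min_gap = motif_len + 1
    limit = config.genome_length - motif_len
    positions = []
    pos = 0
    while True:
        gap = max(min_gap, int(round(rng.exponential(config.motif_spacing_mean))))
        pos += gap
        if pos > limit:
            break
        positions.append(pos)
    return np.asarray(positions, dtype=np.int64)


def make_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[str, np.ndarray]:
    """Synthesize one contig whose first-cutter occurrences are exactly the
    planted positions.

    Background bases at accidental occurrences are re-randomized until a
    full overlapping scan of the emitted sequence finds only the planted
    set; planted bases themselves are never rewritten.
    """
    rng = rng if rng is not None else config.rng()
    motif = config.cutter_motif.upper()
    positions = plant_motif_positions(config, rng)
    length = config.genome_length
    base_codes = rng.integers(0, 4, size=length)
    bases = np.frombuffer(_DNA.encode(), dtype=np.uint8)[base_codes].copy()
    planted_mask = np.zeros(length, dtype=bool)
    motif_bytes = np.frombuffer(motif.encode(), dtype=np.uint8)
    for pos in positions:
        bases[pos : pos + len(motif)] = motif_bytes
        planted_mask[pos : pos + len(motif)] = True
    planted_set = set(int(p) for p in positions)
    for _ in range(10_000):
        seq = bases.tobytes().decode()
        found = find_motif_positions(seq, motif)
        accidental = [p for p in found if int(p) not in planted_set]
        if not accidental:
            break
        for pos in accidental:
            window = np.arange(pos, pos + len(motif))
            rewrite = window[~planted_mask[window]]
            bases[rewrite] = np.frombuffer(_DNA.encode(), dtype=np.uint8)[
                rng.integers(0, 4, size=len(rewrite))
            ]
    else:  # pragma: no cover - astronomically unlikely for sane motifs
        raise ConfigError("could not purge accidental motif occurrences")
    return bases.tobytes().decode(), positions


def fragment_map_for(config: SimConfig, positions: np.ndarray) -> RestrictionFragmentMap:
    """Fragment map implied by planted cut positions (no sequence needed)."""
    return fragment_map_from_cuts(
        config.se_interval.chrom, positions, config.genome_length, config.cutter_motif
    )


def decay_weights(
    config: SimConfig,
    fmap: RestrictionFragmentMap,
    viewpoint: GenomicInterval,
    condition: str,
) -> np.ndarray:
    """Unnormalized contact weights w_i = (|d_i| + d0)^(-alpha) times
    (1 + beta) on enhancer-region fragments in the loop-active condition;
    the viewpoint fragment carries weight 0."""
    vp_index = resolve_viewpoint_fragment(fmap, viewpoint)
    mids = fmap.midpoints.astype(float)
    distance = np.abs(mids - mids[vp_index])
    weights = (distance + config.decay_offset) ** (-config.decay_exponent)
    if condition == config.loop_condition and config.loop_enrichment > 0:
        in_se = (fmap.midpoints >= config.se_interval.start) & (
            fmap.midpoints < config.se_interval.end
        )
        weights[in_se] *= 1.0 + config.loop_enrichment
    weights[vp_index] = 0.0
    return weights


def expected_4c_lambda(
    config: SimConfig,
    fmap: RestrictionFragmentMap,
    viewpoint: GenomicInterval,
    condition: str,
) -> np.ndarray:
    """Per-fragment negative-binomial means; sums to read_depth exactly."""
    if config.read_depth <= 0:
        raise ConfigError("read_depth must be > 0")
    weights = decay_weights(config, fmap, viewpoint, condition)
    return config.read_depth * weights / weights.sum()


def simulate_4c(
    config: SimConfig,
    fmap: RestrictionFragmentMap,
    viewpoint: GenomicInterval,
    condition: str,
    rng: np.random.Generator | None = None,
) -> FourCProfile:
    """Raw negative-binomial counts (mean lambda_i, size theta) per fragment."""
    rng = rng if rng is not None else config.rng()
    lam = expected_4c_lambda(config, fmap, viewpoint, condition)
    theta = config.dispersion
    counts = np.zeros(len(lam), dtype=float)
    positive = lam > 0
    p = theta / (theta + lam[positive])
    counts[positive] = rng.negative_binomial(theta, p).astype(float)
    return FourCProfile(
        fragmap=fmap,
        viewpoint=viewpoint,
        viewpoint_index=locate_viewpoint(fmap, viewpoint),
        condition=condition,
        values=counts,
        mask=np.zeros(len(counts), dtype=bool),
        stage=STAGE_RAW,
    )


def simulate_enhancer_signal(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[SignalPeak], np.ndarray]:
    """Background peaks with i.i.d. gamma signal plus one planted 7-peak
    cluster inside the enhancer region.

    Returns (peaks sorted by coordinate, boolean planted flags). Planted
    peaks all carry signal >= 10x the realized background mean; in-cluster
    gaps are < 12,500 bp. Background peaks keep a stitching distance away
    from the enhancer region so the planted cluster stitches alone.
    """
    rng = rng if rng is not None else config.rng()
    n_planted = 7
    width = config.peak_width
    se = config.se_interval
    footprint = n_planted * width + (n_planted - 1)
    if se.length < footprint:
        raise ConfigError(
            f"se_interval length {se.length} shorter than the {n_planted}-peak "
            f"cluster footprint {footprint}"
        )
    gap = min(12_000, (se.length - n_planted * width) // max(n_planted - 1, 1))
    cluster_span = n_planted * width + (n_planted - 1) * gap
    offset = se.start + (se.length - cluster_span) // 2
    planted_intervals = [
        GenomicInterval(se.chrom, offset + i * (width + gap), offset + i * (width + gap) + width)
        for i in range(n_planted)
    ]

    n_bg = max(int(config.n_background_peaks), 30)
    stitch_guard = 12_500 + width
    exclusion = (se.start - stitch_guard, se.end + stitch_guard)
    starts: list[int] = []
    attempts = 0
    while len(starts) < n_bg and attempts < 100_000:
        attempts += 1
        start = int(rng.integers(0, config.genome_length - width))
        if exclusion[0] - width < start < exclusion[1]:
            continue
        if any(abs(start - s) < width for s in starts):
            continue
        starts.append(start)
    if len(starts) < n_bg:  # pragma: no cover - genome too crowded
        raise ConfigError("could not place background peaks without overlap")
    starts.sort()
    bg_signal = rng.gamma(
        config.background_signal_shape, config.background_signal_scale, size=n_bg
    )
    planted_signal = 10.0 * float(bg_signal.mean()) * (1.0 + rng.uniform(0, 0.5, n_planted))

    peaks: list[tuple[SignalPeak, bool]] = [
        (SignalPeak(GenomicInterval(se.chrom, s, s + width), float(v)), False)
        for s, v in zip(starts, bg_signal)
    ]
    peaks += [
        (SignalPeak(iv, float(v)), True)
        for iv, v in zip(planted_intervals, planted_signal)
    ]
    peaks.sort(key=lambda item: item[0].interval.start)
    flags = np.array([planted for _, planted in peaks], dtype=bool)
    return [p for p, _ in peaks], flags


def simulate_nucleus_matrix(
    config: SimConfig,
    locus: LocusModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Nucleus table: barcode, true class, six QC metrics, and per-gene
    promoter fragment counts.

    Each nucleus draws its promoter counts from a multinomial whose mass on
    the nucleus's own class promoter is ``accessibility_effect``-fold the
    mass on any other promoter. A ``qc_fail_fraction`` share of nuclei is
    made to violate exactly one randomly chosen QC rule (strictly), so the
    expected fraction failing QC equals that parameter.
    """
    if config.n_genes < 2:
        raise ConfigError("need n_genes >= 2 for classification")
    if any(n < 1 for n in config.n_nuclei_per_class):
        raise ConfigError("per-class sizes must be >= 1")
    if len(config.n_nuclei_per_class) != config.n_genes:
        raise ConfigError("n_nuclei_per_class length must equal n_genes")
    rng = rng if rng is not None else config.rng()
    locus = locus if locus is not None else make_locus(config)
    genes = locus.gene_names()
    rows = []
    barcode = 0
    for gene, size in zip(genes, config.n_nuclei_per_class):
        probs = np.ones(config.n_genes)
        probs[genes.index(gene)] = config.accessibility_effect
        probs /= probs.sum()
        for _ in range(size):
            depth = max(int(rng.poisson(config.nucleus_depth_mean)), 1)
            counts = rng.multinomial(depth, probs)
            metrics = {
                name: float(rng.uniform(lo, hi)) for name, (lo, hi) in _QC_PASS.items()
            }
            metrics["peak_region_fragments"] = float(
                rng.integers(*_QC_PASS["peak_region_fragments"])
            )
            if rng.random() < config.qc_fail_fraction:
                name, (lo, hi) = _QC_FAIL[rng.integers(0, len(_QC_FAIL))]
                if name == "peak_region_fragments":
                    metrics[name] = float(rng.integers(int(lo), int(hi) + 1))
                else:
                    metrics[name] = float(rng.uniform(lo, hi))
            row = {"barcode": f"nucleus{barcode:05d}", "true_label": gene}
            row.update({m: metrics[m] for m in QC_METRICS})
            row.update({g: int(c) for g, c in zip(genes, counts)})
            rows.append(row)
            barcode += 1
    return pd.DataFrame(rows)


def qc_pass_mask(table: pd.DataFrame, thresholds: QcThresholds | None = None) -> np.ndarray:
    """Convenience: boolean QC outcome for a simulated nucleus table."""
    from .nucleus import qc_filter

    kept, _ = qc_filter(table, thresholds)
    return table.index.isin(kept.index)
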