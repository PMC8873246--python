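"""snATAC nucleus QC filtering and promoter-accessibility classification.

QC keeps a nucleus only when all six strict inequalities on the standard
per-nucleus metrics hold. Surviving nuclei are assigned a fiber-type label
by the dominance of accessibility at one gene's promoter windows: the
top-scoring gene wins when its score is at least ``margin`` times the
runner-up, otherwise the nucleus is called hybrid (or unassigned when it
has no window signal at all).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError

QC_METRICS = (
    "peak_region_fragments",
    "pct_reads_in_peaks",
    "blacklist_ratio",
    "nucleosome_signal",
    "tss_enrichment",
)

LABEL_HYBRID = "hybrid"
LABEL_UNASSIGNED = "unassigned"
LABEL_FILTERED = "filtered"


@dataclass(frozen=True)
class QcThresholds:
    """All comparisons are strict, mirroring the >/< convention."""

    min_peak_fragments: float = 3000
    max_peak_fragments: float = 100000
    min_pct_in_peaks: float = 15
    max_blacklist_ratio: float = 0.025
    max_nucleosome_signal: float = 10
    min_tss_enrichment: float = 2

    def __post_init__(self) -> None:
        if self.min_peak_fragments >= self.max_peak_fragments:
            raise ConfigError("min_peak_fragments must be < max_peak_fragments")

    def rules(self) -> list[tuple[str, str, str, float]]:
        """(rule name, metric column, operator, threshold) for each rule."""
        return [
            ("peak_fragments_low", "peak_region_fragments", ">", self.min_peak_fragments),
            ("peak_fragments_high", "peak_region_fragments", "<", self.max_peak_fragments),
            ("pct_in_peaks", "pct_reads_in_peaks", ">", self.min_pct_in_peaks),
            ("blacklist", "blacklist_ratio", "<", self.max_blacklist_ratio),
            ("nucleosome", "nucleosome_signal", "<", self.max_nucleosome_signal),
            ("tss_enrichment", "tss_enrichment", ">", self.min_tss_enrichment),
        ]


def qc_filter(
    records: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[pd.DataFrame, Counter]:
    """Keep records passing all six strict QC rules.

    Returns the kept rows (original order preserved) and a tally counting,
    independently per rule, how many records violated it; records with a
    missing metric are rejected under the key 'missing-metric'.
    """
    thresholds = thresholds or QcThresholds()
    missing_cols = [c for c in QC_METRICS if c not in records.columns]
    if missing_cols:
        raise ParameterError(f"metrics table lacks columns: {missing_cols}")
    tally: Counter = Counter()
    n = len(records)
    keep = np.ones(n, dtype=bool)
    metric_missing = records[list(QC_METRICS)].isna().any(axis=1).to_numpy()
    if metric_missing.any():
        tally["missing-metric"] = int(metric_missing.sum())
        keep &= ~metric_missing
    for rule_name, column, op, threshold in thresholds.rules():
        values = records[column].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            ok = values > threshold if op == ">" else values < threshold
        violated = ~ok & ~metric_missing
        if violated.any():
            tally[rule_name] = int(violated.sum())
        keep &= ok | metric_missing  # missing already rejected once
    keep &= ~metric_missing
    return records.loc[keep], tally


def score_promoters(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-gene accessibility scores: window counts over total window
    counts, row-wise. Rows with zero total get all-zero scores (they will
    be labelled unassigned downstream)."""
    frame = pd.DataFrame(counts).astype(float)
    if (frame.to_numpy() < 0).any():
        raise ParameterError("promoter counts must be >= 0")
    totals = frame.sum(axis=1)
    scores = frame.div(totals.where(totals > 0, 1.0), axis=0)
    scores[totals == 0] = 0.0
    return scores


def classify_fiber_type(scores, margin: float = 2.0) -> str:
    """Label one nucleus from its per-gene scores.

    argmax gene when top >= margin * second and top > 0; 'hybrid' when the
    top score is positive but not dominant; 'unassigned' when all zero.
    Invariant to uniform rescaling of the scores.
    """
    if margin < 1:
        raise ParameterError(f"margin must be >= 1, got {margin}")
    series = pd.Series(scores, dtype=float)
    if (series < 0).any():
        raise ParameterError("scores must be >= 0")
    top_gene = series.idxmax()
    top = series[top_gene]
    if top <= 0:
        return LABEL_UNASSIGNED
    second = series.drop(top_gene).max() if len(series) > 1 else 0.0
    if top >= margin * second:
        return str(top_gene)
    return LABEL_HYBRID


def aggregate_features_to_genes(
    matrix: pd.DataFrame, promoters: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Collapse a nucleus x feature matrix to nucleus x gene counts.

    With ``promoters`` (BED-like frame: chrom, start, end, name=gene), a
    feature column named ``chrom:start-end`` contributes to a gene when its
    midpoint lies in one of that gene's windows. Without it, columns are
    taken to be gene names already.
    """
    if promoters is None:
        return matrix.copy()
    from .intervals import parse_region

    gene_for_column: dict[str, str] = {}
    for column in matrix.columns:
        interval = parse_region(str(column), coordinate_system="zero_half_open")
        mid = interval.midpoint
        for row in promoters.itertuples():
            if (
                str(row.chrom) == interval.chrom
                and int(row.start) <= mid < int(row.end)
            ):
                gene_for_column[column] = str(row.name)
                break
    if not gene_for_column:
        raise ParameterError("no matrix feature maps into any promoter window")
    kept = matrix[list(gene_for_column)]
    return kept.T.groupby([gene_for_column[c] for c in kept.columns]).sum().T


def classify_nuclei(
    metrics: pd.DataFrame,
    promoter_counts: pd.DataFrame,
    thresholds: QcThresholds | None = None,
    margin: float = 2.0,
) -> pd.DataFrame:
    """QC filter then promoter-dominance classification of every nucleus.

    Returns one row per input nucleus with per-gene scores and a label;
    QC failures are labelled 'filtered'. Index alignment between the two
    frames is by position when indexes differ, by index otherwise.
    """
    if not metrics.index.equals(promoter_counts.index):
        if len(metrics) != len(promoter_counts):
            raise ParameterError("metrics and matrix row counts differ")
        promoter_counts = promoter_counts.set_axis(metrics.index)
    kept, _tally = qc_filter(metrics, thresholds)
    scores = score_promoters(promoter_counts)
    labels = pd.Series(LABEL_FILTERED, index=metrics.index, dtype=object)
    for idx in kept.index:
        labels[idx] = classify_fiber_type(scores.loc[idx], margin=margin)
    out = scores.add_prefix("score_")
    out.insert(0, "label", labels)
    out.insert(0, "qc_pass", labels != LABEL_FILTERED)
    return out
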