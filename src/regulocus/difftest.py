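"""Differential-contact significance between two conditions.

Per-fragment signs (increased/decreased/tied) are computed on unsmoothed,
reference-normalized profiles; directional fragments are tabulated in a
2x2 table of region (candidate enhancer region vs the remainder of its
containing domain) by direction; association is tested with a G-test of
independence (likelihood-ratio chi-square, df = 1), optionally with the
Williams correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .errors import (
    DegenerateTableError,
    InconsistencyError,
    ParameterError,
    PipelineOrderError,
    RegionError,
)
from .intervals import GenomicInterval
from .tracks import STAGE_NORMALIZED, FourCProfile

INCREASED = np.int8(1)
DECREASED = np.int8(-1)
TIED = np.int8(0)
MASKED = np.int8(-9)


@dataclass(frozen=True)
class SignVector:
    """Per-fragment direction codes comparing condition A vs B."""

    codes: np.ndarray  # int8, values in {INCREASED, DECREASED, TIED, MASKED}
    tie_tol: float
    condition_a: str
    condition_b: str

    @property
    def n_increased(self) -> int:
        return int(np.sum(self.codes == INCREASED))

    @property
    def n_decreased(self) -> int:
        return int(np.sum(self.codes == DECREASED))

    @property
    def n_tied(self) -> int:
        return int(np.sum(self.codes == TIED))

    @property
    def n_masked(self) -> int:
        return int(np.sum(self.codes == MASKED))


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray  # 2x2 observed, rows: region / remainder; cols: inc / dec
    expected: np.ndarray
    g: float
    p: float
    df: int = 1
    williams_corrected: bool = False
    fraction_increased: tuple[float, float] = field(default=(np.nan, np.nan))


def classify_signs(
    profile_a: FourCProfile,
    profile_b: FourCProfile,
    tie_tol: float = 0.0,
) -> SignVector:
    """Per-fragment comparison a vs b on normalized (never smoothed) values.

    increased iff a - b > tie_tol; decreased iff b - a > tie_tol; tied
    otherwise; fragments masked in either profile propagate as masked.
    """
    if tie_tol < 0:
        raise ParameterError(f"tie_tol must be >= 0, got {tie_tol}")
    for profile in (profile_a, profile_b):
        if profile.stage != STAGE_NORMALIZED:
            raise PipelineOrderError(
                "classify_signs requires unsmoothed normalized profiles "
                f"(stage 'normalized'), got {profile.stage!r}"
            )
    if not profile_a.same_map(profile_b):
        raise InconsistencyError("profiles are on different fragment maps")
    codes = np.full(len(profile_a.values), TIED, dtype=np.int8)
    diff = profile_a.values - profile_b.values
    codes[diff > tie_tol] = INCREASED
    codes[-diff > tie_tol] = DECREASED
    codes[profile_a.mask | profile_b.mask] = MASKED
    return SignVector(
        codes=codes,
        tie_tol=tie_tol,
        condition_a=profile_a.condition,
        condition_b=profile_b.condition,
    )


def build_table(
    signs: SignVector,
    fragmap,
    se_region: GenomicInterval,
    tad_region: GenomicInterval,
) -> np.ndarray:
    """2x2 observed counts: rows = fragment midpoint in se_region /
    elsewhere in tad_region; columns = increased / decreased. Tied, masked,
    and out-of-domain fragments are excluded."""
    if not tad_region.contains_interval(se_region):
        raise RegionError(
            f"se_region {se_region} not contained in tad_region {tad_region}"
        )
    if len(signs.codes) != len(fragmap):
        raise InconsistencyError("sign vector length != fragment count")
    mids = fragmap.midpoints
    in_se = (mids >= se_region.start) & (mids < se_region.end)
    in_tad = (mids >= tad_region.start) & (mids < tad_region.end)
    if fragmap.chrom != tad_region.chrom:
        in_se[:] = False
        in_tad[:] = False
    inc = signs.codes == INCREASED
    dec = signs.codes == DECREASED
    rest = in_tad & ~in_se
    table = np.array(
        [
            [int(np.sum(inc & in_se)), int(np.sum(dec & in_se))],
            [int(np.sum(inc & rest)), int(np.sum(dec & rest))],
        ],
        dtype=np.int64,
    )
    return table


def g_test(table: np.ndarray, williams: bool = False) -> ContingencyResult:
    """G-test of independence on a 2x2 table.

    G = 2 * sum over cells with O > 0 of O * ln(O / E), with E the usual
    product-of-margins expectation; p is the upper chi-square tail at
    df = 1. Any zero margin raises: the comparison carries no directional
    information and a p-value would be meaningless.
    """
    observed = np.asarray(table, dtype=float)
    if observed.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {observed.shape}")
    if np.any(observed < 0) or np.any(observed != np.floor(observed)):
        raise ParameterError("observed counts must be non-negative integers")
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    total = observed.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError(
            f"zero margin in table {observed.astype(int).tolist()}; "
            "comparison is uninformative"
        )
    expected = np.outer(row, col) / total
    positive = observed > 0
    g = 2.0 * float(
        np.sum(observed[positive] * np.log(observed[positive] / expected[positive]))
    )
    g = max(g, 0.0)  # guard float round-off on proportional tables
    if williams:
        q = 1.0 + (
            (total / row[0] + total / row[1] - 1.0)
            * (total / col[0] + total / col[1] - 1.0)
        ) / (6.0 * total)
        g /= q
    p = float(chi2.sf(g, df=1))
    with np.errstate(invalid="ignore"):
        frac = (
            float(observed[0, 0] / row[0]),
            float(observed[1, 0] / row[1]),
        )
    return ContingencyResult(
        table=observed.astype(np.int64),
        expected=expected,
        g=g,
        p=p,
        df=1,
        williams_corrected=williams,
        fraction_increased=frac,
    )


def run_difftest(
    profile_a: FourCProfile,
    profile_b: FourCProfile,
    se_region: GenomicInterval,
    tad_region: GenomicInterval,
    tie_tol: float = 0.0,
    williams: bool = False,
    report_path: str | None = None,
) -> tuple[ContingencyResult, SignVector]:
    """classify_signs -> build_table -> g_test, with an optional TSV report."""
    signs = classify_signs(profile_a, profile_b, tie_tol=tie_tol)
    table = build_table(signs, profile_a.fragmap, se_region, tad_region)
    result = g_test(table, williams=williams)
    if report_path is not None:
        write_difftest_report(report_path, result, signs, se_region, tad_region)
    return result, signs


def write_difftest_report(
    path: str,
    result: ContingencyResult,
    signs: SignVector,
    se_region: GenomicInterval,
    tad_region: GenomicInterval,
) -> None:
    rows = [
        ("condition_a", signs.condition_a),
        ("condition_b", signs.condition_b),
        ("se_region", f"{se_region.chrom}:{se_region.start}-{se_region.end}"),
        ("tad_region", f"{tad_region.chrom}:{tad_region.start}-{tad_region.end}"),
        ("se_increased", result.table[0, 0]),
        ("se_decreased", result.table[0, 1]),
        ("rest_increased", result.table[1, 0]),
        ("rest_decreased", result.table[1, 1]),
        ("fraction_increased_se", "%.6g" % result.fraction_increased[0]),
        ("fraction_increased_rest", "%.6g" % result.fraction_increased[1]),
        ("G", "%.10g" % result.g),
        ("df", result.df),
        ("p", "%.6g" % result.p),
        ("williams_corrected", str(result.williams_corrected).lower()),
        ("n_tied_excluded", signs.n_tied),
        ("n_masked_excluded", signs.n_masked),
    ]
    with open(path, "w") as handle:
        handle.write("key\tvalue\n")
        for key, value in rows:
            handle.write(f"{key}\t{value}\n")
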