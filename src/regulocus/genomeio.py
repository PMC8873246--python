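"""Readers and writers for the plain-text genomic formats used throughout.

Conventions: BED and bedGraph are 0-based half-open and tab-separated;
writers sort records by (chrom, start) and serialize floats with 6
significant digits; readers of fragment-resolution tracks validate sort
order and non-overlap and cite the offending line number on failure.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import BedFormatError
from .intervals import GenomicInterval

_FLOAT_FMT = "%.6g"


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with Fasta(str(path), rebuild=True) as fasta:
        return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_fasta(
    path: str | os.PathLike, sequences: Mapping[str, str], width: int = 60
) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _fmt(value: object) -> str:
    if isinstance(value, (float, np.floating)):
        return _FLOAT_FMT % value
    return str(value)


def write_bed(path: str | os.PathLike, rows: Iterable[tuple]) -> None:
    """Write BED rows (chrom, start, end, *extra), sorted by (chrom, start)."""
    rows = sorted(rows, key=lambda r: (str(r[0]), int(r[1])))
    with open(path, "w") as handle:
        for row in rows:
            handle.write("\t".join(_fmt(v) for v in row) + "\n")


def read_bed(path: str | os.PathLike, min_fields: int = 3) -> pd.DataFrame:
    """Read a BED file into a DataFrame with at least chrom/start/end."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedFormatError(
                    f"{path}: line {lineno}: expected >= {min_fields} fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end <= start:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            record = {"chrom": fields[0], "start": start, "end": end}
            for name, value in zip(names[3:], fields[3:]):
                record[name] = value
            records.append(record)
    return pd.DataFrame.from_records(records)


def write_bedgraph(
    path: str | os.PathLike,
    chrom: str,
    starts: np.ndarray,
    ends: np.ndarray,
    values: np.ndarray,
) -> None:
    order = np.argsort(starts, kind="stable")
    with open(path, "w") as handle:
        for i in order:
            handle.write(
                f"{chrom}\t{int(starts[i])}\t{int(ends[i])}\t{_FLOAT_FMT % values[i]}\n"
            )


def read_bedgraph(
    path: str | os.PathLike, validate: bool = True
) -> pd.DataFrame:
    """Read a bedGraph file; optionally enforce sorted, non-overlapping lines."""
    records = []
    last_by_chrom: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedFormatError(f"{path}: line {lineno}: malformed line") from exc
            if start < 0 or end <= start:
                raise BedFormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            if validate:
                last_end = last_by_chrom.get(chrom)
                if last_end is not None and start < last_end:
                    raise BedFormatError(
                        f"{path}: line {lineno}: unsorted or overlapping interval"
                    )
                last_by_chrom[chrom] = end
            records.append((chrom, start, end, value))
    return pd.DataFrame(records, columns=["chrom", "start", "end", "value"])


def read_count_records(path: str | os.PathLike) -> list[tuple[str, int, float]]:
    """Read 4-column count TSV/bedGraph (chrom, start, end, count) into
    (chrom, position, count) records keyed by interval midpoint."""
    df = read_bedgraph(path, validate=False)
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    return list(zip(df["chrom"], mid.tolist(), df["value"].tolist()))


def intervals_from_bed(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
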