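"""Interval arithmetic for CNV / LOH calls.

Sizes follow the array-CGH reporting convention in which the span of a
call is ``end - start`` base pairs (coordinates are 1-based and inclusive;
an inclusive ``+1`` convention is available via ``convention="inclusive"``),
floored to whole kilobases; "about N kb" summaries at coarser granularity
floor to the nearest 100 kb.  Gene content is taken from a BED-like gene
table (0-based half-open, converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ValidationError

__all__ = [
    "GenomicInterval",
    "CnvCall",
    "interval_size_kb",
    "floor_to_100kb",
    "genes_in_interval",
    "read_bed",
    "read_calls",
    "size_report",
]


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).strip()
    if not c:
        raise ValidationError("empty chromosome label")
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    assembly: str = "GRCh37"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise ValidationError("positions are 1-based; start must be >= 1")

    def size_bp(self, convention: str = "end_minus_start") -> int:
        if convention == "end_minus_start":
            return self.end - self.start
        if convention == "inclusive":
            return self.end - self.start + 1
        raise ValidationError(f"unknown size convention {convention!r}")


@dataclass(frozen=True)
class CnvCall:
    interval: GenomicInterval
    call_type: str  # LOH | gain | loss
    subject: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.call_type not in ("LOH", "gain", "loss"):
            raise ValidationError(f"unknown call type {self.call_type!r}")


def interval_size_kb(
    iv: GenomicInterval, convention: str = "end_minus_start"
) -> int:
    """Interval size floored to whole kilobases."""
    return iv.size_bp(convention) // 1000


def floor_to_100kb(kb: int) -> int:
    """Coarser "about N kb" rounding: floor to the nearest 100 kb."""
    return (kb // 100) * 100


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED gene table (chrom, start, end, name; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: BED intervals must have start < end")
    return df


def genes_in_interval(iv: GenomicInterval, genes: pd.DataFrame) -> list[str]:
    """Gene symbols whose span intersects the interval.

    The 1-based inclusive interval is converted to half-open
    ``[start-1, end)`` and intersected with the half-open BED spans; an
    abutting gene (starting at ``end``, i.e. base end+1 in 1-based terms)
    is excluded.  Chromosome labels are compared after stripping any
    ``chr`` prefix.
    """
    required = {"chrom", "start", "end", "name"}
    if not required <= set(genes.columns):
        raise ValidationError(
            f"gene table must have columns {sorted(required)}"
        )
    if genes.empty:
        return []
    lo, hi = iv.start - 1, iv.end  # half-open
    chrom = _norm_chrom(iv.chrom)
    mask = (
        genes["chrom"].map(_norm_chrom).eq(chrom)
        & (genes["start"] < hi)
        & (genes["end"] > lo)
    )
    return genes.loc[mask, "name"].tolist()


def read_calls(path: str | Path) -> list[CnvCall]:
    """CNV/LOH calls as TSV with columns subject, type, chrom, start, end."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "type", "chrom", "start", "end"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: calls need columns {sorted(required)}")
    return [
        CnvCall(
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            call_type=str(r.type),
            subject=str(r.subject),
        )
        for r in df.itertuples()
    ]


def size_report(
    calls: Iterable[CnvCall], genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per call: coordinates, floored sizes, and gene content."""
    rows = []
    for call in calls:
        iv = call.interval
        symbols = (
            genes_in_interval(iv, genes) if genes is not None
            else list(call.genes)
        )
        kb = interval_size_kb(iv)
        rows.append(
            {
                "subject": call.subject,
                "call_type": call.call_type,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "size_kb": kb,
                "size_kb_floor100": floor_to_100kb(kb),
                "n_genes": len(symbols),
                "genes": ",".join(symbols),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "call_type", "chrom", "start", "end",
            "size_kb", "size_kb_floor100", "n_genes", "genes",
        ],
    )
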