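"""Core genomic containers shared by every pipeline stage.

All coordinates are 0-based half-open (BED convention). Formats that use
1-based closed coordinates (GFF3) are converted at the reader boundary in
:mod:`capra.io`, so nothing downstream ever sees another convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: Column schema for read tables. ``fragment_length`` is NaN for single-end
#: records (``mate_present`` False) and set iff ``mate_present`` is True.
READ_COLUMNS = ("chrom", "start", "end", "strand", "mate_present", "fragment_length")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-annotated genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ReadRecord:
    """A single mapped read (or read pair collapsed to its fragment)."""

    chrom: str
    start: int
    end: int
    strand: str
    mate_present: bool = False
    fragment_length: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("read has non-positive length")
        if self.mate_present != (self.fragment_length is not None):
            raise ValueError("fragment_length must be present iff mate_present")


def reads_to_frame(records: Iterable[ReadRecord]) -> pd.DataFrame:
    """Collect ReadRecords into the canonical read table."""
    rows = [
        (r.chrom, r.start, r.end, r.strand, r.mate_present, r.fragment_length)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(READ_COLUMNS))


def empty_reads() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "mate_present": pd.Series(dtype=bool),
            "fragment_length": pd.Series(dtype=float),
        }
    )


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    srt = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in srt:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """One transcript with strand-aware TSS and merged exons.

    ``exons`` are merged to a disjoint sorted union at construction, so
    ``exonic_length`` is the length of the exonic footprint, not the sum of
    possibly overlapping annotated exons.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        object.__setattr__(self, "exons", _merge_intervals(self.exons))
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"transcript {self.transcript_id}: bad exon [{s},{e})")

    @property
    def tss(self) -> int:
        """First transcribed base: start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


class MidpointTrack:
    """Per-chromosome sorted nucleosome-midpoint coordinates for one experiment.

    Parameters
    ----------
    midpoints
        Mapping chromosome -> midpoint coordinates (any integer array-like;
        sorted internally).
    label
        Experiment name, conventionally one of ``hmgd``, ``h1``, ``total``.
    """

    def __init__(self, midpoints: Mapping[str, Iterable[int]], label: str = "total"):
        self.label = label
        self.midpoints: dict[str, np.ndarray] = {
            chrom: np.sort(np.asarray(list(v) if not isinstance(v, np.ndarray) else v,
                                      dtype=np.int64))
            for chrom, v in midpoints.items()
        }

    @property
    def n_total(self) -> int:
        return int(sum(v.size for v in self.midpoints.values()))

    def chroms(self) -> list[str]:
        return sorted(self.midpoints)

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Midpoints on ``chrom`` in [start, end), sorted."""
        mids = self.midpoints.get(chrom)
        if mids is None or mids.size == 0:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(mids, [start, end], side="left")
        return mids[lo:hi]

    def count(self, chrom: str, start: int, end: int) -> int:
        mids = self.midpoints.get(chrom)
        if mids is None:
            return 0
        lo, hi = np.searchsorted(mids, [start, end], side="left")
        return int(hi - lo)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MidpointTrack(label={self.label!r}, n_total={self.n_total})"


Genome = dict[str, int]


def genome_size(genome: Genome) -> int:
    return int(sum(genome.values()))
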