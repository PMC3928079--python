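"""Genomic-feature classification, midpoint densities, TSS aggregate
profiles, and per-promoter architectural-protein rates.

Feature precedence everywhere is promoter > exon > intron > intergenic,
with "promoter" meaning within 1 kb of a TSS (strand-oriented offset sign
splits it into upstream/downstream). Densities are read fractions per unit
length, so a uniformly distributed track has density ~1 in every class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, Genome, MidpointTrack, genome_size

PROMOTER_FLANK = 1000

#: Strand-oriented promoter segments (bp relative to the TSS) used for the
#: per-segment correlation analysis: a nucleosome-depleted region, four
#: downstream and three upstream positioned-nucleosome windows. These
#: boundaries are package defaults, not measured values.
DEFAULT_SEGMENTS: dict[str, tuple[int, int]] = {
    "-3": (-675, -500),
    "-2": (-500, -325),
    "-1": (-325, -150),
    "NDR": (-150, 0),
    "+1": (0, 175),
    "+2": (175, 350),
    "+3": (350, 525),
    "+4": (525, 700),
}

HMGD_WINDOW = (-100, 500)
H1_WINDOW = (-550, 50)

_CLASS_CODES = {
    "intergenic": 0,
    "intron": 1,
    "exon": 2,
    "promoter_upstream": 3,
    "promoter_downstream": 4,
}
_CODE_NAMES = {v: k for k, v in _CLASS_CODES.items()}


def genome_class_arrays(
    genes: Sequence[GeneModel], genome: Genome, flank: int = PROMOTER_FLANK
) -> dict[str, np.ndarray]:
    """Per-base feature codes for each chromosome.

    Promoter bases are resolved against the *nearest* TSS so overlapping
    promoters of adjacent genes split at the midpoint between their TSSs.
    """
    arrays = {c: np.zeros(l, dtype=np.uint8) for c, l in genome.items()}
    for g in genes:
        arr = arrays.get(g.chrom)
        if arr is None:
            continue
        arr[max(0, g.start):min(arr.size, g.end)] = _CLASS_CODES["intron"]
    for g in genes:
        arr = arrays.get(g.chrom)
        if arr is None:
            continue
        for s, e in g.exons:
            arr[max(0, s):min(arr.size, e)] = _CLASS_CODES["exon"]
    dist = {c: np.full(l, np.inf) for c, l in genome.items()}
    for g in genes:
        arr = arrays.get(g.chrom)
        if arr is None:
            continue
        lo = max(0, g.tss - flank)
        hi = min(arr.size, g.tss + flank + 1)
        pos = np.arange(lo, hi)
        off = pos - g.tss if g.strand == "+" else g.tss - pos
        absoff = np.abs(off)
        closer = absoff < dist[g.chrom][lo:hi]
        codes = np.where(off < 0, _CLASS_CODES["promoter_upstream"],
                         _CLASS_CODES["promoter_downstream"]).astype(np.uint8)
        arr[lo:hi][closer] = codes[closer]
        dist[g.chrom][lo:hi][closer] = absoff[closer]
    return arrays


def classify_position(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    flank: int = PROMOTER_FLANK,
) -> tuple[str, str | None]:
    """Classify one position; returns (class, upstream/downstream-or-None)."""
    best_off = None
    for g in genes:
        if g.chrom != chrom:
            continue
        off = pos - g.tss if g.strand == "+" else g.tss - pos
        if best_off is None or abs(off) < abs(best_off):
            best_off = off
    if best_off is not None and abs(best_off) <= flank:
        return "promoter", "upstream" if best_off < 0 else "downstream"
    for g in genes:
        if g.chrom == chrom and any(s <= pos < e for s, e in g.exons):
            return "exon", None
    for g in genes:
        if g.chrom == chrom and g.start <= pos < g.end:
            return "intron", None
    return "intergenic", None


def region_density_table(
    track: MidpointTrack,
    genes: Sequence[GeneModel],
    genome: Genome,
    flank: int = PROMOTER_FLANK,
) -> pd.DataFrame:
    """Midpoint density per feature class.

    density = (midpoints in class / n_total) / (bp in class / genome bp);
    ``read_fraction`` is the unnormalized numerator. Classes with zero bp
    are excluded with a warning. A combined ``promoter`` row sums the
    upstream and downstream classes.
    """
    if track.n_total == 0:
        raise ValueError("empty midpoint track")
    arrays = genome_class_arrays(genes, genome, flank)
    gsize = genome_size(genome)
    n_codes = len(_CLASS_CODES)
    bp = np.zeros(n_codes, dtype=np.int64)
    hits = np.zeros(n_codes, dtype=np.int64)
    for chrom, arr in arrays.items():
        bp += np.bincount(arr, minlength=n_codes)
        mids = track.midpoints.get(chrom)
        if mids is not None and mids.size:
            mids = mids[(mids >= 0) & (mids < arr.size)]
            hits += np.bincount(arr[mids], minlength=n_codes)
    rows = []
    for code in range(n_codes):
        name = _CODE_NAMES[code]
        if bp[code] == 0:
            warnings.warn(f"feature class {name!r} covers 0 bp; excluded")
            continue
        frac = hits[code] / track.n_total
        rows.append((name, int(hits[code]), int(bp[code]), frac,
                     frac / (bp[code] / gsize)))
    up = _CLASS_CODES["promoter_upstream"]
    down = _CLASS_CODES["promoter_downstream"]
    if bp[up] + bp[down] > 0:
        h, b = hits[up] + hits[down], bp[up] + bp[down]
        frac = h / track.n_total
        rows.append(("promoter", int(h), int(b), frac, frac / (b / gsize)))
    return pd.DataFrame(rows, columns=["region", "midpoints", "bp",
                                       "read_fraction", "density"])


def chromosome_density_table(track: MidpointTrack, genome: Genome) -> pd.DataFrame:
    """Per-chromosome midpoint density (read fraction over length fraction)."""
    if track.n_total == 0:
        raise ValueError("empty midpoint track")
    gsize = genome_size(genome)
    rows = []
    for chrom, length in genome.items():
        n = track.midpoints.get(chrom, np.empty(0)).size
        frac = n / track.n_total
        rows.append((chrom, int(n), length, frac, frac / (length / gsize)))
    return pd.DataFrame(rows, columns=["chrom", "midpoints", "bp",
                                       "read_fraction", "density"])


@dataclass
class TSSProfile:
    """Strand-oriented aggregate midpoint density around TSSs.

    ``density`` is per-offset, per-expression-group: summed midpoint counts
    divided by the group gene count and by the track's genome-wide mean
    per-bp midpoint density (so 1.0 means background)."""

    offsets: np.ndarray
    density: pd.DataFrame
    raw_counts: pd.DataFrame
    n_genes: dict[str, int]
    n_truncated: int
    smooth_window: int


def tss_aggregate_profile(
    track: MidpointTrack,
    genes: Sequence[GeneModel],
    groups: Mapping[str, str] | pd.Series,
    genome: Genome,
    flank: int = 1000,
    smooth_window: int = 25,
) -> TSSProfile:
    """Aggregate midpoint density around TSSs per expression group.

    Offsets are negative upstream of the TSS regardless of strand. Genes
    whose flank runs off the chromosome contribute their truncated window
    and are counted in ``n_truncated``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    group_names = sorted(groups.unique())
    width = 2 * flank + 1
    counts = {gname: np.zeros(width, dtype=np.int64) for gname in group_names}
    n_genes = {gname: 0 for gname in group_names}
    n_truncated = 0
    for g in genes:
        gname = groups.get(g.gene_id)
        if gname is None:
            continue
        n_genes[gname] += 1
        chrom_len = genome.get(g.chrom)
        lo, hi = g.tss - flank, g.tss + flank + 1
        if lo < 0 or (chrom_len is not None and hi > chrom_len):
            n_truncated += 1
        mids = track.slice(g.chrom, max(0, lo), hi)
        off = mids - g.tss
        if g.strand == "-":
            off = -off
        counts[gname] += np.bincount(off + flank, minlength=width)
    mean_density = track.n_total / genome_size(genome)
    raw = pd.DataFrame(counts, index=np.arange(-flank, flank + 1))
    dens = raw.copy().astype(float)
    for gname in group_names:
        if n_genes[gname] > 0 and mean_density > 0:
            dens[gname] = raw[gname] / n_genes[gname] / mean_density
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        for gname in group_names:
            dens[gname] = np.convolve(dens[gname].to_numpy(), kernel, mode="same")
    return TSSProfile(
        offsets=raw.index.to_numpy(), density=dens, raw_counts=raw,
        n_genes=n_genes, n_truncated=n_truncated, smooth_window=smooth_window,
    )


def oriented_window_count(track: MidpointTrack, gene: GeneModel,
                          window: tuple[int, int]) -> int:
    """Midpoints in a strand-oriented window [a, b) relative to the TSS."""
    a, b = window
    if gene.strand == "+":
        return track.count(gene.chrom, gene.tss + a, gene.tss + b)
    return track.count(gene.chrom, gene.tss - b + 1, gene.tss - a + 1)


def promoter_rates(
    hmgd: MidpointTrack,
    h1: MidpointTrack,
    total: MidpointTrack,
    genes: Sequence[GeneModel],
    segments: Mapping[str, tuple[int, int]] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 occupancy rates over promoter windows.

    ``hmgd_rate`` = log2((HMGD1 + psi) / (total + psi)) over [-100, +500);
    ``h1_rate`` the same for H1 over [-550, +50). For every configured
    segment the table also carries per-track rates and the direct
    HMGD1/H1 log-ratio.
    """
    if segments is None:
        segments = DEFAULT_SEGMENTS
    psi = pseudocount
    rows = []
    for g in genes:
        row: dict[str, float | str] = {"gene_id": g.gene_id}
        hc = oriented_window_count(hmgd, g, HMGD_WINDOW)
        tc = oriented_window_count(total, g, HMGD_WINDOW)
        row["hmgd_rate"] = np.log2((hc + psi) / (tc + psi))
        oc = oriented_window_count(h1, g, H1_WINDOW)
        tc = oriented_window_count(total, g, H1_WINDOW)
        row["h1_rate"] = np.log2((oc + psi) / (tc + psi))
        for name, win in segments.items():
            hc = oriented_window_count(hmgd, g, win)
            oc = oriented_window_count(h1, g, win)
            tc = oriented_window_count(total, g, win)
            row[f"hmgd:{name}"] = np.log2((hc + psi) / (tc + psi))
            row[f"h1:{name}"] = np.log2((oc + psi) / (tc + psi))
            row[f"ratio:{name}"] = np.log2((hc + psi) / (oc + psi))
            row[f"total:{name}"] = np.log2(tc + psi)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
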