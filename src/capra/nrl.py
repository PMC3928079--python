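"""Phasogram-based nucleosome repeat length (NRL) estimation.

The genome is tiled into fixed regions, each region is scored by its
log2 HMGD1/H1 midpoint ratio and assigned to a rank quintile, and within
each quintile the separations of all ordered pairs of *total*-track
midpoints inside a region are histogrammed (the phasogram). Smoothed
phasogram peaks fall near multiples of the local repeat length, so an
ordinary least-squares fit of peak position on peak index estimates the
NRL as its slope.

A second estimator reproduces the classical gel-ladder protocol: per
digestion time point, the NRL is the slope of band size on band number,
and the time-zero NRL is obtained by extrapolating those slopes back to
t = 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import Genome, MidpointTrack


def ratio_quintiles(
    hmgd: MidpointTrack,
    h1: MidpointTrack,
    genome: Genome,
    region_size: int = 2000,
    n_quantiles: int = 5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Tile the genome and stratify regions by HMGD1/H1 log-ratio rank.

    Regions with no reads from either track are excluded before ranking.
    Quintile 1 holds the lowest ratios, quintile ``n_quantiles`` the
    highest; ties are broken by genomic order and fifths differ in size by
    at most one.
    """
    rows = []
    for chrom, length in genome.items():
        for s in range(0, length - region_size + 1, region_size):
            hc = hmgd.count(chrom, s, s + region_size)
            oc = h1.count(chrom, s, s + region_size)
            if hc + oc == 0:
                continue
            rows.append((chrom, s, s + region_size, hc, oc,
                         float(np.log2((hc + pseudocount) / (oc + pseudocount)))))
    if len(rows) < n_quantiles:
        raise ValueError(
            f"only {len(rows)} nonempty regions; need >= {n_quantiles}"
        )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "hmgd", "h1",
                                     "log_ratio"])
    order = df.sort_values(["log_ratio", "chrom", "start"]).index.to_numpy()
    quintile = np.empty(len(df), dtype=np.int64)
    for q, chunk in enumerate(np.array_split(order, n_quantiles), start=1):
        quintile[chunk] = q
    df["quintile"] = quintile
    return df


@dataclass
class Phasogram:
    """Separation histogram for one quintile.

    ``counts[d]`` (d = 1..max_distance; index 0 unused) is the number of
    ordered midpoint pairs (a, m) with m - a = d inside a single region.
    """

    quintile: int
    max_distance: int
    counts: np.ndarray
    n_regions: int = 0
    smoothed: np.ndarray | None = None


def phasogram(
    total: MidpointTrack,
    regions: pd.DataFrame,
    max_distance: int = 1200,
) -> dict[int, Phasogram]:
    """Per-quintile anchor-separation histograms of total-track midpoints.

    Every midpoint in a region acts as an anchor in turn; pairs never cross
    region boundaries. ``regions`` needs chrom/start/end/quintile columns
    (e.g. from :func:`ratio_quintiles`).
    """
    if (regions["end"] - regions["start"]).min() <= max_distance:
        raise ValueError("max_distance must be smaller than the region size")
    out: dict[int, Phasogram] = {}
    for q, sub in regions.groupby("quintile"):
        counts = np.zeros(max_distance + 1, dtype=np.int64)
        for row in sub.itertuples(index=False):
            mids = total.slice(row.chrom, row.start, row.end)
            m = mids.size
            if m < 2:
                continue
            # all ordered rightward pairs; chunk anchors to bound memory
            step = max(1, 2_000_000 // max(m, 1))
            for i0 in range(0, m, step):
                d = mids[None, i0:i0 + step] * -1 + mids[:, None]
                d = d[(d >= 1) & (d <= max_distance)]
                counts += np.bincount(d, minlength=max_distance + 1)
        out[int(q)] = Phasogram(int(q), max_distance, counts, n_regions=len(sub))
    return out


def detect_peaks(
    phas: Phasogram | np.ndarray,
    smooth_sd: float = 5.0,
    min_separation: int = 120,
    min_peaks: int = 2,
) -> np.ndarray:
    """Locate periodic peaks in a (smoothed) phasogram.

    The histogram is smoothed with a Gaussian kernel (sd = smooth_sd,
    truncated at 3 sd); local maxima in [min_separation, max_distance -
    3*smooth_sd] are kept greedily in decreasing height subject to a mutual
    distance of min_separation, then returned sorted ascending.
    """
    counts = phas.counts if isinstance(phas, Phasogram) else np.asarray(phas, float)
    if counts.size == 0:
        raise ValueError("empty phasogram")
    max_distance = counts.size - 1
    smoothed = gaussian_filter1d(counts.astype(float), smooth_sd, truncate=3.0,
                                 mode="reflect")
    if isinstance(phas, Phasogram):
        phas.smoothed = smoothed
    hi = int(max_distance - 3 * smooth_sd)
    if hi <= min_separation:
        raise ValueError("search window empty; increase max_distance")
    # find_peaks' distance parameter implements the greedy
    # keep-highest-first rule; restrict the domain first so the tall
    # sub-nucleosomal shoulder cannot suppress genuine peaks
    lo = max(min_separation - 1, 0)
    idx, _ = find_peaks(smoothed[lo: hi + 1], distance=min_separation)
    idx = idx + lo
    idx = idx[idx >= min_separation]
    if idx.size < min_peaks:
        raise ValueError(
            f"insufficient phasing: found {idx.size} peaks, need {min_peaks}"
        )
    return np.sort(idx)


@dataclass
class NRLEstimate:
    """Least-squares fit of peak position on peak index; slope = NRL (bp)."""

    peaks: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def fit_nrl(peaks: np.ndarray, with_intercept: bool = True) -> NRLEstimate:
    """OLS of peak position (bp) on peak number 1..k."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("need >= 2 peaks to fit an NRL")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak positions must be strictly increasing")
    k = np.arange(1, peaks.size + 1, dtype=float)
    if with_intercept:
        slope, intercept = np.polyfit(k, peaks, 1)
    else:
        slope = float(np.dot(k, peaks) / np.dot(k, k))
        intercept = 0.0
    fitted = slope * k + intercept
    sst = float(np.sum((peaks - peaks.mean()) ** 2))
    ssr = float(np.sum((peaks - fitted) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return NRLEstimate(peaks, float(slope), float(intercept), r2)


def estimate_nrl_by_quintile(
    total: MidpointTrack,
    hmgd: MidpointTrack,
    h1: MidpointTrack,
    genome: Genome,
    region_size: int = 2000,
    max_distance: int = 1200,
    smooth_sd: float = 5.0,
    min_separation: int = 120,
    with_intercept: bool = True,
) -> pd.DataFrame:
    """Full stratified pipeline: quintiles -> phasograms -> peaks -> slopes."""
    regions = ratio_quintiles(hmgd, h1, genome, region_size)
    phas = phasogram(total, regions, max_distance)
    rows = []
    for q in sorted(phas):
        peaks = detect_peaks(phas[q], smooth_sd, min_separation)
        est = fit_nrl(peaks, with_intercept)
        rows.append((q, est.slope, est.intercept, est.r_squared, peaks.size,
                     phas[q].n_regions))
    return pd.DataFrame(rows, columns=["quintile", "nrl", "intercept",
                                       "r_squared", "n_peaks", "n_regions"])


@dataclass
class LadderNRL:
    """Gel-ladder NRL regression result."""

    nrl_by_time: pd.DataFrame  # time, nrl (slope of size on band number)
    nrl_time0: float
    extrapolated: bool


def nrl_from_ladder(bands: pd.DataFrame) -> LadderNRL:
    """NRL from polynucleosome ladder band sizes, extrapolated to time 0.

    ``bands`` has columns time, band, size. Per time point, NRL(t) is the
    OLS slope of size on band number (time points with a single band are
    dropped with a warning); with >= 2 time points NRL(t) is regressed on t
    and the intercept is the time-0 NRL, otherwise the single NRL is
    returned unextrapolated.
    """
    rows = []
    for t, sub in bands.groupby("time"):
        if len(sub) < 2:
            warnings.warn(f"time point {t} has a single band; dropped")
            continue
        slope, _ = np.polyfit(sub["band"].to_numpy(float),
                              sub["size"].to_numpy(float), 1)
        rows.append((float(t), float(slope)))
    if not rows:
        raise ValueError("no time point has >= 2 bands")
    per_time = pd.DataFrame(rows, columns=["time", "nrl"])
    if len(per_time) == 1:
        return LadderNRL(per_time, float(per_time["nrl"].iloc[0]), False)
    slope, intercept = np.polyfit(per_time["time"], per_time["nrl"], 1)
    return LadderNRL(per_time, float(intercept), True)
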