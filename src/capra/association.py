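"""Correlation and model-comparison statistics.

Three analyses share this module: occupancy-rate vs expression correlations
with Fisher-z confidence intervals and nested-model F-tests; 1-kb-window
statistics against distance to the nearest DNase hypersensitive site; and
hierarchical clustering of histone-mark and architectural-protein signals
over TSS windows with 1 - R as the distance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import distance_transform_edt
from scipy.spatial.distance import squareform

from .core import GeneModel, GenomicInterval, Genome, MidpointTrack


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson R with a Fisher-transform confidence interval.

    CI = tanh(atanh(R) +/- z_crit / sqrt(n - 3)); p is the usual two-sided
    t-test with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or y.size != n:
        raise ValueError("need two equal-length samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    zcrit = scipy.stats.norm.ppf(1 - alpha / 2)
    rz = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = zcrit / np.sqrt(n - 3)
    lo, hi = np.tanh(rz - half), np.tanh(rz + half)
    return CorrelationResult(float(r), int(n), float(lo), float(hi), float(p))


@dataclass
class ModelComparison:
    f: float
    df_num: int
    df_den: int
    p: float
    sse_full: float
    sse_reduced: float


def nested_f_test(response, predictor_a, predictor_b) -> ModelComparison:
    """F-test of y ~ a + b (full) against y ~ a (reduced), both with intercept.

    F = ((sse_reduced - sse_full) / 1) / (sse_full / (n - 3)). A collinear
    added predictor that cannot reduce the SSE yields F = 0; a perfect full
    fit yields F = +inf with p = 0.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    a = np.asarray(predictor_a, dtype=float)
    b = np.asarray(predictor_b, dtype=float)
    n = y.size
    if n <= 3:
        raise ValueError("need n > 3 observations")
    x_red = sm.add_constant(a)
    x_full = np.column_stack([np.ones(n), a, b])
    fit_red = sm.OLS(y, x_red).fit()
    fit_full = sm.OLS(y, x_full).fit()
    sse_r, sse_f = float(fit_red.ssr), float(fit_full.ssr)
    df_den = n - 3
    # a residual at rounding-noise level is a perfect fit
    if sse_f <= 1e-12 * max(sse_r, float(y @ y), 1.0):
        return ModelComparison(np.inf, 1, df_den, 0.0, 0.0, sse_r)
    f = max((sse_r - sse_f) / (sse_f / df_den), 0.0)
    p = float(scipy.stats.f.sf(f, 1, df_den))
    return ModelComparison(float(f), 1, df_den, p, sse_f, sse_r)


# ---------------------------------------------------------------------------
# DHS distance analysis


def dhs_window_stats(
    dhs: Sequence[GenomicInterval],
    hmgd: MidpointTrack,
    h1: MidpointTrack,
    genes: Sequence[GeneModel],
    genome: Genome,
    window: int = 1000,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Non-overlapping fixed-width window statistics against DHS distance.

    Per base, distance is the bp to the nearest DHS interval edge (0 inside);
    per window: dhs_dist = log2(mean distance + 1), occupancy values are
    log2(mean midpoint depth + psi), ratio is their difference, and tss_dist
    is the distance from the window midpoint to the nearest TSS. Windows on
    chromosomes without any DHS are dropped with a warning.
    """
    if not dhs:
        raise ValueError("DHS set is empty")
    dhs_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in dhs:
        dhs_by_chrom.setdefault(iv.chrom, []).append(iv)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    rows = []
    for chrom, length in genome.items():
        if chrom not in dhs_by_chrom:
            warnings.warn(f"no DHS on {chrom}; its windows are dropped")
            continue
        mask = np.ones(length, dtype=bool)
        for iv in dhs_by_chrom[chrom]:
            mask[max(0, iv.start):min(length, iv.end)] = False
        dist = distance_transform_edt(mask)
        n_win = length // window
        if n_win == 0:
            continue
        mean_dist = dist[: n_win * window].reshape(n_win, window).mean(axis=1)
        starts = np.arange(n_win) * window
        tss = tss_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        centers = starts + window // 2
        if tss.size:
            j = np.searchsorted(tss, centers)
            lo = np.clip(j - 1, 0, tss.size - 1)
            hi = np.clip(j, 0, tss.size - 1)
            tss_dist = np.minimum(np.abs(centers - tss[lo]), np.abs(tss[hi] - centers))
        else:
            tss_dist = np.full(n_win, np.inf)
        for i, s in enumerate(starts):
            hc = hmgd.count(chrom, s, s + window)
            oc = h1.count(chrom, s, s + window)
            hv = np.log2(hc / window + pseudocount)
            ov = np.log2(oc / window + pseudocount)
            rows.append((chrom, int(s), int(s + window), hv, ov, hv - ov,
                         float(np.log2(mean_dist[i] + 1.0)), float(tss_dist[i])))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "hmgd_val", "h1_val", "ratio",
                 "dhs_dist", "tss_dist"],
    )


def exclude_tss_proximal(stats: pd.DataFrame, cutoff: int = 2000) -> pd.DataFrame:
    """Keep windows at least ``cutoff`` bp from the nearest TSS."""
    return stats[stats["tss_dist"] >= cutoff].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Histone-mark clustering


@dataclass
class PTMMatrix:
    """Experiments-by-TSS-window signal matrix with its correlation structure.

    ``merges`` is a scipy linkage matrix (average linkage on 1 - R);
    :meth:`families` cuts it into k flat clusters.
    """

    labels: list[str]
    values: pd.DataFrame
    correlation: pd.DataFrame
    merges: np.ndarray

    def families(self, k: int = 2) -> dict[str, int]:
        flat = fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))


def bedgraph_window_means(bedgraph: pd.DataFrame,
                          windows: Sequence[GenomicInterval]) -> np.ndarray:
    """Mean bedGraph value over each window (bases without signal count as 0)."""
    out = np.zeros(len(windows))
    by_chrom = dict(tuple(bedgraph.groupby("chrom")))
    for i, w in enumerate(windows):
        sub = by_chrom.get(w.chrom)
        if sub is None:
            continue
        s = np.maximum(sub["start"].to_numpy(), w.start)
        e = np.minimum(sub["end"].to_numpy(), w.end)
        ov = np.clip(e - s, 0, None)
        out[i] = float((ov * sub["value"].to_numpy()).sum() / w.width)
    return out


def cap_window_values(
    cap: MidpointTrack,
    total: MidpointTrack,
    windows: Sequence[GenomicInterval],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """log2((cap midpoints + psi) / (total midpoints + psi)) per window."""
    vals = np.empty(len(windows))
    for i, w in enumerate(windows):
        c = cap.count(w.chrom, w.start, w.end)
        t = total.count(w.chrom, w.start, w.end)
        vals[i] = np.log2((c + pseudocount) / (t + pseudocount))
    return vals


def tss_windows(genes: Sequence[GeneModel], width: int = 2000) -> list[GenomicInterval]:
    return [
        GenomicInterval(g.chrom, max(0, g.tss - width // 2), g.tss + width // 2)
        for g in genes
    ]


def ptm_cluster(
    ptm_values: pd.DataFrame,
    hmgd: MidpointTrack,
    h1: MidpointTrack,
    total: MidpointTrack,
    genes: Sequence[GeneModel],
    width: int = 2000,
    pseudocount: float = 1.0,
) -> PTMMatrix:
    """Correlate and cluster mark signals with HMGD1/H1 occupancy at TSSs.

    ``ptm_values`` holds one column per mark experiment with one row per
    gene TSS window (any row order matching ``genes``). Normalized HMGD1 and
    H1 columns are appended, constant columns are dropped with a warning,
    and experiments are clustered by average linkage on 1 - Pearson R.
    """
    if len(genes) < 3:
        raise ValueError("need >= 3 TSS windows")
    windows = tss_windows(genes, width)
    values = ptm_values.copy()
    values.index = [g.gene_id for g in genes]
    values["HMGD1"] = cap_window_values(hmgd, total, windows, pseudocount)
    values["H1"] = cap_window_values(h1, total, windows, pseudocount)
    keep = []
    for col in values.columns:
        if np.std(values[col].to_numpy()) == 0:
            warnings.warn(f"experiment {col!r} is constant; excluded")
        else:
            keep.append(col)
    values = values[keep]
    if len(keep) < 2:
        raise ValueError("need >= 2 non-constant experiments")
    corr = values.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    merges = linkage(squareform(dist, checks=False), method="average")
    return PTMMatrix(list(values.columns), values, corr, merges)
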