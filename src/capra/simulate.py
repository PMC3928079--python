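"""Ground-truthed simulator for nucleosome arrays, competitive linker binding,
MNase fragments, expression, DHSs and histone-mark tracks.

The generator emulates the statistical structure the analysis assumes:

* nucleosome positions follow a renewal process with region-specific repeat
  length (spacings ~ Normal(NRL, jitter), truncated below at 148 bp so
  adjacent cores cannot overlap);
* each nucleosome linker is bound by exactly one of two competing
  architectural proteins (HMGD1 or H1), with the HMGD1 probability a
  logistic function of local gene activity — active promoters are
  HMGD1-rich, silent and intergenic chromatin H1-rich;
* MNase-protected fragments have Normal(146, 23) lengths (central 95%
  ~ [101, 191] bp) and midpoints blurred around the true dyad by
  Normal(0, 3) trimming noise;
* DHSs of 200 bp sit on the TSS of the most expressed gene tertile;
* activating marks track gene activity positively, repressive marks
  negatively.

Everything derives from a single :class:`numpy.random.Generator`, so a fixed
:class:`SimulationConfig` reproduces its outputs exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, Genome, empty_reads

GENE_LENGTH = 1500
GENE_MARGIN = 800
DHS_WIDTH = 200
READ_LENGTH = 36
MIN_SPACING = 148  # adjacent dyads closer than a core particle would overlap

DEFAULT_GENOME: tuple[tuple[str, int], ...] = (
    ("chr2L", 400_000),
    ("chr2R", 400_000),
    ("chrX", 200_000),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model (lengths in bp)."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_genes: int = 200
    region_size: int = 2000
    nrl_by_quintile: tuple[int, ...] = (174, 177, 180, 184, 187)
    spacing_jitter_sd: float = 5.0
    fraglen_mean: float = 146.0
    fraglen_sd: float = 23.0
    midpoint_blur_sd: float = 3.0
    depth: float = 20.0
    ratio_slope: float = 1.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.region_size <= 0 or self.depth <= 0:
            raise ValueError("region_size and depth must be positive")

    @property
    def genome_dict(self) -> Genome:
        return dict(self.genome)


@dataclass
class SimulationTruth:
    """Everything the generator knows, for validating every pipeline stage."""

    config: SimulationConfig
    genes: list[GeneModel]
    expression: pd.DataFrame          # gene_id, log_expr (true log2 RPKM scale)
    dhs: list[GenomicInterval]
    nucleosomes: pd.DataFrame         # chrom, midpoint, nuc_id, label, ...
    regions: pd.DataFrame             # per-region truth (stratum/NRL/log-ratio)
    reads: dict[str, pd.DataFrame]    # hmgd / h1 / total fragment tables
    ptm: pd.DataFrame | None = None   # TSS-window mark values (genes x tracks)
    ptm_windows: list[GenomicInterval] | None = None
    counts: pd.DataFrame | None = None  # simulated exon tag counts


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# Annotation


def _split_counts(n: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of n items over weights."""
    total = sum(weights)
    raw = [n * w / total for w in weights]
    out = [int(math.floor(r)) for r in raw]
    rem = n - sum(out)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - out[i], reverse=True)
    for i in order[:rem]:
        out[i] += 1
    return out


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> tuple[list[GeneModel], pd.DataFrame, list[GenomicInterval]]:
    """Place non-overlapping genes, draw expression, emit DHSs.

    Genes alternate strand and are spread over chromosomes proportionally to
    length, one per equal-width slot, with a uniform offset inside the slot.
    log2 expression ~ Normal(2, 2); genes in the top expression tertile get a
    200-bp DHS centered on their TSS.
    """
    rng = _rng(config.seed if rng is None else rng)
    if config.n_genes == 0:
        return [], pd.DataFrame(columns=["gene_id", "log_expr"]), []
    chroms = [c for c, _ in config.genome]
    lengths = [l for _, l in config.genome]
    per_chrom = _split_counts(config.n_genes, lengths)
    genes: list[GeneModel] = []
    idx = 0
    for chrom, length, n_c in zip(chroms, lengths, per_chrom):
        if n_c == 0:
            continue
        slot = length // n_c
        if slot < GENE_LENGTH + 2 * GENE_MARGIN:
            raise ValueError(
                f"genome too small: {chrom} fits {n_c} genes only with slots of "
                f"{slot} bp < {GENE_LENGTH + 2 * GENE_MARGIN} bp"
            )
        for j in range(n_c):
            lo = GENE_MARGIN
            hi = slot - GENE_LENGTH - GENE_MARGIN
            start = j * slot + int(rng.integers(lo, hi + 1))
            strand = "+" if idx % 2 == 0 else "-"
            gid = f"g{idx:05d}"
            exons = ((start, start + 600), (start + 900, start + GENE_LENGTH))
            genes.append(
                GeneModel(gid, f"{gid}.t1", chrom, start, start + GENE_LENGTH,
                          strand, exons)
            )
            idx += 1
    log_expr = rng.normal(2.0, 2.0, size=len(genes))
    expression = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "log_expr": log_expr}
    )
    n_top = math.ceil(len(genes) / 3)
    top = expression.sort_values(["log_expr", "gene_id"],
                                 ascending=[False, True]).head(n_top)
    top_ids = set(top.gene_id)
    dhs = [
        GenomicInterval(g.chrom, g.tss - DHS_WIDTH // 2, g.tss + DHS_WIDTH // 2)
        for g in genes
        if g.gene_id in top_ids
    ]
    return genes, expression, dhs


# ---------------------------------------------------------------------------
# Nucleosome arrays and labels


def simulate_nucleosome_array(
    region: GenomicInterval,
    nrl: float,
    jitter_sd: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Renewal-process dyad positions in a region.

    First midpoint at ``region.start + U(0, nrl)``; successive spacings drawn
    from Normal(nrl, jitter_sd) truncated below at 148 bp; stops at
    ``region.end``.
    """
    if nrl <= 147:
        raise ValueError(f"nrl={nrl} <= 147 bp: nucleosomes would overlap")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = _rng(rng)
    pos = region.start + float(rng.uniform(0, nrl))
    mids: list[int] = []
    while pos < region.end:
        mids.append(int(round(pos)))
        if jitter_sd == 0:
            step = float(nrl)
        else:
            step = float(rng.normal(nrl, jitter_sd))
            while step < MIN_SPACING:
                step = float(rng.normal(nrl, jitter_sd))
        pos += step
    return np.asarray(mids, dtype=np.int64)


def assign_cap_labels(
    nucleosomes: pd.DataFrame,
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Competitively label each nucleosome HMGD1 or H1.

    p(HMGD1) = logistic(ratio_slope * z) with z the standardized log
    expression of the nearest gene when the nucleosome lies within 1 kb of
    its TSS, else z = -1 (intergenic baseline). Exactly one label per
    nucleosome. Returns the labeled table and a per-region truth table with
    the expected log2 HMGD1/H1 ratio (pseudocount 1).
    """
    rng = _rng(config.seed if rng is None else rng)
    nucs = nucleosomes.reset_index(drop=True).copy()
    z = np.full(len(nucs), -1.0)
    if len(genes) > 0:
        le = expression.set_index("gene_id")["log_expr"]
        sd = le.std(ddof=0)
        zle = (le - le.mean()) / sd if sd > 0 else le * 0.0
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {g.chrom for g in genes}:
            gs = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.tss)
            by_chrom[chrom] = (
                np.array([g.tss for g in gs]),
                np.array([zle[g.gene_id] for g in gs]),
            )
        for chrom, sub in nucs.groupby("chrom"):
            if chrom not in by_chrom:
                continue
            tss, gz = by_chrom[chrom]
            mids = sub["midpoint"].to_numpy()
            j = np.searchsorted(tss, mids)
            j_lo = np.clip(j - 1, 0, len(tss) - 1)
            j_hi = np.clip(j, 0, len(tss) - 1)
            pick = np.where(
                np.abs(mids - tss[j_lo]) <= np.abs(tss[j_hi] - mids), j_lo, j_hi
            )
            dist = np.abs(mids - tss[pick])
            zz = np.where(dist <= 1000, gz[pick], -1.0)
            z[sub.index.to_numpy()] = zz
    p = _logistic(config.ratio_slope * z)
    u = rng.uniform(size=len(nucs))
    nucs["p_hmgd"] = p
    nucs["label"] = np.where(u < p, "hmgd", "h1")
    nucs["region_id"] = (
        nucs["chrom"].astype(str) + ":" + (nucs["midpoint"] // config.region_size).astype(str)
    )
    truth = (
        nucs.groupby("region_id")
        .agg(expected_hmgd=("p_hmgd", "sum"), n_nuc=("p_hmgd", "size"))
        .reset_index()
    )
    truth["true_log_ratio"] = np.log2(
        (truth["expected_hmgd"] + 1.0)
        / (truth["n_nuc"] - truth["expected_hmgd"] + 1.0)
    )
    return nucs, truth


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(
    nucleosomes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    paired: bool = True,
) -> dict[str, pd.DataFrame]:
    """Sample sequencing fragments for the three experiments.

    Each nucleosome contributes Poisson(depth) fragments; fragment lengths
    are Normal(fraglen_mean, fraglen_sd) rounded and truncated to [50, 400];
    the fragment midpoint is the dyad plus rounded Normal(0, 3) MNase
    trimming noise. ChIP experiments (``hmgd``, ``h1``) sample only
    matching-label nucleosomes; ``total`` samples all. In single-end mode
    one 36-bp end is emitted per fragment with equal strand probability.
    """
    rng = _rng(config.seed if rng is None else rng)
    genome = config.genome_dict
    out: dict[str, pd.DataFrame] = {}
    for experiment in ("hmgd", "h1", "total"):
        if experiment == "total":
            sub = nucleosomes
        else:
            sub = nucleosomes[nucleosomes["label"] == experiment]
        if len(sub) == 0:
            out[experiment] = empty_reads()
            continue
        counts = rng.poisson(config.depth, size=len(sub))
        mid = np.repeat(sub["midpoint"].to_numpy(), counts)
        chrom = np.repeat(sub["chrom"].to_numpy(), counts)
        nuc_id = np.repeat(sub["nuc_id"].to_numpy(), counts)
        n = mid.size
        if config.fraglen_sd == 0:
            length = np.full(n, int(round(config.fraglen_mean)), dtype=np.int64)
        else:
            length = np.rint(
                rng.normal(config.fraglen_mean, config.fraglen_sd, n)
            ).astype(np.int64)
        length = np.clip(length, 50, 400)
        blur = np.rint(rng.normal(0.0, config.midpoint_blur_sd, n)).astype(np.int64)
        fmid = mid + blur
        start = fmid - (length - 1) // 2
        end = start + length
        chrom_len = np.array([genome[c] for c in chrom])
        ok = (start >= 0) & (end <= chrom_len)
        df = pd.DataFrame(
            {
                "chrom": chrom[ok],
                "start": start[ok],
                "end": end[ok],
                "strand": "+",
                "mate_present": True,
                "fragment_length": length[ok].astype(float),
                "nuc_id": nuc_id[ok],
            }
        )
        if not paired:
            fwd = rng.uniform(size=len(df)) < 0.5
            s = df["start"].to_numpy().copy()
            e = df["end"].to_numpy().copy()
            e[fwd] = s[fwd] + READ_LENGTH
            s[~fwd] = e[~fwd] - READ_LENGTH
            df["start"], df["end"] = s, e
            df["strand"] = np.where(fwd, "+", "-")
            df["mate_present"] = False
            df["fragment_length"] = np.nan
        out[experiment] = df.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Marks and expression counts


def simulate_ptm_tracks(
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    n_per_family: int = 3,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    width: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """Two families of mark tracks over TSS windows.

    Activating tracks = amplitude*z + noise, repressive = -amplitude*z +
    noise, where z is the standardized log expression and the noise is iid
    Normal(0, noise_sd) per gene and track. Returns a genes-by-tracks value
    table plus the TSS windows the values refer to.
    """
    rng = _rng(rng)
    le = expression.set_index("gene_id")["log_expr"]
    sd = le.std(ddof=0)
    z = ((le - le.mean()) / sd if sd > 0 else le * 0.0).to_numpy()
    data = {}
    for i in range(n_per_family):
        data[f"activating_{i + 1}"] = amplitude * z + rng.normal(0, noise_sd, z.size)
    for i in range(n_per_family):
        data[f"repressive_{i + 1}"] = -amplitude * z + rng.normal(0, noise_sd, z.size)
    values = pd.DataFrame(data, index=le.index)
    windows = [
        GenomicInterval(g.chrom, max(0, g.tss - width // 2), g.tss + width // 2)
        for g in genes
    ]
    return values, windows


def simulate_expression_counts(
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    total_reads: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Exon tag counts ~ Poisson(total_reads * weight), weight proportional to
    2**log_expr times exonic length."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    rng = _rng(rng)
    le = expression.set_index("gene_id")["log_expr"]
    exlen = pd.Series({g.gene_id: g.exonic_length for g in genes})
    w = (2.0 ** le) * exlen.reindex(le.index)
    w = w / w.sum()
    counts = rng.poisson(total_reads * w.to_numpy())
    return pd.DataFrame(
        {
            "gene_id": le.index,
            "count": counts,
            "exonic_length": exlen.reindex(le.index).to_numpy(),
        }
    )


def simulate_rate_expression(
    n: int,
    ratio_slope: float = 1.0,
    occupancy_sd: float = 0.5,
    noise_sd: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Summary-level generator where the HMGD1/H1 log-ratio drives expression.

    A latent per-gene ratio r ~ Normal(0,1) splits symmetrically into the two
    occupancy values (hmgd_val = r/2 + e, h1_val = -r/2 + e'), and expression
    is ratio_slope*r plus noise, so the ratio is by construction a better
    predictor than either occupancy alone.
    """
    rng = _rng(rng)
    r = rng.normal(0, 1, n)
    hmgd = r / 2 + rng.normal(0, occupancy_sd, n)
    h1 = -r / 2 + rng.normal(0, occupancy_sd, n)
    expr = ratio_slope * r + rng.normal(0, noise_sd, n)
    return pd.DataFrame({"hmgd_val": hmgd, "h1_val": h1, "log_expr": expr})


# ---------------------------------------------------------------------------
# End-to-end studies


def _tile_regions(genome: Genome, region_size: int) -> list[GenomicInterval]:
    out = []
    for chrom, length in genome.items():
        for s in range(0, length - region_size + 1, region_size):
            out.append(GenomicInterval(chrom, s, s + region_size))
    return out


def simulate_gene_study(
    config: SimulationConfig,
    total_expression_reads: int = 1_000_000,
    gene_study_nrl: float = 180.0,
    paired: bool = True,
) -> SimulationTruth:
    """Full gene-centric simulation: annotation, arrays, labels, reads,
    marks and tag counts, all from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes, expression, dhs = simulate_annotation(config, rng)
    rows = []
    nuc_id = 0
    for region in _tile_regions(config.genome_dict, config.region_size):
        for m in simulate_nucleosome_array(
            region, gene_study_nrl, config.spacing_jitter_sd, rng
        ):
            rows.append((region.chrom, int(m), nuc_id))
            nuc_id += 1
    nucs = pd.DataFrame(rows, columns=["chrom", "midpoint", "nuc_id"])
    nucs, region_truth = assign_cap_labels(nucs, genes, expression, config, rng)
    reads = simulate_reads(nucs, config, rng, paired=paired)
    ptm, ptm_windows = simulate_ptm_tracks(
        genes, expression, noise_sd=config.noise_sd, rng=rng
    )
    counts = simulate_expression_counts(genes, expression, total_expression_reads, rng)
    return SimulationTruth(
        config=config,
        genes=genes,
        expression=expression,
        dhs=dhs,
        nucleosomes=nucs,
        regions=region_truth,
        reads=reads,
        ptm=ptm,
        ptm_windows=ptm_windows,
        counts=counts,
    )


def simulate_spacing_study(
    config: SimulationConfig,
    n_regions_per_stratum: int = 500,
    paired: bool = True,
) -> SimulationTruth:
    """Spacing-centric simulation for repeat-length analysis.

    The genome is one chromosome tiled with ``region_size`` regions cycling
    through ``len(nrl_by_quintile)`` strata. Stratum s (1-based) gets repeat
    length ``nrl_by_quintile[s-1]`` and HMGD1 probability
    logistic(ratio_slope * z_s) with z_s decreasing in s — so the smallest
    repeat length co-occurs with the highest HMGD1/H1 ratio, and rank-based
    ratio quintiles computed downstream should recover the strata.
    """
    rng = np.random.default_rng(config.seed)
    strata_nrl = config.nrl_by_quintile
    k = len(strata_nrl)
    n_regions = n_regions_per_stratum * k
    chrom = "chrS"
    genome = ((chrom, n_regions * config.region_size),)
    cfg = SimulationConfig(
        seed=config.seed,
        genome=genome,
        n_genes=0,
        region_size=config.region_size,
        nrl_by_quintile=strata_nrl,
        spacing_jitter_sd=config.spacing_jitter_sd,
        fraglen_mean=config.fraglen_mean,
        fraglen_sd=config.fraglen_sd,
        midpoint_blur_sd=config.midpoint_blur_sd,
        depth=config.depth,
        ratio_slope=config.ratio_slope,
        noise_sd=config.noise_sd,
    )
    rows = []
    region_rows = []
    nuc_id = 0
    for i in range(n_regions):
        s = i % k + 1
        z = (k + 1) / 2.0 - s
        p = float(_logistic(cfg.ratio_slope * z))
        region = GenomicInterval(chrom, i * cfg.region_size, (i + 1) * cfg.region_size)
        mids = simulate_nucleosome_array(region, strata_nrl[s - 1],
                                         cfg.spacing_jitter_sd, rng)
        labels = np.where(rng.uniform(size=mids.size) < p, "hmgd", "h1")
        for m, lab in zip(mids, labels):
            rows.append((chrom, int(m), nuc_id, lab, p, i, s))
            nuc_id += 1
        region_rows.append(
            (chrom, region.start, region.end, i, s, strata_nrl[s - 1], z)
        )
    nucs = pd.DataFrame(
        rows,
        columns=["chrom", "midpoint", "nuc_id", "label", "p_hmgd", "region_id",
                 "stratum"],
    )
    regions = pd.DataFrame(
        region_rows,
        columns=["chrom", "start", "end", "region_id", "stratum", "true_nrl",
                 "true_z"],
    )
    reads = simulate_reads(nucs, cfg, rng, paired=paired)
    return SimulationTruth(
        config=cfg,
        genes=[],
        expression=pd.DataFrame(columns=["gene_id", "log_expr"]),
        dhs=[],
        nucleosomes=nucs,
        regions=regions,
        reads=reads,
    )
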