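"""Readers and writers for the plain-text genomic formats the pipeline touches.

BED-family parsing is done line-by-line so that malformed input can be
reported with its line number; GFF3 is delegated to :mod:`gffutils`.
GFF3's 1-based closed coordinates are converted to 0-based half-open here
and nowhere else.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import READ_COLUMNS, GeneModel, GenomicInterval, Genome, MidpointTrack


def _parse_bed_line(line: str, lineno: int, path: str) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    strand = fields[5] if len(fields) >= 6 else "."
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc


def read_intervals(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals in file order; missing strand becomes '.'."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed_line(line, lineno, str(path)))
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str | os.PathLike,
                    bed6: bool = False) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_midpoints(track: MidpointTrack, path: str | os.PathLike) -> None:
    """Write a midpoint track as BED3, one 1-bp interval per midpoint."""
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for m in track.midpoints[chrom]:
                fh.write(f"{chrom}\t{m}\t{m + 1}\n")


def read_midpoints(path: str | os.PathLike, label: str = "total") -> MidpointTrack:
    """Inverse of :func:`write_midpoints`; accepts any BED3 of 1-bp intervals."""
    by_chrom: dict[str, list[int]] = {}
    for iv in read_intervals(path):
        by_chrom.setdefault(iv.chrom, []).append(iv.start)
    return MidpointTrack(by_chrom, label=label)


# ---------------------------------------------------------------------------
# Gene models


def _gene_models_from_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for kind in ("mRNA", "transcript"):
        for t in db.features_of_type(kind):
            exons = [(e.start - 1, e.end) for e in db.children(t, featuretype="exon")]
            if not exons:
                raise ValueError(f"transcript {t.id} has no exons")
            if t.strand not in ("+", "-"):
                raise ValueError(f"transcript {t.id}: unknown strand {t.strand!r}")
            parents = list(db.parents(t, featuretype="gene"))
            gene_id = parents[0].id if parents else t.attributes.get("gene_id", [t.id])[0]
            genes.append(
                GeneModel(gene_id, t.id, t.seqid, t.start - 1, t.end, t.strand,
                          tuple(exons))
            )
    return genes


def _gene_models_from_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            offsets = [int(x) for x in f[11].rstrip(",").split(",") if x]
            if not sizes:
                raise ValueError(f"{path}:{lineno}: transcript without exon blocks")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            genes.append(GeneModel(name.split(".")[0], name, chrom, start, end,
                                   strand, exons))
    return genes


def read_gene_models(path: str | os.PathLike, fmt: str | None = None,
                     one_per_gene: str | None = "longest") -> list[GeneModel]:
    """Read gene models from GFF3 or BED12.

    Parameters
    ----------
    fmt
        "gff3" or "bed12"; inferred from the extension when None.
    one_per_gene
        "longest" (default) keeps the longest transcript of each gene, the
        convention used for all TSS-centric statistics; None keeps every
        transcript.
    """
    if fmt is None:
        ext = str(path).lower()
        fmt = "gff3" if ext.endswith((".gff", ".gff3")) else "bed12"
    if fmt == "gff3":
        genes = _gene_models_from_gff3(path)
    elif fmt == "bed12":
        genes = _gene_models_from_bed12(path)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    if one_per_gene == "longest":
        best: dict[str, GeneModel] = {}
        for g in genes:
            cur = best.get(g.gene_id)
            if cur is None or (g.end - g.start, g.transcript_id) > (
                cur.end - cur.start, cur.transcript_id
            ):
                best[g.gene_id] = g
        genes = sorted(best.values(), key=lambda g: (g.chrom, g.start))
    elif one_per_gene is not None:
        raise ValueError(f"unknown one_per_gene policy {one_per_gene!r}")
    return genes


def write_gene_models_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcapra\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tcapra\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.transcript_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tcapra\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.transcript_id}.exon{i};Parent={g.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# Reads, bedGraph, tables


def read_reads(path: str | os.PathLike) -> pd.DataFrame:
    """Read a read table written by :func:`write_reads`.

    Single-end records are BED6 lines; paired records carry a 7th column with
    the fragment length (the interval itself spans the whole fragment).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 fields")
            frag = float(f[6]) if len(f) >= 7 and f[6] not in (".", "") else np.nan
            rows.append((f[0], int(f[1]), int(f[2]), f[5], not np.isnan(frag), frag))
    return pd.DataFrame(rows, columns=list(READ_COLUMNS))


def write_reads(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads.itertuples(index=False):
            frag = int(r.fragment_length) if r.mate_present else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\t{frag}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 fields")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def read_chrom_sizes(path: str | os.PathLike) -> Genome:
    """Two-column (chrom, length) tab-delimited file -> genome dict."""
    genome: Genome = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"{path}:{lineno}: need chrom and length")
            genome[f[0]] = int(f[1])
    return genome


def write_chrom_sizes(genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
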