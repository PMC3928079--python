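"""Expression quantification from exon tag counts.

RPKM uses a pseudocount of one read, so every gene has a finite log2
expression even with zero tags:

    RPKM = (count + 1) / ((exonic_length / 1e3) * (mapped_total / 1e6))
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd


def compute_rpkm(count, exonic_length, mapped_total):
    """Pseudocounted reads per kilobase of exonic length per million mapped
    reads; accepts scalars or arrays."""
    exonic_length = np.asarray(exonic_length, dtype=float)
    if np.any(exonic_length <= 0):
        raise ValueError("exonic_length must be positive")
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    rpkm = (np.asarray(count, dtype=float) + 1.0) / (
        (exonic_length / 1e3) * (mapped_total / 1e6)
    )
    return float(rpkm) if rpkm.ndim == 0 else rpkm


def expression_table(counts: pd.DataFrame, mapped_total: int | None = None) -> pd.DataFrame:
    """Add RPKM and log_expr columns to a (gene_id, count, exonic_length)
    table. ``mapped_total`` defaults to the column sum."""
    df = counts.copy()
    if mapped_total is None:
        mapped_total = int(df["count"].sum())
    df["rpkm"] = compute_rpkm(df["count"].to_numpy(), df["exonic_length"].to_numpy(),
                              mapped_total)
    df["log_expr"] = np.log2(df["rpkm"])
    return df


def assign_expression_groups(records: pd.DataFrame) -> pd.DataFrame:
    """Partition genes into expression tertiles ``low``/``medium``/``high``.

    Ranking is by (log_expr, gene_id) ascending — the gene id breaks ties —
    and group sizes differ by at most one, with the larger remainder going
    to ``low`` (then ``medium``).
    """
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 genes to form tertiles")
    df = records.sort_values(["log_expr", "gene_id"]).reset_index(drop=True)
    n_low = math.ceil(n / 3)
    n_high = n // 3
    n_med = n - n_low - n_high
    df["group"] = (["low"] * n_low) + (["medium"] * n_med) + (["high"] * n_high)
    return df.sort_values("gene_id").reset_index(drop=True)
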