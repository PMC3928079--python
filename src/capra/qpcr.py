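"""qPCR fold-enrichment and fold-change arithmetic.

ChIP enrichment uses the signal-over-background form, fold =
E^(Ct_IgG - Ct_antibody), so the IgG control itself maps to 1. Expression
changes use the delta-delta-Ct form against a reference gene and a mock
control, fold = E^(-ddCt). Amplification efficiency E defaults to perfect
doubling and is exposed because real assays rarely achieve exactly 2.
Both statistics are invariant to adding a constant to every Ct value.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd


def chip_fold_enrichment(ct_antibody: float, ct_igg: float,
                         efficiency: float = 2.0) -> float:
    """Signal-over-background fold enrichment of an antibody over IgG."""
    if not (math.isfinite(ct_antibody) and math.isfinite(ct_igg)):
        raise ValueError("Ct values must be finite")
    return float(efficiency ** (ct_igg - ct_antibody))


def expression_fold_change(
    ct_target_kd: float,
    ct_ref_kd: float,
    ct_target_mock: float,
    ct_ref_mock: float,
    efficiency: float = 2.0,
) -> float:
    """ddCt fold change of a knockdown vs mock, normalized to a reference gene."""
    cts = (ct_target_kd, ct_ref_kd, ct_target_mock, ct_ref_mock)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_kd - ct_ref_kd) - (ct_target_mock - ct_ref_mock)
    return float(efficiency ** (-ddct))


def summarize_chip(ct_table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Replicate-aware ChIP enrichment per (target, antibody).

    ``ct_table`` columns: target, antibody, ct (one row per replicate); the
    IgG rows are the background. Replicates are averaged on the Ct scale
    and the replicate SD is propagated as a fold range
    [E^(dCt - sd), E^(dCt + sd)].
    """
    igg = ct_table[ct_table["antibody"].str.lower() == "igg"]
    if igg.empty:
        raise ValueError("missing IgG control rows")
    igg_ct = igg.groupby("target")["ct"].mean()
    rows = []
    for (target, antibody), sub in ct_table.groupby(["target", "antibody"]):
        if target not in igg_ct.index:
            raise ValueError(f"missing IgG control for target {target!r}")
        dct = float(igg_ct[target] - sub["ct"].mean())
        sd = float(sub["ct"].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append((target, antibody, len(sub),
                     efficiency ** dct,
                     efficiency ** (dct - sd), efficiency ** (dct + sd)))
    return pd.DataFrame(rows, columns=["target", "antibody", "n_replicates",
                                       "fold", "fold_low", "fold_high"])


def summarize_expression(
    ct_table: pd.DataFrame,
    reference: str = "actin",
    mock: str = "mock",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Replicate-aware ddCt fold change per (target, condition) vs mock.

    ``ct_table`` columns: target, condition, ct. The reference-gene rows
    normalize each condition; the mock condition is the baseline (fold 1).
    """
    ref = ct_table[ct_table["target"] == reference]
    if ref.empty:
        raise ValueError(f"missing reference gene rows ({reference!r})")
    ref_ct = ref.groupby("condition")["ct"].mean()
    if mock not in set(ct_table["condition"]):
        raise ValueError(f"missing mock condition rows ({mock!r})")
    mock_means = ct_table[ct_table["condition"] == mock].groupby("target")["ct"].mean()
    rows = []
    for (target, cond), sub in ct_table.groupby(["target", "condition"]):
        if target == reference:
            continue
        if cond not in ref_ct.index:
            raise ValueError(f"missing reference rows for condition {cond!r}")
        if target not in mock_means.index:
            raise ValueError(f"missing mock rows for target {target!r}")
        ddct = (sub["ct"].mean() - ref_ct[cond]) - (mock_means[target] - ref_ct[mock])
        sd = float(sub["ct"].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append((target, cond, len(sub), efficiency ** (-ddct),
                     efficiency ** (-ddct - sd), efficiency ** (-ddct + sd)))
    return pd.DataFrame(rows, columns=["target", "condition", "n_replicates",
                                       "fold", "fold_low", "fold_high"])
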