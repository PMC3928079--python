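# capra

Analysis of two competing chromatin architectural proteins — the linker
histone H1 and the high-mobility-group protein HMGD1 — from
nucleosome-resolution sequencing data, with a ground-truthed simulator so
every stage of the pipeline is testable without raw sequencing downloads.

## Who this is for

Chromatin and regulatory-genomics researchers who have MNase-seq /
nucleosome-ChIP-seq read coordinates for two linker-binding proteins plus a
total-nucleosome control, and who want to ask: where do the two proteins
bind, how does their balance relate to transcription and open chromatin,
and does that balance set the local nucleosome spacing?

## What it computes

* **Nucleosome midpoints (dyads).** Single-end libraries: the mean fragment
  length is estimated as the lag maximizing the covariation (Pearson
  correlation) of forward- vs reverse-strand 5′ read depth, and each read is
  shifted inward by half that length. Paired-end libraries: fragments are
  filtered to the central 95% of the length distribution and midpoints are
  the fragment centers.
* **Occupancy statistics.** Midpoint densities per chromosome and per
  feature class (promoter/exon/intron/intergenic), strand-oriented TSS
  aggregate profiles by expression tertile, and per-gene promoter rates
  `log2((ChIP + 1)/(total + 1))` over fixed windows (HMGD1: −100..+500 bp;
  H1: −550..+50 bp).
* **Association statistics.** Pearson correlations with Fisher-z 95%
  confidence intervals; nested-model F-tests comparing
  `expr ~ log2(H1) + log2(HMGD1)` against each univariate model
  (`F = ((SSE_r − SSE_f)/1)/(SSE_f/(n−3))`); 1-kb-window statistics against
  `log2(mean distance to nearest DHS + 1)`; and hierarchical clustering of
  histone-mark and occupancy signals over 2-kb TSS windows with `1 − R`
  distance and average linkage.
* **Nucleosome repeat length (NRL).** The genome is tiled into 2-kb regions
  stratified into HMGD1/H1 log-ratio quintiles; within each quintile the
  separations of all ordered midpoint pairs form a phasogram whose smoothed
  peaks lie near multiples of the local NRL, estimated as the least-squares
  slope of peak position on peak index. A gel-ladder estimator (band size ~
  band number per digestion time, extrapolated to time 0) is included for
  bulk-chromatin assays.
* **qPCR arithmetic.** Signal-over-background ChIP enrichment
  (`2^(Ct_IgG − Ct_ab)`) and ΔΔCt expression fold changes.
* **Simulator.** Renewal-process nucleosome arrays with region-specific
  repeat length, competitive logistic HMGD1/H1 labeling driven by gene
  activity, Normal(146, 23) MNase fragments, DHSs at active promoters, and
  activating/repressive mark tracks — all with recorded ground truth.

## Worked example

```python
from capra.simulate import SimulationConfig, simulate_spacing_study
from capra.midpoints import fragment_size_filter, midpoints_from_pairs
from capra.nrl import estimate_nrl_by_quintile

st = simulate_spacing_study(SimulationConfig(seed=2), n_regions_per_stratum=500)
tracks = {}
for name in ("hmgd", "h1", "total"):
    kept, bounds = fragment_size_filter(st.reads[name])
    tracks[name] = midpoints_from_pairs(kept, name)

print(estimate_nrl_by_quintile(tracks["total"], tracks["hmgd"], tracks["h1"],
                               st.config.genome_dict))
```

prints

```
   quintile         nrl  intercept  r_squared  n_peaks  n_regions
0         1  186.457143  -0.600000   0.999999        6        500
1         2  184.600000  -0.933333   0.999999        6        500
2         3  179.142857   1.333333   0.999999        6        500
3         4  176.114286   1.600000   0.999993        6        500
4         5  174.628571   0.466667   0.999999        6        500
```

Quintile 1 (lowest HMGD1/H1 ratio, H1-rich chromatin) has the longest
repeat length, ~187 bp; quintile 5 (HMGD1-rich) the shortest, ~175 bp — the
simulation coupled repeat length 187→174 to the ratio and the full pipeline
(fragment filter → pair midpoints → ratio quintiles → phasogram → peak
regression) recovers each value within about 1 bp.

The same steps are available from a shell via the `capra` command
(`capra simulate`, `capra midpoints`, `capra nrl`, `capra correlate`,
`capra dhs`, `capra ptm-cluster`, `capra qpcr`); every subcommand takes
`--seed`, `--config` and `--out-dir` and records its parameters.

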