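# splicemark

Tools for asking whether an intragenic histone mark — H3K79me2, the
DOT1L-deposited mark found on actively transcribed gene bodies — is
preferentially deposited around alternative-splicing (AS) sites, and
whether that preference separates cell types. The package implements the
full chain as a tested, seeded pipeline:

1. **ψ estimation** (percent spliced in) per event and cell type from
   inclusion/exclusion junction reads, with a Beta-binomial posterior and
   confidence-interval filtering, and predominant-isoform calls for the
   five AS event types (SE, MXE, RI, A5SS, A3SS) at the standard cutoffs
   (ψ ≤ 0.2 for SE/A3SS, ψ ≥ 0.8 for RI/A5SS, either tail for MXE).
2. **Splice-window enrichment**: read-start coverage in four 50-bp windows
   on the splice boundaries of each event, gene-level enrichment/kb
   (reads · kb⁻¹ per 10⁷ mapped reads), classification of each site as
   higher/same/lower than randomized non-AS control sites by an exact
   two-sided Poisson test, a sliding-window Poisson peak caller, and
   z-scored meta-profiles over −200..+400 bp around the splicing exon start.
3. **SOM clustering**: a hexagonal self-organizing map trained on the
   genes × cell-types enrichment matrix, node grouping by hierarchical
   clustering (default six clusters), cell-type assignment to the most
   enriched cluster, and per-cluster SE vs non-SE log₂ fold changes with
   permutation p-values.
4. **Downstream comparisons**: Mann–Whitney expression comparison of
   SE-associated vs other genes, and log-odds PWM scanning of splice-site
   flank sequences with Fisher/BH motif enrichment.
5. **Synthetic data with ground truth**: every stage is exercised on a
   simulated genome (planted ψ, planted window enrichment, planted
   cell-type clusters), so recovery can be measured exactly.

## Model sketch

For an event with `I` inclusion and `S` exclusion junction reads and a
Beta(a, b) prior, the ψ posterior is Beta(a+I, b+S); the point estimate is
the posterior mean and the interval the central posterior interval.
Window enrichment for a region set `R` in a track with library size `N` is

    enrichment/kb = reads(R) / (len(R)/1000) / (N/10⁷)

and a site with `x` reads over `L` bp is compared against a control rate
`r` (reads/bp from non-AS exon windows) by the exact two-sided Poisson
test of `x` against `rL`. The SOM is a Kohonen map on a hexagonal lattice:
winner = nearest codebook vector, update
`w ← w + α(t)·exp(−d²/2σ(t)²)·(x−w)` with α and σ decaying linearly over
epochs.

## Worked example

```sh
splicemark init-config --out splicemark.yaml   # defaults: 200 genes, 6 cell types
splicemark run --config splicemark.yaml
```

or step through the narrative drivers:

```sh
cd analysis
python 01_simulate.py && python 04_som_clusters.py
```

which prints (seed 7, two planted cell-type clusters):

```
cell-type assignment (planted cluster in parentheses):
  ct01 -> cluster 3 (planted 0)
  ct02 -> cluster 3 (planted 0)
  ct03 -> cluster 3 (planted 0)
  ct04 -> cluster 4 (planted 1)
  ct05 -> cluster 4 (planted 1)
  ct06 -> cluster 4 (planted 1)
per-cluster SE vs non-SE enrichment:
 cluster  n_celltypes  log2_fold_change  p_value  p_label
       3            3            1.2468   0.0005 < 0.0005
       4            3            1.3867   0.0005 < 0.0005
```

The map recovers the planted two-cluster partition of cell types exactly
(cluster labels are arbitrary), and within each cluster the SE sites of
its own genes are significantly more enriched than non-AS control sites
(positive log₂ fold change; permutation p below the 1/n_perm resolution).
`05_downstream.py` confirms the planted null for expression (SE vs non-SE
genes, p ≈ 0.24) and recovers the planted flank motifs (q < 10⁻³).

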