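# Methods

## Scope and data model

The package analyses the relationship between an intragenic coverage mark
(H3K79me2-style ChIP read starts) and alternative-splicing events. All
coordinates are 0-based half-open in memory and in BED/bedGraph output;
GTF output is 1-based inclusive. Coverage is represented as per-base
read-start counts per contig with a recorded library size that always
equals the summed counts; this makes every window statistic exactly
reproducible by per-base counting, which the tests exploit as an oracle.

An AS event stores its alternative element plus the flanking exons in
transcription orientation; on the minus strand the transcriptionally
upstream exon is genomically to the right, and all 5′/3′ boundary logic
resolves through the strand.

## ψ estimation and isoform calls

ψ (percent spliced in) is the fraction of transcripts containing the
alternative element. Rather than a full isoform-mixture model, ψ is
estimated from inclusion (I) vs exclusion (S) junction reads under a
Beta-binomial model: prior Beta(a, b) (default uniform, a = b = 1),
posterior Beta(a+I, b+S), point estimate the posterior mean, interval the
central posterior interval at the requested level (default 95%). The
downstream analysis consumes only ψ and a confidence filter, so this
captures everything the pipeline needs. Filter defaults: interval width
≤ 0.3 and depth ≥ 10; zero-depth events return the prior mean flagged
unfiltered. These filter values are package defaults exposed as
configuration — there is no canonical published setting.

Predominant-isoform calls use ψ ≤ 0.2 for SE and A3SS, ψ ≥ 0.8 for RI and
A5SS, and either tail for MXE. For MXE, ψ refers to the transcriptionally
upstream of the two mutually exclusive exons (the convention is not
standardized; this choice is documented and symmetric to invert). Isoform
labels: SE "skipped", A3SS "excluded", RI "retained", A5SS "included",
MXE "downstream_exon"/"upstream_exon".

Interval behaviour worth knowing: because the data are discrete and the
prior proper, the central posterior interval's frequentist coverage at
95% is close to nominal when ψ itself is drawn uniformly (the prior);
the test suite checks 93–97% empirically at depth ~50.

## Splice-site windows and enrichment

Each event contributes four 50-bp windows: on the 5′ and 3′ ends of the
alternative element, the 3′ end of the upstream exon and the 5′ end of the
downstream exon. "50 bp around" is interpreted as 25 bp on each side of
the boundary (configurable via the window flank); windows clipped at
contig edges are flagged. Gene-level enrichment/kb counts read starts in
the gene's exons each padded by 50 bp (overlaps merged), divides by the
merged length in kb, and normalizes per 10⁷ mapped reads. The 10⁷ scale
is a package choice (any fixed scale gives identical downstream ratios);
the statistic is invariant under joint rescaling of counts and library
size.

Sites are classified against randomized controls: control window sets are
sampled without replacement from internal exons of genes with no AS event
(same four-window geometry as a skipped exon), and the pooled control
read rate r (reads/bp) sets the expectation rL for a site of L bp. The
higher/same/lower call is an exact two-sided Poisson test (doubled
smaller tail, capped at 1) at α = 0.05. The exact test is mildly
conservative on discrete counts — at the default expectation rL = 20 the
null "higher" rate is ≈ 0.022 against the nominal 0.025 — which the
calibration tests account for by Monte Carlo bands.

Peaks are called by a sliding-window Poisson scan (200-bp windows, 50-bp
step): each window's count is tested against Poisson with rate the larger
of the track-wide mean and a 10-kb local mean, p-values are BH-adjusted
across all windows, windows with q < 0.01 are merged. This caller is
deliberately minimal — no fragment-size model, no input track — and
externally called peaks can be supplied as BED instead.

Meta-profiles z-score each event's per-base density over −200..+400 bp
around the splicing exon start (minus-strand events reflected first), then
average positionally; constant-density events are excluded and counted,
since a z-score is undefined for them.

## Self-organizing map

Input is the genes × cell-types matrix of gene-level enrichment/kb for
genes with at least one SE site, rows scaled to unit variance by default
(options: none, z-score). The SOM is an online Kohonen map on a hexagonal
lattice (default 12×8 at desk scale; 40×25 reproduces the full-scale
layout). Node (col, row) sits at Cartesian (col + 0.5·(row mod 2),
row·√3/2) — odd-row offset, pointy-top — and grid distance is Euclidean
distance between centers, so immediate hex neighbours are at distance 1.

Training: codebooks initialize uniformly at random inside the
per-dimension data range; per presented vector the best-matching unit is
the nearest codebook (ties to the lowest node index) and all codebooks
update by w ← w + α(t)·exp(−d²/2σ(t)²)·(x−w). α decays 0.05→0.01 and σ
(grid diagonal)/3 → 1, both linearly over epochs (default 100);
presentation order reshuffles each epoch from the run seed. Range-uniform
initialization (rather than sampling data rows) is what makes the
training contract "quantization error after training ≤ at initialization"
hold robustly, and it degenerates to an exact fixed point for single-row
input. The trained model records its training column order, so cell-type
assignment is invariant to column permutations of the query frame.

Nodes are grouped by complete-linkage hierarchical clustering of codebook
vectors (default k = 6), with a homogeneity curve (1 − SSW/SST over
codebooks) reported for k = 2..12 to support choosing k. Each cell type
is assigned the node cluster where its mean gene enrichment is maximal.
Per-cluster statistics compare SE-site window read rates against control
window rates within the cluster's cell types: log₂FC with a small
pseudocount (ε = 10⁻⁸) and a two-sided permutation p-value on the mean
difference, reported as (b+1)/(n_perm+1) so it is never zero and shows as
"< 1/n_perm" when no permutation reaches the observed difference.
Permutation (rather than a t-test) is used because the rate distributions
are skewed counts.

## Downstream comparisons

Expression of SE-associated genes is compared against a seeded,
without-replacement sample of genes with no AS event, on log₂(x+1), with
a two-sided Mann–Whitney U test; overlapping groups are refused.

Motif scanning is plain log-odds PWM scoring in bits against a background
base composition: score(offset) = Σ log₂(p/bg), N contributing zero; a
sequence is a hit when any offset reaches a threshold fraction (default
0.8) of the motif's maximum attainable score. Flanks from the minus
strand are expected reverse-complemented before scanning. Per-motif
enrichment of skip-site flanks vs control flanks is a Fisher exact test
on hit/no-hit counts with Haldane 0.5 correction for zero cells (flagged)
and BH adjustment across motifs, ranked by q then odds ratio. PWMs load
from MEME minimal text, parsed directly so probabilities are preserved at
full precision. The bundled toy motifs are synthetic test objects, not
real splicing-factor models.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with full ground truth:

- **Annotation**: genes tiled without overlap on one contig ("chrS1"),
  fixed 1-kb intergenic gaps, alternating strands, 4–8 exons of 80–200 bp
  with introns of 200–500 bp (redrawn below 200 bp so adjacent 50-bp
  windows plus A5SS/A3SS shifts can never collide). A configurable
  fraction of genes (default 0.6) carries exactly one AS event; the rest
  are the control pool. Event geometry per type: SE skips an internal
  exon; MXE places two adjacent alternatives (ψ refers to the upstream
  one); RI retains an intron; A5SS/A3SS shift a donor/acceptor by
  30–80 bp.
- **True ψ**: by default drawn from a mixture favouring the tails (45%
  U(0, 0.2), 45% U(0.8, 1), 10% U(0.2, 0.8)) so the isoform-calling
  thresholds have work to do; per-event overrides are available and never
  perturb the geometry (the default draw is always consumed).
- **Junction reads**: n ~ Poisson(depth) per event and cell type (default
  depth 50), inclusion ~ Binomial(n, ψ).
- **Coverage**: per-base Poisson at the background rate (default
  0.1 reads/bp). Cell types are partitioned into planted clusters
  (default two halves of six); AS genes are dealt round-robin to
  clusters, and a cell type's rate is multiplied by the effect size
  (default 4) only inside the four windows of its own cluster's events.
  Clusters therefore have distinguishable signatures, making the SOM
  recovery test a genuine parameter-recovery experiment. When a library
  size is fixed, reads are drawn multinomially so track sums are exact.
- **Expression**: log-normal (log-mean 3, log-SD 1) identical for SE and
  non-SE genes (null); a shift parameter moves SE genes' log-mean in SD
  units for power experiments.
- **Determinism**: every per-cell-type stream derives its own sub-seed
  from the master seed by splitmix64-style mixing of (seed, stage,
  cell-type index), so adding a cell type never perturbs the others and
  every output is a pure function of the config.

What the generator does *not* emulate: sequence content (flank sequences
for motif scanning are generated separately and labelled synthetic),
fragment-length structure, mappability/GC bias, replicates, and
biological coupling between ψ and the mark. Passing recovery tests
therefore demonstrates correctness of the estimators and the pipeline
plumbing under the assumed noise model, not biological conclusions about
real chromatin data.

## Orchestration and determinism

The pipeline runs stages in dependency order from a strict YAML config
(unknown keys rejected), records per-stage output SHA-256 checksums,
elapsed times and the config hash in `manifest.json`, and skips stages
whose config and outputs are unchanged. All tabular outputs are
deterministic functions of the config, so identical runs byte-match
(the manifest's timestamps excepted). Validation reports file/line for
BED, bedGraph, GTF, event-table and junction-count violations. Exit
codes: 0 ok, 2 validation, 3 stage failure.

## Problem sizes

Desk-scale defaults — 200 genes, 6 cell types, depth 50, background
0.1 reads/bp, effect 4, 12×8 SOM grid, 100 epochs — were chosen so a full
run completes in seconds while every calibration quantity (interval
coverage, classifier type-I error, ARI recovery, log₂FC recovery) is
estimated with usefully small Monte Carlo error; they are the conditions
the test suite and `scripts/acceptance.py` report.

## Known limitations

- The ψ estimator ignores exon-body reads and models exactly two
  isoforms; events with more alternatives are out of scope.
- The peak caller has no input/IgG normalization and no fragment model.
- Control sites are matched in number, not in exon length or expression
  (length matching is a straightforward extension).
- The higher/same/lower exact test is conservative at small expected
  counts; percentages of "same" are accordingly slightly inflated.
- SOM cluster labels are arbitrary; comparisons against planted truth use
  label-invariant scores (adjusted Rand index).
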