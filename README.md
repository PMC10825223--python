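# rbekit

Simulation and analysis toolkit for RNA base-editor profiling of
protein–RNA interactions.

## The problem

RNA base editors (rBEs) — C-to-U deaminases of the APOBEC/AID family and
A-to-I deaminases of the TadA/ADAR families — can be fused to an RNA-binding
protein (RBP) so that the editor deposits mutations on the transcripts the
RBP touches (the STAMP / TRIBE family of methods). Sequencing then reads the
protein's footprints directly off the RNA: C>T and A>G mismatch pileups mark
binding sites, and their density is a quantitative signal. The same trick
applied to a ribosomal protein turns editing density into a translation
proxy. Making this work requires a stack of statistical machinery — edit
calling from pileups, cluster detection against a background editing rate,
enzyme sequence-bias characterization, per-gene edits-per-read statistics,
and enrichment testing against orthogonal binding data. `rbekit` implements
that stack, together with a generative simulator that produces reporter
constructs, toy transcriptomes, and edited reads with complete ground truth,
so every stage is testable without any external data download.

It is written for computational biologists who design or analyze
tethered-editing experiments and want calibrated, reproducible statistics
at desk scale.

## Core statistics

**Edit calling.** From a base-quality-filtered pileup, a candidate C-to-U
site at a reference-C position with coverage *n* and *k* alternate (T) reads
gets a Beta-posterior confidence

> conf = P(θ > ε | k, n) with θ ~ Beta(k+1, n−k+1),

the posterior probability under a flat prior that the true editing fraction
θ exceeds the sequencing-error rate ε (default 10⁻³). Sites with
conf > 0.9 count as high-confidence (A-to-I is symmetric with A→G).

**Cluster calling.** Confident sites are tallied into 30-bp bins tiled from
each gene's 5′ end. With background rate *b* = mean editing fraction across
bins and *m* editable substrate positions in a bin, the bin's edited-site
count *k* is tested against Poisson(λ = b·m), one-sided upper tail
p = P(X ≥ k). Benjamini–Hochberg adjustment is applied across bins, bins
with q < 0.1 are kept, bins ≤ 15 bp apart are merged, clusters must
replicate in all three replicates (≥ 1 bp overlap), and clusters that also
appear with the free (unfused) editor are subtracted as background.

**Context bias.** Each enzyme's 16-dimensional vector of (upstream,
downstream) flanking-base counts at confident sites is normalized to
proportions, mean-centered, and decomposed by PCA; loadings separate
A/U-preferring from G/C-preferring enzymes. A two-layer 1-D convolutional
network (16 filters of width 8 per layer, global max pooling, sigmoid
output; binary cross-entropy with early stopping) classifies 200-bp one-hot
cluster windows by enzyme of origin, scored by rank-statistic AUC.

**Translation.** Per gene, EPR = edited-base observations / assigned reads.
Treated-vs-control contrasts use Welch t-tests on replicate EPRs with BH
correction; gene groups (e.g. TOP-like mRNAs) are contrasted on log2
fold-changes.

**Interval enrichment.** Overlap of cluster sets with reference peak sets
is tested by permutation: each cluster is re-placed uniformly in the
transcribed domain, and p = (1 + #{null ≥ observed}) / (1 + N) with the
add-one rule.

## Worked example

```bash
python analysis/02_fusion_clusters.py --seed 1 --outdir results
```

prints (abridged):

```
Cluster summary per enzyme:
enzyme  replicable_clusters  free_clusters  clusters_after_subtraction  genes  motif_presence_fraction
c2u_au                   21              0                          21     19                 0.952381
a2i_gc                   22              0                          22     19                 0.909091

Permutation overlap with reference binding peaks:
  "combined": { "observed": 1.0, "null_mean": 0.134, "p_value": 0.00498, "enrichment": 7.45 }
```

Reading this: each simulated RBP-fusion editor yields ~20 replicable edit
clusters after free-editor background subtraction, >90% of them contain the
planted RBP motif, and the combined cluster set overlaps the reference
binding peaks far more often than randomly placed size-matched intervals
(p = 1/201, the smallest value 200 permutations allow, ~7-fold enrichment
over the null mean). The other drivers follow the same pattern:
`01_reporter_screen.py` (reporter profiles, spillover, on/off-target
ratios), `03_translation_epr.py` (TOP-gene EPR repression),
`04_cluster_statistics.py` (caller calibration and power),
`05_context_and_classifier.py` (context PCA and CNN),
`06_overlap_permutation.py` (permutation-test calibration).

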