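# Methods

This note documents the generative models, statistical procedures, default
parameters and design choices behind `rbekit`, and what the simulation
studies do and do not establish about real data.

## Generative models

### Reporter constructs

A reporter is a 720-bp random coding sequence (ATG…TAA, ~50% GC) followed
by a synthetic 3′UTR assembled from 50-bp random linkers and fixed 22-nt
stand-in stem-loop sequences for the MS2 and PP7 hairpins. The hairpin
sequences are synthetic placeholders — only their coordinates matter to any
downstream computation. Four layouts are provided: twelve MS2 loops with
50-bp linkers (`MS2x12`); MS2/PP7 pairs 50 bp apart separated by 350-bp
spacers (`PAIRED_350`, three pairs, chosen so the construct length is
comparable to the 12-loop designs); and twelve or four alternating MS2/PP7
loops 50 bp apart (`ALT12`, `ALT4`). Construct assembly is a pure function
of (layout, seed).

### Enzyme model

An editor is described by: edit channel (C-to-U, A-to-I, or both with
independent rate sets); `peak_rate`, the per-read probability that an
editable base at the center of a bound site is edited; a recruitment kernel
over distance *d* (bp) from the nearest bound-site midpoint — Gaussian
exp(−d²/2h²) truncated at 4h, or flat 1{d ≤ h} — with halfwidth `h` in bp;
`background_rate`, the per-read per-base off-target editing probability on
untethered RNA; and `context_weights`, multipliers in [0,1] over the 16
(upstream, downstream) flanking-base pairs. Context weights multiply both
the recruited and the background term, because flanking-base preference is
a property of the catalytic domain, not of recruitment — this is what makes
free (unfused) editors carry the same sequence signature as fusions. The
two terms combine as independent chances,
p = 1 − (1 − peak·kernel·w)(1 − background·w), which is bounded by 1 by
construction. The helper weight sets `au_rich_weights(r)` /
`gc_rich_weights(r)` assign 1 to favored flanks and r^(−1/2) per disfavored
flank, so a doubly disfavored context is r-fold down (default r = 10).

### Transcriptome and reads

The toy transcriptome has one transcript per gene in transcript space
(each gene is its own reference): a 20-bp leader, a CDS (normal lengths,
default 900 ± 300, floored and rounded to codons), and a 3′UTR (500 ± 150).
A configurable fraction of genes is TOP-flagged and receives a pyrimidine
tract at the 5′ end; a fraction of genes gets 1–3 copies of a planted
binding motif (default GCAUG, written GCATG in DNA alphabet) in the 3′UTR,
with all planted positions recorded. `plant_bound_sites` places recruitment
sites in a chosen region, optionally resampling the local sequence
composition around each site; this emulates the empirical observation that
different enzymes' clusters live in compositionally distinct neighbourhoods
(A/U-rich versus G/C-rich). Reads are single-end 100 bp, sense strand,
ungapped, drawn uniformly (or weighted) across references; each editable
base is flipped independently with its per-position probability, then an
independent substitution-only sequencing-error process (default 10⁻³ per
base) runs after editing. Every introduced edit is recorded per read; an
error that later hits an edited base may revert the observed base, so the
exact read/truth conservation invariant is asserted at error rate 0.

### Translation simulator

Per condition, each gene's per-position edit probability is scaled so the
expected edits per read equals load × `epr_scale` exactly (normalized
against the uniform read-coverage profile), with CDS substrate positions
weighted `cds_bias`-fold (≥ 1) over 3′UTR positions. The default treated
condition divides TOP-gene loads by 4 and all others by 1.25. Reads per
gene are multinomial with equal expectation (`reads_per_gene`).

## Statistical procedures and numerical choices

* **Confidence score.** P(θ > ε) under Beta(k+1, n−k+1); computed as a
  regularized incomplete beta function (scipy `beta.sf`). At 50× coverage
  even a single alternate read is confident when ε = 10⁻³ — separating true
  edits from sequencing errors at that depth is the cluster stage's job,
  not the site caller's.
* **Binning.** Fixed 30-bp tiling anchored at the gene's 5′ end (right edge
  for minus-strand genes); terminal partial bins retained. The pipeline
  tiles *every* bin of genes that exhibit at least one edit, including
  zero-count bins. Restricting to edited bins only (available as
  `keep_empty=False`, the `bin_edits` default, matching the per-bin
  contract) conditions the background mean on observing an edit and biases
  it upward severely at moderate depth; the gene-region interpretation
  keeps the Poisson null calibrated. Editable positions are substrate bases
  with coverage ≥ 5 (`min_coverage`).
* **Edit counts per bin** are confident edited *sites* by default (units
  match the background "fraction of editable substrate positions edited");
  an edited-read-count mode is the natural alternative and the site-count
  choice is the one whose calibration we verify.
* **Poisson test.** λ = background × editable; when the background estimate
  is exactly 0, λ is floored at 10⁻⁶ × editable to avoid p = 0 artifacts.
  p = P(X ≥ k) via the survival function.
* **BH adjustment** uses statsmodels' step-up implementation behind the
  `bh_adjust` surface; q < 0.1 is strict.
* **Merging** joins kept bins with inter-bin gap ≤ 15 bp; cluster p and q
  are the minima over member bins (a min is reported, not a combined test —
  cluster-level inference rests on the member bins).
* **Replicate intersection** keeps a first-replicate cluster iff it
  overlaps ≥ 1 bp with a cluster in every other replicate, reporting the
  first replicate's coordinates.
* **PCA** operates on proportion-normalized, mean-centered context vectors
  without unit-variance scaling (counts are compositional; raw per-context
  contributions are wanted in the loadings), via full SVD with a
  deterministic sign convention (largest-magnitude loading positive).
* **CNN.** Two 1-D convolution layers (16 filters × width 8 each), ReLU,
  global max pooling, one sigmoid unit; binary cross-entropy, Adam
  (lr 3·10⁻³, batch 64), 70/15/15 stratified splits, early stopping when
  validation loss improves < 10⁻⁴ for 5 consecutive epochs, 80-epoch cap.
  Implemented directly on numpy with hand-written gradients (verified
  against finite differences in the test suite), which makes training
  bit-deterministic for a fixed seed on one CPU. AUC is the Mann–Whitney
  rank statistic with midranks for ties, identical to trapezoidal ROC
  integration.
* **EPR statistics.** Genes enter comparisons when quantifiable (read
  count ≥ 10) in every replicate of both conditions. Welch t-tests on
  replicate EPRs; log2FC uses an offset of 10⁻⁶; the degenerate
  zero-variance/equal-means case is reported as p = 1. The group contrast
  is a Welch t-test of log2 fold-changes, group versus complement, oriented
  so positive t means the group decreased more. Region EPRs assign a read
  to CDS or 3′UTR by its alignment midpoint (avoids double counting across
  the junction) and count edited-base observations at positions in that
  region; the group-level figure is the ratio of means, with the per-gene
  ratio distribution also returned.
* **Permutation test.** Null placement re-draws each query interval,
  length preserved, uniformly over all valid start positions across the
  domain regions (the transcribed regions by default). Empirical p uses the
  add-one rule and is therefore never 0; with N permutations the smallest
  attainable value is 1/(N+1).

## Simulation studies (frozen designs)

Study conditions were fixed by analytic power calculation before the
studies were run and are not tuned afterwards.

* **Null calibration:** 12 background-only libraries (20 genes ≈ 620 bp,
  background 2·10⁻³ per read per base, 50× depth, no sequencing error),
  ~5,000 bins pooled; the per-bin false-positive fraction is compared to
  nominal α, and the 4 replicate-triplets are intersected.
* **Power:** 100 simulations, each with one 8-bp site planted in a C-rich
  (45% C) neighbourhood in the covered body of one transcript among 10,
  flat kernel of halfwidth 30 bp so a full 30-bp bin is elevated regardless
  of bin phase, site edited at 20× the 2·10⁻³ background, 50× depth;
  success = a q < 0.1 cluster covers the site midpoint. The C-rich
  neighbourhood and bin-spanning kernel are what make a 30-bp bin
  informative at this depth: ~12 editable positions at per-site editing
  probability ≈ 0.87 against λ ≈ 1.
* **Fidelity:** 20 genes, 20 planted sites, 100× depth, error-free reads;
  false positives are confident calls at zero-probability positions, recall
  is over truth positions with per-read rate ≥ 0.1 and coverage ≥ 5.
* **Context recovery:** two free editors (background 2·10⁻³) with 10:1
  A/U- versus G/C-favoring weights, 3 replicates each at 30× depth.
* **Classifier:** 450 sites per enzyme on disjoint gene subsets, each in a
  window-wide (±96 bp) A/U-rich or G/C-rich neighbourhood; 200-bp windows;
  held-out AUC and a permuted-label control. Disjoint gene subsets prevent
  the two enzymes' neighbourhoods from overwriting each other.
* **EPR:** 200 genes, 3 replicate pairs, 40 reads/gene, lognormal control
  loads around 0.1 edits/read, TOP genes 4-fold down under treatment (or a
  matched null with equal loads).
* **Permutation calibration:** 100 null trials of 120 query intervals
  (20 bp) against 80 subject peaks (60 bp) on 20 × 500 bp transcripts at
  200 permutations. The large query set keeps the overlap-fraction lattice
  fine; with coarser query sets the inclusive-tie add-one p is visibly
  conservative and the KS distance from uniform grows.

Problem sizes throughout (gene counts, depths, replicate numbers) are desk
scale: large enough for the statistics to stabilize, small enough that the
entire suite and the acceptance script each run in a couple of minutes on
one CPU.

## What the simulations do not show

The generator emulates editing statistics, not sequencing reality: no
splicing or isoforms, no paired-end reads, no PCR duplicates, no indels, no
mapping ambiguity (reads are placed, not aligned), no SNV contamination
(the caller's SNV mask is exercised only on toy inputs), uniform base
quality, and transcript-space coordinates with one gene per reference.
Passing studies therefore establish the correctness and calibration of the
statistical machinery under the stated model, not robustness to alignment
artifacts or library-preparation biases. Cluster counts, AUCs and t
statistics from the simulations are properties of these study conditions
and are not comparable in magnitude to values obtained from full-scale
sequencing datasets.

## Other design choices

* Dual-editor interference (two enzymes tethered to the same construct) is
  modeled, if desired, as a multiplicative factor ≤ 1 on the recruited
  rate; the default is 1 (off), since no quantitative magnitude is
  established for it.
* Libraries are treated as stranded-sense by default; the antisense option
  complements substrate and product bases in reference coordinates (C-to-U
  appears as G>A).
* The on/off-target ratio counts edited read-base observations (alt-read
  counts summed over confident sites), not site counts, and is reported
  both per replicate and pooled across replicates.
* "Edit spillover" is the fraction of edited-base observations on the CDS;
  it is undefined (NaN), not zero, for a construct without edits.
* The reporter's off-target compartment in simulation is the toy
  transcriptome.
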