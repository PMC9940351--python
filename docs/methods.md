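# Methods

## Background and scope

`soluseq` analyses experiments that fractionate a cell lysate into a
*soluble* pool and a *total* pool (which additionally contains insoluble
mRNAs) and sequence both with two assays: RNA-Seq for abundance and 5'P-Seq
for 5'-monophosphorylated decay intermediates. During co-translational
5'→3' decay the exonuclease trails the last translating ribosome, so 5'P
ends accumulate ~17 nt upstream of the ribosome A-site and carry a 3-nt
periodicity; their codon-resolved depth reads out relative ribosome
dwelling. A fixed amount of foreign-species RNA (spike-in) added to every
sample anchors normalization between assays. The package covers the
quantitative layer only: it consumes aligned 5'-end positions (BAM/SAM or
BED) and annotation, never raw reads. Adapter trimming, UMI handling,
alignment and PAR-CLIP transition calling are upstream and out of scope.

## Coordinate and counting conventions

Internal coordinates are 0-based, half-open; GFF3 input (1-based, closed)
is converted at the parser. Transcript coordinate 0 is the A of the start
codon; codon *k* occupies nucleotides [3k, 3k+3). The 5' end of a
plus-strand read is its leftmost aligned base, of a minus-strand read its
rightmost; antisense reads are ignored and only primary alignments counted.
A 5'P CDS count is the number of 5' ends inside the (spliced) CDS; an
RNA-Seq CDS count is the number of reads overlapping the CDS by ≥1 nt.
Genes with overlapping same-strand CDSs receive a shared end in both.
Intron-containing genes are handled as spliced CDS coordinates.

Frame *k* means (transcript position mod 3) = k. Because codon starts are
≡ 0 (mod 3) and −17 ≡ 1 (mod 3), ribosome-delimited 5'P ends fall in frame
1; this is the quantity reported by `dwell.frame_fractions` (computed on
unshifted ends).

## Differential statistics

Both headline per-gene quantities are log2 fold changes of negative-
binomial counts:

* **solubility** = log2FC of soluble over total RNA-Seq counts within a
  condition, normalized with *library* (target-species) median-of-ratios
  size factors — solubility is a within-species compositional ratio, so
  spike factors would be wrong here. A switch (`normalization='spike'`) is
  provided.
* **relative degradation** = log2FC of 5'P over RNA-Seq counts for the same
  condition and fraction, normalized with median-of-ratios factors computed
  **on the spike-in genes only**, so genuine genome-wide changes in the
  degradome are retained. Doubling all target 5'P counts with the spike
  fixed must shift every LFC by +1; doubling target and spike together must
  change nothing — both contracts are asserted in tests.

The contrast itself (`differential.nb_contrast`) is deliberately minimal:
normalized group means, LFC with a 0.5 pseudocount, and a delta-method
standard error Var(log m) = (1/μ + α)/n per group. The NB dispersion α is
estimated by method of moments per gene but used only through a
mean-dispersion trend α(μ) = a0 + a1/μ fitted by least squares across all
genes (floored at 0.01): with 2–3 replicates, gene-wise dispersions are far
too noisy to calibrate a Wald test, whereas the trend pools thousands of
genes, which justifies the normal reference for the Wald p-value. Under a
simulated NB null (2000 genes, 3 vs 3) the type-I error at α = 0.05 is
0.045–0.053. No LFC shrinkage, no outlier refitting, no independent
filtering — only a count floor (10 normalized counts summed per contrast;
below it a gene is reported NA).

The **ratio-of-ratios (interaction) test** is the z-contrast of two
independent LFCs: estimate = LFC_A − LFC_B, SE = √(SE_A² + SE_B²). This has
the same estimand as a four-sample GLM interaction term but a closed,
testable form. Category calls combine it with fold-change cutoffs
(defaults α = 0.05, cutoff 0.5): *red* = significant interaction, change
< −0.5 upon Not1 depletion and > +0.5 upon Not4 depletion; *green* the
mirror image; *orange*/*blue* = non-significant interaction with both
changes positive/negative (control groups); everything else *none*.
High/low solubility flags use the disjunctive rule (log2FC > 0 and
FDR < 0.05) or (log2FC > 1 and p < 0.05), and its mirror.

Shared primitives: Welch's t (Welch–Satterthwaite df), Wilcoxon rank-sum
(exact when both n ≤ 20 and tie-free, tie-corrected normal otherwise),
Pearson r with a t-test on n−2 df (groups < 30 refused by default),
Benjamini–Hochberg step-up FDR, and an upper-tail hypergeometric
over-representation test over flat gene sets.

## Codon dwelling occupancy and profiles

`dwell.rdo` computes, for each of the 61 sense codons, the mean 5'P depth
17 nt upstream of its occurrences (codons whose start lies before nt 17
contribute no positions) divided by the same mean over all codons, so the
position-weighted mean occupancy is exactly 1 — asserted after every call.
The stop codon is excluded; the stop peak is visible in the stop-anchored
metagene instead. Library scaling cancels in the ratio (tested). The
differential RDO is the per-codon log2 ratio of two normalized tables, and
`tai_analysis` relates it to codon optimality: Pearson r against tAI over
all codons plus a one-sided rank-sum test that the 15 least-optimal codons
(lowest tAI) exceed the 15 most-optimal. A gene-copy tAI table for budding
yeast ships with the package; any codon→tAI TSV can be substituted.

Anchored metagenes aggregate 5'-end depth around the first nucleotide of
the start or stop codon after shifting ends +17 nt (A-site equivalence),
scaled per million mapped ends. Scaled metagenes split every CDS into
20 or 100 equal bins, average bin means across transcripts, and divide by
the mean depth over all nucleotides of the group (uniform coverage → flat
1.0). Window proportions report the fraction of a gene's CDS reads in the
10–30%, 40–60% and 70–90% fractional windows (half-open in fraction
space), including a transcript only if it has ≥ 20 5'P reads in *both* the
soluble and total library. A 150-nt 3' mask for the known insert-size
artifact is available but off by default.

## PAR-CLIP and ChEC

Cross-link density = (T→C transitions / T count) per million total
transitions; NA when a region has no T. The Not4-vs-RNAPII comparison fits
a least-squares line of log2 Not4 density on log2 RNAPII density over
regions with both densities positive and classifies residuals beyond
±log2(fold_cutoff) (default twofold) as higher/lower than expected.

ChEC promoter windows span 400 bp upstream to 100 bp downstream of the +1
nucleosome (strand-aware, 501 bp, clipped-and-flagged at contig edges).
Counts become RPKM; the log2 ratio over the free-MNase control (0.5 RPKM
pseudocount) is centered on its estimated mode so the unbound bulk sits at
zero. The mode is estimated by fitting a log-normal to 2^LFC (strictly
positive by construction) and returning log2 of exp(μ−σ²); a KDE-argmax
fallback is available. On log2 draws of a lognormal(0,1) the estimator
returns −1.443 (analytic mode) within ±0.02 at n = 10⁴. The fit is mildly
biased when an enriched subpopulation fattens the right tail — with 10% of
promoters at 4× the planted set centers at ≈ 2.05 rather than 2.00 — a
property inherited from the mode-fitting procedure itself. No significance
threshold is hard-coded for "bound" promoters; callers threshold the
centered LFC or its quantiles.

## The simulator

`simulate.SimulationConfig` defines a complete experiment with known ground
truth; identical config + seed gives byte-identical files (verified by
manifest digests). Default study conditions: 300 target + 40 spike genes,
CDS 300–1500 nt with uniform sense-codon usage, log-normal expression
(σ = 0.8), 4 conditions × 2 fractions × 2 assays × 3 replicates, and mean
CDS counts of 300 per library.

* **Solubility**: each gene has s_g ∈ (0.2, 0.8); the total pool contains
  all molecules, the soluble pool a binomial thinning by s_g. Planted
  *red* genes shift s by −1 log2 unit upon Not1 depletion and +1 upon Not4
  depletion (green mirrored; Not5 ±0.2, tracking the Not4 direction). True
  solubility LFCs are stored both per condition (log2 s_cond/s_WT) and
  within-condition relative to the median gene, which is what a
  library-normalized soluble/total contrast estimates.
* **Degradation**: per-condition/fraction factors multiply 5'P means only
  (soluble pool: ×0.6 upon Not1, ×1.5 upon Not4, ×1.2 upon Not5 depletion;
  total pool: ×1.1–1.15), with library depth held fixed so the shift is
  carried by the spike-in share — exactly the situation spike
  normalization exists for.
* **5'P placement**: with probability π (0.75 total, 0.55 soluble) an end
  sits 17 nt upstream of a codon drawn ∝ exp(−a·tAI) (a = 3, halved in the
  soluble pool) times a linear positional ramp modelling decay-onset delay
  (slope 1 in the total pool); otherwise uniform over the CDS. π is exposed
  rather than fixed because the real periodic:background mixture is
  unknown.
* **Replicate noise**: NB with dispersion 0.005 for both assays. The
  emulated design splits one lysate into fractions and spikes each library
  identically — technical-quality replication (cv ≈ 7%). This is the one
  parameter the recovery guarantees are sensitive to: with biological-scale
  dispersion (≥ 0.02) no estimator could reach rank correlation 0.95 at
  n = 3 and mean count 300, by straightforward attenuation.
* **ChEC / PAR-CLIP**: Poisson counts around length-proportional
  backgrounds; 10% of promoters enriched 4×; 10%/5% of PAR-CLIP regions at
  4×/0.25× the shared per-region cross-link rate (beyond-twofold classes).
  A subset at exactly 2× would sit on the twofold decision boundary where
  recall is 50% by construction, so the planted deviation is 4×.

What the simulator does **not** model: sequencing error, UMI duplication,
alignment ambiguity, 5'UTR/3'UTR sequence, rRNA contamination, overlapping
genes, nucleosome positioning, and the insert-size depletion of the last
~150 CDS nt. Passing recovery tests therefore demonstrate estimator
correctness under the stated generative model, not robustness to these
real-data artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script use 300–2400 genes, ~10⁵–10⁶ 5'P
ends, 1000–2000 promoters/regions — sizes at which every stochastic
guarantee has comfortable margin while a full run stays in seconds.
Tables are written with %.6g floats for byte-stable output. Degenerate
inputs fail loudly: empty spike partition, zero-target samples, zero
libraries, empty transcript filters and invalid configs all raise
ValueError with the offending name.
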