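# soluseq

Solubility-resolved 5'P degradome analysis for budding yeast-style
experiments: which mRNAs are soluble, which are being degraded
co-translationally, and how ribosome dwelling at non-optimal codons differs
between the soluble and total RNA pools.

The package is aimed at computational biologists working with paired
RNA-Seq / 5'P-Seq libraries of soluble vs total lysate fractions across
conditions (here WT plus depletion of the Ccr4-Not subunits Not1, Not4,
Not5), with a foreign-species spike-in, optionally complemented by
PAR-CLIP cross-linking and ChEC-seq promoter data. It consumes aligned
5'-end positions (BAM/SAM or BED), annotation (GFF3 + FASTA) and count
tables — never raw reads.

## The quantities it computes

For gene *g* with CDS counts *K* (median-of-ratios normalized):

* **Solubility** `sol_g = log2( K_RNA,soluble / K_RNA,total )` within a
  condition, with library (target-species) size factors.
* **Relative degradation** `deg_g = log2( K_5P / K_RNA )` for one
  condition and fraction, with size factors from the **spike-in species
  only**, so genome-wide degradome shifts survive normalization.
* **Interaction (ratio-of-ratios)** `Δ = LFC_A − LFC_B`,
  `SE = sqrt(SE_A² + SE_B²)`, z-test + BH FDR; category calls (red / green /
  orange / blue) combine interaction significance with ±0.5 fold-change
  cutoffs on the solubility changes upon Not1 and Not4 depletion.
* **5'P-RDO** (ribosome dwelling occupancy): for each sense codon, the mean
  5'P depth 17 nt upstream of its occurrences, normalized so the
  position-weighted mean over all codons is 1; differential RDOs are
  compared with the tRNA adaptation index (tAI), including the one-sided
  rank-sum test of the 15 least- vs 15 most-optimal codons.
* Start/stop-anchored and CDS-scaled **metagene profiles**, reading-frame
  fractions of unshifted 5' ends, and windowed read proportions
  (10–30 / 40–60 / 70–90 % of the CDS, ≥20-read filter).
* **PAR-CLIP density** (T→C transitions per T, per million transitions) and
  classification of regions deviating ≥twofold from the Not4~RNAPII trend;
  **ChEC** promoter-window RPKM log-ratios over free MNase, mode-centered
  via a log-normal fit.

A fully seeded simulator (`soluseq.simulate`) generates complete
experiments — two-species transcriptome, all 48 libraries, ChEC and
PAR-CLIP tables — with ground truth for every estimator, which is how the
whole pipeline is verified without any external data.

## Worked example

```bash
soluseq simulate --seed 1 --out sim/
soluseq report --data sim/ --out results/
```

or equivalently in Python:

```python
from soluseq.simulate import SimulationConfig, simulate_experiment
from soluseq.pipeline import run_report

simulate_experiment(SimulationConfig(seed=1), "sim")
summary = run_report("sim", "results")
```

The report writes one TSV per analysis (solubility and relative-degradation
contrasts per condition/fraction, interaction test, categories, RDO tables,
metagenes, frame fractions, window proportions, ChEC signal, PAR-CLIP
classes) and prints a summary; with seed 1 and default settings:

```json
{
 "category_counts": {"blue": 145, "none": 67, "green": 30, "red": 29, "orange": 29},
 "tai_pearson_r": -0.9936664940562608,
 "tai_wilcoxon_p": 6.44672503789385e-09,
 "frame1_wt_total": 83.20950911363362,
 "n_genes_windowed": 300,
 "chec_mode": -0.4445920865383872,
 "parclip_class_counts": {"expected": 821, "higher": 110, "lower": 69}
}
```

Reading this: the 30 planted "green" and 30 planted "red" genes are
recovered almost exactly (29/30 each; orange/blue are the non-significant
control groups, which soak up null genes by design). The differential RDO
between the total and soluble pools anticorrelates with codon optimality
(r = −0.99; rank-sum p = 6.4e-9, the smallest value achievable with 15+15
codons), because the simulator dwells ribosomes as exp(−a·tAI) with a
stronger effect in the total pool. 83.2% of 5'P ends fall in frame 1,
matching the configured 75% periodic fraction plus a third of the uniform
background (75 + 25/3 = 83.3). The ChEC log-ratio mode of −0.44 reflects
the depth shift caused by the 10% of promoters enriched 4-fold; after mode
centering those promoters sit at ≈ +2 log2 units.

## Layout

```
src/soluseq/
  core_io.py     annotation, 5'-end tracks, CDS counts, spike split
  simulate.py    seeded generator + ground truth
  differential.py  size factors, NB contrasts, interaction, categories
  dwell.py       RDO, tAI analysis, metagenes, windows, frames
  crosslink.py   PAR-CLIP density/classes, ChEC windows and mode-centering
  stats.py       Welch t, rank-sum, Pearson test, BH FDR
  pipeline.py    end-to-end report
  cli.py         `soluseq` command-line interface
  data/tai_yeast.tsv  bundled gene-copy tAI table
docs/methods.md  model, conventions, parameter choices, limitations
```
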