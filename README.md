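# stratomics

Spatial transcriptome–proteome integration for laminated brain tissue.

Neurons distribute their molecular machinery unevenly across compartments:
in hippocampal area CA1, the strata SO, SP, SR and SLM hold basal dendrites,
somata, proximal and distal apical dendrites, each with its own synaptic
inputs. Mapping which mRNAs and proteins are enriched where — and whether a
protein's spatial profile follows its mRNA's — requires a pipeline that
joins count-based RNA-seq statistics, intensity-based DIA proteomics
statistics, and a set of integrative analyses on top. `stratomics` is that
pipeline as a reusable, tested Python library, exercised end-to-end on
synthetic data with a planted ground truth.

## What it computes

* **Differential enrichment.** RNA counts: negative-binomial GLM with
  median-of-ratios size factors `s_j`, moment-based dispersions shrunk to a
  robust `a0 + a1/mu` trend, and a two-sided Wald test on
  `K_gj ~ NB(s_j q_g 2^{beta_{g,c}}, alpha_g)`. Protein log2 intensities:
  per-protein linear model with empirical-Bayes variance moderation,
  `s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)`, t with `d0 + d_g` df.
  Enrichment calls at `q < alpha` (BH) and `|log2FC| >= 0.1`, per pairwise
  or one-vs-rest compartment contrasts.
* **Synaptosome contaminant filtering.** Sorted (P3) vs unsorted control
  (P2) fractions per compartment; features enriched in P2 anywhere are
  compiled into a contaminant list and removed before synaptic comparisons.
* **Normalization / iBAQ.** Robust-linear-regression (rlr) normalization of
  intensities against the median reference profile; iBAQ = intensity
  divided by the count of theoretical Trypsin/P peptides of length 7–35.
* **mRNA–protein integration.** Population-level Pearson correlation of
  mean abundances; per-gene profile correlation across the 4 strata with
  strong-coupling classes (`r >= 0.9` / `r <= -0.9`); protein half-life
  comparisons across classes by tie-corrected Kruskal–Wallis with Dunn's
  post hoc z tests; co-enrichment cross-tabulation with translatome
  (soma/neuropil) proportions; row-wise z-scored fold-change distributions
  for gene sets.
* **Overrepresentation analysis.** One-sided hypergeometric test against a
  custom background with BH control.
* **PLS-DA.** NIPALS PLS2 on autoscaled complete cases, stratified repeated
  3-fold cross-validation with oneSE component selection, and VIP scores
  (`mean(VIP^2) = 1`, scaled 0–100).
* **Synthetic data.** A generator that plants per-stratum enrichments,
  coupling classes, abundance-linked missing values, contaminants,
  half-life structure and translatome labels — every downstream stage has a
  recoverable truth.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

```python
from stratomics.pipeline import RunConfig, run_pipeline, evaluate_against_truth
from stratomics.simulate import SimConfig

cfg = RunConfig(sim=SimConfig(n_genes=500, seed=7), seed=7)
res = run_pipeline(cfg)            # simulate -> normalize -> DE -> filter
s = res["summary"]                 #   -> PLS-DA -> integrate -> ORA
print("enriched mRNAs per stratum:", s["enriched_mrna_per_compartment"])
print("correlation classes:", s["correlation_classes"])
print("pooled mRNA-protein r: %.3f" % s["population_correlation"]["pooled"])
```

prints

```
enriched mRNAs per stratum: {'SLM': 50, 'SO': 50, 'SP': 51, 'SR': 50}
correlation classes: {'neither': 292, 'positive': 114, 'negative': 94}
pooled mRNA-protein r: 0.307
```

The generator planted 50 enriched genes per stratum (10% of 500 per
compartment, +1 log2); the one-vs-rest Wald test at q < 0.01 recovers them
essentially exactly (`evaluate_against_truth(res)` reports sensitivity
1.000 at FDR 0.005 here). 114 genes are classed as strongly positively and
94 as strongly negatively coupled, recovering the planted 20%/15% coupling
fractions; the pooled cross-gene mRNA–protein correlation of 0.31 reflects
the generator's modest population-level coupling (r = 0.35) after
measurement noise. Downstream, the half-life rank test on the same run
gives H = 61.4 (df 2, p = 4.7e-14) with positively coupled genes turning
over faster, and PLS-DA separates the four strata with cross-validated
accuracy 1.000 at 3 components.

The same analyses are available from the shell:

```sh
stratomics simulate --seed 7 --out bundle/
stratomics run-all --seed 7 --out run/
stratomics plsda --table run/protein_log2.tsv --meta run/rna_meta.tsv --out plsda/
```

Every product is a TSV; `summary.json` holds the headline numbers and
`manifest.json` the config, seed and version. Reruns with the same config
and seed are byte-identical.

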