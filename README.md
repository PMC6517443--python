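# linchk

`linchk` identifies and annotates **housekeeping long intergenic noncoding
RNAs (HK-lincRNAs)**: lincRNAs that are ubiquitously expressed across
tissues with low expression variability, and that behave like core
essential genes in tumours (rarely down-regulated, deleted or silenced).
It is written for computational biologists who want a tested, reusable
implementation of this multi-evidence annotation strategy that can be
exercised end to end on synthetic data with planted ground truth — no
external cohort downloads required.

## The method

The pipeline chains seven analyses:

1. **Classification.** From a genes × tissues abundance matrix (FPKM-like),
   a gene is *detected* in a tissue iff its tissue-mean expression is
   strictly above 0.5. With CV = sd/mean (sample sd, over all tissue
   means), genes detected in ≥ 75 % of tissues with CV < 1.5 are
   candidate housekeeping (cHK); genes detected in < 25 % of tissues with
   CV > 3.5 are tissue-specific (TS). lincRNAs ≤ 1 kb from a
   protein-coding gene are excluded first.
2. **Sequence features.** Exon-restricted mean conservation, SNP density
   (SNPs per kb of exon union) and per-class repeat coverage; orthologue
   calls from best alignment hits at ≥ 30 % identity, with expression CV
   in each other species.
3. **Structure.** A Randfold-style permutation test: the folding score of
   each transcript (Nussinov base-pair maximisation, lower = more stable;
   an external thermodynamic engine can be plugged in) is compared with
   scores of dinucleotide-preserving shuffles (Altschul–Erickson Eulerian
   construction); p = (1 + #{null ≤ observed})/(N + 1), BH-FDR across genes.
4. **Tumour refinement.** cHK genes are kept as **core HK** only if they
   are *not* significantly down-regulated in any tumour type
   (|FC| > 2 and q < 0.05, both strict), *not* recurrently homozygously
   deleted (≥ 1 % of samples, inclusive), and *not* inside a focal
   deletion region.
5. **Methylation.** Probe betas are averaged over the promoter window
   (−2000 bp to +200 bp around the strand-aware TSS) and gene groups are
   compared by per-sample median beta (paired Wilcoxon signed-rank).
6. **Function prediction.** Protein-coding genes are ranked by Pearson
   correlation to each lincRNA; preranked GSEA (weighted
   Kolmogorov–Smirnov ES, gene-label permutation null, sign-matched NES,
   pooled-null FDR) finds associated gene sets; terms significant in
   ≥ 10 % of lincRNAs are reduced to non-redundant representatives via
   Wang semantic similarity and an average-linkage tree cut at h = 0.85.
7. **Survival.** Patients are split at the 75th expression percentile
   (upper quartile = "high"); Kaplan–Meier curves and a log-rank test
   compare the groups.

A synthetic-data module generates every input with planted truth
(ubiquitous/low-CV genes, tissue-restricted genes, inverted-repeat stems,
tumour DE/CNA events, group-shifted methylation betas, pathway-driven
co-expression, expression-dependent hazards), so each stage's recovery,
calibration and power can be measured.

## Worked example

```bash
linchk demo --seed 7 --out linchk_demo
```

generates a 200-gene × 16-tissue cohort (50 planted HK, 50 TS, 100
background) plus all downstream inputs, runs all seven stages, and prints:

```json
{
 "clean_hk_funnel_recall": 1.0,
 "function_lincRNAs_tested": 3,
 "function_planted_term_recovered": 3,
 "function_terms_kept": 6,
 "funnel": {
  "candidate_HK": 50,
  "core_HK": 30,
  "lincRNAs_input": 200,
  "retained_after_proximity": 190,
  "tissue_specific": 52
 },
 "methylation_paired_p": 1.8189894035458565e-12,
 "seed": 7,
 "structure_significant": 25,
 "structure_tested": 50,
 "survival_logrank_p": 1.495520804136381e-06
}
```

Reading the funnel: of 200 input lincRNAs, 190 survive the 1 kb
proximity filter (10 were planted next to coding genes), 50 are called
candidate HK and 52 tissue-specific; tumour evidence (planted
down-regulation in 25 % and deletions in 15 % of the cHK set) reduces the
candidates to 30 core HK genes. Every planted clean housekeeping gene
(HK-planted, no tumour event) is recovered (`clean_hk_funnel_recall`
= 1.0). The structure stage finds exactly the 25 planted stem-bearing
sequences significant; the methylation and survival p-values reflect the
planted low-beta promoter shift and the hazard ratio of 2 between
expression groups. Per-stage tables (`classification.tsv`,
`structure.tsv`, `core_hk.tsv`, `km_curves.tsv`, ...) and `truth.json`
are written under `linchk_demo/`.

Every stage is also exposed as a subcommand on real files
(`linchk classify`, `features`, `structure`, `refine`, `methylation`,
`function`, `gsea-ranked`, `survival`, `simulate`, `run`); see
`linchk <cmd> --help` for the input column contracts.

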