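# Methods

This note documents the models, conventions and design choices behind
`linchk`, stage by stage, including what the synthetic-data generators
do and do not emulate.

## Coordinates and shared statistics

All genomic coordinates are 0-based half-open internally; GTF input
(1-based inclusive) is converted at the I/O boundary, so a GTF exon
`start=1,end=10` becomes `[0, 10)`. Interval intersection counts each
base once after per-chromosome merging; abutting half-open intervals
share no base.

The coefficient of variation uses the sample standard deviation
(ddof = 1) divided by the mean and is computed over **all** tissues,
zeros included — undetected tissues are real variability, not missing
data. CV is undefined (NaN) for a zero mean or fewer than two values.
Multiple-testing correction is Benjamini–Hochberg throughout
(statsmodels). Rank-based comparisons use scipy's Mann–Whitney
implementation: exact enumeration for small tie-free samples, normal
approximation with midrank tie correction otherwise.

## Stage 1 — HK/TS classification

Samples are collapsed to per-tissue means before anything else (the
reference multi-tissue cohort has one sample per tissue; tumour-style
inputs may have many). Detection is strict (`tissue mean > 0.5`), so a
tissue at exactly the threshold does not count. "Detected in ≥ 75 % of
tissues" is evaluated as `n_detected / n_tissues ≥ 0.75`, i.e. 12 of 16.
The HK rule (fraction ≥ 0.75 and CV < 1.5) and TS rule (fraction < 0.25
and CV > 3.5) cannot overlap for any valid parameterisation, which the
parameter class enforces (`ts_max_fraction < hk_min_fraction`,
`hk_max_cv < ts_min_cv`).

The proximity prefilter computes the gap between gene spans (min exon
start to max exon end), strand-agnostic, and retains a lincRNA only if
the gap to every protein-coding gene on its chromosome is strictly
greater than 1000 bp. Whether the CV should be computed on linear or
log abundances is genuinely open; the default is linear FPKM with a
`log_scale_cv` switch, and an aggregation choice (tissue means of
replicates) is fixed rather than exposed per call.

## Stage 2 — sequence features

Conservation is the arithmetic mean of available per-base scores over
the exon union; unscored bases are **skipped**, not zero-filled, because
conservation tracks are sparse over masked repeats and zero-filling
would bias gene means downward. SNP density is
`1000 × (#SNPs in exon union) / exonic length`. Repeat coverage merges
each repeat class before intersecting so overlapping annotations within
a class are not double counted. Orthologue calling consumes a
precomputed alignment hit table (query, species, subject, identity %),
keeps the best identity per (query, species) and calls an orthologue at
identity ≥ 30 (inclusive); alignment itself is out of scope.

## Stage 3 — folding-stability permutation test

The dinucleotide-preserving shuffle is the Altschul–Erickson Eulerian
construction: the sequence is an Eulerian path in the dinucleotide
multigraph; random "last exit" edges forming an in-tree to the terminal
base are resampled until valid, remaining edges are shuffled, and the
path is rewalked. This preserves the dinucleotide count multiset, the
first and last base and the length *exactly* — asserted for every call
in the tests.

The default folding engine is Nussinov base-pair maximisation
(Watson–Crick plus GU wobble, minimum hairpin loop of 3 unpaired bases,
O(n³) DP, numba-compiled with a pure-Python fallback), reported as
−(max pairs) so that lower = more stable, matching the sign convention
of thermodynamic MFE. This replaces a thermodynamic engine to avoid an
external dependency while preserving the test's logic; an `external`
hook shells out to any folding command (e.g. RNAfold) and parses the
last kcal/mol value from its output. Note that under the stated
min-loop-3 convention `GCAAAGC` admits two nested pairs (the inner C–G
encloses exactly three unpaired bases), a case worth knowing when
comparing against engines with a different loop convention.

The permutation p-value uses the add-one convention
p = (1 + #{null ≤ observed}) / (N + 1), which is valid (never
anti-conservative) for any N and lies in (0, 1]. Per-sequence RNG
streams are derived by stable hashing of (seed, sequence id), so results
are independent of iteration order. One-sided direction: lower tail on
the folding score ("more stable than expected").

Because maximum base-pair counts are largely determined by sequence
composition — which the shuffle preserves — the null distribution is
narrow, and planted structure must be substantial to stand out. The
generator therefore plants a single long inverted repeat (arm + 5-base
loop + reverse-complement arm + random tail) covering 40 % of the
sequence by default (floor 30 %). At these settings a 200-base planted
sequence is significant at p ≤ 0.05 with 200 shuffles in essentially
every instance, while i.i.d. random sequences reject at the nominal
5 % rate.

## Stage 4 — tumour refinement

Threshold senses follow the printed wording literally: fold-change and
q-value cuts are strict (|FC| > 2 ⇔ |log2 FC| > 1; q < 0.05), the
recurrence rule is inclusive (homozygous deletion in ≥ 1 % of samples),
and focal overlap counts any ≥ 1 bp overlap of the gene span with a
deletion-type region. The recurrence denominator pools all samples
across tumour types by default (matching a pooled pan-cancer copy-number
cohort); a per-type mode is available. `core = ¬down ∧ ¬deleted ∧
¬focal`, so adding a tumour type can only shrink the core set.

`simple_de` is an explicitly labelled stand-in for count-based DE tools:
Welch's t on log2(x+1) with BH correction and linear-scale fold changes.
It exists so the synthetic pipeline (whose abundances are lognormal, not
counts) is self-contained; externally computed DE tables can be supplied
wherever one is consumed.

## Stage 5 — methylation

The promoter window is −2000 bp to +200 bp around the strand-aware TSS,
reflected through the TSS on the minus strand (the plain-text window
definition does not state strand handling; a strand-agnostic switch is
provided). Gene-level beta is the mean of probes strictly inside the
half-open window; genes with no probes are absent, not zero-filled.
Because the same samples index both group medians, the primary test is
a paired two-sided Wilcoxon signed-rank across samples, with an
unpaired rank-sum reported as secondary.

## Stage 6 — function prediction

The enrichment score is the classical weighted KS running sum: hits add
|r|^p (p = 1 by default) normalised by the total hit weight, misses
subtract 1/(N − N_hit), ES = signed maximum deviation. With all-zero hit
weights the walk degrades gracefully to unweighted steps. The null
permutes gene membership over the fixed ranking — the only permutation
available for an externally ranked list. NES divides ES by the mean
|null ES| of matching sign; the p-value is the matching-sign null tail
with add-one correction; FDR follows the pooled-null procedure (fraction
of pooled sign-matched null NES at least as extreme, divided by the
fraction of observed NES at least as extreme, clipped to [0, 1]).
Default set-size bounds are 15–500. Per-set RNG streams are keyed by
set name, so identical collections give identical results regardless of
iteration order. When the extreme positive and negative deviations of
the running sum tie exactly, the reported sign is arbitrary (float
rounding decides); the tests treat such ties as equal-magnitude matches.

Cross-lincRNA filtering keeps terms significant (FDR < 0.05) in at
least ⌈0.10 × n_lincRNAs⌉ lincRNAs (ceiling convention: 6 of 52, not 5).
Term redundancy uses Wang-method semantic similarity (S-value
propagation with edge weights 0.8 for `is_a` and 0.6 for `part_of`;
similarity = shared S-mass over total S-mass), average-linkage
clustering on 1 − similarity, tree cut at h = 0.85, and one
representative per cluster chosen by seeded RNG (a deterministic
lowest-id option exists). The similarity measure and linkage are not
pinned down by the procedure this reimplements; Wang + average linkage
is the common default of GO semantic-similarity tooling.

## Stage 7 — survival

Stratification uses the type-7 (linear interpolation) quantile with a
strict-above rule: "high" iff expression > the 75th percentile, ties go
low. Kaplan–Meier estimation and the log-rank test are delegated to
lifelines; with no censoring the KM estimate equals empirical survival,
which the tests assert. The synthetic survival generator draws
exponential event times whose hazard is multiplied by the configured
ratio (default 2) in the high-expression group, with independent
exponential censoring (~50 % at defaults).

## Synthetic cohorts: what they emulate and what they don't

Generators are pure functions of their seed (bit-identical reruns, via
per-purpose hashed child streams). Defaults encode the study
conditions: 16 tissues; HK genes lognormal around 4 FPKM with mild
multiplicative noise (realised CV ≈ 0.5); TS genes dominated by one
tissue with CV > 3.5 in ≥ 99 % of draws; background genes detected in
~30 % of tissues so that a cohort without planted HK genes yields no HK
call in ≥ 99 % of seeds; 13 tumour types with planted down-regulation
(log2 FC ≤ −1.2, q < 0.045) and homozygous deletions (~3 % of samples
vs 0.1 % background); Beta(2, 10) vs Beta(6, 4) promoter betas;
pathway co-expression at Pearson r ≈ 0.7 via shared latent Gaussian
factors; exponential survival with hazard ratio 2.

These cohorts are deliberately idealised: abundances are lognormal
rather than count-derived (no overdispersion or library-size effects),
tissues are exchangeable (no correlated tissue blocks), DE q-values are
planted rather than estimated from replicates, methylation probes are
independent, and co-expression has a single-factor structure. Passing
tests therefore demonstrate that the decision rules, statistics and
plumbing are correct and calibrated — not that the thresholds would
achieve the same precision on real cohorts, where noise is heavier
tailed and confounded.

## Problem sizes and numerics

The test suite and acceptance script scale simulations to desk size:
20 × (200 genes × 16 tissues) classifier runs; 1000 shuffle-exactness
sequences (lengths 10–500); 200 folding-oracle cases (length ≤ 12,
exhaustive enumeration); 200 null sequences × 100 shuffles plus 30
planted stems × 200 shuffles for calibration/power; 1000 enrichment
oracle instances; 50 co-expression datasets (60 samples, 8 pathways of
30 genes + 150 background, 1000 permutations); 200-gene tumour tables
over 500 samples; 100 log-rank simulations at n = 200 per arm; and a
full demo at 200 genes. Degenerate inputs are handled explicitly:
sequences shorter than 4 bases are skipped with a warning, constant
genes are dropped from correlation rankings and DE with warnings,
all-censored cohorts give a flat survival curve, and genes without
promoter probes are absent rather than imputed.
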