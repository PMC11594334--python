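# Methods

`cernaforge` infers circRNA-mediated competitive-endogenous-RNA (ceRNA)
networks from a two-group expression study: circRNA back-spliced-junction
(BSJ) counts, mRNA counts, and miRNA counts for the same treated-vs-control
design, plus circRNA and mature-miRNA sequences, an external miRNA-to-gene
target table, and a disease-associated miRNA list. This note documents the
model behind each stage, the tunable parameters, the synthetic-data
generator, and the numerical choices.

## The ceRNA screening model

The ceRNA hypothesis holds that a circRNA carrying miRNA-response elements
(MREs) can sequester ("sponge") a miRNA and thereby de-repress that miRNA's
mRNA targets. The observable footprint of such regulation is a *positive*
expression correlation between the circRNA and the mRNA, together with
sequence evidence that both bind the same expressed miRNA. An **axis** is a
triple (circRNA, miRNA, mRNA) satisfying all four gates:

1. the circRNA and mRNA are each differentially expressed (DE) under the
   treatment;
2. their expression correlates positively across all samples of the model
   (one-sided Pearson, r > 0.90, Benjamini-Hochberg adjusted p < 0.05);
3. the circRNA sequence carries a canonical seed site for the miRNA, and the
   (miRNA, mRNA) pair appears in the external target table;
4. the miRNA itself is expressed in the samples.

The network induced by the axis set is tripartite by construction
(circ-miRNA "sponges" edges and miRNA-mRNA "targets" edges only).

## Stage-by-stage detail

### Junction-read confidence filter

BSJ detectors emit a long tail of one-read artefacts. A circRNA is retained
only if it has at least `min_reads` (default 2) junction reads in at least
`ceil(min_sample_fraction * n_samples)` samples (default fraction 0.5 -
"half of the samples", with the even-n convention that exactly n/2
suffices). Treated and control samples are pooled for the rule; the filter
runs once per model. It is idempotent, and raising either parameter can
only shrink the retained set.

### Normalization and differential expression

Library sizes are adjusted by trimmed-mean-of-M-values (TMM) factors
(30% two-sided trim on log-ratios M, 5% on abundances A, inverse-variance
weights, reference = the sample whose 75th count-fraction percentile is
closest to the mean; factors rescaled to geometric mean 1). Expression is
reported as CPM and log2(CPM + 0.5).

The default DE test (`nb_exact`) is an exact conditional negative-binomial
test on group sums: counts are rescaled to a common effective library size
(and rounded), a **single common dispersion** phi is estimated, and the
treated-group sum is compared with its conditional distribution given the
grand total, where the sum of n i.i.d. NB(mu, phi) replicates is
NB(n*mu, phi/n). The two-sided p-value aggregates all outcomes no more
likely than the observed split, evaluated in log space over a window of
+/- 50 conditional standard deviations (truncation error < 1e-14).

The common dispersion is the **median of per-feature method-of-moments
estimates** phi_i = sum_g(v_gi - m_gi) / sum_g m_gi^2 over features with
positive mean, divided by median(chi2_df)/df (df = total residual degrees
of freedom; 0.839 for a 3v3 design). The division corrects the downward
bias of the median of a right-skewed variance statistic - the same
consistency-factor idea as the MAD's 1.4826. The median (rather than a
pooled ratio of sums) keeps a minority of strongly co-regulated,
overdispersed features from inflating the common value for everything
else. Under a 3v3 null simulation with 2000 NB features the fraction of
p < 0.05 is 0.05-0.065 for `nb_exact` and 0.03-0.05 for the `welch_logcpm`
alternative (Welch t on log2-CPM); both are recomputed by the test suite
and the acceptance script.

Fold change is the difference of group means of log2(CPM + 0.5) - the
limma/voom convention - rather than the log of the ratio of arithmetic mean
CPM; this makes the estimate robust to a single extreme replicate. Two
threshold presets are exposed, both with strict inequalities: circRNAs at
raw p < 0.05 and linear FC > 2 (BSJ counts are low; few circRNAs survive
FDR control at n = 3), mRNAs at BH FDR < 0.05 and FC > 1.5. BH adjustment
is always computed jointly over the tested family.

### Co-expression screen

Every DE circRNA x DE mRNA combination is tested for positive correlation
on log2-CPM across all samples of the model (treated + control, n = 6 by
default; variance stabilization is the reason for the log scale). The
p-value is the upper tail of t = r*sqrt((n-2)/(1-r^2)) on n-2 df; BH runs
jointly over the full grid. Retention requires r > 0.90 AND adjusted
p < 0.05, both strict; note that at n = 6 the joint BH gate typically binds
at sample r around 0.92, i.e. slightly above the nominal r threshold.

### Interaction prediction

circRNA-miRNA interactions come from canonical TargetScan-style seed
matching on the circular sequence: the seed is miRNA positions 2-7, and a
site is graded 8mer (seed + position-8 match + 'A' opposite position 1),
7mer-m8, 7mer-A1, or 6mer; each site receives exactly one grade, the
strongest applicable. Because the molecule is circular, the sequence is
scanned with a 7-nt overhang appended (longest site length minus one, the
minimum guaranteeing discovery of junction-spanning sites); flanking
positions are resolved with modular indexing, and duplicate hits from the
overhang are de-duplicated by start position modulo the circle length. The
default interaction threshold is 7mer-A1 or better. Alignment scoring and
hybridization energies are deliberately out of scope: seed classes are
deterministic and oracle-testable. miRNA-mRNA interactions are the rows of
the external target table whose gene is DE. The miRNA expression gate
reuses the junction-filter rule (default: >= 1 count in >= half the
samples).

### Network, hubs, enrichment

Axes are assembled by intersecting the three evidence sets (gate list
above). Hub circRNAs are ranked by degree (default) or Maximal Clique
Centrality, MCC(v) = sum over maximal cliques C containing v of (|C|-1)!.
On a triangle-free graph every maximal clique is an edge, so MCC equals
degree on every network this pipeline can build - the two methods are kept
as a built-in cross-check, and ties break lexicographically for
reproducibility. The subnetwork of the top-k hubs (k = 10 by default) is
all axes whose circRNA is a hub.

The sponge/disease enrichment asks whether miRNAs sponged in the network
are over-represented among disease-associated miRNAs, with all expressed
miRNAs as the universe: the 2x2 table (a = sponged & associated, b =
sponged only, c = associated only, d = neither) is tested with the
one-sided "greater" Fisher exact test, i.e. the upper hypergeometric tail
P(X >= a) with N = a+b+c+d, K = a+c, n = a+b, computed in log space.
Over-representation analysis for gene sets applies the same tail per term
over a flat term-to-gene mapping (GMT or two-column TSV) with BH across
terms; no GO-DAG propagation is performed.

## Synthetic studies

The generator emulates a desk-scale two-group H2O2-exposure experiment with
three biological replicates per arm (the defining design of the study type
this package targets). Defaults: 150 circRNAs, 400 mRNAs, 80 miRNAs,
NB dispersion phi = 0.1, linear planted fold change 4, 8% decoy DE
features, 30 planted axes, log-normal library-size factors (sigma = 0.2),
150-nt circRNA sequences, 22-nt miRNAs. A quarter of circRNAs and 30% of
miRNAs are drawn near-silent so the confidence/expression filters have real
work to do. The low-noise preset (`SimConfig.low_noise()`: phi = 0.05,
fold change 8, latent sd 0.6) is the regime used for recovery scoring.

Each planted axis is realized end-to-end: the (miRNA, gene) row is added to
the target table, an 8mer seed site for the miRNA is embedded in the
circRNA sequence at a random position on the circle (sites never overlap;
junction-spanning placements occur naturally), and the miRNA is guaranteed
to pass the expression rule. Axis members are forced into the DE sets with
a shared fold-change direction, and their baseline abundance is floored at
200 expected counts so that count noise does not dominate the correlation.
Discoverability of every planted axis (site survives the scanner, row in
the table, miRNA expressed) is asserted at generation time.

Co-expression is planted through a per-axis latent factor: one centered
per-replicate pattern z (sd `latent_sd`) multiplies both members' means as
exp(latent_beta * z), with the same pattern applied to the treated and the
control replicates. Repeating the centered pattern in both arms makes the
factor exactly orthogonal to the treatment contrast - it creates strong
cross-sample correlation between the pair members without perturbing
fold-change estimates or group sums. The amplitude (latent_beta = 4 on the
natural-log scale) was chosen so the population correlation of planted
pairs is about 0.99 under the low-noise preset, which the n = 6 screen
(effective r threshold ~0.92) then detects with high probability. Decoy
structure - extra target-table rows and extra seed sites at
`decoy_interaction_rate`, plus coincidental seed matches in random
sequence - makes false axes reachable, so precision is a meaningful score.
Disease annotation is planted with odds `assoc_enrichment_odds` (default 4)
for sponge-site miRNAs over a baseline rate of 0.2.

What the generator does *not* emulate: read-level sampling (no FASTQ),
isoform structure, shared exons between circRNAs and host mRNAs,
miRNA-family seed redundancy, batch effects, or biologically structured
correlation among non-planted features (decoy DE features do correlate
through the treatment effect itself, which is realistic, but there is no
background co-expression network). Passing recovery tests therefore shows
the inference machinery is correct and calibrated under the stated
generative model - not that real studies attain these error rates.

## Problem sizes and numerical choices

- End-to-end recovery is scored over 20 independent low-noise studies
  (about one second each); null calibration uses 2000 features; the Fisher
  oracle sweep covers every 2x2 table with all margins <= 12; the scanner
  oracle covers 500 random (circle, miRNA) instances.
- Exact-test window: +/- 50 conditional SDs; dispersion clipped to
  [1e-4, 10]; prior count 0.5 for log scales; BH implemented as the
  textbook step-up, cross-checked against statsmodels.
- Degenerate inputs: all-zero features give CPM 0 and log2FC 0; a zero
  grand total gives p = 1; an empty DE set propagates to an empty (valid)
  network and a report flag rather than an error; constant vectors are
  rejected in single-pair correlation and excluded with a warning in the
  grid screen.
- T/U are interchangeable on sequence input; circRNA identifiers are
  `chrom:start|end` with 1-based inclusive coordinates and round-trip
  byte-for-byte (leading zeros are rejected for that reason).

## Known limitations

- The exact NB test uses one common dispersion; features with genuinely
  higher dispersion receive anti-conservative p-values (no tagwise
  shrinkage, no GLM, no covariates).
- Seed classes ignore pairing thermodynamics, 3'-supplementary pairing,
  and conservation; the target table is trusted as given.
- The co-expression screen at n = 6 has limited resolution: sample r must
  clear ~0.92 after BH, so true pairs with population r below ~0.95 are
  frequently missed. This is a property of the published screen design,
  not of the implementation.
- `compare` intersects DE circRNA calls of two runs; it does not test for
  differential response between models.
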