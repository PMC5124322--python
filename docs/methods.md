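# Methods

This note documents the models and procedures implemented in respiroscreen,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter for
reproducibility.

## Colony-screen scoring

A screen design pairs each respiratory condition (glycerol or galactose,
optionally with antimycin A or 2,4-dinitrophenol) with a glucose reference
measured in parallel.  The default design has nine screens: two biological
repeats each of galactose and glycerol plus three drug screens in a
prototroph background, and galactose and glycerol screens in an auxotroph
background.  Plates are 1536-format (32 × 48); each strain occupies a 2 × 2
quadruplicate block, 384 strains per plate.

Scoring proceeds strictly in this order:

1. **Plate normalization** — every colony size is divided by the median of
   the non-missing sizes on its plate.  The median of an even number of
   values is the mean of the two middle values (the standard convention).
   Because plate effects are multiplicative and plate-wide, this step cancels
   them exactly, and multiplying a plate by any c > 0 is provably neutral
   downstream; the test suite asserts bitwise neutrality using a power-of-two
   factor (exact in binary floating point) and hit-set equality otherwise.
2. **Replicate aggregation** — per strain, the median of its non-missing
   replicate colonies; strains with fewer than `min_present = 2` of their
   four replicates are missing for that table.  The median makes a single
   overgrown or pinned-out colony irrelevant.
3. **Ratios** — respiratory / fermentative per screen.  A fermentative value
   of zero is treated as missing, never as a division error.  With
   completeness filtering on (the default), strains missing in any screen are
   dropped; then ratios below the floor (default 0.2) are clamped.  The
   order filter → ratio → floor is a fixed convention of this package.
4. **Hit calling** — ratio < threshold (default 0.85), strictly.  Hit sets
   are monotone in the threshold.  `consensus_hits` aggregates per-screen
   hits to strain level (default: hit in a majority of screens), which is the
   conservative core-hit notion used by the recovery evaluation.

**Recovery evaluation.**  `synthdata.evaluate_hits` scores strain-level
consensus calls against the planted truth.  Per-screen calls at 0.85 under
10% colony noise have an irreducible per-cell false-positive rate of a few
percent (the ratio of two medians-of-four has a standard deviation near
0.08), so strain-level aggregation across screens — not single-screen calls —
is what achieves high sensitivity at low FDR.  When planted deficiency is
background-specific, majority consensus over nine screens cannot reach
auxotroph-only strains (two matching screens); those are recovered by the
cluster flags instead, and `evaluate_hits` reports per-background
sensitivities to make this visible.

**Clustering.**  Ratio profiles are clustered into 12 groups by default.  The
SOM is a batch self-organizing map on a 3 × 4 rectangular grid: codebook
initialised on the plane of the first two principal components (component
signs fixed so the largest-magnitude loading is positive), Gaussian
neighbourhood with width decaying linearly from half the grid's larger
dimension to 0.5 over 50 batch epochs, best-matching-unit ties broken by
lowest unit index.  Batch updates make fitting deterministic and invariant to
the order of input strains, which an online SOM is not; commercial tools'
"default settings" are undocumented, so cluster identity is validated by
recovery properties (planted archetypes separate; planted
prototroph-only/auxotroph-only strains land in distinct flagged clusters),
never by label equality.  K-means (scikit-learn, 10 restarts, seeded) is the
alternative.  A cluster is flagged P-like (A-like) when its median ratio
falls below 0.85 in at least half of the prototroph (auxotroph) screens;
"both" when in both.

## Differential expression

Counts are normalized to counts-per-million; log2 fold change is computed on
condition-mean CPM with pseudocount 1.  A gene is called DE when all three
hold: |log2 FC| ≥ log2(fc_threshold) (default twofold), mean abundance ≥
`min_abund` = 5 CPM in at least one condition (guards twofold calls on
near-zero counts), and BH-adjusted q < 0.05 from the significance test.  The
direction flag is a function of the log2 FC sign and threshold only;
significance gates the call but never flips a direction.

The significance test is a two-sided exact binomial test of the gene's pooled
counts split between the two conditions against the library-size-implied
proportion, computed by the minimum-likelihood method (summing all outcome
probabilities not exceeding the observed one) and cross-checked against
`scipy.stats.binomtest` in the unit tests.  This is a deliberately simple
stand-in for a full count-model test: with only two replicates per condition
it ignores biological overdispersion and is anti-conservative at the p-value
level, but the fold-change and abundance thresholds dominate the selection,
and the null simulations in the acceptance suite show the realized call rate
stays well below alpha.  For a production analysis with more replicates a
dedicated count-model package would be the significance engine of choice; the
thresholds and direction semantics here would be unchanged.

## Time course

Input is a genes × timepoints matrix of log2 ratios against a common
reference (timepoints 0, 0.2, 0.5, 1, 2, 4, 24 h).  `relative_to_t0`
subtracts the t = 0 column (idempotent; t = 0 becomes zero).
`count_changed_per_timepoint` counts genes with log2 ratio > 1 (up) or < −1
(down) per timepoint — disjoint by construction — and computes the upper-tail
hypergeometric p of an annotation set among the up genes against the measured
universe (p = 1 when nothing is up, including at t = 0).
`cluster_profiles` is K-means with k = 12 by default, Euclidean distance on
the log2 profiles.

## Chromosomal windows and ncRNA adjacency

Windows are gene-rank based, not bp-based: ten consecutive genes in each
chromosome's gene order, coding and non-coding alike, strand ignored, sliding
by one, never crossing a chromosome boundary.  A window is flagged induced
(repressed) when ≥ `min_count` = 6 of its genes have log2 FC > 1 (< −1);
genes without fold-change data count as non-qualifying but keep their rank,
preserving genomic adjacency.  A window can in principle carry both flags.
Overlapping or abutting same-direction windows merge into maximal regions
(equivalently: connected components of the window overlap graph, which the
acceptance suite verifies against networkx), recording the maximal per-window
count; the stricter ≥ 7 summary is available by re-running the scan with
`min_count=7`.  The scan is validated against brute-force enumeration of all
windows on random instances.

For each differentially expressed ncRNA, the adjacency statistic asks whether
the gene at rank ± 1 on the same chromosome is a differentially expressed
coding gene; chromosome ends have one neighbour and there is no wraparound.
With no DE ncRNAs the fraction is undefined (None), never 0.

## Set statistics

The enrichment p-value is P(X ≥ k) for X ~ Hypergeom(N, K, n), computed by
exact summation of log-probabilities (gammaln + logsumexp), clipped to ≤ 1;
k = 0 returns exactly 1.  The acceptance suite compares it to an
exact-rational enumeration (math.comb + Fraction) over every instance with
N ≤ 25 at relative error ≤ 1e−12, and unit tests cross-check
`scipy.stats.hypergeom`.  Benjamini–Hochberg adjustment (via statsmodels)
rejects p-values outside (0, 1].

The retrograde concordance caller uses a strict fold threshold
(|log2 FC| > log2(1.5) for the default 1.5-fold): per experiment a gene is
up, down or unchanged; all3 classes need the same direction in all three
experiments; 2of3 classes need the same direction in exactly two with the
third *unchanged* (a third experiment moving the opposite way makes the gene
discordant — a documented choice, since heat-map figures of such experiments
do not pin this down); the six classes partition the gene universe, and
mismatched universes fail loudly with the symmetric difference.

## Synthetic data: what it emulates and what it does not

All generators take a seed and are bit-reproducible; truth objects suffice to
score every downstream stage without re-simulation.

* **Screen** (`simulate_screen`): constant baseline colony size (200 area
  units) per strain, multiplicative plate effects (lognormal, sd 0.1 on the
  log scale), lognormal per-colony noise with CV 10% by default (noise
  magnitudes are module parameters, not claims about any real screen),
  colonies dropped independently at 1%.  Deficient strains (5% by default)
  get a respiratory-only multiplicative growth factor drawn from (0.3, 0.7),
  expressed in prototroph screens only, auxotroph screens only, or all
  screens, with default split 0.40/0.45/0.15 mirroring the relative sizes of
  background-specific versus core hit classes in published screens.  The
  constant baseline is deliberate: it makes the zero-noise pipeline exactly
  pass planted effects through (effect 0.4 → recovered ratio 0.4), giving
  closed-form oracles.  Real screens add strain-intrinsic size variation
  (which the fermentative reference cancels in the ratio), spatial plate
  gradients and border effects — none of which are modelled, so passing
  recovery tests demonstrate the scoring arithmetic, not robustness to
  spatial artefacts.
* **Expression** (`simulate_expression`): negative-binomial counts
  (var = μ + αμ², shared dispersion α = 0.05, Poisson in the α → 0 limit)
  for 2 × 2 samples over 7022 genes on three chromosomes by default, ~27%
  ncRNA, gene means log-uniform in (10, 1000), mild library-size factors.
  Planted: 10% twofold DE genes (random signs), fourfold co-regulated
  10-gene blocks with 80% member density at random non-overlapping ranks,
  and forced DE-coding neighbours for 70% of DE ncRNAs (the adjacency
  truth).  Not modelled: GC/length bias, sample-specific dispersion,
  batch effects.
* **Time course** (`simulate_timecourse`): six archetypes — flat, transient
  up/down peaking at 0.5 h (the fast stress response, with a mild stationary
  echo at 24 h), a delayed mitochondrial peak at 1 h, late up/down at 24 h —
  with i.i.d. Gaussian noise (sd 0.2) on every entry including t = 0,
  mimicking a shared-reference design.  Default 1284 genes with ~10%
  mitochondrial-peak genes (~128, near the observed scale of that class).
  Real profiles are continuous mixtures, not six discrete shapes.
* **Retrograde** (`simulate_retrograde`): three experiments over 5000 genes;
  planted all-three sets of 40 repressed and 9 induced genes (log2 effect
  ±1), two-of-three sets of 14 and 19 (unchanged experiment rotating), and a
  4-gene "complex-2-like" subset of the repressed family with fold changes
  near 1; Gaussian noise (sd 0.2) elsewhere.  At zero noise recovery is
  exact by construction, which is the oracle the concordance caller is tested
  against.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen as the
package's own defaults for validation: 2000 strains × 9 screens for screen
recovery, 2000 genes for DE sensitivity, 20 × 500 genes for the null call
rate, 50 random 200-gene instances for the window-scan oracle, full
enumeration at N ≤ 25 for the hypergeometric oracle.  Every stochastic stage
takes an explicit seed; the config-driven pipeline refuses a stochastic stage
without one, and its manifest contains no timestamps so identical configs
reproduce byte-identical output trees.

## Known limitations

* The binomial DE test ignores biological overdispersion (see above).
* SOM/K-means cluster labels are arbitrary; only partitions and flags are
  meaningful.
* The window scan reports no per-region significance beyond the matched-null
  false-flag comparison in the tests; subtelomeric runs are ordinary windows.
* The screen generator's missingness is independent per colony; structured
  missingness (failed pinning rows, plate edges) is not modelled.
* How real screens distinguish colonies absent on the source versus target
  plate is not modelled; both appear simply as missing.
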