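# Methods

`springdiv` implements the comparative computations used to ask how the
functional coding potential of a chemosynthetic hot-spring community relates
to the geochemistry of its spring, and how closely related genomes within such
a community differentiate. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic test bed does and
does not establish.

## Protein-family clustering

Proteins are grouped into family "bins" by greedy incremental clustering.
Sequences are sorted longest-first (ties by id) and swept once; each sequence
joins the best-matching existing cluster representative, or founds a new
cluster. A match requires a Smith–Waterman local alignment (BLOSUM62, affine
gap open 11 / extend 1) with

* identity ≥ the level's threshold, where identity = identical pairs /
  aligned columns, internal gap columns included in the denominator
  (a conservative, symmetric convention), and
* coverage of the shorter sequence ≥ 0.8 (span of the shorter sequence
  inside the local alignment / its length).

"Best-matching" means highest identity; ties go to the longer representative,
then the lexicographically smaller id, so the sweep is deterministic.
Clustering is cascaded at 90% → 60% → 30% identity: representatives of each
level are re-clustered at the next, and membership is propagated down, giving
every protein exactly one family at the coarsest level. Proteins of 50 amino
acids or shorter are excluded beforehand (strict >50).

Word-size prefilters (shared 5-mer at the 90% level, 4-mer at 60%, none at
30%) skip alignments against representatives that cannot plausibly match;
threshold-level similarity at those identities implies a shared word, and the
coarsest level always aligns exhaustively. Correctness is defined by the
alignment criterion alone — the prefilter is a speed device and can be
disabled (`prefilter_k=None`).

At the coarsest level an alignment must still achieve a positive score with
the coverage floor; no e-value screen is applied, since calibrating e-values
requires a database-size model outside this package's scope. This is a
documented, configurable simplification.

Two readings of "abundance-weighted" family counts are possible (member
counts vs coverage-weighted counts); member counts per metagenome are used.

## Rarefaction and the diversity–mixing regression

Family richness at a common depth is estimated by subsampling proteins
without replacement. The analytic expectation is hypergeometric:

E[S_d] = Σ_f [ 1 − C(N−N_f, d) / C(N, d) ]

with N the metagenome's protein total, N_f family f's count, d the depth;
binomials are evaluated in log space (gammaln) for stability. The Monte-Carlo
estimator reports mean ± sd over `n_reps` (default 100) subsamples and is
seeded. Fixed-depth comparison uses 10,000 proteins by default at full scale;
examples in this repository use smaller depths on smaller simulated studies.
The default depth ladder is geometric with half-decade steps (1000, 3162,
10000, …), truncated per metagenome; metagenomes shallower than a requested
depth are skipped and logged.

Richness is regressed on the fluid-mixing proxy log₁₀(SO₄²⁻/Cl⁻) by ordinary
least squares (statsmodels). High ratios indicate vapor-phase (sulfide-derived
sulfate) input mixing with meteoric water; low ratios indicate deep
chloride-rich reservoir water. Springs lacking richness or defined
geochemistry are dropped listwise and counted. Reported: slope, intercept,
R², adjusted R² = 1 − (1−R²)(n−1)/(n−2), F-test p, n, slope SE and 95% CI.
Only the single mixing predictor is modeled; temperature and pH are carried
in the geochemistry records but deliberately not fitted.

## KO profiles: normalization, enrichment, ordination

KO counts per metagenome are normalized to frequencies (row totals 1) to
correct for unequal sequencing effort. The enrichment of KO k in metagenome s
is

E_{k,s} = (a_{k,s} − m_k) / m_k,   m_k = mean_s a_{k,s}.

Consequences used as analytic anchors: the across-metagenome mean of E is 0;
E = −1 exactly where the KO is absent; and E = S−1 (14 for S = 15
metagenomes) exactly when the KO occurs in a single metagenome — the
exclusivity ceiling. KOs with zero mean are dropped (logged) to avoid 0/0.

Category subsetting restricts a table to KOs carrying a KEGG-style category
or subcategory label (e.g. "Energy Metabolism"); subsetting does not commute
with normalization, and the subset-then-normalize order is the caller's
choice. Bray–Curtis dissimilarity d(x,y) = Σ|x−y| / Σ(x+y) is computed on
frequencies by default (configurable to raw counts). PCoA double-centers the
squared distances (B = −½ J D² J), eigendecomposes symmetrically, embeds only
positive-eigenvalue axes (eigenvector × √eigenvalue), truncates negative
eigenvalues without a correction constant, and fixes each axis's sign by
making its largest-magnitude loading positive so plots are reproducible.
Proportions explained are computed over the positive eigenvalues.

## MAG filtering and relative abundance

Medium–high-quality draft bins are those strictly >50% complete and strictly
<7% contaminated. Relative abundance is the three-step chain: relativized
coverage = mapped reads / assembled length; multiplied by the estimated
genome size, taken as assembled length / completeness fraction (a first-order
correction, replaceable by a supplied size column); renormalized to fractions
over the retained bins. Abundances sum to 1 and are invariant to uniform
scaling of read counts.

## Intra-lineage differentiation and AAI

For a genome pair and a KEGG category, shared = |A∩B| and unshared = |A△B|
(symmetric difference — both directions pooled, giving one ratio per pair;
per-genome unique counts are also emitted). The differentiation ratio is
unshared/shared, undefined (flagged, not infinite) when nothing is shared.
Comparing the Metabolism ratio against the Genetic Information Processing
ratio — the conservative baseline, since genetic-processing complements
should diverge slowly among close relatives — places each pair relative to
the 1:1 line; points above it are metabolically differentiated. KOs missing
from the category map are ignored (logged), as the statistic is defined over
annotated proteins only.

AAI uses reciprocal best hits under the same local-alignment machinery, with
hit floors of 20% identity and 50% shorter-sequence coverage (configurable);
the mean and sd of retained best-hit identities are reported in percent.

## Branch-length metrics

Root-to-tip distance is the path sum from the root. The "contribution" of a
tip set to a tree's total branch length is ambiguous, so two modes are
provided: `exclusive` (edges whose entire descendant tip set lies inside the
set, i.e. clade-exclusive branch length — the default) and `tip_only`
(terminal branches only). Exclusive ≥ tip_only always. Unrooted newick input
is treated as rooted at its basal node (with a warning), matching
root-distance semantics. Missing branch lengths default to 0 with a warning;
duplicate tip labels are an error.

## The synthetic study generator

The generator emulates the pipeline's upstream inputs with known ground
truth:

* **Families.** A pool of founder sequences (default 200, length 150) with
  mutual positional identity held below 0.25 by rejection sampling; each
  family member is its founder substituted at half the target divergence at
  member-specific random positions, so realized pairwise member identity sits
  at the 0.95 target within ±1/length. The positional (Hamming) screen on
  founders, rather than full alignment, is sufficient because random
  same-length sequences that differ at >75% of positions cannot meet the
  clustering criterion at any cascade level.
* **Geochemistry and richness.** SO₄²⁻ and Cl⁻ are log-uniform
  (10–316 and 1–500 mg/L), spanning the mixing axis; planted richness is
  round(intercept + slope·log₁₀(SO₄/Cl) + ε), ε ~ N(0, sd), clamped to
  [1, pool]. Defaults: intercept 40, slope 8 families per log unit, sd 2,
  40 springs. Member counts per family are lognormal (μ=1, σ=1) — abundance
  distributions of environmental gene families are strongly right-skewed and
  the lognormal is the simplest standard stand-in; no particular abundance
  law is asserted for real data.
* **KO tables.** Default 240 KOs over 3 (category, subcategory) pairs,
  round-robin assigned. A configurable number of exclusive KOs (default 3)
  occur in exactly one metagenome; all others are forced into ≥2 metagenomes
  so exclusivity is exactly as planted.
* **Genome pairs.** Per category, shared and unique KO sets are drawn to hit
  the planted shared fractions (Metabolism 0.5, Genetic Information
  Processing 0.8) to within rounding, so the planted differentiation ratios
  are 2(1−f)/f = 2.0 vs 0.5 — above the 1:1 line.
* **MAGs and trees.** MAG fields are drawn uniform/lognormal-ish over
  realistic ranges (1–5 Mbp, completeness 30–100%, contamination
  exponential, mean 3%); trees are random binary topologies with uniform
  branch lengths (0.01–0.3 substitutions/site) and a tagged tip subset
  (default 10%) whose realized branch fractions are recorded in the truth.

Everything is driven by one seeded NumPy generator in a fixed order, so a
fixed config yields byte-identical studies.

**What the synthetic bed does not emulate:** read-level noise, assembly and
binning artifacts, gene-prediction errors, uneven protein lengths, paralogy,
alignment-twilight-zone families, covarying geochemistry (temperature and pH
are decorative), or the unmodeled environmental variance of real springs.
Consequently the synthetic regression explains far more variance (R² ≈ 0.9 on
planted richness) than a field dataset would, and passing recovery tests show
the *computations* are correct under controlled separability — not that real
communities are this clean.

## Problem sizes used in tests

The test suite runs on deliberately small instances: clustering-recovery
fixtures of ~10–30 proteins over 8 families (50 seeds), 100 replicate
40-spring studies for slope recovery, 1000-replicate rarefactions on single
metagenomes, 20-tip trees for the branch-fraction oracles, and a
15-metagenome KO table for the enrichment bounds. These sizes give stable
Monte-Carlo checks while keeping the whole suite and the worked example at
desk scale.

## Known limitations

* Clustering is not bit-compatible with any external tool; it is a
  specification-complete reimplementation of the greedy
  best-representative algorithm with documented tie-breaks.
* The 30% cascade level substitutes a positive-score/coverage criterion for
  an e-value screen.
* Greedy clustering is order-dependent in principle; order-invariance holds
  on well-separated inputs (tested) but is not guaranteed near thresholds.
* AAI is all-vs-all Smith–Waterman, quadratic in proteome size — fine for
  the handful-of-proteins comparisons exercised here, slow for full
  proteomes.
* The enrichment statistic inherits compositional coupling from
  normalization; no significance testing is attached to it or to the
  ordination.
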