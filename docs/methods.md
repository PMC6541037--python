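# Methods

This note records the models, conventions and numerical choices behind
`lipidont`, and what the synthetic fixtures do and do not establish about
real data.

## Species enumeration and the ontology graph

Lipid species are generated combinatorially.  Each lipid class rule
(shipped as an editable CSV, `src/lipidont/data/class_rules.csv`) declares a
backbone (glycerol, sphingoid, sterol), a number of acyl positions, a
linkage type (ester, alkyl ether `O-`, vinyl ether `P-`), a classification
lineage, and class-level headgroup charge, intrinsic curvature, function
and sub-cellular component assignments.  Molecular species are all
unordered multisets of chains drawn with repetition from the fatty-acid
alphabet — 37 chains from C12:0 to C26:7 by default — so a k-position class
over n chains yields C(n+k−1, k) species; sphingoid classes take one base
(d18:0 or d18:1) plus k−1 N-acyls.  A sum-composition layer (total carbons
and double bonds only, e.g. `PS(34:2)`) is added for classes with ≥ 2
positions; for one-chain classes the two levels render identically, so no
separate sum species exists.  With the shipped 27-class rule set the build
yields ~112,000 species (cardiolipin, with four positions, dominates) and
~1.3 million edges, built in a few seconds.

Terms live in a DAG with four roots, each a category ("CAT"-prefixed) term:
lipid classification, chemical and physical properties, function, cellular
component.  Generated term ids are content-hashes of the term name, so
rebuilds are reproducible.  A species carries *direct* associations (its
classification leaf; chemical terms read off the name — "contains CX:Y" per
distinct chain at molecular level only, total length, total unsaturation,
bond type; class-level charge/curvature/function/component; biophysical
category terms).  Annotation closure — association with every ancestor of a
direct term — is computed on demand and cached.  An **edge** is one `is_a`
link or one direct association; closure edges are not counted, which keeps
the count comparable to a curated ontology file's link count.

Nomenclature is *sn*-position-blind: chains sort by (carbons, double
bonds) ascending, sphingoid base first, and the ether prefix attaches to
the first chain after sorting.  The accepted input dialects are an explicit
whitelist (separators `/`, `_` or space; optional parentheses; `O-`/`P-`
prefixes; `d` sphingoid prefix; a small synonym table for vendor aliases).
Anything else is returned as unmatched-with-reason — deliberately so, since
guessing at ambiguous names would silently corrupt downstream statistics.
Molecular names absent from the enumeration fall back to their
sum-composition parent.

## Biophysical property models

Each property — chain-melting transition temperature (°C), bilayer
thickness and lateral diffusion (units carried as metadata) — is fitted by
ordinary least squares with main effects only:

    value ~ 1 + C(lipid class) + total chain length + total unsaturation

The reference class is the lexicographically first; no interaction terms
are used (the predictors are deliberately coarse, since the point is
extrapolation to thousands of species seen only as class + sum
composition).  Rank-deficient designs are rejected with the name of the
collinear column.  Validation is leave-one-out cross-validation by actual
refits; records whose refit is rank-deficient (e.g. a class observed once)
are flagged and excluded from the aggregate RMSE/R².

Ether and plasmalogen classes borrow their diacyl parent's coefficients
through an editable proxy table; classes absent from the training data and
the proxy table are *not predictable* and simply receive no biophysics
terms — notably sphingolipids under the simulation-derived thickness and
diffusion models, whose source data lack them.

Predictions are discretized into five categories via four limits: the
20/40/60/80th percentiles (inclusive linear interpolation, numpy's
`linear` method) of predictions over a *reference lipidome*, so the bins
mean "low for a typical membrane", not "low among all 112,000 enumerated
species".  Binning uses half-open intervals, lower-inclusive in the
interior: (−∞,q20) → very low, [q20,q40) → low, [q40,q60) → average,
[q60,q80) → high, [q80,∞) → very high.  Values outside the calibrated
range therefore land in the extreme bins by construction.  At least five
distinct reference values are required; degenerate distributions are
errors, not silent single-bin assignments.

The package ships no measured training data.  The bundled defaults are
generated at run time by the seeded synthetic-fixtures module: training
tables drawn from linear models whose coefficient *signs* follow the
literature (transition temperature rises with chain length, falls with
unsaturation; lateral diffusion does the opposite; thickness grows with
length), and a synthetic mammalian-like reference lipidome sampled from the
membrane-lipid classes.  Sum-composition and molecular species are
annotated identically from class + totals — a documented interpretation,
since only the totals enter the predictors either way.

## Enrichment statistics

Both modes use "classic" per-term semantics: every candidate term is tested
independently with its full closed annotation set; there is no elim/weight
style parent–child decorrelation.  Candidate terms are those annotating at
least `min_term_size` (default 1) matched lipids, optionally intersected
with a user-supplied term subset (the subset terms plus their descendant
closure).  The BH family is exactly the set of terms actually tested, so
restricting the subset changes q-values but never a raw p-value.  The
significance threshold (default q < 0.05) labels rows; it never filters.

*Target-list mode.*  For a term annotating K of N universe lipids, with a
of the n target lipids annotated, the one-tailed Fisher p-value is the
hypergeometric upper tail P(X ≥ a) — over-representation only; depletion is
out of scope.

*Ranking mode.*  Lipids are ordered by the local statistic — p-value
statistics ascending (most significant first), fold changes descending,
manual override available — with ties and non-finite values placed
deterministically by canonical name, because the KS p-value depends on the
ordering.  For a term whose m lipids sit at ranks r₁<…<r_m of n, the
statistic is D⁺ = max_i (i/m − r_i/n), sensitive to over-representation at
the top.  The null is the *rank permutation* null (the m annotated lipids
occupy a uniformly random size-m subset of the n ranks), not the
continuous-sample KS null.  Scaled by m·n the statistic is an integer, and
P(T ≥ t) is computed exactly by a dynamic program counting the subsets
with all sᵢ above per-position bounds — O(m·n) big-integer operations —
for m ≤ 50; beyond that the one-sided Smirnov distribution
(`scipy.stats.ksone.sf`) serves as the documented approximation.  The test
suite verifies the exact branch against exhaustive enumeration of all
subsets for n ≤ 12.

Local statistics: one-tailed Welch t-test p-values (Welch–Satterthwaite
degrees of freedom, alternative "condition of interest greater", interest
defaulting to the first-listed condition), log₂ fold changes (pseudocount =
half the minimum positive value of the matrix, applied only when a group
mean is zero; all-zero lipids get the neutral value 0), one-way ANOVA F
p-values, or user-supplied values passed through.

Benjamini–Hochberg is the literal step-up formula
q₍ᵢ₎ = min_{j≥i} (m·p₍ⱼ₎/j), capped at 1, mapped back to input order; it is
order-invariant and monotone, and is cross-checked in the tests against an
independent implementation.

Redundant-parent pruning removes, *after* testing and correction, any
ancestor term whose annotated species set (within the tested universe)
equals that of a tested descendant, keeping only the most specific term of
such chains.  Pruning removes rows; it never alters surviving statistics.

## Preprocessing workflow

The cluster workflow fixes the order: half-minimum imputation on the
original intensities (every missing cell gets 0.5 × the global minimum
positive value), fraction-of-total normalization per sample (missing cells
excluded from the sums), per-lipid z-scoring (sample SD, ddof = 1, the R
`scale()` convention; constant rows are dropped with a warning), then
complete-linkage hierarchical clustering on Euclidean row distances cut to
k clusters (scipy's deterministic tie handling; labels renumbered by first
appearance).  Z-scored values feed only the clustering; group statistics in
the enrichment modes use normalized, unscaled intensities.  Each cluster is
then tested in target-list mode against all matched lipids as universe.

## Synthetic data

`make_abundance_matrix` draws per-lipid baseline abundances log-normally
(natural-log σ = 1 across lipids — abundances spanning roughly two orders
of magnitude), adds log-normal replicate scatter of σ = 0.4 (~40% CV, the
upper end of typical biological replicate variation in lipidomics), and
multiplies the lipids annotated to a chosen term by the effect size in the
affected condition; missingness is completely at random.  Everything is
reproducible byte-for-byte from (parameters, seed).

The generator emulates intensity scale, replicate noise, multiplicative
effects and missingness.  It does **not** emulate the correlation structure
of real lipidomes (co-regulated classes, shared precursors), instrument
batch effects, intensity-dependent missingness, or isomer ambiguity.
Passing the planted-recovery tests therefore shows the statistics are wired
correctly and have the expected power under clean conditions — not that any
particular real dataset would yield a given term list.

Under these study conditions (3 vs 3 samples, 4-fold planted effect on a
~20-species class term among ~120 lipids), ranking-mode recovery of the
planted term at q < 0.05 succeeds in ≥ 95 of 100 seeded simulations, and
under the null (effect 1.0) some term reaches q < 0.05 in ≤ 5 of 100 —
measured, not assumed, by `scripts/acceptance.py` and the test suite.

## Problem sizes and limitations

The acceptance script uses: the full 27-class build (~112k species) once;
500 sampled species names for matching; 1,000 reference values for
quintile calibration; all 2×2 tables with grand total ≤ 20 (tests: ≤ 30,
plus sampled larger tables with margins ≤ 30) for the Fisher oracle; all
rank subsets for n ≤ 10 (tests: ≤ 12) for the KS oracle; 100 + 100 seeded
simulations for power and null rates.  These sizes keep a full run well under
a minute while leaving every code path exercised.

Known limitations: no abundance weighting in either enrichment mode
(low-abundance lipids count as much as high-abundance ones — a custom
local statistic can partially compensate); no sterol biophysics (the
cholesterol effect depends on interactions the linear model cannot carry);
no sn- or double-bond-position-resolved nomenclature; no oxidized-lipid
grammar; curvature is treated as headgroup-determined, ignoring chain
composition; ambiguous class abbreviations are surfaced as unmatched
rather than guessed.
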