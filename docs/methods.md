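# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Differentiality calling

All downstream statistics consume only booleans x_s(i,j): "marker s
discriminates the parents of hybrid (i,j)". Rules per data type:

* **SNP** — call true iff both parental alleles are observed and unequal.
  Missing calls (`N`/empty) make the pair non-differential: a conservative
  choice, since an unobserved allele cannot support an association. A
  marker missing in one line can still be a candidate through other pairs.
* **sRNA** (rpmqn = reads per million, quantile-normalized) — with
  lo/hi the lower/higher expressed parent: differential iff
  (lo ≥ 0.5 and hi ≥ 2·lo) or (lo < 0.5 and hi ≥ 1). All thresholds
  inclusive, so the boundary pair (0.5, 1.0) is differential under either
  branch. The rule treats 0.5 rpmqn as the detection floor: a change from
  "not reliably expressed" to ≥ 1 rpmqn counts as differential.
* **mRNA** — microarray intensities have no natural zero, so the rule is a
  config object (`DifferentialRule(fold, floor)`); the default is a pure
  two-fold rule (floor 0) paralleling the sRNA fold branch, with the floor
  available when the platform's background is known. Equal intensities are
  never differential (the rule requires hi > lo), so a fold threshold of 1
  degenerates to "any unequal pair".

*Candidate markers* are those differential in at least one Flint × Dent
combination of the design; they form the marker universe for the Euclidean
distance and the multiple-testing family for the association test.

## Distances and predictors

* Euclidean parental distance D_e = √(Σ d_s) with d_s the squared
  expression difference, or an allele-difference indicator for SNPs. The
  SNP indicator is exposed under `snp_distance_convention`:
  `"difference"` (default; d_s = 1 when alleles differ) or `"as_printed"`
  (the complementary similarity scoring). The difference convention is the
  one under which larger parental distance can correlate positively with
  hybrid performance; the alternative is retained as a switch.
* Binary distance D_b = √(mean of x_s over a chosen marker set) — the
  square root of a mean, so D_b ∈ [0, 1] regardless of set size.
* Combined binary distance D_b,com = (D_b,pos·n_pos + (1−D_b,neg)·n_neg) /
  (n_pos+n_neg). The single-direction limits (n_neg = 0 → D_b,pos;
  n_pos = 0 → 1−D_b,neg) are returned exactly, not via the weighted
  formula, so the algebraic identities hold to the last bit.
* m_f = n_pos(i,j)/(n_pos(i,j)+n_neg(i,j)). For a hybrid with no
  differential associated marker in either direction the ratio is 0/0; the
  uninformative midpoint 0.5 is substituted (`mf_fill`), keeping the
  regression row usable without biasing it toward either direction.
* m_d = (n_pos(i,j)−n_neg(i,j))/(n_pos−n_neg+0.1). The 0.1 offset prevents
  a zero denominator when the global sets are equally large and is kept
  exactly as defined — including the sign flip the formula produces when
  n_neg > n_pos. m_d is a *predictor*, not a distance; OLS absorbs its
  scale and sign into the coefficient.

## Association test

Hybrids are sorted by trait value (ties broken lexicographically by hybrid
id so cross-validation is deterministic) and halved into L and H; with an
odd count the median hybrid is excluded. Per candidate marker, o_L and o_H
count differential hybrids per class; P_s is the upper binomial tail at
p = ½ starting at k_min = max(o_L, o_H), computed with `scipy`'s binomial
survival function; n = 0 yields P_s = 1. Benjamini–Hochberg selection runs
over all candidate markers of one data type jointly (one family per data
type and per training set). Direction: positive = enriched among
high-trait hybrids (o_H > o_L); ties get the negative label but can never
pass FDR control since P_s ≥ ½. The opposite labeling is available as
`direction_convention="low_enriched"`.

The binomial model treats the 98 hybrids as independent observations. They
are not — each line appears in 7 or 14 hybrids — so p-values for markers
whose expression tracks a single line are anti-conservative. This is a
property of the method itself and is the main source of the (small)
empirical false discovery observed on synthetic data: markers tagging a
high-combining-ability line are statistically associated with the trait
even though no effect was planted on them.

## Prediction and cross-validation

Simple prediction is OLS of the trait on one distance (intercept + slope);
the multivariate model adds D_b,pos, D_b,neg, m_f, m_d. Constant predictor
columns are dropped with a warning (e.g. D_b,pos is constant when every
training hybrid is differential for all positively associated markers);
fewer rows than coefficients is a fit error. Both go through
`statsmodels` OLS; `HybridPerformanceRegressor` wraps class split →
association → FDR selection → predictor computation → OLS as a
scikit-learn estimator (`fit(X, y)` / `predict(X)` with X the
hybrid × marker boolean table).

Cross-validation samples 3 Flint + 5 Dent estimation lines per run;
validation hybrids are the 4 × 9 = 36 crosses among non-estimation lines.
Training sets per scheme: type-2 = all 62 hybrids with ≥ 1 estimation
parent; type-1 = all crosses of one (randomly drawn) "tested" heterotic
group with the estimation lines of the other group (35 or 42 hybrids);
type-0 = the 15 estimation × estimation crosses. Association and marker
selection are recomputed on training hybrids only — validation trait
values never enter splitting, selection or fitting (verified by a leakage
test). Runs whose selection yields no marker in a direction the predictor
requires are recorded as failures with a reason, excluded from the
mean ± SD, and reported via the success count. The master seed spawns
per-run seeds (`numpy.random.SeedSequence`), so any single run can be
reproduced in isolation.

## Synthetic data generator

The generator emulates the motivating design: 7 Flint + 14 Dent lines, the
complete 98-hybrid factorial, and per-line marker matrices. Default marker
counts (2000 SNP, 2000 mRNA, 5000 sRNA) are desk-scale stand-ins for the
study's tens of thousands, chosen so the full pipeline (including 100
permutations and 3 × 100 cross-validation runs) completes in seconds.

**Trait.** With planted positive/negative marker sets,
trait(i,j) = 10 + 0.01·#diff_pos(i,j) − 0.02·#diff_neg(i,j) + N(0, 0.25²)
Mg ha⁻¹, where differentiality is evaluated with the same rules the
analysis uses — the association signal exists by construction and the
noise-free trait is exactly recomputable from the matrices.

**Planted markers.** 200 positive + 100 negative sRNAs by default, each
group organized as a co-regulated family: a latent line profile per block
(median-centered within each heterotic group so the family segregates in
the factorial), thresholded per marker after mixing with marker-specific
noise (`pattern_corr`, default 0.99). This correlation structure is the
point, not a convenience: in a 98-hybrid factorial a marker is detectable
by the class-split binomial test only if its differentiality pattern
explains a substantial share of the trait — with 300 *independent* planted
markers each would correlate ~1/√300 with the trait and none would ever be
found. Effect sizes are balanced (200·0.01 = 100·0.02) so both directions
carry equal weight. The default settings give median within-class
differential-frequency gaps ≈ 0.45 for planted markers.

**Null markers.** Zero-inflated log-normal expression: a variable marker
(default 20% of markers) is "on" in a sparse Beta(0.3, 2.7)-distributed
fraction of lines with log-normal(log 4, 0.25) rpmqn, and exactly 0
otherwise; non-variable markers are constant across lines. The tight
on-state scatter keeps two expressing parents from passing the two-fold
rule spuriously (~2.5% of both-on pairs). SNPs are biallelic with
Beta-free ancestral frequencies and a heterotic-group divergence shift;
mRNA adds a multiplicative scale and additive background so intensities
have no true zeros.

**What the generator does not model:** linkage disequilibrium and genomic
positions of trait markers, dominance/epistasis, genotype × environment
variance, pedigree structure within heterotic groups, and the full
correlation spectrum of real sRNA families (it has a small number of
planted families plus independent nulls). Passing tests therefore
demonstrate the statistical machinery under the stated generative
assumptions, not performance on real breeding data.

## Enrichment and annotation analyses

Bootstrap enrichment draws B = 1000 background subsets of the target's
cardinality *without replacement*; empirical p-values use the add-one
convention p = (1 + #{replicates ≥ observed})/(B + 1), so p ∈ [1/(B+1), 1]
and a maximally enriched stratum sits exactly at the floor. Multi-mapping
sRNAs count once per mapping position in genomic-bin analyses but once per
sRNA in length analyses; strand is ignored. Genomic bins tile each
chromosome at 1 Mb with the trailing partial bin kept. Annotation overlap
uses half-open interval intersection (≥ 1 shared base) against gene and
repeat tracks; positions overlapping neither are intergenic, and a
multi-mapping sRNA is labeled with the union of categories over its
positions. GFF3 input (1-based closed) is converted to the internal
0-based half-open convention on read.

## Numerical and testing choices

* Binomial tails via `binom.sf(k_min−1, n, ½)`; verified against
  brute-force enumeration of all 2ⁿ class assignments for n ≤ 12 to
  < 10⁻¹² absolute error.
* BH selection via `statsmodels.multipletests`, cross-checked against an
  independently written step-up on 1000 random p-vectors.
* OLS coefficient recovery checked against the closed-form normal
  equations; multivariate fits with a single varying predictor reproduce
  the simple fit to < 10⁻⁸.
* The permutation-null study uses a dataset with moderate family coherence
  (`pattern_corr = 0.85`). With a perfectly coherent family making up ~40%
  of the candidate set, the whole family occasionally rides a chance trait
  split jointly past BH — a dependence concentration far beyond anything
  in real candidate families and outside BH's guarantees. Moderate
  coherence is the faithful emulation; under it, shuffled traits yield no
  associations in effectively all permutations while the real split still
  recovers planted markers.
* Cross-validation accuracy orderings are compared between schemes with at
  least 10 successful runs; a mean over fewer (selection-biased) successes
  is not meaningful, and the type-0 regime is instead characterized by the
  collapse of its success count.
* Bootstrap calibration: on null targets, p < 0.05 in ~5% of strata
  (within ±2% over 50 seeded datasets); discreteness of count statistics
  makes the check slightly conservative.

## Known limitations

* The association test's independence assumption across hybrids (above).
* The type-0/1/2 training-set composition is one consistent reading of the
  testcross scenarios; it is isolated behind `_training_hybrids` so
  alternative readings can be added.
* The mRNA differential rule is a stand-in for the original microarray
  pipeline's criterion, which is platform-specific.
* rpmqn normalization is upstream of this package; expression inputs are
  taken as given.
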