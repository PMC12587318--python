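# Methods

## The transmission model

The package models a quantitative trait as

    P = T + E,        T = G + C,

where `T` is the component transmitted vertically from parents to
offspring, `E` is independent residual noise, and the split of `T` into a
genetic part `G` and a non-genetic part `C` is latent bookkeeping.
Phenotypic variance is normalised to 1, so `Var(T) = t2` is the
*transmissibility* — the share of trait variance attributable to anything
parents pass on, whether genes, wealth, culture or environment.

Spouses correlate at `m` on `T` (assortment on the latent component — the
"social genotype" style assumption; assortment on the phenotype is
available as an option).  A child receives the midparent value plus an
innovation:

    T_child = (T_father + T_mother) / 2 + eps,
    Var(eps) = Var(T) (1 - m) / 2,

which keeps `Var(T)` stationary.  Under this recursion the expected
phenotypic correlation of a relative pair at genealogical distance `n` is

    E[r_n] = t2 * b^n,      b = (1 + m) / 2,

where `b` is the intergenerational persistence rate: random mating
(`m = 0`) halves the transmitted covariance per link, perfect assortment
(`m = 1`) preserves it.  Genealogical distance follows one auditable
convention (`kin_model.RELATIONSHIP_DISTANCE`): lineal pairs use the
number of links (parent–offspring 1, grandparent 2, ...); collateral
pairs with closest-common-ancestor depths `(j, k)` use `n = j + k - 1`
(siblings 1, avuncular 2, k-th cousins `2k + 1`).  For lineal pairs the
exact parameterization of `b` additionally depends on assortment on the
focal trait itself; the package applies `t2 * b^n` uniformly and emits a
warning for lineal labels rather than guessing a correction.

The scientific point the model encodes: `t2` and `b` are identified by
kin correlations, but the split of `T` into `G` and `C` is not.  The
generator makes this exact — `h2_share` (the genetic fraction of the
transmitted variance) is drawn from an RNG stream that never touches the
observed phenotypes, so a fully genetic and a fully cultural process at
matched seeds produce bit-identical data.  `reinterpret_fit` returns the
same fitted numbers under a "genetic" reading (`t2` labelled narrow-sense
heritability h2) and a "transmissible" reading; only the labels differ.

## Simulator mechanics and numerical choices

**Mating.**  Within each generation, mates are rank-matched on
`T + noise`.  The large-sample noise variance that yields spousal
correlation `m` is `Var(T)(1 - m)/m`, but in finite, family-structured
pools this under-delivers by ~0.01 and the shortfall compounds through
the variance recursion, biasing distant-kin correlations below `t2 b^n`.
The noise scale is therefore solved numerically per matching: the unit
noise is drawn once and the scale found by bisection (25 iterations)
against the realised spousal correlation of that very pool, making the
procedure deterministic given the stream.  Achieved spousal correlations
sit within ±0.01 of the target in every generation.

**Close-kin unions.**  The closed form assumes mates are otherwise
unrelated.  Unions between individuals sharing an ancestor within
`forbid_kin_depth` links (default 2: no sibling, avuncular or
first-cousin marriages) are broken up by swapping rank-adjacent brides.
Such unions are rare (~0.1% without the exclusion), so this is hygiene
rather than a correction.

**Storage order.**  Couples are stored in a random order after matching.
The matched order is score-sorted, and a value-informative storage order
would make pair orientation (smaller id first) systematically pair a
lower-`T` member with a higher-`T` member for same-generation relatives,
inflating pooled Pearson correlations well above `t2 b^n`.  Any
generator feeding orientation-sensitive estimators must preserve this
orientation neutrality.

**G/C split under assortment.**  With matching on `T`, the spousal
correlation of `G` is `h*m` (not `m`), so independent `G` and `C`
innovations would not keep `Var(G)/Var(T)` stationary at `h = h2_share`.
The child's `G`-innovation is therefore `h * eps_T + delta` with
`Var(delta) = h(1-h) Var(T)/2`, equivalent to negatively correlated
`(eps_G, eps_C)`; this holds the split `(h, 1-h, 0 cross-covariance)`
stationary in expectation for every `m`.

**Demography.**  Generations are discrete and non-overlapping; birth
year is `1700 + 30g ± 5`; surnames transmit patrilineally (daughters
carry the father's surname as a clustering key, not a social claim).
Offspring counts are Poisson (default mean 2.2, truncated at 6 per
couple and capped per generation); a subcritical distribution raises an
extinction error naming the generation.  There is no migration,
mortality or overlapping-generation structure, and no allele-level
genetics — `G` is an infinitesimal-style latent value.

**Declining-transmissibility variant.**  `t2_schedule` rescales each
generation's latent components by the deterministic factor
`sqrt(t2_g / t2_{g-1})` (expectation-based, not empirically
standardised), giving cohort-varying kin correlations
`b * sqrt(t2_g t2_{g-1})` for parent–offspring pairs — the generator for
cohort-trend studies.

## Estimation

**Pair enumeration** finds, for every pair, the closest relationship
only: each collateral pair is emitted at the ancestor where the two
lineages diverge (branch tracking), and the minimum-`n` candidate wins,
preferring a male common ancestor on ties so that the pair's clustering
surname is the shared patriline.  A ~57k-individual pedigree enumerates
(~5.8M pairs) in ~15 s within 2 GB.

**Correlation estimates** report both `n_pairs` and `n_unique` (distinct
individuals), because their ratio is the signature of pseudoreplication.
The naive method is the Pearson correlation over all pairs with the
Fisher-z CI.  The corrected method never uses more than one pair per
surname at a time: the point estimate averages the Pearson correlation
over random one-pair-per-surname selections; its percentile 95% CI comes
from outer replicates (default 1000) that resample surname clusters with
replacement and average over inner selections (default 20), so the CI
reflects between-cluster sampling variability while the selection noise
that the estimator averages out is not padded into the interval.  With
singleton clusters this reduces exactly to the standard cluster
bootstrap.  Measured coverage at a true pair correlation of 0.4: ~95%
under heavy pair-sharing (30 sibships of 12, where the naive CI covers
~43%) and ~94% with independent pairs (~95% naive).

**Model fit** is ordinary least squares of `log r` on `n` (intercept
`log t2`, slope `log b`; `m_hat = 2 b_hat - 1`), with an inverse-variance
weighted variant available.  Estimates with `r <= 0` cannot enter the log
fit and are excluded with a count.  Standard errors resample each
relationship's `r` from its bootstrap distribution (or a normal
approximation) and refit; back-transformed values above 1 are clipped
with a warning.

**Cohort trends** assign each pair the younger member's birth decade (or
generation index), estimate the corrected correlation per cohort
(default 500 replicates, matching the reporting style of per-cohort
bootstrap means), and summarise the trend as the last-minus-first
difference with a percentile CI formed elementwise from the two cohorts'
independent bootstrap draws.  A rank variant correlates within-cohort
percentile ranks of the pooled member values.

## Wealth confounding

Log wealth at death is `base + decade drift + loading * T + noise`;
individuals below their period's probate minimum are recorded unprobated
with wealth missing.  Preprocessing assigns unprobated records the log of
half the period minimum, then mean-centres by decade (decades with fewer
than two records fall back to the global mean, with a warning).  The
1.5×IQR outlier rule uses linearly interpolated quartiles and is
affine-invariant by construction.

The confounding analysis computes, per relationship category, the pair
correlation in status and the pair correlation in paternal wealth (each
member's father's centred log wealth), and reports the Pearson
correlation of these two vectors across categories, with and without the
outlier rule (and a pair-count-weighted variant).  Same-father pairs
(siblings) are excluded: their paternal-wealth similarity is identically
1 by construction and that single degenerate point alone drives the
cross-category correlation to ~0.5 even with no wealth→status channel.
With ~7 categories the cross-category correlation of a pure-noise
similarity vector has sd ≈ 0.4 regardless of noise amplitude (Pearson is
scale-invariant), so zero-loading behaviour is a distributional
statement — near zero on average over seeds — not a per-seed bound.

## Mediator screen

For a labelled correlation matrix `R` with sampling covariance `V` (over
the distinct off-diagonal entries), the partial correlation of A and B
given X is `(r_AB - r_AX r_BX) / sqrt((1 - r_AX^2)(1 - r_BX^2))`, with a
first-order delta-method SE through the analytic gradient and a Wald
two-sided p-value.  The screen repeats this over many candidate
mediators; the default significance rule is uncorrected `p < alpha`
(Benjamini–Hochberg available), and the summary also records, per
mediator, whether the mediator's own partial correlation with B given A
is significant.  The module makes no causal claims: a screen in which
most mediators void the focal correlation shows the data support no
unique mediation story, and the same correlations are consistent with
contradictory causal structures.

The generator builds `R` from a single latent factor
(`r_ij = loading_i * loading_j` plus symmetric noise, projected to the
nearest valid correlation matrix by eigenvalue clipping and diagonal
renormalisation) and attaches a diagonal `V` with the large-sample
Pearson variance `(1 - r^2)^2 / n_effective`; the partial-correlation
code accepts any PSD `V`, so user-supplied full covariances work
unchanged.  Note that under this construction a bounded-loading mediator
cannot fully mediate exactly (that would require a loading of 1); the
canonical screen conditions (`simulate_screen_set`: mediator loadings
0.85–0.95, `n_effective = 500`) instead place the residual partials
within sampling noise while the raw focal correlation stays clearly
significant — the screen's qualitative outcome, with 18 mediators
mirroring a many-measures design whose mediators were selected for high
genetic correlations.

## Classification audit

The default rule flags records with at least one same-sex and at least
one opposite-sex lifetime partner — the minimal reading of a "both
sexes" behavioural classification; thresholds are configurable because
classification choices are exactly what the audit probes.  Rates are
stratified by age at first sex with inclusive band bounds (10–12
contains 10, 11, 12), missing ages form an explicit stratum, and
uncertainty uses exact Clopper–Pearson binomial CIs (strata can be
small) plus Woolf odds-ratio intervals against the oldest band.  The
association test across strata is exact: full enumeration of 2×K tables
with fixed margins (total ≤ 500), seeded Monte-Carlo sampling of tables
otherwise, with the two-sided p-value defined as the total probability
of tables no more probable than the observed one.  The questionnaire
generator plants stratum rates 25% / 9.8% / 2.2% (before 10, 10–12, 13+)
with ages drawn from a rounded normal centred at 18, so early-age strata
are naturally small.

## What the synthetic data do and do not show

The generators reproduce the *structure* of the real analyses — surname
lineages with heavy pair-sharing, probate-style censoring, decade drift,
stratum-dependent classification, latent-factor correlation sets — with
known ground truth, which is what makes the estimators testable.  They
do not model realistic demography (no mortality, migration, overlapping
generations or surname extinction dynamics), real genotypes, secular
trends other than the explicit `t2_schedule`, or the measurement error
of archival records.  Passing tests therefore demonstrate that the
estimators recover truth under the stated model, not that any historical
dataset satisfies that model — which is precisely the interpretive gap
the pipeline is built to expose.

## Problem sizes

Default study conditions: 5,000 founder couples and 5 generations for
closed-form comparisons (≥ 2.6M pairs); 1,000 couples × 100 matched
replicate pairs for the non-identifiability suite; 300 replicates for
coverage; 10^6 draws × 20 correlation sets for the partial-correlation
oracle; 200 seeds for the screen; ~20,000 parent–offspring pairs across
four cohorts for trend detection.  The full test suite runs in about
eight minutes on one CPU; `scripts/acceptance.py` in about one minute.
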