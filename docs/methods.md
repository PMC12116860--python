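# Methods

## The ASEP statistic

ASEP treats a diet as a mixture of energy sources and asks what fraction
of energy came from animal-source ingredients. For scored record entries
with energies E_i (kJ) and item scores ASWP_i ∈ [0, 1],

    ASEP = Σ(E_i · ASWP_i) / Σ E_i.

The statistic is unitless and invariant to energy rescaling, to splitting
an entry into parts with the same score, and monotone in any single item's
score. The period value over several days equals the energy-weighted mean
of daily values; a day with zero recorded energy has no defined daily ASEP
and is dropped with a warning rather than imputed.

Item scores are mass proportions, not energy proportions: the fraction of
ingredient mass (excluding added water and trace ingredients) of animal
origin. This is a deliberate simplification — ingredients differ in
energy yield per mass unit, and a mass-based proportion misallocates
energy for items mixing, say, butterfat with flour. The package documents
rather than corrects this; in the motivating application the affected
mixed-origin items carried under 10% of total energy, most of them fat
spreads whose ingredients have similar energy density.

### Scoring rules

The rule hierarchy is ordered (priority ascending): pure plant → 0, pure
animal → 1, dairy product → 1, meat sausage / cold cut → 1, then a
calculated recipe proportion for remaining mixed items and for generic
database codes (the latter flagged with an `estimated_similar_product`
basis so their provenance is visible downstream). The dairy and
meat-product blanket rules encode the judgement that such products are
>90% animal by energy-relevant mass; the thresholds justify the rules but
are not enforced numerically, since a recipe for, e.g., a fruit yogurt is
rarely available at the precision that would make the check meaningful.
The ordering is configurable because a product can plausibly sit in two
categories (a fruit-milk smoothie recorded as one item is both "dairy"
and "mixed"); the default places the blanket rules above the calculation.

### Diet categories

Vegan means no animal-sourced products at all; vegetarian means no red
meat or poultry, with fish, eggs and dairy permitted (pesco-vegetarians
included); everything else is omnivore. Classification uses the union of
record evidence and optional screener flags, because a few recording days
can miss occasional animal-food use that a frequency screener catches.
Record evidence of red meat or poultry requires an `asf_group` tag on
animal items; the item score alone cannot distinguish beef from cheese.

## Variability and required recording days

Per-person daily-ASEP standard deviations use the population divisor d_i
(the person's day count), matching the estimator the pooled value feeds:

    s_i = sqrt(Σ_day (ASEP_day − m_i)² / d_i),    ŝ = Σ d_i·s_i / Σ d_i.

The d_i−1 divisor would be the conventional unbiased choice; the
population divisor is kept deliberately for fidelity to the estimator
whose outputs the day-requirement formulas consume. Vegans are excluded
from pooling and from the pair correlation: their within-person SD is 0
by definition and would bias both quantities toward optimism.

Beaton's method, in absolute-deviation form, gives the days needed so an
individual's estimated ASEP stays within ±a of their habitual value with
95% confidence: D = ceil(((1.96/a)·ŝ)²), floored at 1. The ceiling is
the conservative reading of a "days required to achieve" target; z is
fixed at 1.96 by default with a hook for other quantiles.

Liu's method addresses group-level correlation analyses: day-to-day
variation attenuates an observed correlation by e = sqrt(1/(1 +
(1−r)/(n·r))), where r is the intraindividual correlation (between-person
variance over total variance) estimated from all within-person day pairs.
Pairs are enumerated exhaustively and entered in both orders
(symmetrized), which removes the arbitrary ordering of a day pair;
the unordered pair count is reported. Pearson correlation is the default
(the framework is variance-based); Spearman is available behind a flag.
The required days for an error-term floor e* (default 0.9) are
D = ceil((e*²/(1−e*²))·(1−r)/r), floored at 1, and the returned D always
satisfies e(r, D) ≥ e* with D−1 failing it except at the floor.

With the pooled SD 0.0813 reported for the motivating cohort, the Beaton
table reads 3 / 11 / 64 / 254 days for a = 0.1 / 0.05 / 0.02 / 0.01. At
a = 0.005 full precision gives 1016 where the published table prints
1015; the printed pooled SD is itself rounded (a value near 0.08127
yields 1015), and the package reproduces the value implied by the printed
SD rather than tuning it.

## Correlation screens

Spearman correlations are tested against a critical |r| derived from the
Student-t approximation t = r·√((n−2)/(1−r²)) with a Bonferroni
correction: r* = t*/√(n−2+t*²) at the two-sided α/m quantile. The number
of tests m is always supplied explicitly — in a block design it belongs
to the block (12 targeted intakes/biomarkers, 872 metabolites in the
motivating study), not to whatever subset of columns happens to be in the
table. At n = 51 the thresholds evaluate to 0.395 (m = 12) and 0.533
(m = 872); published values of 0.40 and 0.54 differ in the final digit,
consistent with rounding up. Missing values are removed pairwise per
feature, with n (and hence the threshold) reported per feature. Constant
features have undefined correlation and are reported missing, never
silently dropped.

The top-k panel (default 20) is ranked by |r| with lexicographic
tie-breaking on feature id for determinism. Complete-linkage clustering
of the panel uses d = 1 − r_Pearson between feature vectors, so heights
live in [0, 2] (0 = perfectly correlated, 2 = perfectly anti-correlated);
the tree is exported as Newick with merge heights as branch lengths.

## The synthetic cohort generator

The generator emulates the statistical structure of a ~51-child cohort
whose raw records cannot be shared; it makes no attempt at culinary or
instrumental realism (no food-composition data, no m/z values — items and
features are opaque). Design choices, with defaults:

* **Categories** 7 vegan / 11 vegetarian / 33 omnivore; 4 recording days
  with a 4/51 fraction having 3 days.
* **Person-level mean ASEP** from two-piece uniform distributions hitting
  the observed ranges and medians exactly: vegetarians 0–0.20 (median
  0.08), omnivores 0.11–0.52 (median 0.33), vegans exactly 0.
* **Daily ASEP** i.i.d. normal around the person mean, censored to
  [0, 1]. Days are independent given the person, so the day-pair
  correlation estimator is unbiased for the generating between/total
  variance ratio; the ground truth records the censored-normal mean and
  variance per person analytically, and the implied ICC. The generating
  SD is inflated by 1/(c4(d)·√((d−1)/d)) relative to the 0.08 target so
  that the population-divisor pooled estimator — the estimator the target
  value refers to — is centred on the target; censoring near 0 for
  low-mean vegetarians pulls the realized pooled SD a few thousandths
  below it.
* **Record realization.** Each day becomes 8–15 entries whose
  energy-weighted score equals the day's target exactly: decoy items are
  placed first, then one pure-animal and one pure-plant balancer absorb
  the closed-form energy remainder (decoys are shrunk if the split is
  infeasible, which terminates because all-plant decoys always admit a
  solution). Exactness makes downstream recovery tests sharp (1e-9)
  instead of statistical. Omnivore balancers are red-meat/poultry items
  and vegetarian balancers dairy/fish/egg items, so record-based diet
  classification agrees with the drawn category.
* **Nutrients** couple to period ASEP through a Gaussian copula on ranks
  (Pearson ρ on the latent scale = 2·sin(π·ρ_s/6)), at Spearman targets
  +0.8 SAFA, −0.8 PUFA, −0.8 fibre, +0.55 protein, +0.7 cholesterol,
  −0.8 folate, with two-piece-uniform marginals spanning the observed
  intake ranges. Realized rank correlations converge to the targets as n
  grows (checked at n = 500 within ±0.05); at n = 51 Monte-Carlo noise of
  roughly ±0.1 is expected, slightly attenuated by the vegan ties at 0.
* **Metabolites**: 872 log-normal features, 20 of them (15 positive, 5
  negative, mirroring the observed sign split) copula-coupled to ASEP
  with |ρ_s| drawn in 0.78–0.92 — strong, biomarker-grade associations by
  design, so that recovering the full planted panel in the top 20 is a
  property of the screen rather than a coin flip (at n = 51 the largest
  null |r| among 852 features is typically ≈ 0.45).

Everything is driven by one seeded generator in fixed order; identical
seeds give byte-identical CSV output.

What passing tests on these cohorts do **not** show: robustness to real
food-composition error, correlated nutrient margins, non-monotone
diet–biomarker relationships, batch effects in metabolomics, or missing
data mechanisms beyond pairwise deletion. The generator plants monotone
signals because the screen is rank-based; it cannot certify behaviour on
signals the screen is not designed to find.

## Numerical and interface choices

* Energies are kJ in files (kcal accepted with explicit conversion at
  4.184 kJ/kcal); the statistic itself is unit-invariant.
* Scores and ASEP values are kept at full precision throughout; rounding
  (nearest whole percent) happens only in reported summaries.
* Medians use the midpoint convention for even counts.
* Day-requirement outputs are integers via ceiling with a floor of one
  day.
* The correlation matrix feeding the cluster tree is symmetrized and
  clipped to [0, 2] to absorb floating-point asymmetry before linkage.
* Degenerate inputs fail loudly with typed errors: zero total energy
  (undefined ASEP), zero non-water recipe mass (undefined proportion),
  no eligible non-vegan participants (no pooled SD), constant features
  (undefined correlation), out-of-domain method parameters.

## Problem sizes used in the checks

The test suite and the acceptance script use the generator at the study's
own dimensions (51 × 3–4 days, 872 features) — single runs for exactness
checks, 20 independent seeds for parameter-recovery and screen-power
properties, n = 500 for copula convergence, and 10⁴ replicates for the
familywise-error simulation at n = 51, m = 12. These sizes give
Monte-Carlo standard errors comfortably inside the stated tolerances.
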