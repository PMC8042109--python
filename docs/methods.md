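# Methods

`paleobrain` implements a phylogenetic comparative workflow for endocast
measurements on a fossil-bearing tree: stochastic time-calibration,
generalized least squares regression under four trait-evolution models with
AIC selection, a phylogenetically derived encephalization quotient,
permutation-based group comparisons, residual-randomization ANOVA, and
ancestral reconstruction of continuous traits and a discrete locomotor
character.  This note records the models, the defaults, and the design
choices made where the design was genuinely open.

## Trees and units

Branch lengths are in millions of years (Myr) throughout; ages are Ma
(millions of years before present).  A `Phylogeny` is rooted; tips are
numbered `0..n-1` in Newick input order and internal nodes `n..2n-2` in
post-order, so node ids are stable across serialisation and key every
exported node table.  Polytomies are accepted and treated as hard.
Unrooted trees and networks are out of scope.

## Covariance models

All regressions model the error covariance of tip values:

* **Brownian motion** — `C[i,j]` = height above the root of the most recent
  common ancestor of tips i and j; the diagonal holds root-to-tip path
  lengths.
* **Pagel's lambda** — off-diagonal entries of `C` multiplied by
  λ ∈ [0, 1]; λ = 1 recovers Brownian motion, λ = 0 a star phylogeny.
* **Early Burst** — time is warped by the decelerating-rate integral
  `t → (e^{rt} − 1)/r` with r ≤ 0 before shared paths are measured; r = 0
  recovers Brownian motion.
* **Ornstein–Uhlenbeck** — the stationary correlation `exp(−α·d_ij)` with
  unit diagonal, where `d_ij` is patristic distance.  On a non-ultrametric
  (fossil-bearing) tree several OU parameterisations exist; the stationary
  form is used because it remains a valid correlation matrix regardless of
  tip ages.  The rate scalar σ² absorbs the overall scale in every model
  and is profiled out during fitting.

## PGLS and model selection

Coefficients are `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y`, computed through a Cholesky
whitening of V (one shot of `1e-10·mean(diag)` jitter if V is numerically
singular; failure after that is an error).  Estimation is **maximum
likelihood, not REML**, because the workflow compares formulas with
different fixed effects by AIC, which is invalid under REML.  Fits by tools
whose default is REML will therefore differ slightly in the reported
likelihoods and information criteria.

The covariance parameter (λ, α, or r) is profiled by a coarse grid (25
points) followed by bounded Brent refinement inside the bracketing
interval; the optimum is checked against the best grid point.  Bounds:
λ ∈ [0, 1], α ∈ (10⁻⁶, 50/h], r ∈ [−10/h, 0] with h the tree height.

Six named regressions (`1.EB`, `1.PB`, `1.OB`, `2.PE`, `2.NE`, `2.OE`)
relate log10 brain measurements to log10 body mass or brain size plus a
five-level locomotor factor (arboreal, fossorial, glider, scansorial,
terrestrial).  Formula "a" has no interaction; formula "b" adds
`predictor1 × locomotion`.  Selection fits all four covariance models per
formula, takes each formula's AIC minimum, then the overall minimum, with
exact ties resolved toward the simpler formula "a"; the full 8-fit trace is
retained.  The locomotor factor uses treatment coding with **arboreal**
(alphabetically first) as reference — contrasts affect coefficients but not
AIC, log-likelihood, or the sequential tests.

Per-term p-values are **sequential (Type I) F tests** in formula order
(predictor 1, locomotion, interaction) computed from generalized residual
sums of squares under the fitted covariance, with denominator df `n − p`.
Exported degrees of freedom are the pair `(n, n − p)`; this convention is
documented rather than asserted as universal.  λ̂ from the lambda-model fit
of the selected formula is reported for every regression regardless of
which model won, as a phylogenetic-signal summary.

A diagnostic decides OLS vs PGLS: OLS residuals are laid out in the
post-order tip sequence and scored by the mean absolute difference between
adjacent residuals; a permutation test (999 shuffles by default) flags
clustering at the 5% level.  I.i.d. residuals are flagged at roughly the
nominal rate; Brownian-simulated residuals on a 38-tip tree are flagged in
well over 80% of replicates.

## Time-calibration

Fossil tip ages are known to stratigraphic intervals (NALMA-style bins of
2–5 Myr).  Calibration draws each tip age uniformly inside its
first-appearance interval, then dates each internal node
`mbl + Exp(node_incr)` older than its oldest child (`mbl` = 0.1 Myr,
`node_incr` = 2 Myr by default).  This is a deliberate simplification of
likelihood-based (cal3-style) time-scaling, which additionally models
branching, extinction, and sampling rates: the topology here is fixed, so
all dating uncertainty lives in node ages.  The exponential waiting time
matters: a pure minimum-branch-length rule dates every node exactly 0.1 Myr
above its oldest child, collapsing clades of extant tips into near-zero
combs (on synthetic data this halves the total tree length and saturates
the discrete-character rate estimate).  One hundred calibrated trees are
drawn from per-tree seeds expanded from a master seed; downstream analyses
use the per-node **mean-age average tree** (valid because the topology is
shared, so tree variation is entirely in node ages).  Extant tips are
pinned at age 0; their Pleistocene first-appearance interval is a
feasibility convention only.

## Encephalization quotients

`EQ = E_i / (0.12·M^0.67)` uses Jerison's mammal-wide constants.  The
phylogenetic variant `PEQ = E_i / (a·M^b)` takes `a = 10^intercept` and
`b = slope` from the PGLS regression of log10 endocranial volume on log10
body mass under the AIC-selected covariance model.  The exponent is
unit-free; the coefficient depends on units (grams, mm³ here) and both
facts are attached to every fitted model.  Component percentages are
`OB% = 100·V_OB/E_i`, `PL% = 100·V_PL/E_i`, `Neo% = 100·SA_N/SA_E`;
missing measurements propagate as missing, never as zeros.

A caveat on a tempting invariant: the geometric mean of PEQ over the
fitting sample is close to 1 only when phylogenetic signal is weak.  Under
λ-correlated residuals the GLS intercept estimates the **root** value, and
the shared drift of the tips away from the root (standard deviation roughly
√(mean off-diagonal covariance), ~0.05 dex at the default settings) moves
the tip-average residual; deviations beyond 10% are possible for ordinary
seeds.

## Permutation tests

The K-sample Fisher–Pitman test uses the asymptotic (moment-based) form:
the linear statistic is the vector of within-group sums, whose exact
permutation mean and covariance have closed forms; the quadratic form with
a generalized inverse is χ² with k−1 df.  Pairwise comparisons use the
standardized two-sample statistic with a normal reference and
Benjamini–Hochberg adjustment over the 10 pairs.  An exact-enumeration mode
(all distinct group assignments, n ≤ 12) serves as the oracle in tests.

The χ² approximation to the discrete permutation null is accurate in the
decision-relevant tail (agreement within 0.05 for p ≤ 0.1 on balanced
two-group fixtures at n = 10) but can sit a whole atom away in the centre
of the distribution — at n = 10 the null has only 252 support points.
Agreement claims are therefore stated for the tail, not uniformly.

Preconditions follow the usual route: Shapiro–Wilk for normality (delegated
to scipy), then Bartlett (normal) or Brown–Forsythe Levene with median
centring (non-normal; mean centring by flag).  A failed homogeneity check
attaches a warning to the result — e.g. the neocortex block typically
violates homogeneity — rather than refusing to compute.

## RRPP ANOVA

The non-phylogenetic ANOVA permutes reduced-model residuals: for each term,
residuals of the model excluding it are shuffled, added back to the reduced
fitted values, and the sequential F recomputed; `p = (#{F* ≥ F} + 1)/(B+1)`
with B = 1000 iterations by default and a mandatory seed.  Post-hoc
pairwise statistics are distances between group least-squares means with
the covariate at its grand mean (slope-adjusted when the interaction
formula was selected), referred to the same residual-randomization
distribution, unadjusted by default (BH by flag).  Pairwise tests are run
only when the locomotion term is significant at 5% in the ANOVA.  Null
simulations put the empirical type-I error of the locomotion term inside
[0.03, 0.07] at α = 0.05.

## Ancestral reconstruction

**Continuous traits** are reconstructed under Brownian motion by GLS: the
root estimate is `(1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x` and every internal node receives its
conditional expectation given the tips, which equals the re-rooted ML
estimate (verified against an independent belief-propagation implementation).
BM is assumed regardless of which covariance model the corresponding
regression selected, matching standard practice for this estimator.  Seven
traits are reconstructed: PEQ, the PGLS allometric residual (the documented
reading of "residuals"), log10 endocranial volume, log10 body mass, and the
three component percentages; traits with missing species run on the
correspondingly pruned tree.

**The locomotor character** evolves under a continuous-time Markov model
with equal rates (Mk-ER): off-diagonal rate q, diagonal −(k−1)q, so the
transition probabilities have the closed form
`P_ii = 1/k + (k−1)/k·e^{−kqt}`.  q is estimated by maximising the
Felsenstein pruning likelihood (grid + Brent in log space) with a uniform
root prior, which for ER is also the stationary distribution.  Stochastic
character maps first sample joint node states from the conditional
distribution (root draw from prior × partials, then child draws down the
tree), then fill in each edge's substitution history conditioned on its
endpoints by rejection sampling (budget 100 attempts) with a
uniformization bridge as fallback.  Node state probabilities are
frequencies across maps (1000 by default); per-state occupancy times and
per-map change counts are also reported.  Note the rate convention when
reasoning about change counts: the total rate of leaving a state is
(k−1)q, i.e. 4q for five states.

## Synthetic data

The generator emulates the structure of a fossil-inclusive rodent endocast
study; its defaults are the emulated study conditions and are not tuning
knobs:

* **Tree** — forward birth–death simulation (birth 0.12/Myr, death
  0.06/Myr, origin 56 Ma) conditioned by rejection on ≥ 25 surviving and
  ≥ 13 extinct lineages inside a 10–52 Ma fossil window; 25 extant and 13
  fossil tips are then subsampled, giving 38 tips.
* **Locomotion** — five states simulated under ER with q = 0.01/Myr from a
  scansorial root; by default resimulated until all five categories appear
  among the tips (disable `require_all_categories` for rare-change
  scenarios).
* **Body mass** — Brownian motion on log10 grams (root 2.7 ≈ 500 g, rate
  0.007 per Myr).
* **Endocranial volume** — `log10 E = log10 0.42 + 0.57·log10 M` plus
  locomotor offsets (fossorial −2, arboreal +1, in units of the residual
  SD 0.103) plus λ-transformed Brownian noise (λ = 0.72) scaled so the mean
  tip variance is 0.103²; the noise law lies inside the lambda family the
  regressions fit.
* **Component fractions** — generated on the logit scale around root
  baselines Neo 18.3%, PL 1.25%, OB 5.8% with logit-SD 0.30 and the same
  offset pattern (reversed and halved for the olfactory bulbs, which run
  opposite to the neocortex in fossorial taxa), then back-transformed; the
  logit keeps every percentage inside (0, 100) so trait-table invariants
  hold automatically.  Surfaces derive from volumes via a near-spherical
  `SA = 4.84·V^{2/3}`.
* **Missingness** — one extant glider lacks petrosal lobules, so
  petrosal analyses run at n = 37.
* **Age bins** — fossil tips receive intervals of width 2–5 Myr containing
  the true age; extant tips are 0.

What the generator does **not** emulate: measurement error from CT
segmentation, the empirical magnitude of locomotor separation (real
fossorial/arboreal contrasts are larger), body-mass estimation error, and
named-clade structure.  Passing tests on synthetic data therefore show the
estimators recover known generating values under study-shaped conditions;
they do not certify agreement with any particular empirical dataset.

## Problem sizes and reproducibility

Default analysis sizes: 100 calibrated trees, 1000 RRPP iterations, 1000
stochastic maps.  Recovery simulations use 200 replicate datasets; null
calibrations use 500 simulations at 99 permutations each.  All randomness
flows from a master seed through named substreams (calibration, rrpp,
simmap, diagnostic), so a config + seed pair regenerates every output file
bit-identically.  The acceptance script averages recovery-type quantities
(allometric exponent and coefficient, λ̂, ASR roots) over 10 replicate
datasets to shrink the Monte-Carlo error of a single 38-species draw;
single-run quantities (χ² blocks, Mk rate, map summaries) come from one
full-size run.

## Known limitations

* The time-calibration is a stand-in for rate-informed (cal3-style)
  dating; absolute node ages — and anything downstream of them — carry that
  simplification.
* λ̂ at n = 38 is strongly variable (SD ≈ 0.36 across replicates) and
  biased toward the interior; only replicate means are meaningful.
* The Mk-ER rate estimate degrades when the dated tree compresses real
  branch-length structure; comparing q̂ across differently calibrated trees
  is not meaningful.
* OU fits use the stationary-correlation convention; other OU variants
  (e.g. fixed-root) would give different α̂ on fossil-bearing trees.
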