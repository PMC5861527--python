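# Methods

This note records the statistical models implemented in `avadjust`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Recoding model

The non-parametric vignette adjustment locates a self-rating *y* ∈ 1..m
relative to the respondent's own ratings *z₁…z_K* of K design-ordered
vignettes. Categories on the adjusted 2K+1-point scale alternate between
gaps (odd) and exact ties with a vignette (even).

**Ties and violations.** With B = #{j : z_j < y} and E = #{j : z_j = y},
the adjusted answer is the category 2B+1 if E = 0 and the interval
[2B+2, 2B+2E] otherwise. Because B and E depend only on the multiset of
vignette ratings, order violations among the vignettes are automatically
treated as ties; this is equivalent to sorting the respondent's vignette
ratings into the design order before recoding. The test suite proves the
formula against an independent brute-force oracle that enumerates
extensions of the observed weak order (vignette-vignette ties refine
freely; a self-rating tied with vignettes stays weakly inside its tied
block) over all m^(K+1) = 625 input combinations for m = 5, K = 3.

**Strict mode.** For comparison, `mode="strict"` keeps the design order:
each comparison of *y* with *z_j* constrains the category, constraints are
intersected, and a contradictory set (an order violation) is widened to the
span between the clashing bounds. When no contradiction exists, the strict
interval always contains the ties-mode scalar.

**Scalarization.** Default is the interval lower bound (the variant with
the best reliability track record); `upper` and `midpoint` are provided for
sensitivity analysis. Entropy of a vignette set is the Shannon entropy
(nats) of the scalarized category distribution; interval mass is not
fractionally allocated across categories — a deliberate simplification,
configurable only by choosing a different scalarization.

**Missingness.** A missing self or vignette rating propagates to a missing
adjusted value for the affected construct only; nothing is imputed.

## Cleaning rules

Respondents are removed when any of four rules fires, evaluated on the
original keyed table (no iterative re-cleaning), and reported under the
first firing rule in this order:

1. *missing*: strictly more than 10 % of the survey columns unanswered
   (all declared columns by default; configurable to the self-report +
   vignette block);
2. *low variance*: population variance of the respondent's own answered
   self-report + vignette responses strictly below 0.5 (computed after
   keying; the boundary value 0.5 is retained);
3. *pattern*: straightlining, operationalized as the longest run of
   identical consecutive responses over the self-report + vignette columns
   at ≥ 90 % of answered columns — the concern is standard, the detector is
   this package's choice;
4. *consistent violations*: vignette-order violations in ≥ 3 of the 5
   vignette sets (configurable).

Removal percentage is exactly removed/initial.

## Graded response model

Unidimensional per construct, P(X ≥ k | θ) = logistic(a(θ − b_{k−1})),
identified by fixing θ ~ N(0,1) (marginal ML). Estimation is EM on a fixed
grid of 61 equally spaced nodes on [−6, 6] weighted by the standard-normal
density (Gauss–Hermite was considered; the rectangular grid matches the θ
range used for reporting and makes information curves free). The M-step
maximizes each item's expected complete-data log-likelihood with L-BFGS in
an unconstrained parametrization (log a, b₁, log threshold gaps), which
enforces a > 0 and strictly increasing thresholds. Convergence: marginal
log-likelihood gain < 1e−4 (monotonicity is asserted every iteration);
non-convergence at the iteration cap is flagged, not raised. Observed
categories are collapsed onto consecutive codes per item; items with a
single observed category are excluded with a flag.

Standard errors come from the observed information matrix — a full central
finite-difference Hessian of the marginal log-likelihood in the
unconstrained parametrization, mapped to (a, b) by the delta method.
Confidence intervals are Wald at 95 % by default; the interval construction
is a package choice and configurable.

Item information uses the graded-response formula Σ_k (P′_k)²/P_k; test
information is the item sum and the latent-score standard error is 1/√I.

**Response-consistency check.** Threshold k estimates are pooled within
each instrument (vignette items vs self-report items) by inverse-variance
weighting; the two pooled Wald CIs are tested for overlap per index, and
the requirement is judged met when ≥ 75 % of indices overlap (cutoff
configurable). Index-matched pairing is used because no substantive mapping
between vignette and self-report thresholds is available. Threshold indices
that are not estimable in one instrument (rare categories in small samples)
are excluded from the denominator.

## Reliability

ω-total from a single-factor ML fit of the item covariance matrix:
ω = (Σλ)² / [(Σλ)² + Σψ]. The fit concentrates the loadings out: for fixed
uniquenesses the optimal loading vector is the leading eigenvector of
Ψ^{−1/2} S Ψ^{−1/2}, so only log ψ is optimized (uniquenesses floored at
1e−6; hitting the floor flags a Heywood case). Covariances are
pairwise-complete under missingness. CIs are percentile bootstrap over
respondents (B = 1000 default, seeded); the before/after comparison calls a
difference significant iff the two CIs are disjoint. The covariance-based ω
equals coefficient alpha under tau-equivalence (asserted to 1e−6 in tests)
and is invariant under a common rescaling of the items; it is *not*
invariant under per-item rescaling (that would require the correlation-based
variant, which breaks the alpha identity). Hierarchical ω is out of scope.

## Confirmatory factor analysis

Simple-structure correlated-factors model on Pearson covariances of the
integer item scores (polychoric estimation is out of scope). Identification:
unit factor variances, so loadings are standardized against the factors.
The ML discrepancy F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p is minimized by
L-BFGS from a deterministic start (loadings from item–scale-score
covariances, uniquenesses at half the item variance, factor correlations at
zero); factor correlations are parametrized through a row-normalized
Cholesky factor, which keeps the matrix positive definite with a unit
diagonal. χ² = (n−1)F; CFI against the independence baseline; RMSEA =
√(max(χ²−df,0)/(df(n−1))). A 36-item five-factor model has
666 − (36+36+10) = 584 degrees of freedom.

*Pruning* removes, one at a time, the item with the smallest standardized
loading below 0.20 (or negative), refitting after each removal, with a
floor of 3 items per factor and index-order tie-breaks — deterministic
given a fit. *Configural* multigroup fit is implemented as independent
per-group fits with summed χ² and df (equivalent to a configural model with
all parameters free); combined CFI uses the summed baselines, combined
RMSEA the total n. The expected factor-correlation pattern (neuroticism
negative with the rest, others weakly positive) is a reporting observation,
never a constraint.

## Criterion validity

Scale scores are available-case item means (missing below 50 % answered).
Constructs whose vignettes are worded against the conventional scoring
direction (neuroticism via emotional-stability vignettes) carry a codebook
flag and are flipped at scoring time only, so recoding always happens in
the vignette orientation. Spearman ρ uses average-rank ties with the
two-sided t-approximation. The raw-vs-adjusted change in an outcome
correlation is tested with Steiger's z for two dependent correlations
sharing one variable, via Fisher's transformation; the test's null
calibration is verified by Monte-Carlo in the suite.

## Synthetic cohorts

The generator emulates the measurement situation the pipeline assumes: two
groups (default sizes 423 and 143), five latent traits correlated at 0.20
(neuroticism generated in its stability orientation), 8–10 five-point items
per trait (44 total, roughly one third reverse-keyed), three vignettes per
trait at latent locations (−1.5, 0, 1.5), a 5-item life-satisfaction scale,
and a 7-item counterproductive-behavior scale on 7 points.

Each respondent draws one set of person thresholds
τ_k = α + γ(b_k + δ_g) with acquiescence α ~ N(0, 0.3), extremity
γ ~ LogNormal with unit mean and log-sd 0.25 (a mean-preserving spread, so
raising the dispersion adds extreme responders without shifting the average
scale use), base thresholds b = (−1.8, −0.6, 0.6, 1.8), and a group
threshold shift δ = (0, 0.8) — DIF that leaves the latent traits untouched.
The *same* thresholds generate self-report, vignette, and outcome
responses, so response consistency holds by construction. Self responses
follow the graded mechanism (count of thresholds below a·θ + standard
logistic noise, item discriminations uniform on 1.2–2.2); vignette ratings
apply the same mechanism to discrimination 2.5 times the vignette location
plus N(0, 0.2) perception noise, with the logistic rating noise separately
switchable (`vignette_rating_noise=0` makes vignette ratings deterministic,
hence perfectly ordered). Under the defaults this yields roughly 52–62 %
correct orderings, 30–40 % ties and 5–10 % violations per construct —
magnitudes typical of field administrations of three-vignette sets — and
these rates were not fit to any particular dataset. An optional misorder
injection permutes a respondent's vignette ratings with a given
probability; outcomes are linear in the latent traits plus noise and can be
discretized with base thresholds instead of person thresholds
(`outcome_styles=False`) when a style-free criterion is wanted. All
randomness flows from one seed through named substreams.

**What the cohorts do not emulate.** Item-level DIF heterogeneity (all
items of a group shift together), translation artifacts, vignette-specific
quality problems, non-monotone response styles, and planned missingness.
Passing tests on these cohorts therefore demonstrate that the pipeline
recovers truth under its own assumptions — group-level threshold DIF plus
person styles — not that the adjustment cures every real-world artifact.

**A consequence worth knowing.** All of a construct's adjusted items are
recoded against the same three vignette ratings, so vignette rating noise
is shared across the construct: adjusted scores are internally consistent
(ω rises) and group-comparable (bias falls), yet individually *noisier*
measures of the latent trait than raw item means. Criterion correlations
therefore tend to shrink after adjustment — visible in the pipeline's
validity table — and the adjustment's demonstrable benefit is between-group
comparability, not individual-level predictive power.

## Problem sizes and numerical defaults

Tests and examples use cohorts of 200–2000 respondents, GRM recovery at
n = 2000 with 8 items, CFA recovery at n = 500–600 with 30–44 items, and
bootstrap sizes of 20–1000 — sizes at which each stage's sampling error is
comfortably below the asserted margins. Degenerate inputs are handled
explicitly: empty tables, non-positive-definite covariances (rejected with
a ridge-repair suggestion), single-category items (excluded), all-missing
rows (dropped), Heywood cases (floored and flagged), constant score vectors
(correlations reported missing). Pipeline outputs contain no timestamps and
all randomness is seeded, so identical configurations reproduce identical
artifacts.
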