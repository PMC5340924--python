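# Methods

`gradedcat` implements a five-stage psychometric evaluation and adaptive-
testing simulation for short screening questionnaires whose items are scored
on three ordered categories (0 = no, 1 = sometimes, 2 = regularly or more).
The package is organized around a four-scale, 50-item primary-care
mental-health instrument (distress 16 items, depression 6, anxiety 12,
somatization 16), but every stage works for any scale composition.

## The measurement model

Each scale is modelled with Samejima's graded response model (GRM). For item
*j* with discrimination α_j > 0 and ordered thresholds β_{j1} < β_{j2}, the
boundary probabilities at trait level θ are

    P*_{jk}(θ) = 1 / (1 + exp(−α_j (θ − β_{jk}))),   k = 1, 2,

and the category probabilities are the adjacent differences
p_0 = 1 − P*_1, p_1 = P*_1 − P*_2, p_2 = P*_2. Two conventions matter and
are fixed throughout:

* **Logistic metric, no 1.7 constant.** Discriminations are logit slopes per
  unit θ. Published values such as α = 7.377 are treated as logistic slopes;
  a normal-ogive reading would rescale every α by ≈1.7.
* **Ordered thresholds by construction.** During estimation the second
  threshold is parameterized as β_2 = β_1 + exp(δ), so p_1 ≥ 0 always.

Fisher information is I_j(θ) = Σ_k (∂p_k/∂θ)² / p_k with
∂P*_k/∂θ = α P*_k (1 − P*_k); it is additive over items under local
independence, and SE(θ) = I^{−1/2}.

## Stage 1 — descriptives

Raw 5-option frequency answers (0–4) are collapsed to 0/1/2 by the scoring
rule 0→0, 1→1, {2,3,4}→2; already-collapsed input is detected (max code ≤ 2)
and passed through. Missing answers are never imputed: persons with any
missing cell are dropped once, at load, and the exclusion list and retention
percentage are always reported. Scale totals are plain sums; the standard
error of the mean total is SD/√n with the n−1 denominator SD (the
alternative n-denominator changes nothing at realistic n). Internal
consistency is Cronbach's α = (k/(k−1))(1 − Σ s²_i / s²_total) with sample
variances, plus α-if-item-deleted.

## Stage 2 — IRT assumptions

**Unidimensionality.** A polychoric correlation matrix is estimated two-step
(thresholds from the marginal cumulative proportions via Φ⁻¹; each pairwise
ρ by bounded 1-D maximum likelihood on (−0.999, 0.999)). The bivariate
normal rectangle probabilities use the Owen's-T identity
(`scipy.special.owens_t`), exact to machine precision, with explicit
handling of zero and infinite cut points. A one-factor model is then fit by
unweighted least squares on the off-diagonal entries, starting from squared
multiple-correlation communalities — the classical minres start, which also
resolves the degenerate diagonal-matrix case where any single-spike loading
vector has zero off-diagonal discrepancy.

Fit indices: SRMR is the root mean square off-diagonal residual. CFI, TLI
and RMSEA are computed from a normal-theory ML discrepancy chi-square
evaluated at the ULS solution, with the zero-correlation model as baseline.
This is a documented approximation: the chi-square treats the polychoric
matrix as if it were a Pearson matrix from normal data, so it over-rejects
at small n where polychoric sampling error dominates. On data simulated
from a single-trait bank, all four good-fit verdicts (CFI > .95, TLI > .95,
RMSEA < .06, SRMR < .08) hold at n = 2000; at n ≈ 380 the chi-square-based
indices can fail on truth-unidimensional data while SRMR stays clean. The
contract of this stage is therefore the threshold verdicts at calibrated
sample sizes, not agreement with any particular robust-weighted CFA
estimator to the third decimal.

**Local independence.** Residuals are observed-minus-implied correlations on
the polychoric scale; unordered pairs with residual > 0.2 are flagged,
sorted descending.

**Monotonicity.** Polytomous Loevinger coefficients:
H_ij = cov(X_i, X_j) / cov_max(X_i, X_j), where cov_max is the covariance of
the comonotonically paired sorted marginals — the largest covariance the
observed marginals permit. Item and scale coefficients aggregate the
numerators and denominators separately; H > 0.3 is read as adequate
scalability. Rest-score trace lines bin persons by total-minus-item score,
merging bins greedily from the low end until each holds `min_group`
persons. Two violation flags are reported per adjacent bin pair: a strict
one (any mean decrease beyond 1e−9, appropriate for deterministic data) and
a significance-qualified one (decrease exceeding its two-sample standard
error at one-sided 5%), because with ~50-person bins an exactly monotone
model still produces raw inversions of 0.03–0.09 by sampling noise alone.

## Stage 3 — calibration

Marginal maximum likelihood via EM. The population distribution is N(0, 1)
discretized on 61 equally spaced nodes over [−4.5, 4.5] with normal-density
weights. The E-step computes each person's posterior over the grid; the
M-step improves each item's expected complete-data log-likelihood with a
few bounded L-BFGS steps (analytic gradients) in (α, β_1, δ) — a
generalized EM, so the marginal log-likelihood is monotone across
iterations (asserted in tests). Bounds α ∈ [0.05, 50], β ∈ [−10, 10]
stabilize extreme items. Convergence is a maximum absolute parameter change
below 1e−5 (default cap 500 iterations); failure raises an error carrying
the log-likelihood trace, never a silent result. Items whose top category
is unobserved are calibrated as two-category items and flagged
(`collapsed`), with a placeholder far-right β_2 in the returned bank.

Standard errors come from a per-item observed-information block: the
marginal log-likelihood is profiled over one item's three parameters with
the others fixed, and a central-difference 3×3 Hessian is inverted. With
n = 2000 cohorts simulated from the fixture bank, recovered discriminations
correlate with truth above 0.95 and threshold RMSEs sit near 0.05 (well
under the 0.15 tolerance asserted for items with α ≤ 4); items as extreme
as α = 7.4 recover with larger, honestly reported uncertainty.

Category response curves are tabulated on a grid spanning at least [−4, 4];
an item is flagged CRC-anomalous when the middle category is modal at no
grid point, which happens when its two thresholds nearly coincide
(max p_1 = 2σ(αd/2) − 1 at the threshold midpoint, small when the spacing d
is small).

## Stage 4 — differential item functioning

For each item and each binary grouping (sex as given; age dichotomized at
the sample median), three cumulative-logit models are fit by ML with
`statsmodels`' `OrderedModel`: response ~ θ; + group; + θ×group, where θ is
the person's EAP score on the item's scale under the calibrated bank (a
single pass; no purification loop). Each model warm-starts from the
previous one with the new coefficient at zero, which enforces the nesting
numerically. Uniform DIF is the McFadden pseudo-R² gain of the group main
effect, non-uniform DIF the gain of the interaction; the null log-likelihood
uses the closed multinomial form. An item is flagged when either gain
reaches 0.03 **and** the corresponding likelihood-ratio test has p < .01 —
a two-part "significant and relevant" rule that keeps trivial but
significant effects at large n from flagging. Operating characteristics on
synthetic data: with permuted labels at n = 1000/group the flag rate is
≤ 2%; a uniform −0.8 threshold shift on a median-discrimination item
(α ≈ 2.4) is flagged with ≥ 90% power and localized to the injected item.
Note that the same shift on a weakly discriminating item (α ≈ 1.5) yields
ΔR² right at the 0.03 boundary — the effect size on the response scale
grows with α, so hosts for power evaluation should be representative items.

## Stage 5 — post-hoc CAT simulation

The adaptive loop replays complete observed records; answers are looked up,
never generated, and nothing in the loop is random. The trait estimator is
EAP under a N(0, 1) prior on a 61-node grid spanning ±6 prior SDs — well
defined from zero items (where it returns the prior, matching "start at
θ = 0"), never divergent on all-0/all-2 records, and within 1e−3 of a
2001-node dense quadrature. Item selection is maximum Fisher information at
the current estimate, ties to the earliest bank position. Stopping is
checked after every administered item (minimum one), SE rule before the
length cap: stop when SE(θ̂) ≤ the threshold, or when ⌊k/2⌋ items have been
given (where the cap is enabled), or when the pool is exhausted.

Cohort summaries report the mean and SD (across persons) of items
administered and the Pearson correlation (Spearman alongside) between
adaptive and full-scale EAP scores. At threshold 0 the adaptive run
administers everything and reproduces the full-scale estimate bit for bit
(the posterior is accumulated in bank order to make this exact), so the
correlation is exactly 1. The full-scale reference threshold is the cohort
mean EAP SE using all items, rounded **up** to the nearest grid value
(grid 0.2–0.8 by 0.1), so the adaptive test is never allowed to be less
precise than the full scale; the unrounded value is returned alongside.
The whole-questionnaire report runs each scale at its reference threshold,
adds the half-length cap where configured, and prints per-scale means,
the total expected adaptive length and the percent reduction versus the
full questionnaire (rounded to an integer).

## The synthetic-data generator

The generator emulates the structure of the motivating study, not its
patient data: n = 379 complete responders (of 408 approached), 66.8%
female, age 44.8 ± 16.5 clipped to 16–87, four scales of 16/6/12/16
three-category items. Latent traits are standard normal per scale with a
configurable cross-scale correlation (default 0.6 — the scales measure
related constructs but all analyses treat them separately; the true
correlation in the study sample is unknown, so this is a stand-in, not an
inference). Responses are drawn cell-wise from the GRM. The fixture bank
carries the five published parameter values verbatim (full sets for the two
depression items, the top discrimination of each remaining scale) and fills
the rest with deterministic seeded draws: α ~ U[1.0, 3.5], β_1 ~ U[−1, 1],
β_2 − β_1 ~ U[0.5, 1.5], from a fixed seed so the bank never drifts. DIF is
injected by shifting a focal group's thresholds (uniform) and optionally
scaling its slope (non-uniform).

What the generator does **not** reproduce: the real items' actual
discrimination profile (the real depression scale reaches a full-scale SE
of 0.2 with six items, which the filler band cannot), item wording or
content effects, response styles, missing-data mechanisms, and any
between-scale structure beyond a single correlation. Passing tests
therefore demonstrate that the algorithms behave correctly under a known
GRM truth at realistic sizes — not that the real questionnaire would yield
these exact efficiency numbers. On the synthetic four-scale cohort the
dual-rule simulation reduces the 50-item form to ≈22–24 expected items
(≈52–57% reduction) with per-scale adaptive-vs-full correlations ≥ 0.95 —
the same regime the motivating study reports.

## Numerical choices and problem sizes

* Quadrature: 61 nodes for both EM ([−4.5, 4.5]) and EAP (±6 SD);
  validated against 2001-node references.
* Polychoric ρ search: bounded Brent on (−0.999, 0.999), xatol 1e−7; cell
  probabilities clipped at 1e−12 before logs.
* Probability floors 1e−10 in the EM objective, 1e−300 in EAP posteriors.
* Ties in item selection break to the earliest bank position; rest-score
  bins merge from the low end; the reference SE rounds up.
* Test and acceptance runs use cohorts of 150–2000 persons and 10
  calibration seeds — sizes chosen so every Monte-Carlo assertion has
  comfortable margins while a full run stays interactive.

## Known limitations

* The fit-index chi-square is a normal-theory approximation on polychoric
  input; treat its verdicts at n ≲ 500 with caution (SRMR is the robust
  member of the quartet here).
* Standard errors for extreme discriminations (α ≳ 5) are wide and the
  observed-information block can be near-singular; such items are reported
  with NaN SEs rather than fabricated precision.
* No iterative DIF purification, no content balancing or exposure control,
  no multidimensional models — all deliberately out of scope.
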