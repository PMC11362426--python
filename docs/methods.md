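# Methods

## Model

`mixgpcm` fits the restrictive mixed generalized partial credit model
(rmGPCM): a finite mixture of adjacent-category logit IRT models for
polytomous rating-scale items. A person in latent class *g* with trait value
θ responds to item *i* in category *x* ∈ {0, …, m} with probability

    P(x | θ, g) = exp( Σ_{s=0}^{x} δ_i (θ − τ_{isg}) )
                  / Σ_{c=0}^{m} exp( Σ_{s=0}^{c} δ_i (θ − τ_{isg}) )

and the marginal category probability mixes over classes with weights π_g.
The "restrictive" constraints are: class-specific step thresholds τ_{isg}
(with τ_{i0g} ≡ 0), class-invariant discriminations δ_i (δ_1 = 1 for
identification), a normal trait within class with mean zero and a freely
estimated class variance σ_g², and mixture weights on the simplex. The free
parameter count is therefore I·m·G + (I − 1) + G + (G − 1).

The mixture structure absorbs *response styles*: classes differ in their
threshold geometry, so the same trait level maps to different category-use
patterns (ordinary use, extreme-category preference, a restricted range of
preferred categories) without contaminating the trait estimate.

## Estimation

Marginal maximum likelihood by EM over the joint latent structure
(class × trait). The trait integral uses a fixed Gauss–Hermite rule on the
standard-normal scale with θ = σ_g·u, so the node weights never change and
σ_g enters the response kernel; 49 nodes is the default
(`EstimationOptions.n_quadrature_nodes`), which reproduces the toy-model
integrals to better than 1e−8 against adaptive quadrature. Tests and
simulations mostly use 21 nodes, which changes fitted log-likelihoods by
< 1e−6 on the designs used here.

* **E-step.** Persons are collapsed to unique response patterns; the
  posterior over (class, node) cells is computed with log-sum-exp
  stabilization throughout (safe up to |δθ| ≈ 700).
* **M-step.** Mixing weights update in closed form. Thresholds,
  log-discriminations and log-trait-SDs are updated jointly by L-BFGS on the
  expected complete-data log-likelihood with analytic gradients
  (the multinomial score chain rule; verified against finite differences),
  warm-started at the current values so each step cannot decrease the
  observed-data likelihood (generalized EM). `mstep_maxiter` (default 25)
  bounds the inner iterations.
* **Starts.** `n_starts` (default 20) random initializations — item
  thresholds equally spaced around an item-mean-matched center plus
  N(0, 0.25²) jitter, uniform weights, σ_g = 1 — each run for
  `burnin_iterations` EM steps; the best continues to convergence
  (relative log-likelihood change < 1e−8, cap 1000 iterations). A
  non-converged run is returned with `converged=False`, not an exception.
* **Canonical order.** Classes are relabeled by decreasing π̂_g after
  fitting; the likelihood is label-invariant, so this is presentation only.
* **Missing data.** Missing responses are dropped from the within-person
  item product (missing at random). An item observed in fewer than two
  categories aborts with an error naming the item: its thresholds are not
  identifiable.

Person scores are EAPs mixing the class-conditional posteriors; the
posterior variance includes the between-class dispersion of the
class-conditional means. The single model-based reliability coefficient is
Var(EAP) / (Var(EAP) + mean posterior variance) — the score-variance
decomposition implied by describing total variance as class-level score
variance plus average score uncertainty. Alternative decompositions (e.g.,
true-score regressions per class) exist; this one is the documented choice
because it needs nothing beyond the fitted posteriors.

## Model selection and absolute fit

Candidates over a class range are compared by the sample-size-adjusted BIC,
saBIC = −2LL + p·ln((N + 2)/24), with BIC and AIC reported alongside; the
lowest saBIC wins and ties go to the smaller class count. N is the number of
persons in the fitted subsample.

Absolute fit uses Pearson X² and the Cressie–Read power divergence
(λ = 2/3) over the distinct *observed* response patterns. Pearson adds one
aggregate cell for the expected mass of unobserved patterns; expected
probabilities below 1e−300 are floored and counted. Because the pattern
space dwarfs any sample, the χ² reference distribution is unusable and
p-values come from a parametric bootstrap: B datasets of the original size
are simulated from the fitted model and refitted — by default a single EM
run started at the generating values with capped iterations, which is the
standard shortcut for parametric goodness-of-fit bootstraps (a full
multi-start refit per replicate is available via `multi_start=True`). The
add-one rule p = (1 + #{boot ≥ obs})/(B + 1) avoids p = 0; the standard
error is √(p(1−p)/B). Failed refits are dropped and reported.

## Threshold diagnostics and style labels

A threshold is *disordered* when τ_{i,s} < τ_{i,s−1}; the violation is
charged to the right member, giving per-item counts in [0, m−1] and a scale
percentage over I·m thresholds. An alternative convention (m minus the
longest increasing subsequence) is available behind a flag for runs of
violations.

Which categories are ever modal is characterized exactly: the log-numerators
are lines in θ with increasing slopes, so category c has a nonempty modal
region iff (c, T_c) is a vertex of the lower convex hull of the cumulative
thresholds (with a 1e−10-scaled tolerance that treats collinear-within-
rounding points as non-vertices). An adjacent disorder always empties the
left category of the pair, but long-range domination can empty additional
categories — the adjacent count is a lower bound on the empty-modal count,
not an identity.

Style profiles summarize each class over the central 95% interval of
N(0, σ_g²): per-item modal-category sets, the fraction of the interval where
an extreme category (0 or m) is modal, and the disorder percentage. Labels
are heuristics with exposed cutoffs (`StyleRules`), evaluated in a fixed
order with first-match-wins, and always reported together with the numeric
evidence:

* **eERS** — extreme coverage ≥ 0.50 *and* near-extreme (categories 1, m−1)
  coverage ≥ 0.20;
* **ERS** — extreme coverage ≥ 0.60;
* **ORS** — disorder ≤ 25% and ≥ m modal categories per item on average;
* **RRS** — ≤ 3 modal categories, upper non-extreme categories covering
  ≥ 0.50 of the interval, extreme coverage ≤ 0.20;
* **eRRS** — the RRS shape with extreme coverage in (0.20, 0.50);
* **other** — anything else.

These cutoffs reproduce the qualitative class descriptions that expert
inspection of category characteristic curves yields on the synthetic
templates below; they are a labeling aid, not a substantive claim.

## Downstream study statistics

* **Careless screening** — three flags: ≥ 2 failed instructional
  manipulation checks; log response time strictly below mean − 3·SD of the
  supplied log-RT vector (a person exactly at the cutoff is retained);
  an invariant run covering ≥ half of the successive task items. Missing
  auxiliary data skip the rule with a warning.
* **Paired ORS membership** — McNemar χ² = (n12 − n21)²/(n12 + n21)
  *without* continuity correction (the uncorrected statistic is the one that
  reproduces published values of this design), two-sided p from χ²(1), the
  one-sided value for the directed hypothesis alongside; effect size
  OR_pop = n12/n21. Bonferroni control divides the family α by the number of
  comparisons.
* **Criterion validity** — Spearman correlations (average ranks, pairwise
  complete); comparisons of independent coefficients convert to the Pearson
  scale by r = 2·sin(πρ/6), Fisher-z transform, and
  Z = (z1 − z2)/√(1/(n1−3) + 1/(n2−3)). Fieller's variance inflation (1.06)
  is available via flag, off by default.
* **McDonald's ω** — one-factor ML fit to the item correlations (statsmodels
  `Factor`), rescaled to the raw-score covariance metric;
  ω = (Σλ)²/((Σλ)² + Σψ) with loadings sign-aligned (equivalent to
  reverse-coding) so ω is invariant to item reflection; percentile bootstrap
  CI over persons (default B = 1000).

## Synthetic data: what it emulates, what it does not

The generator produces the inputs a rating-scale response-style study needs:
mixture GPCM responses with known class and trait, paired-condition data
with class switching, screening columns with planted careless responders,
and external criteria hitting target Spearman correlations via a Gaussian
copula on the trait ranks (exact for any continuous trait margin, including
mixtures).

Default preset (three classes, m+1 ∈ {4, 6, 11} supported):

* weights (0.55, 0.26, 0.19) for ORS/ERS/RRS — inside the 55–58 / 24–29 /
  14–19% bands such mixtures typically show;
* trait SDs 1.0 / 1.1 / 0.5; the smaller RRS dispersion keeps the
  dominant-category geometry of a range responder while every category
  retains a few-percent expected frequency, as real datasets show even for
  style classes;
* discriminations cycling over 0.8–1.4 with δ_1 = 1;
* a −0.8 downward shift of all thresholds, inducing the left-skewed
  category frequencies of well-being items while keeping within-class
  traits normal.

Templates (unshifted bases; all constants live in `mixgpcm.simulate`):
ORS = equidistant thresholds across [−1.8, 1.8] — inside the central 95%
window so every category, extremes included, owns a latent segment there;
ERS = thresholds compressed into [−0.3, 0.3]; RRS = a strictly decreasing
lower block (m = 3: (−0.5, −2.3, 1.9)) that empties the lower categories'
modal regions and leaves the penultimate category dominant over the whole
central range; eERS/eRRS move near-extreme or top categories into the
dominant set.

What passing tests on these data do **not** show: the generator draws from
the fitted model family itself, so it cannot detect misspecification of the
normal-trait or class-invariant-discrimination assumptions; it contains no
acquiescence or mimicry confound, no item-content effects, and no
non-normal trait shapes. Results on real data depend on those assumptions
holding approximately.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen for a single CPU: parameter
recovery and class-count selection at N = 2500 (the subsample size
recommended for this model family), selection over 5 seeded replications,
bootstrap calibration on a 3-item/3-category toy with B = 200 and N = 500
over 50 replications, and Monte-Carlo quadrature validation at 10⁶ draws.
Tie-breaks: modal categories and hard class assignments resolve ties toward
the lower index. The default modal-map grid spans ±4·max σ_g with 1001
points.

## Known limitations

* Thresholds whose adjacent categories have expected frequencies in the
  low percents (the deep lower block of a genuine range-response class, or
  any avoided category on a long left-skewed scale) carry standard errors of
  several tenths at N = 2500 — an information bound, not an optimizer
  limitation: the likelihood is flat in those directions, and mixture-model
  class overlap inflates all item-parameter errors by roughly another factor
  of two relative to the perfectly-separated case. Class weights, trait
  variances, well-populated thresholds and style labels are unaffected.
* No standard errors for item parameters are reported (the EM map does not
  produce them for free; a supplemented-EM or bootstrap layer would).
* Exchanging saBIC for other criteria (CAIC, AIC3) or mixture
  likelihood-ratio bootstrap tests is out of scope.
* The one-factor ω assumes a congeneric scale; it is computed on Pearson
  covariances of the raw scores, not polychorics.
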