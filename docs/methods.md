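# Methods

## The model

`harmcox` selects risk factors in Cox's proportional hazards model,
h(t | x) = h0(t) exp(xᵀβ), from right-censored data (tᵢ, δᵢ, xᵢ) with
p ≫ n. Inference is based on the partial log-likelihood

    l(β) = Σ_{i: δᵢ=1} [ ηᵢ − log Σ_{j: tⱼ ≥ tᵢ} exp(ηⱼ) ],   η = Xβ,

with the Breslow convention for tied event times (a tied block shares one
risk set; risk sets always include the subject itself, so they are never
empty). Sparsity comes from the harmonic penalty

    P(b) = sqrt( (2 / (a(a−1))) b + c² ) − c,    c = (2−a)/(a−1),  b = |βⱼ|,

a concave function of the coefficient magnitude indexed by a single
shrinkage parameter a ∈ (1, 2). As a → 1 it approaches the lasso penalty
|b|; as a → 2 it approaches the L1/2 penalty sqrt(b). In between it behaves
like an Lq penalty with 1/2 < q < 1 — sparser than the lasso — but, unlike
a true Lq penalty with q < 1, its slope at the origin is finite,
P′(0) = 1/(a(2−a)). That finite slope is what makes direct path seeking
well-defined at zero coefficients. Near a = 1 the constant c is large and
the textbook form sqrt(x + c²) − c cancels catastrophically; the package
evaluates the equivalent ratio x / (sqrt(x + c²) + c).

## Working least-squares linearization

The Cox loss is not quadratic, so the solver works on a local expansion.
With μ = −∂l/∂η and A = −∂²l/∂η∂ηᵀ (computed exactly; A is symmetric PSD
with zero row sums because l is invariant to constant shifts of η), the
second-order expansion of −l around η₀ is minimized at the working response
z = η₀ − A⁻μ, where A⁻ is the Moore–Penrose pseudo-inverse (A is rank
deficient by construction, so a generalized inverse is forced; μ lies in
the range of A). A Choleski factor C with CᵀC = A + εI, ε = 1e−8·tr(A)/n,
turns the weighted problem into plain least squares on ŷ = Cz, x̂ = CX:
½‖ŷ − x̂β‖² reproduces the expansion of −l up to an additive constant.
The jitter ε guards the factorization; it is reported on the
`QuadraticApprox` object and never fatal. The full n×n Hessian is used
(cost n²·#events per linearization, negligible at n ≤ a few hundred).

Covariates are centered and scaled to unit variance inside `fit`; a path
walked with one shared step size presumes comparable coordinate scales.
Coefficients map back to the original scale on output (Cox models have no
intercept, so centering is free).

## Generalized path seeking

Instead of solving the penalized problem per value of a tuning multiplier
λ, the solver builds the entire regularization path directly. At path
position v, with working residual r = ŷ − x̂β:

1. gⱼ = (1/n) Σᵢ rᵢ x̂ᵢⱼ (negative working-loss gradient), pⱼ = P′(|βⱼ|),
   τⱼ = gⱼ/pⱼ.
2. Coordinates whose sign opposes their ratio (τⱼβⱼ < 0, with |τⱼ| above
   tolerance) are corrected first; otherwise the largest |τⱼ| wins (lowest
   index on ties, for determinism).
3. The chosen coordinate moves by Δv·sign(τⱼ), with two caps: it never
   crosses zero in one move (it lands exactly on zero instead — this is
   what produces exact zeros and a meaningful "number selected"), and it
   never overshoots the coordinate-wise minimizer of the working loss
   (step ≤ |gⱼ|/Ḡⱼⱼ, Ḡⱼⱼ the mean-square of column j). Without the second
   cap a fixed increment oscillates forever around the optimum and the
   stopping rule below is unreachable.
4. The walk stops when max|τⱼ| ≤ `tau_tol` (default 1e−4; the practical
   version of "all τⱼ = 0") or at the step cap, in which case the path
   carries a warning flag.

An outer loop re-linearizes the likelihood at the current coefficients and
resumes the walk — by default after every 100 moves
(`relinearize_every`), which keeps the path close to the true likelihood
geometry; with `relinearize_every=None` it re-linearizes only at inner
convergence, as the plain algorithm reads. The outer loop ends when the
terminal coefficients change by less than `outer_tol` (relative), when the
total step budget `max_inner_steps` is spent, or if ‖η‖∞ exceeds 30
(divergence guard for the overfit end of a p ≫ n path; the path collected
so far is returned with a warning). Every intermediate point is retained:
`CoefficientPath` stores the move sequence (one coordinate, ≤ Δv each) and
reconstructs β at any point, so model selection can pick any position.

Defaults: Δv = 0.01 on standardized covariates, `max_inner_steps` 20 000,
`max_outer_iters` 20, `outer_tol` 1e−4. The simulation harness uses a
coarser desk-scale configuration (Δv = 0.02, 600 total steps,
re-linearize every 100) — at these sample sizes the selected models are
indistinguishable from the fine-step ones and a full fit takes well under
a second.

## Model selection: cross-validated partial likelihood

The held-out value of coefficients β fitted without fold f is the fold's
contribution to the full partial likelihood,
l(β) − l₍₋f₎(β) (Verweij–van Houwelingen); risk sets couple subjects, so
this is not a sum of per-subject terms. CVPL(a, candidate) is the mean
contribution over folds, maximized over a grid of a values
({1.1, 1.3, 1.5, 1.7, 1.9} by default) and over path points where the
active-set size changes (capped at 100 per a, evenly thinned). Ties break
toward sparser models, then smaller a. The winning coefficients are read
off the all-data path — the path fit *is* the refit.

Matching "the same amount of regularization" between a fold fit (smaller
n) and the all-data fit is done through the effective penalty strength
λ̂ = running-minimum of max_j|τⱼ| along the path: at a stationary point of
the penalized working problem every active coordinate satisfies
|gⱼ| = λ pⱼ, so λ̂ is the natural surrogate for the penalty multiplier and
is comparable across sample sizes, unlike the raw path position v. Each
fold therefore fits one path and is evaluated at every candidate λ̂ —
(k+1) path fits per a in total.

`select_model` defaults to k = 5 folds; the simulation harness
(`run_study`) uses k = 10, the convention of the benchmark it replicates.
Both formulations of the criterion (k-fold and leave-one-out via k = n)
are supported. Folds are reshuffled (with a logged warning) in the rare
event a training part contains no events.

A known property inherited from likelihood-based cross-validation: the
criterion targets predictive fit, not support recovery, so it tolerates a
few spuriously selected variables whose coefficients are small (AIC-like
behavior). A sparsest-within-one-standard-error rule was evaluated and
rejected: on these problems it collapses to 2–4 variables and measurably
degrades concordance.

## Prediction and evaluation

Survival curves come from the Breslow cumulative baseline hazard
Ĥ0(t) = Σ_{event times ≤ t} d_t / Σ_{j∈R_t} exp(ηⱼ) (the Nelson–Aalen
estimator at β = 0), via S(t|x) = exp(−Ĥ0(t)·e^{xᵀβ}).

*Brier score.* BS(t) is the inverse-probability-of-censoring weighted
squared error (Graf): subjects with an observed event by t contribute
S(t|x)²/Ĝ(tᵢ−), subjects still at risk contribute (1−S(t|x))²/Ĝ(t), and
subjects censored before t contribute zero; Ĝ is the Kaplan–Meier estimate
of the censoring distribution (censorings treated as events), evaluated
with a left limit at event times. Subjects with zero weight are excluded
with a logged count. BS is a right-continuous step function of t whose
jumps lie on the union of observed times, prediction jump times and Ĝ jump
times, so IBS = (1/max tᵢ)∫₀^{max tᵢ} BS(t)dt is computed as an exact
weighted sum over that grid — refining the grid cannot change it.

*Concordance.* A pair (i, j) is comparable when tᵢ < tⱼ and δᵢ = 1;
it is concordant when the predicted risk of i exceeds that of j. Tied
risk scores count 1/2, which makes the random-score expectation exactly
0.5. The fitted linear predictor xᵀβ is used as the risk score (any
monotone transform, e.g. negated predicted survival, gives the same
value). With no comparable pairs the index is undefined and raises.

*Recovery rate.* Across simulation replicates: (mean number of selected
true-signal variables) / (mean number selected overall) — means first,
then the ratio. Undefined (raises) when nothing is ever selected.

## Synthetic data generator

The generator reproduces a standard high-dimensional survival benchmark:

1. Predictors: xᵢⱼ = zᵢⱼ√(1−ρ) + zᵢ₀√ρ with i.i.d. standard normal z —
   each column is marginally N(0,1) and every pair of columns has
   correlation exactly ρ. (The mixing weights must be the square roots for
   ρ to be the literal correlation; a Monte-Carlo test pins this.)
2. Event times by inverse transform from a Gompertz proportional-hazards
   model: t′ = (1/γ)·log(1 − γ·log(U)/(ω·exp(xβ + σε))), U ~ U(0,1),
   ε ~ N(0,1). log U < 0 keeps t′ > 0; larger linear predictors give
   stochastically shorter lives. σ is noise on the log-hazard scale.
3. Censoring times t″ ~ Exponential(rate θ), independent of covariates;
   observed time min(t′, t″), δ = 1(t′ ≤ t″). θ is calibrated by
   bisection so the expected censored fraction E[1 − exp(−θt′)] (exact
   given a simulated t′ sample of 20 000 draws, seed-isolated from the
   evaluation data) hits the target, 25% by default, within 0.2%.
   Because t′ depends on x only through xβ, calibration samples only the
   signal coordinates and its cost is independent of p.

Default truth: p = 1000 with β = (1, 0.8, −1, −0.8, 1, 0, …, 0);
scenarios vary n ∈ {100, 150, 200}, ρ ∈ {0.1, 0.5}, σ ∈ {0.2, 0.5}.
Gompertz shape and scale are not identified by anything the benchmark
reports — and the *ranking* of inverse-transform times, hence the
concordance ceiling, is invariant to them — so γ = ω = 1, giving times on
an O(1) scale; both are exposed on `SimulationScenario`.

What the generator does not emulate: covariate-dependent or
administrative censoring, non-Gaussian or block-structured predictors
(real expression data has both), time-varying effects, and measurement
error in x. Passing tests therefore demonstrate correctness of the
machinery and behavior under equicorrelated Gaussian designs, not
performance on real microarray cohorts.

An intrinsic ceiling worth knowing: with σ = 0.2, ρ = 0.1 and the default
β, the concordance of the *true* coefficient vector on fresh data is
≈ 0.843 — no fitted model can beat it on average, and fitted models at
n = 200 come within ~0.01–0.02 of it.

## The simulation harness

`run_study` runs, per scenario and replicate: draw a training set; fit and
select by CVPL (k = 10, default a-grid); count nonzero coefficients; draw
an independent 100-subject test set from the same scenario; evaluate IBS
and concordance there. Aggregation (mean counts, recovery rate as a ratio
of means, mean IBS/CI) is a pure function of the per-replicate records,
which are returned alongside — `StudyReport.aggregate` recomputes the
summary from them exactly. All randomness descends from one master seed
through `numpy.random.SeedSequence.spawn`; θ calibration gets its own
stream. A failed replicate is logged and excluded, with the count
reported. `scripts/acceptance.py` runs this harness at 30 replicates per
scenario, p = 1000.

## Numerical notes and limitations

- Risk-set log-sums use a cumulative log-add-exp, so large |η| cannot
  overflow; the divergence guard caps ‖η‖∞ at 30 anyway.
- Sorting is by ascending time with events before censorings at ties.
- `argmax` ties anywhere resolve to the lowest index; reruns with the same
  seed are bit-identical.
- The GPS path approximates the nonconvex penalized solution set; there is
  no global-optimality guarantee (none exists for concave penalties), and
  coefficient profiles between re-linearizations are only as good as the
  local quadratic model.
- CVPL model size inherits the usual cross-validation tilt toward slightly
  denser models; expect the selected support to contain the strong signal
  plus occasionally a few small-coefficient extras.
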