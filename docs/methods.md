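# Methods

## Model and reliability definition

Item responses follow the two-parameter logistic model: the probability of
a correct answer to item *i* given the latent trait θ is

    P_i(θ) = exp[D a_i (θ − b_i)] / (1 + exp[D a_i (θ − b_i)])

with discrimination a_i > 0, difficulty b_i, and scaling constant D that
places the logistic curve on the normal-ogive metric.  D defaults to 1.702
and is carried inside every `ItemBank`, so simulation, estimation and the
reliability formulas always share one value; setting `D = 1` switches the
whole pipeline to the pure logistic metric (multiplying D by c and dividing
all a by c changes nothing observable — a property the tests assert).

Classical reliability of the unweighted sum score is ρ = Var(T)/(Var(T) +
Var(E)), where the item error variance is E_θ[P_i(1 − P_i)] and the
true-score variance is Var_θ[Σ_i P_i(θ)].  True-score variability is thus
attributed entirely to θ; item-specific stable variance is counted as error.

### Quadrature route (DQ)

The variance integrals are evaluated by a rectangular rule on Q equally
spaced nodes X_q over [lo, hi] with weights W_q = φ(X_q)/Σφ(X_q).  The
default (Q = 101 on [−6, 6], both endpoints included) is accurate to well
under 10⁻⁶ in the reliability for the item-parameter ranges used anywhere
in this package (the tests compare against Q = 2001 and against adaptive
quadrature).  Given item parameters, DQ is the reference definition of
true reliability throughout.

### Analytic route (DA)

Dimitrov's closed-form approximation replaces the integrals with:

* marginal probability π_i ≈ [1 − erf(Z_i)]/2, Z_i = a b/√(2(1 + a²)),
  using the Abramowitz–Stegun four-constant polynomial
  erf(z) ≈ 1 − (1 + m₁z + m₂z² + m₃z³ + m₄z⁴)⁻⁴ (odd-extended; max
  absolute error < 5·10⁻⁴);
* item error variance Var(E_i) ≈ m_i exp[−½(b_i/d_i)²] with
  m_i = 0.2646 − 0.118a + 0.0187a² and d_i = 0.7427 + 0.7081/a + 0.0074/a²
  (m_i > 0 for all real a, so the guard for nonpositive m never fires in
  practice);
* true-score variance Var(T) = (Σ_i √[π_i(1−π_i) − Var(E_i)])².

The last line deserves comment.  Writing v_i = π_i(1−π_i) − Var(E_i) for
the item true-score variance, the covariance construction under a single
latent trait treats item true scores as perfectly correlated, giving
Σ_i Σ_j √v_i √v_j = (Σ√v_i)².  A sum of plain products Σ_i Σ_j v_i v_j
would be dimensionally a squared variance and is not used.  Perfect
correlation of item true scores is exact only for the normal-ogive curve
family with common shape; for 2PL banks with heterogeneous parameters it
overstates Var(T) — by roughly 15–20% for banks sampled from the default
distributions — which is why DA reliabilities run mildly above DQ, and why
DA-disattenuated correlations fall short of the truth in the benchmark
study.  Negative v_i (possible for extreme items under the approximation)
are clipped to zero with a warning.

## Sample coefficients

All sample moments use the unbiased n−1 denominator.

**alpha** is computed directly from item and sum-score variances.

**GLB.**  The greatest lower bound solves max Σe_i subject to e ≥ 0 and
Σ_Y − diag(e) ⪰ 0, then GLB = 1 − Σe_i/1'Σ_Y1.  This semidefinite program
is solved by a primal log-det barrier method: along the central path the
objective −Σe − μ[log det(Σ_Y − diag(e)) + Σ log e_i] is smooth and convex
in e (gradient −1 + μ diag(A⁻¹) − μ/e, Hessian μ(A⁻¹∘A⁻¹) + μ diag(1/e²)),
so damped Newton steps with a Cholesky-guarded line search stay strictly
feasible; μ is reduced geometrically until the duality-gap proxy 2Iμ falls
below 10⁻⁸.  Singular inputs (e.g. exactly rank-one matrices) are
perturbed by 10⁻¹⁰ on the diagonal.  Tests verify the solver against a
refined brute-force grid search on 3×3 instances (1e−4) and an SLSQP
eigenvalue-constrained solve on sampled data.

**omega.**  The minres variant minimizes the squared off-diagonal
residuals of R − λλ' (L-BFGS-B with analytic gradient, SMC start values,
loadings bounded so uniquenesses stay ≥ 10⁻³; hitting the bound flags a
Heywood case but does not fail).  The CFA variant minimizes the
normal-theory ML discrepancy log|Σ(ϑ)| + tr(SΣ(ϑ)⁻¹) − log|S| − I over
Σ(ϑ) = λλ' + diag(ψ²) with the latent variance fixed at 1 and ψ² ≥ 10⁻³.
Loadings are sign-fixed so Σλ ≥ 0.  Omega is scale-free, so the
correlation-metric (minres) and covariance-metric (CFA) solutions agree
for exact one-factor structures.

## Categorical (Green–Yang) reliability

The underlying-variable model dichotomizes latent normal response
variables at thresholds τ_i = Φ⁻¹(P(Y_i = 0)).  Estimation is sequential
limited-information: thresholds from margins; tetrachoric correlations by
two-step ML (thresholds fixed, ρ maximizing the four-cell multinomial
likelihood, bounded in ±0.999; zero cells get a +0.5 continuity correction
with a warning, or an error in strict mode); one-factor loadings on the
probit metric by unweighted least squares on the tetrachoric matrix (a
diagonally weighted variant using inverse asymptotic variances of the
tetrachorics — observed-information based — is available, and agrees with
ULS to ~0.02 on well-behaved data).  The reliability is

    ρ_GY = Σ_ij [Φ₂(τ_i, τ_j; λ_iλ_j) − Φ(τ_i)Φ(τ_j)]
         / Σ_ij [Φ₂(τ_i, τ_j; ρ*_ij) − Φ(τ_i)Φ(τ_j)]

with ρ*_ii = 1 in the denominator and λ_i² on the numerator diagonal.
Φ₂ is computed by the Drezner–Wesolowsky/Genz Gauss–Legendre algorithm
(20-point rule, complementary expansion for |ρ| > 0.925), accurate to
~10⁻¹⁴ — the tests check it against scipy's bivariate CDF and closed
orthant formulas.  Because the model is the probit-link twin of the 2PL
(λ = a/√(1+a²), τ = ab/√(1+a²)), the population GY value equals the
quadrature reliability of the probit test, which the tests assert to 10⁻³.

## 2PL estimation

Bock–Aitkin EM on an estimation grid of 61 equally spaced nodes over
[−6, 6] (deliberately distinct from the 101-node reliability grid; both
configurable).  The E-step computes posterior node weights per person in
log space; the M-step refits each item by damped Newton on the
intercept/slope parametrization (vectorized across items, slope floored at
10⁻³).  Start values: common slope 0.851/D, difficulties from
probit-transformed proportions.  Convergence: max absolute change in
(a, b) below 10⁻⁴, cap 500 cycles; the marginal log-likelihood trace is
returned and is nondecreasing.

Estimation is pure maximum likelihood by default.  A weak logN(−0.75, 1²)
prior on the discriminations is available (`prior="auto"` activates it for
N < 300, `"always"` forces it) for data with near-separable items, but it
is not the default: at I = 15, N = 100 the shrinkage depresses the implied
DQ reliability by about 0.06 on average — enough to distort the estimator
comparison — while plain ML converges without failures across the study
grid, so stabilization is opt-in rather than silent.

## Simulation studies

**Disattenuation benchmark.**  Two unit-variance latent constructs with
known correlation r ∈ {.3, .5, .7, .9}; each measured by I ∈ {10, …, 70}
freshly drawn items (a ~ logN(−.75, .25²), b ~ N(0, .75²)); N = 500
persons; the Pearson correlation of the two sum scores is corrected by
r/√(ρ_xx ρ_yy) with reliabilities computed from the true parameters by DA
or DQ.  A method that computes reliability correctly recovers the true
correlation on average.  The default is 1000 replications per cell — a
deliberate scale-down from exhaustive settings that keeps the Monte Carlo
SE of a cell mean near 0.002, small against the .006 accuracy band being
tested.  Cells are vectorized over batches of replications.

**Coefficient comparison.**  I ∈ {15, 40, 65} crossed with
N ∈ {100, 300, 500, 1000, 3000}; per dataset fresh parameters, θ ~ N(0,1),
and the full roster (DA at true parameters; DQ and DA at EM estimates;
alpha; GLB; omega; CFA; GY) scored against that dataset's DQ-at-truth.
RMSE and bias are reported on the raw and ×100 scales with delta-method
Monte Carlo SEs; failures (non-convergence, degenerate items) are dropped
per-coefficient and counted.  Default 200 replications per cell, again a
deliberate scale-down; each cell draws from an independent child of the
root seed, so any subset of cells reproduces exactly.

The generator emulates complete, unidimensional, locally independent
binary data — exactly the idealized conditions of a correctly specified
2PL.  It does not emulate missing responses, guessing, multidimensionality
or local dependence, so passing results say nothing about robustness under
those violations.

## Known limitations

* The GLB's sampling bias is large at small N (about +0.15 at I = 15,
  N = 100 under the default generating distributions, shrinking roughly as
  1/√N); the harness reports it honestly rather than correcting it.
* The analytic (DA) route inherits the perfect-correlation construction
  above; it is a fast approximation, not a second truth.
* Tetrachoric-based estimates degrade when 2×2 tables contain zero cells
  (small N with extreme items); the continuity correction keeps the
  pipeline running but is flagged.
* No standard errors or confidence intervals for any coefficient; no
  polytomous items; no weighted composites.
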