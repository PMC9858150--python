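# Methods

## Model and inference

The sampling model is the Gaussian linear model with unknown variance,
y | θ, σ² ~ N_n(Xθ, σ²Iₙ), with the conjugate normal–inverse-gamma prior
(θ, σ²) ~ NIG(m₀, V₀, a₀, b₀): σ² ~ IG(a₀, b₀) and θ | σ² ~ N_p(m₀, σ²V₀).
The posterior is NIG(m*, V*, a₁, b₁) with

    V* = (V₀⁻¹ + XᵀX)⁻¹            m* = V*(V₀⁻¹m₀ + Xᵀy)
    a₁ = a₀ + n/2                  b₁ = b₀ + (m₀ᵀV₀⁻¹m₀ + yᵀy − m*ᵀV*⁻¹m*)/2.

All linear algebra goes through Cholesky factorisations; scale matrices are
symmetrised as (A + Aᵀ)/2 before factoring (relative tolerance 1e-8), and
all densities are computed and compared in log space — e-value comparisons
span hundreds of log units at n in the thousands. V* is obtained by
factoring V₀⁻¹ + XᵀX, which is positive definite whenever V₀ is, so a
rank-deficient design needs no regularisation.

Conditioning on a coefficient block uses the Schur complement: given the
last r coefficients θ₂, the law of (θ₁, σ²) is NIG with location
m¹ + V¹²(V²²)⁻¹(θ₂ − m²), scale V¹¹ − V¹²(V²²)⁻¹V²¹, shape a + r/2 and
rate b + (θ₂ − m²)ᵀ(V²²)⁻¹(θ₂ − m²)/2. The tested block is canonically the
*last* r coordinates; testing an arbitrary coefficient permutes the design
columns and the prior jointly (`move_tested_last`, `permute_params`).
Testing all coefficients (s = 0) is a first-class case with an empty free
block.

## The FBST e-value

For H: θ₂ = 0 the supremum of the posterior density over the null set is
closed-form: θ̂₁ is the conditional location m*^{1.2}(0) and
σ̂² = b′/(a′ + 1 + s/2), the joint mode of the conditional NIG, where
(a′, b′) are the conditioned shape/rate. The e-value is
1 − P(f(ξ|y) > f(θ̂₁, 0, σ̂²|y) | y), estimated from M posterior draws.
Tangential-set membership uses the strict inequality; ties occur with
probability zero and a test asserts that replacing > by ≥ moves the
estimate by at most 1/M. The HPD region is taken with respect to Lebesgue
measure on (θ, σ²); no reparameterisation option is offered.

Two numerically equivalent estimators are implemented:

* `fbst.evalue` draws (θ, σ²) from the posterior explicitly and evaluates
  the log density per draw — the reference path, used for observed data.
* The error-curve sweep uses a scalar reduction: under the posterior,
  (θ − m*)ᵀV*⁻¹(θ − m*) = σ²W with W ~ χ²_p independent of σ², and
  σ² = b₁/G with G ~ Gamma(a₁), so membership reduces to
  Ã ln G − G − W/2 > Ã(ln Ã − 1 − ln(1 + u)) with Ã = a₁ + p/2 + 1 and
  u = Q_H/(2b₁), where Q_H = m*²ᵀ(V*²²)⁻¹m*² is the null offset. Each
  dataset still gets M_inner fresh (G, W) pairs, so this is the same Monte
  Carlo estimator at cost independent of p and n. The two paths are
  checked against each other and against an independent
  χ²/inverse-gamma quadrature oracle at p = 1.

## Predictive densities, Bayes factor, P-value

Under the unrestricted prior, y ~ t_n(2a₀; Xm₀, (b₀/a₀)(Iₙ + XV₀Xᵀ)).
Under H, with (m_H, V_H, a_H, b_H) the conditional prior given θ₂ = 0 and
X₁ the free design columns, y ~ t_n(2a₀ + r; X₁m_H, (b_H/a_H)(Iₙ + X₁V_H X₁ᵀ)).
Scale matrices are kept in the low-rank form c(Iₙ + AWAᵀ); density
evaluation uses the Woodbury identity and the matrix determinant lemma, so
a batch of M datasets costs O(Mnp + np²) rather than O(Mn³). The closed
forms were confirmed against 1-D/2-D quadrature of the hierarchical
integrals before anything was built on them.

The Bayes factor BF(y) = f_H(y)/f_A(y) yields the optimal test φ*
(reject iff BF ≤ b/a), its adaptive level α* = P_{f_H}(BF ≤ b/a), the
type-II rate β* = P_{f_A}(BF > b/a), and the P-value
P(y₀) = P_{f_H}(BF(Y) ≤ BF(y₀)), all estimated from hierarchical draws.
H is rejected when P(y₀) < α* (strict); φₑ rejects when ev ≤ k*
(inclusive). Both boundary conventions are tested.

Hierarchical sampling under H is implemented σ²-first (σ² ~ IG(a_H, b_H),
θ₁ | σ² normal), which has no special case at s = 0; the θ-first
factorisation (θ₁ from its Student-t marginal, then σ² | θ inverse-gamma)
is kept as a cross-check and a two-sample KS test confirms the two agree.

## Adaptive thresholds

`evalue_error_curves` draws M_outer datasets from each of f_H and f_A,
computes each dataset's posterior and e-value, and returns the sorted
samples with step functions α̂(k) = frac(ev_H ≤ k) and
β̂(k) = frac(ev_A > k). The Monte Carlo objective a·α̂(k) + b·β̂(k) is
piecewise constant with jumps only at sampled e-values, so `find_kstar`
minimises it *exactly* over the candidate set {0} ∪ ev_H ∪ ev_A and
reports the smallest minimiser (the objective is typically flat over a
wide k-interval near its minimum — at (n, d) = (10, 3) the objective is
within 0.005 of its minimum for k between roughly 0.49 and 0.61 — so the
reported minimiser of a finite-M run carries substantial Monte Carlo
jitter even when the attained objective is stable).

Error weights default to a = b = 1 (equally serious errors); only the
ratio b/a enters φ*.

## Simulation studies and the synthetic-data generator

A scenario is (n, d) with p = d − 1 coefficients: the design has an
intercept column plus d − 2 independent standard-normal covariates, and
the tested block is the last coefficient (for d = 2 the model is
intercept-only and the intercept itself is tested). The design is drawn
once per scenario and held fixed across the Monte Carlo replicates: the
predictive densities condition on X, so the averaged error probabilities
are X-conditional. This mirrors how the generator is used throughout:
y-values are produced by the hierarchical samplers above, i.e. exactly
from the model the tests assume — Gaussian errors, homoscedastic,
exchangeable rows, prior-consistent coefficient scales. Passing tests
therefore certify internal coherence of the method, not robustness to
model misspecification (heavy tails, heteroscedasticity, dependent rows),
which real data may exhibit.

Defaults are the standard study conditions: M_outer = M_inner = 1000,
prior m₀ = 0, V₀ = I, a₀ = 3, b₀ = 2, a = b = 1. The inner e-value Monte
Carlo size is not separately prescribed anywhere, so it defaults to the
same M = 1000 and is exposed as a parameter. For one-off data analyses
(e.g. the real-data workflows) M = 10,000 is the documented choice.

Consequences of the X-conditional design worth knowing:

* d = 2 cells are design-free (X = 1ₙ) and reproduce sharply.
* Cells with covariates inherit the randomness of the single design draw;
  across design draws the conditional k* at (n, d) = (50, 3) ranges
  roughly 0.16–0.38. Comparisons against any single published run of such
  a cell are therefore only meaningful within that spread.

## Reproducibility

Every stochastic routine takes a seed (int, `SeedSequence`, or
`Generator`). Multi-stream computations split one master seed with
fixed-order `SeedSequence` spawns, and scenario cells key their streams by
`(master_seed, n, d, stage)`, so any table cell is a pure function of the
grid entry and the master seed, independent of grid order. Reruns are
bit-identical; a test asserts this end-to-end.

## Numerical edge cases

* Non-positive-definite scale matrices raise `ValueError` at construction
  (eager Cholesky); a singular tested-block V²² raises a linear-algebra
  error.
* A design with singular XᵀX is an error for OLS and for the classical
  t-test (which also rejects an exactly-interpolating fit: zero residual
  variance leaves the t statistic undefined), but poses no problem for the
  Bayesian update.
* b₁ > 0 holds analytically; it is asserted to guard against catastrophic
  cancellation at extreme scales.
* Missing values in CSV input are an error by design — no imputation.

## Known limitations

* Conjugate NIG priors only: no improper or hierarchical priors, no GLMs.
* The averaged error probabilities are X-conditional (see above); no
  attempt is made to integrate over design distributions.
* Per-coefficient reports perform no multiplicity adjustment.
* The asymptotic (χ²) calibration of the e-value is out of scope.
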