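# Methods

## Model

All measures are computed under a multivariate-Gaussian model of
expression profiles: `fit_gaussian` returns the sample mean and sample
covariance (denominator m−1) of the optionally log-transformed,
optionally per-gene-standardized genes × samples matrix. The Gaussian
assumption is what makes every information quantity closed-form; it is a
reasonable working model for (log) expression intensities but ignores
heavy tails, multimodality and genuinely nonlinear regulation — see
*Limitations*.

Mutual information and conditional mutual information are
log-determinant ratios of covariance blocks:

- MI(X;Y) = ½ ln(|C(X)|·|C(Y)| / |C(X,Y)|)
- CMI(X;Y|Z) = ½ ln(|C(X,Z)|·|C(Y,Z)| / (|C(Z)|·|C(X,Y,Z)|))

with natural logarithms throughout, so all measures and thresholds are
in nats. Scale invariance of these quantities makes the
covariance-vs-correlation choice immaterial; this is asserted by test
rather than assumed.

## Interventional distribution and CMI2

For a query (X, Y | Z), severing the X→Y dependence replaces the joint
by P(x, z) · ∫ P(y | z, x′) P(x′) dx′. For Gaussians this has an exact
finite-dimensional form: writing the original conditional as
y | x, z ~ N(μ_y + b_x(x−μ_x) + b_z′(z−μ_z), s), the severed joint sets
y = μ_y + b_z′(z−μ_z) + ε with ε ~ N(0, s + b_x² Var(x)) independent of
(x, z). The (x, z) marginal is preserved *exactly* (bit-for-bit in the
implementation), the mean is unchanged, and the result is again a valid
Gaussian.

CMI2(X;Y|Z) is the average of the two KL divergences from the joint to
the two severed distributions. Two code paths compute it:

1. `cmi2` — a closed trace/log-determinant form. Because the joint and
   both severed models share a mean, each KL term reduces to
   ½[tr(Σ̂⁻¹Σ) − n + ln|Σ̂| − ln|Σ|], giving
   CMI2 = ¼[tr(Σ̂₁⁻¹Σ) + tr(Σ̂₂⁻¹Σ) + ln|Σ̂₁| + ln|Σ̂₂| − 2ln|Σ| − 2n]
   with n = |Z| + 2. The severed covariances are built by Schur-style
   regression algebra (`_sever_child`).
2. `cmi2_oracle` — the definition evaluated literally:
   `interventional_model` (conditional-integration construction) plus
   the generic `kl_gaussian` closed form.

The oracle is normative: the closed form is accepted only because the
test suite and the acceptance script show agreement below 1e-8 across
hundreds of random SPD covariances of 3–6 variables and conditioning
orders 1–3 (observed agreement is at machine precision, ~1e-15).
Published block formulas for this closed form exist but contain
transcription ambiguities; this package derives the algebra directly
and pins it to the oracle instead of transcribing them.

The decomposition CMI2 = CMI + two nonnegative conditional-KL terms is
used as a test property (CMI2 ≥ CMI everywhere; equality under block
independence of Z) rather than as a computational route.

## Path-consistency engine

`infer_network` starts from the complete graph. Order 0 scores every
pair by MI (for the `pcor` measure: absolute correlation) and deletes
pairs below θ. At order L ≥ 1, for each surviving pair with T ≥ L
common neighbours, all C(T, L) conditioning sets are scored, aggregated
(max by default — an edge survives if *any* conditioning set still shows
dependence — or geometric mean), and the pair is deleted when the
aggregate is below θ. Design choices where the procedure is genuinely
open:

- **Batched deletions.** All tests at order L see the graph as it stood
  at the start of that order; deletions apply at order end. This makes
  the result independent of pair iteration order, at the cost of one
  extra pass relative to eager deletion.
- **Convergence rule.** The loop stops when an order L ≥ 1 deletes
  nothing, when no surviving pair has T ≥ L, or when L reaches
  `max_order`. Order 0 always advances to order 1: stopping on "no
  change" at order 0 would freeze the complete graph whenever all
  pairwise MIs clear θ (e.g. on a mediated chain) and is how reference
  PC implementations behave. `final_order` is the highest order at
  which any test was computed, so a converged order-L network used
  conditioning sets of at most L variables (and thus needs only L + 2
  independent samples' worth of covariance information).
- **Score ledger.** Removed pairs keep the aggregated score at which
  they were removed instead of being zeroed. Ranking all pairs by these
  scores yields the ROC input without re-running the engine; how a
  ROC curve is obtained from a binary PC output is a convention, and
  this score-ranking one is ours.
- **Full enumeration.** All C(T, L) conditioning sets are evaluated; no
  sampling. `max_order` (default unlimited; 1 is a pragmatic cap beyond
  ~100 genes) is the only complexity control.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `theta` | 0.03 nats | independence threshold; 0.03–0.05 suits moderate compendia, smaller values retain more edges |
| `max_order` | unlimited | cap on conditioning order L |
| `aggregation` | `max` | combine per-conditioning-set scores (`max` or `geometric-mean`) |
| `measure` | `cmi2` | association measure (`cmi2`, `cmi`, `pcor`) |
| `log_transform` / `pseudocount` / `standardize` | off | preprocessing before fitting |

Default preprocessing is off: log-transformation is appropriate for raw
intensity data but wrong for data already in log space, so it is the
caller's decision.

## Numerical policy

- **Degeneracy.** A covariance submatrix with determinant below 1e-300
  or condition number above 1e12 raises `DegenerateModelError` in
  strict mode; in the default lenient mode it receives a ridge λI with
  λ = 1e-10·trace/dim. Near-duplicate expression profiles (the
  redundant-conditioner regime) are *expected* inputs, so lenient is the
  default; the canonical fixture uses correlation 0.999 rather than 1
  to stay inside it.
- **Negative leakage.** MI, CMI, CMI2, KL are analytically ≥ 0. Float
  results in [−1e-12, 0) clamp to 0; below −1e-12 an
  `InternalConsistencyError` is raised — that magnitude indicates a
  fault, not roundoff.
- **Undefined metrics.** Evaluation ratios with zero denominators are
  reported as `None`/`NA`, never 0; small networks hit these routinely.
- **Ties in ROC.** Equal scores are grouped in the threshold sweep;
  trapezoidal AUC then equals the normalized Mann–Whitney statistic,
  which the tests verify against an independent rank-based computation.

## Synthetic data

The simulator draws from a linear-Gaussian structural equation model on
a DAG: each gene is a weighted sum of its parents plus independent
Gaussian noise, giving the exactly-normal joint with covariance
(I−W)⁻ᵀD(I−W)⁻¹, exposed via `population_covariance` so estimator
ground truth is analytic. `random_dag` defaults: weights uniform on
±[0.5, 1.0] (bounded away from zero so every edge carries detectable
signal), unit noise SD, edge density 0.25 at 10 genes, 500 samples —
a desk-scale regime in which skeleton recovery is hard enough to be
informative (mean AUC ≈ 0.93–0.95, not 1.0) yet runs in seconds.

What this emulates and what it does not: community GRN benchmarks
generate expression from nonlinear ODE systems with knockout designs;
the linear-Gaussian SEM instead matches the estimators' own
distributional assumption, which is precisely the regime where
population values of MI/CMI/CMI2 are computable in closed form. Passing
tests therefore demonstrate correctness of the estimators and engine
*under the Gaussian model*, not robustness to nonlinearity,
non-Gaussian noise, or perturbation designs. The published external
benchmarks (DREAM3 yeast subnetworks; the E. coli SOS DNA-repair
network) require third-party datasets and remain optional external
validations; the metric arithmetic of those studies is nevertheless
verified exactly from their published confusion counts.

The three `fixture_triples` scenarios (all unit variance, zero mean):
direct edge with independent conditioner (ρ_xy = 0.8); mediated chain
X→Z→Y (ρ_xz = ρ_zy = 0.8, hence ρ_xy = 0.64); and direct edge with a
near-redundant conditioner (ρ_xy = 0.8, ρ_yz = 0.999). 0.8 puts the
direct-edge signal (≈0.51 nats) an order of magnitude above typical
thresholds, and 0.999 is deep inside the CMI-collapse regime while
keeping the covariance numerically nonsingular.

## Problem sizes used in the test and acceptance runs

Skeleton recovery: 20 random seeds × (10 genes, 500 samples), θ = 0.05.
Oracle equivalence: 500 random SPD covariances, 3–6 variables, orders
1–3. KL Monte-Carlo spot checks: 10⁶ draws, 3-SE agreement. Estimator
consistency: 20 seeds × m ∈ {100, 1000, 10000} on the mediated chain,
median absolute error strictly decreasing in m. These sizes were chosen
so the full suite completes in well under a minute while leaving the
stochastic checks statistically meaningful.

## Limitations

- Output is an undirected skeleton; edge directionality is not
  inferred.
- The Gaussian closed forms capture only monotone-linear dependence
  structure; kernel-density or discrete MI estimation is out of scope.
- Conditioning-set selection is exhaustive per order; beyond a few
  hundred genes `max_order=1` is effectively required.
- Aggregating with `max` makes edge deletion conservative; geometric
  mean deletes more aggressively and is provided but not the default.
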