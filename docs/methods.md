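# Methods

## Model

`bnsbm` performs simultaneous hypothesis testing on a real-valued score
matrix **X** (n₁ × n₂), where entry x_ij summarizes the association between
row feature i (e.g. a taxon) and column feature j (e.g. a metabolite). The
unobserved truth is a bipartite adjacency matrix **A**: A_ij = 1 exactly
when the null hypothesis of no association is false. **A** is modeled as a
bipartite stochastic block model — independent multinomial memberships Z₁
(B₁ row blocks, mixing proportions α₁) and Z₂ (B₂ column blocks, α₂), and
conditionally independent edges A_ij ~ Bernoulli(π[q,l]) given the block
pair (q, l). The scores are emitted as a two-component mixture:

    x_ij | A, Z₁, Z₂  ~  g₀(·; ν₀)          if A_ij = 0
                         g(·; ν[q,l])        if A_ij = 1,

with a Gaussian null g₀ = N(0, σ₀²) (mean fixed at zero; σ₀² known by
default) and Gaussian block alternatives ν[q,l] = (μ_ql, σ²_ql). The
Gaussian family is the `DensitySpec` enum's only member at present; the
enum is the extension point for other tractable families.

The full parameter set is θ = (α₁, α₂, Π, ν₀, ν). With B₁, B₂ ≥ 2 and all
(μ_ql, σ²_ql) distinct from each other and from (0, σ₀²), the model is
identifiable up to label swapping; `BlockModelParams.check_identifiability`
emits diagnostics when a fitted configuration approaches a non-identifiable
one.

## Structured ℓ-values and mFDR control

The decision statistic is the structured ℓ-value

    ℓ(x, q, l; θ) = (1 − π_ql) g₀(x) / [π_ql g(x; ν_ql) + (1 − π_ql) g₀(x)],

the posterior probability that an entry is null given its score and block
pair — a block-informed local false discovery rate. After fitting, hard
memberships Ẑ = argmax β are plugged in (matching the estimator's plug-in
definition; β-weighted variants are not used). Sorting the N = n₁n₂
ℓ-values ascending, the plug-in marginal-FDR of rejecting the k smallest is
their running mean, so the rule rejects the k* smallest with
k* = max{k : mean of k smallest ≤ α}; ties at the threshold are all
rejected. This running-mean estimator is the standard local-fdr
thresholding construction; by definition the mean ℓ-value of the rejection
set (the reported `mfdr_hat`) never exceeds α when anything is rejected.
`empirical_rates` returns per-replicate FDP/TDP plus the raw counts so a
harness can average numerators and denominators separately (the
ratio-of-expectations form of mFDR, with the max(R, 1) denominator guard).

Baselines for benchmarking: Benjamini–Hochberg step-up (via statsmodels)
and Storey q-values with the fixed-λ π₀ estimate (λ = 0.5), both applied to
two-sided normal p-values p = 2(1 − Φ(|x|)).

## Variational EM

The marginal likelihood integrates over A, Z₁, Z₂ and is intractable, so
fitting maximizes the ELBO over the factorized family
Q = P(A | Z, X; θ) · ∏ β₁ · ∏ β₂ (the edge posterior given memberships is
exact and analytic). Writing ρ_ij^ql for the edge responsibility
P(A_ij = 1 | blocks q,l, x_ij; θ) and

    d_ij^ql = ρ log(π g / ρ) + (1 − ρ) log((1 − π) g₀ / (1 − ρ)),

the E-step fixed point is β₁[i,q] ∝ α₁[q] exp{Σ_jl β₂[j,l] d_ij^ql} (and
symmetrically for β₂); five inner sweeps are run per E-step. Because ρ is
recomputed from the current θ at the start of every E-step (never stored),
d evaluated at those responsibilities collapses to the per-block log
mixture density, so one (B₁, B₂, n₁, n₂) array serves the sweeps and the
ELBO; it is built in a single fused numba pass. The Gaussian M-step is
closed-form (responsibility-weighted block means/variances; ρ evaluated at
the pre-update θ; σ₀² re-estimated only when `fix_null=False`). Blocks
whose total soft weight falls below 1e-8 keep their previous parameters
(frozen, not deleted, so the model dimension stays comparable across grid
cells). All probabilities are clipped to [1e-10, 1 − 1e-10] before logs,
and all density arithmetic is in log space (stable to |x| ≈ 40).

The outer loop alternates E and M and records the ELBO each iteration; the
trace is non-decreasing up to 1e-8. It stops when the relative ELBO change
drops below `elbo_rel_tol` (default 1e-6) or after `max_outer_iter`
(default 100) iterations.

### Initialization and restarts

Initialization order: memberships from k-means on the rows and on the
columns of X; a rough edge indicator ρ̂ = 1{two-sided p-value under the
null < 0.5}; Π as block means of ρ̂; null/alternative moments conditional
on the initial memberships and ρ̂; ρ then refreshed from these parameters
(implicitly — the first E-step recomputes it). Our outer loop runs
E-then-M; the refreshed ρ is identical to an M-first loop, the only
difference being that β is smoothed once before the first M-step.

Two refinements address a practical failure mode of the raw threshold
moments. The p < 0.5 cut flags half of all genuinely null entries as rough
edges, so in sparse blocks the initial alternative is a wide,
near-zero-mean component; from there the coupled EM crawls along a long
plateau (per-iteration ELBO gains of ~1e-5 relative) toward the separated
optimum and routinely exhausts the iteration budget inside the spurious
basin. Since the model separates per block at one-hot memberships, each
block's (π, μ, σ²) is therefore polished by a one-dimensional
two-component EM with the null held fixed (up to 500 iterations; these
cost ~10³ less than outer iterations and reliably cross the plateau).
Second, because the k-means labels the moments were conditioned on are
often noisy while the outer loop's settled memberships are not, `fit`
finishes with a warm-started continuation: θ is re-derived per block from
the settled hard labels and the loop re-run, the continuation replacing
the incumbent only when its final ELBO is higher. Both refinements are
pure initialization strategy — the objective, updates and stopping rule
are untouched — and with them the fitted parameters match a truth-started
per-block oracle EM (the MLE) almost exactly, replicate by replicate.
`initialize(..., refine=False)` exposes the raw threshold-moment stage.

The objective is non-convex, so `fit` uses short-run restarts: restart r
seeds k-means with `seed + r` and cycles the rough-ρ p-value threshold
through {0.5, 0.1, 0.3, 0.05, 0.2} (threshold choice, not k-means seeding,
is what moves the init between mixture basins). Each restart advances 15
outer iterations; only the best-ELBO restart is run to convergence. The
returned fit carries that restart's own trace. Output labels are
canonicalized — blocks sorted by mixing proportion descending, ties by
mean alternative mean — so seeded runs are byte-reproducible despite label
swapping.

### Null-collapse resolution

When a fitted block's alternative density coincides with the null, the
block's mixture weight is unidentifiable: every (π, g = g₀) is
likelihood-equivalent to (0, g₀) and the ELBO is exactly flat in π, which
strands π at whatever the initialization produced (≈ 0.5 on pure-null
blocks, from the p < 0.5 indicator). `fit` detects this by
KL(g₀ ‖ g_ql) < 0.01 nats and reports the identified boundary
representative π → 0 — the same kind of canonical-representative choice as
label sorting, and the inferentially correct one: a pure-null block should
produce no discoveries (its ℓ-values become ≈ 1). A genuinely separated
alternative (N(1,1) vs N(0,1), KL = 0.5) is two orders of magnitude above
the threshold. The diagnostic warning is emitted either way.

## Model selection

Block counts maximize the integrated classification likelihood

    ICL(B₁, B₂) = E_Q̂[log L(X, A, Z₁, Z₂; θ̂)] − pen_BIC,
    pen_BIC = (B₁−1) log n₁ + (B₂−1) log n₂ + [d₀ + (1+d₁) B₁B₂] log(n₁n₂),

with d₀ the number of free null parameters (0 when the null is fixed, 1
when σ₀² is estimated — the `fix_null` flag decides, and the simulation
defaults fix it) and d₁ = 2 for the Gaussian alternative. The expectation
is computed directly (membership terms plus responsibility-weighted edge
terms); algebraically it equals ELBO − H(Q̂), so ICL ≤ ELBO − pen always,
and the entropy gap is what penalizes diffuse posteriors. Ties on the grid
break toward smaller B₁+B₂, then smaller B₁. The default grid is
1..5 × 1..5. A subsampling stability score (mean pairwise adjusted Rand
index of row/column clusterings across random subsamples, 1 by convention
for a one-cluster axis) is provided as auxiliary plumbing for noisy data;
it is a simple documented score, not a reproduction of any published
stability procedure.

## Simulation scenarios

Three generators emulate the benchmark conditions, all 150 × 200 with a
standard-normal null by default, and all pure functions of their seed
(NumPy PCG64 via `default_rng`, so seeds are portable):

- **(a) modular** — three equal-probability blocks per side,
  Π = 0.1 + 0.7·I, alternatives N(1, 1) on the dense diagonal blocks and
  N(3, 1) elsewhere (the sparser blocks carry the larger effect).
- **(b) nested** — the minimal fully nested graph: one generalist per
  vertex type connected to everything, specialist–specialist pairs
  unconnected (n₁ + n₂ − 1 edges); scores N(0,1) off edges, N(2,1) on.
  A general nonincreasing-degree-sequence variant
  (`nested_graph_from_degrees`) is exposed for sensitivity checks, since
  richer nested topologies exist and selection behavior depends on this
  choice.
- **(c) preferential attachment** — type-I vertices arrive with degree
  drawn uniformly from {2,…,6}; each edge attaches to a new type-II vertex
  with probability 1 − λ (λ = 0.8) or to an existing one proportionally to
  degree. Duplicate attachments are redrawn (up to 50 times, then a new
  vertex is created); when an exact column count is requested the axis is
  padded with isolated vertices, or regeneration restarts under a derived
  sub-seed if it overshoots (these two policies are this package's own).

What the generators do **not** emulate: zero inflation, compositional
constraints, non-Gaussian score distributions, or dependence between
entries beyond the block structure. Passing tests therefore certify the
method under its own assumptions plus the two fixed-graph misspecifications
(b) and (c), not robustness to count-data artifacts.

## Differential cross-correlation front end

For paired omics tables Y₁ (m × n₁), Y₂ (m × n₂) with a two-level group
label, each feature pair is scored by

    x_ij = 2 (ρ̂⁽¹⁾_ij − ρ̂⁽²⁾_ij) / sqrt(s⁽¹⁾_ij/m₁ + s⁽²⁾_ij/m₂),

where within each group the blocks are column-standardized with the
m-denominator (so ρ̂ = m⁻¹ Σ Ỹ₁Ỹ₂ is a true correlation in [−1, 1]) and
s_ij is the delta-method variance of ρ̂. The default variance squares the
standardized terms, s = m⁻¹ Σ (2ab − ρ̂a² − ρ̂b²)², which is the influence-
function form and vanishes at |ρ̂| = 1 as a correlation variance must; an
`as_printed` variant with unsquared terms (2ab − ρ̂a − ρ̂b)² is kept because
that form appears in print, but it is not a valid delta-method variance
(nonzero at perfect correlation) and is never the default. The leading
factor 2 is reproduced exactly as displayed. Group 1 is the
lexicographically smaller label, so relabeling the sample sets negates
every score. Identical groups produce exactly 0 via the 0/0 → 0 guard.

For compositional counts, `mclr` applies the centered log-ratio to the
positive entries of each sample and shifts all positive results by
|global minimum| + eps (default eps = 1), leaving zeros exactly at zero;
the shift is global across samples so within-column orderings survive.
mclr-transformed profiles still sum to a constraint, and induced
anti-correlation between components can echo one feature's differential
association into others (visible in `examples/04_differential_zscores.py`);
no correlation statistic provided here removes compositional distortion.

## Numerical choices

- Probability clip 1e-10; variance floor 1e-6; frozen-block weight
  threshold 1e-8; null-collapse KL threshold 0.01 nats.
- `elbo_rel_tol` 1e-6 on |ΔELBO| / (|ELBO| + 1); `max_outer_iter` 100;
  5 inner E-sweeps; 5 restarts with 15 short-run iterations each.
- k-means uses 4 `n_init` per restart with re-seeding (up to 10 attempts)
  if a cluster comes out empty.
- Degenerate inputs: empty ℓ-value sets, constant omics columns, all-zero
  compositional samples and mismatched identifiers raise informative
  errors; a rejection threshold that nothing satisfies returns −∞ and an
  empty rejection set.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the simulation study at
reduced replicate counts chosen to keep a full run on a laptop-class
machine comfortable: 20 replicates for each model-selection rate (the
original study used 100), 10 replicates for parameter recovery, 20 for the
error-rate comparison, and enumeration oracles at n ≤ 4. Selection rates
at 20 replicates carry a binomial standard error of ~7–8 percentage
points, which is why the acceptance checks use the wide bands they do.

## Known limitations

- Parameter recovery in weakly separated blocks (π = 0.8 with μ = 1
  against a standard-normal null) is information-limited: the per-block
  mixture weight has standard error ≈ 0.03–0.05 at ~3 300 entries per
  block, and the VEM cannot beat the MLE it matches. Tight recovery bands
  fail there for any estimator; see the recovery test.
- The single-alternative-per-block Gaussian family cannot represent
  within-block effect-size mixtures; misspecification shows up as inflated
  σ̂²_ql.
- On the minimal single-generalist nested graph the ICL choice of (2, 2)
  is nearly deterministic; richer nested topologies would produce more
  selection variability.
- The B₁ = B₂ = 1 fit is the parametric single-block analogue of
  two-group local-fdr procedures, provided as a baseline; it is not an
  adaptive nonparametric local-fdr estimator.
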