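# bnsbm — bipartite noisy stochastic block model

Structured multiple testing for matrix-valued association scores, built for
microbiome–metabolome network inference and any problem of the same shape:
given an n₁ × n₂ matrix of z-scores **X**, decide which entries correspond
to real associations while controlling the false discovery rate, and
cluster the rows and columns into interpretable modules along the way.

Vector-based corrections (Benjamini–Hochberg, q-values) rank each score in
isolation and leave power on the table when the true association network
has densely connected modules. `bnsbm` instead treats the unknown pattern
of true/false nulls as a latent bipartite graph **A** drawn from a
stochastic block model,

    Z_i1 ~ Mult(α₁),  Z_j2 ~ Mult(α₂),  A_ij | Z ~ Bern(π[Z_i1, Z_j2]),
    x_ij | A_ij = 0 ~ N(0, σ₀²),   x_ij | A_ij = 1 ~ N(μ_ql, σ²_ql),

fits θ = (α₁, α₂, Π, ν₀, ν) by variational EM, chooses the block counts
(B₁, B₂) with the integrated classification likelihood (ICL), and rejects
entries whose structured ℓ-value

    ℓ(x; q, l) = (1 − π_ql) g₀(x) / [π_ql g(x; ν_ql) + (1 − π_ql) g₀(x)]

falls below the largest threshold keeping the plug-in marginal-FDR
estimate within the nominal level α. Pooling information within blocks is
what buys the extra power. See `docs/methods.md` for the full model,
algorithm and design choices.

The package also ships the simulation scenarios used to benchmark the
method (modular, nested, preferential-attachment), classical baselines
(BH, Storey q-values), and a front end that turns paired omics tables into
a differential cross-correlation z-score matrix (with an mclr transform
for compositional counts).

## Worked example

```python
from bnsbm import FitOptions, decide, fit, sample_noisysbm, scenario_a_params

theta = scenario_a_params()                       # 3x3 modular benchmark
X, truth = sample_noisysbm(150, 200, theta, seed=1)
res = fit(X, FitOptions(B1=3, B2=3, n_restarts=5, seed=0))
dec = decide(X, res, alpha=0.1)
```

Running `examples/01_simulate_and_fit.py` (this model, these seeds) prints

```
row-cluster ARI: 1.0
col-cluster ARI: 1.0
estimated Pi:
 [[0.092 0.09  0.848]
 [0.797 0.093 0.089]
 [0.111 0.835 0.103]]
```

— the latent row and column clusters are recovered exactly (adjusted Rand
index 1.0), and the estimated connectivity matrix is the generating
Π = 0.1 + 0.7·I up to block relabeling. `examples/03_structured_testing_vs_bh.py`
compares the decisions against BH on another replicate at α = 0.1:

```
structured: rejected  7921 of 30000 (tau=0.229)  FDP=0.105  TDP=0.709
BH        : rejected  1534 of 30000             FDP=0.062  TDP=0.144
```

The structured procedure recovers 71% of the true edges at a realized
false discovery proportion near the nominal level, where BH finds 14%.
Each `examples/` script is a short narrative of one capability: fitting,
ICL model selection, testing vs baselines, and the z-score front end.

## Command line

A thin CLI wraps the library for file-based pipelines (TSV matrices with
identifier headers, JSON fits):

```sh
bnsbm simulate --scenario a --seed 1 --out sim
bnsbm fit      --scores sim.X.tsv --b1 3 --b2 3 --seed 0 --out fit.json
bnsbm select   --scores sim.X.tsv --b1-max 4 --b2-max 4 --out select.json
bnsbm test     --scores sim.X.tsv --fit fit.json --alpha 0.1 --out edges.tsv
bnsbm zscores  --omics1 taxa.tsv --omics2 metabolites.tsv \
               --groups groups.tsv --transform mclr --out X.tsv
bnsbm benchmark --scenario a --reps 10 --alphas 0.05,0.1 --out summary.tsv
```

All randomized commands take `--seed` and are byte-reproducible for a
fixed seed and version.

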