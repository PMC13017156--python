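"""Structured l-value testing versus Benjamini-Hochberg on one replicate.

Fits the block model, thresholds the structured l-values at the largest
cutoff whose plug-in marginal-FDR estimate stays within alpha = 0.1, and
compares the realized false/true discovery proportions with BH applied to
the two-sided p-values of the same scores. Pooling information within
blocks typically finds many more of the true edges at comparable error.
"""

from bnsbm import (
    Decision,
    FitOptions,
    bh_reject,
    decide,
    empirical_rates,
    fit,
    sample_noisysbm,
    scenario_a_params,
    zscores_to_pvalues,
)

alpha = 0.1
X, truth = sample_noisysbm(150, 200, scenario_a_params(), seed=2)
res = fit(X, FitOptions(B1=3, B2=3, n_restarts=5, seed=0))

dec = decide(X, res, alpha=alpha)
r = empirical_rates(dec, truth)
print(f"structured: rejected {dec.n_rejected:5d} of {X.n1 * X.n2} "
      f"(tau={dec.tau:.3f})  FDP={r.fdp:.3f}  TDP={r.tdp:.3f}")

bh = bh_reject(zscores_to_pvalues(X.values), alpha)
rb = empirical_rates(Decision(dec.lvalues, dec.tau, bh, 0.0, alpha), truth)
print(f"BH        : rejected {int(bh.sum()):5d} of {X.n1 * X.n2} "
      f"            FDP={rb.fdp:.3f}  TDP={rb.tdp:.3f}")
print("\nFDP = false discovery proportion among rejections; "
      "TDP = fraction of the true edges recovered.")
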