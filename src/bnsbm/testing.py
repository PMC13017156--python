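"""Multiple-testing decisions from a fitted block model, plus baselines.

The structured procedure plugs the hard block memberships and parameter
estimates into the l-value formula (the posterior probability that an entry
is null given its score and block pair), then rejects all entries whose
l-value falls at or below the largest threshold for which the plug-in
marginal-FDR estimate — the running mean of the sorted l-values — stays
within the nominal level. Classical vector-based baselines (Benjamini-
Hochberg, Storey q-values) and truth-based error-rate evaluators are
included for benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .model import LatentTruth, ScoreMatrix, ell_value
from .vem import FitResult


@dataclass
class Decision:
    """Rejection decision: l-values, threshold, binary rejections, mFDR estimate."""

    lvalues: np.ndarray
    tau: float
    reject: np.ndarray
    mfdr_hat: float
    alpha: float

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


def lvalue_matrix(X: ScoreMatrix, fit: FitResult) -> np.ndarray:
    """Structured l-value of every entry at the hard plug-in memberships.

    Entry (i, j) uses block pair (Z1_hat[i], Z2_hat[j]); with a single block
    per axis this reduces to the classical two-group local false discovery
    rate applied entrywise.
    """
    theta = fit.theta_hat
    L = np.empty(X.shape)
    for q in range(theta.B1):
        rows = fit.Z1_hat == q
        if not rows.any():
            continue
        for l in range(theta.B2):
            cols = fit.Z2_hat == l
            if not cols.any():
                continue
            L[np.ix_(rows, cols)] = ell_value(X.values[np.ix_(rows, cols)], q, l, theta)
    return L


def mfdr_threshold(lvalues: np.ndarray, alpha: float) -> tuple[float, np.ndarray]:
    """Largest threshold whose plug-in marginal-FDR estimate stays <= alpha.

    Sort the l-values ascending; the plug-in mFDR of rejecting the k
    smallest is their running mean, so take k* = max{k : mean of the k
    smallest <= alpha}. Returns (tau, reject-mask on the input's shape) with
    tau = the k*-th smallest l-value; ties at tau are all rejected. When no
    k qualifies, tau is -inf and nothing is rejected.
    """
    lvalues = np.asarray(lvalues, dtype=float)
    if lvalues.size == 0:
        raise ValueError("empty l-value input")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    flat = np.sort(lvalues, axis=None)
    running_mean = np.cumsum(flat) / np.arange(1, flat.size + 1)
    ok = np.nonzero(running_mean <= alpha)[0]
    if ok.size == 0:
        return -np.inf, np.zeros_like(lvalues, dtype=bool)
    tau = float(flat[ok[-1]])
    return tau, lvalues <= tau


def decide(X: ScoreMatrix, fit: FitResult, alpha: float) -> Decision:
    """Full structured decision at nominal mFDR level alpha."""
    L = lvalue_matrix(X, fit)
    tau, reject = mfdr_threshold(L, alpha)
    mfdr_hat = float(L[reject].mean()) if reject.any() else 0.0
    return Decision(lvalues=L, tau=tau, reject=reject.astype(int), mfdr_hat=mfdr_hat, alpha=alpha)


@dataclass
class EmpiricalRates:
    """Per-replicate error-rate components against a known latent graph.

    ``fdp``/``tdp`` are the false/true discovery proportions of this single
    decision; the numerator/denominator counts let a harness average them
    separately to estimate the marginal FDR (ratio of expectations) across
    replicates.
    """

    fdp: float
    tdp: float | None
    n_false_rejections: int
    n_rejections: int
    n_true_edges: int


def empirical_rates(decision: Decision, truth: LatentTruth) -> EmpiricalRates:
    """Evaluate a decision against the ground-truth adjacency.

    The false discovery proportion guards the denominator with ``max(R, 1)``
    so that no rejections yield FDP 0. The true discovery proportion is None
    when the truth has no edges.
    """
    phi = np.asarray(decision.reject, dtype=int)
    A = truth.A
    if phi.shape != A.shape:
        raise ValueError(f"shape mismatch: decision {phi.shape} vs truth {A.shape}")
    n_rej = int(phi.sum())
    n_false = int(((1 - A) * phi).sum())
    n_true_edges = int(A.sum())
    fdp = n_false / max(n_rej, 1)
    tdp = float((A * phi).sum() / n_true_edges) if n_true_edges else None
    return EmpiricalRates(fdp, tdp, n_false, n_rej, n_true_edges)


def zscores_to_pvalues(z: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-values, p = 2(1 - Phi(|z|))."""
    return 2.0 * norm.sf(np.abs(np.asarray(z, dtype=float)))


def bh_reject(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level alpha (binary array)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(pvalues.shape).astype(int)


def storey_q(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the fixed-lambda pi0 estimate.

    ``pi0 = min(1, #{p > lam} / ((1 - lam) N))``, then the usual step-up
    construction: q_(i) = min over j >= i of pi0 N p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flat = p.ravel()
    N = flat.size
    pi0 = min(1.0, np.sum(flat > lam) / ((1.0 - lam) * N))
    order = np.argsort(flat)
    q_sorted = pi0 * N * flat[order] / np.arange(1, N + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(N)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.reshape(p.shape)
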