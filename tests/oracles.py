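"""Independent brute-force oracles used to validate the implementation.

Everything here is written against scipy/numpy primitives only and avoids
the package's own code paths: enumeration over latent configurations,
naive triple-loop accumulations, grid searches and a direct one-dimensional
EM. Deliberately slow and only usable at tiny sizes.
"""

from itertools import product

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import norm


def log_mix_entry(x, pi, mu0, s0, mu1, s1):
    """log[pi N(x; mu1, s1) + (1-pi) N(x; mu0, s0)] by direct arithmetic."""
    return np.log(
        pi * norm.pdf(x, mu1, np.sqrt(s1)) + (1.0 - pi) * norm.pdf(x, mu0, np.sqrt(s0))
    )


def posterior_null_prob(x, pi, mu0, s0, mu1, s1):
    """P(A=0 | x, block) = (1-pi) g0 / (pi g + (1-pi) g0) by direct arithmetic."""
    a = pi * norm.pdf(x, mu1, np.sqrt(s1))
    b = (1.0 - pi) * norm.pdf(x, mu0, np.sqrt(s0))
    return b / (a + b)


def exact_log_marginal(x, alpha1, alpha2, Pi, s0, mu, s):
    """log P(X) by enumerating every membership assignment.

    Given (Z1, Z2) the latent adjacency marginalizes analytically entry by
    entry, so the marginal is a logsumexp over B1^n1 * B2^n2 terms.
    """
    n1, n2 = x.shape
    B1, B2 = len(alpha1), len(alpha2)
    terms = []
    for z1 in product(range(B1), repeat=n1):
        for z2 in product(range(B2), repeat=n2):
            lp = sum(np.log(alpha1[q]) for q in z1) + sum(np.log(alpha2[l]) for l in z2)
            for i in range(n1):
                for j in range(n2):
                    q, l = z1[i], z2[j]
                    lp += log_mix_entry(x[i, j], Pi[q, l], 0.0, s0, mu[q, l], s[q, l])
            terms.append(lp)
    return logsumexp(terms)


def posterior_null_by_graph_enumeration(x, z1, z2, Pi, s0, mu, s):
    """P(A_ij = 0 | X, Z1, Z2) by summing over every adjacency matrix.

    Exponential in n1*n2; checks that the entrywise closed form really is
    the full joint conditional.
    """
    n1, n2 = x.shape
    cells = [(i, j) for i in range(n1) for j in range(n2)]
    num = np.zeros((n1, n2))
    den = 0.0
    for bits in product((0, 1), repeat=len(cells)):
        lp = 0.0
        for (i, j), a in zip(cells, bits):
            q, l = z1[i], z2[j]
            p = Pi[q, l]
            if a:
                lp += np.log(p) + norm.logpdf(x[i, j], mu[q, l], np.sqrt(s[q, l]))
            else:
                lp += np.log(1 - p) + norm.logpdf(x[i, j], 0.0, np.sqrt(s0))
        w = np.exp(lp)
        den += w
        for (i, j), a in zip(cells, bits):
            if a == 0:
                num[i, j] += w
    return num / den


def naive_m_step(x, b1, b2, rho):
    """Triple-loop M-step accumulations; rho has shape (B1, B2, n1, n2)."""
    n1, n2 = x.shape
    B1, B2 = b1.shape[1], b2.shape[1]
    alpha1 = b1.mean(axis=0)
    alpha2 = b2.mean(axis=0)
    Pi = np.zeros((B1, B2))
    mu = np.zeros((B1, B2))
    var = np.zeros((B1, B2))
    for q in range(B1):
        for l in range(B2):
            num_pi = den_pi = num_mu = den_mu = 0.0
            for i in range(n1):
                for j in range(n2):
                    w = b1[i, q] * b2[j, l]
                    num_pi += w * rho[q, l, i, j]
                    den_pi += w
                    num_mu += w * rho[q, l, i, j] * x[i, j]
                    den_mu += w * rho[q, l, i, j]
            Pi[q, l] = num_pi / den_pi
            mu[q, l] = num_mu / den_mu
            num_v = 0.0
            for i in range(n1):
                for j in range(n2):
                    w = b1[i, q] * b2[j, l] * rho[q, l, i, j]
                    num_v += w * (x[i, j] - mu[q, l]) ** 2
            var[q, l] = num_v / den_mu
    num_s0 = den_s0 = 0.0
    for i in range(n1):
        for j in range(n2):
            for q in range(B1):
                for l in range(B2):
                    w = b1[i, q] * b2[j, l] * (1.0 - rho[q, l, i, j])
                    num_s0 += w * x[i, j] ** 2
                    den_s0 += w
    return alpha1, alpha2, Pi, mu, var, num_s0 / den_s0


def pooled_mixture_em(x, s0, pi0, mu0, v0, n_iter=500, tol=1e-12):
    """One-dimensional two-group EM with a fixed N(0, s0) null.

    The single-block specialization of the model: every observation shares
    one edge probability pi and one alternative N(mu, v).
    """
    x = np.asarray(x, dtype=float).ravel()
    pi, mu, v = pi0, mu0, v0
    prev = -np.inf
    for _ in range(n_iter):
        a = pi * norm.pdf(x, mu, np.sqrt(v))
        b = (1 - pi) * norm.pdf(x, 0.0, np.sqrt(s0))
        r = a / (a + b)
        pi = r.mean()
        mu = (r * x).sum() / r.sum()
        v = (r * (x - mu) ** 2).sum() / r.sum()
        ll = np.sum(np.log(a + b))
        if abs(ll - prev) < tol:
            break
        prev = ll
    return pi, mu, v


def bh_stepup(p, alpha):
    """Classical BH step-up by explicit enumeration of thresholds."""
    p = np.asarray(p, dtype=float).ravel()
    N = p.size
    order = np.argsort(p)
    k_star = 0
    for k in range(1, N + 1):
        if p[order[k - 1]] <= k * alpha / N:
            k_star = k
    reject = np.zeros(N, dtype=int)
    if k_star:
        reject[order[:k_star]] = 1
    return reject


def mfdr_threshold_enumerated(lvalues, alpha):
    """Try every candidate threshold; keep the largest with mean l <= alpha."""
    lv = np.sort(np.asarray(lvalues, dtype=float).ravel())
    best_tau = -np.inf
    for tau in lv:
        sel = lv[lv <= tau]
        if sel.mean() <= alpha:
            best_tau = max(best_tau, tau)
    return best_tau


def match_blocks(Z_true, Z_hat, B):
    """Permutation of estimated labels maximizing agreement (Hungarian)."""
    confusion = np.zeros((B, B))
    for t, h in zip(Z_true, Z_hat):
        confusion[t, h] += 1
    row, col = linear_sum_assignment(-confusion)
    perm = np.empty(B, dtype=int)
    perm[col] = row
    return perm  # perm[h] = true label matched to estimated label h
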