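"""Core probabilistic objects for the bipartite noisy stochastic block model.

The observation model: a latent bipartite graph ``A`` (n1 x n2) whose edges
follow a bipartite stochastic block model — row vertices carry one of B1
latent blocks drawn from mixing proportions ``alpha1``, column vertices one
of B2 blocks from ``alpha2``, and ``A_ij ~ Bernoulli(pi[q, l])`` given the
block pair ``(q, l)``. The graph itself is unobserved; instead each entry of
a score matrix ``X`` is emitted from a null density ``g0`` when ``A_ij = 0``
and from a block-specific alternative density ``g(.; nu[q, l])`` when
``A_ij = 1``.

This module holds the domain types and the per-entry quantities every other
module consumes: log-densities, edge responsibilities
``rho = P(A_ij = 1 | Z, X; theta)``, structured l-values (the posterior null
probability, a block-informed local false discovery rate), the variational
lower bound (ELBO), and the ``d`` terms that drive the variational E-step.

All density arithmetic is done in log space so that scores as extreme as
|x| ~ 40 neither overflow nor underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, xlogy

#: probabilities are clipped into [PROB_CLIP, 1 - PROB_CLIP] before any log,
#: since the variational identities divide by rho and 1 - rho.
PROB_CLIP = 1e-10

_SUPPORTED_FAMILIES = ("gaussian",)


def _clip_prob(p):
    return np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)


@dataclass(frozen=True)
class DensitySpec:
    """A parametric emission density.

    Currently only ``family="gaussian"`` is supported, with
    ``params = (mean, variance)``; the enum is the extension point for other
    tractable families. ``n_free_params`` is the number of free parameters
    this density contributes to the model-complexity penalty (2 for an
    estimated Gaussian alternative, 1 for a Gaussian null with estimated
    variance, 0 for a fully fixed null).
    """

    family: str
    params: tuple[float, ...]
    n_free_params: int = 2

    def __post_init__(self):
        if self.family not in _SUPPORTED_FAMILIES:
            raise ValueError(
                f"unsupported density family {self.family!r}; "
                f"supported: {_SUPPORTED_FAMILIES}"
            )
        if self.family == "gaussian":
            if len(self.params) != 2:
                raise ValueError("gaussian density takes params=(mean, variance)")
            if not self.params[1] > 0:
                raise ValueError(f"variance must be > 0, got {self.params[1]}")

    @property
    def mean(self) -> float:
        return float(self.params[0])

    @property
    def variance(self) -> float:
        return float(self.params[1])


def gaussian(mean: float, variance: float, n_free_params: int = 2) -> DensitySpec:
    """Shorthand constructor for a Gaussian :class:`DensitySpec`."""
    return DensitySpec("gaussian", (float(mean), float(variance)), n_free_params)


def density_eval(spec: DensitySpec, x) -> np.ndarray | float:
    """Log-density ``log g(x; params)``; vectorized over ``x``."""
    if spec.family == "gaussian":
        m, v = spec.params
        out = -0.5 * (np.log(2.0 * np.pi * v) + (np.asarray(x, dtype=float) - m) ** 2 / v)
        return out if np.ndim(x) else float(out)
    raise ValueError(f"unsupported density family {spec.family!r}")  # pragma: no cover


@dataclass
class ScoreMatrix:
    """An n1 x n2 matrix of association scores with row/column identifiers.

    Rows index one vertex type (e.g. taxa), columns the other (e.g.
    metabolites); each entry is a dimensionless statistic such as a z-score.
    """

    values: np.ndarray
    row_ids: list[str] = field(default=None)  # type: ignore[assignment]
    col_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2-dimensional")
        n1, n2 = self.values.shape
        if n1 < 2 or n2 < 2:
            raise ValueError(f"need at least 2 rows and 2 columns, got {n1}x{n2}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix contains non-finite entries")
        if self.row_ids is None:
            self.row_ids = [f"r{i + 1}" for i in range(n1)]
        if self.col_ids is None:
            self.col_ids = [f"c{j + 1}" for j in range(n2)]
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != n1 or len(self.col_ids) != n2:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.row_ids)) != n1 or len(set(self.col_ids)) != n2:
            raise ValueError("identifiers must be unique within each axis")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n1(self) -> int:
        return self.values.shape[0]

    @property
    def n2(self) -> int:
        return self.values.shape[1]


@dataclass
class BlockModelParams:
    """Full parameter set theta = (alpha1, alpha2, Pi, nu0, nu).

    ``alpha1``/``alpha2`` are the block mixing proportions for the two vertex
    types, ``Pi[q, l]`` the edge probability between row block q and column
    block l, ``nu0`` the null emission density (Gaussian with mean fixed at
    0) and ``nu[q][l]`` the alternative emission density of block (q, l).
    ``Pi`` is clipped into the open unit interval on construction.
    """

    alpha1: np.ndarray
    alpha2: np.ndarray
    Pi: np.ndarray
    nu0: DensitySpec
    nu: Sequence[Sequence[DensitySpec]]

    def __post_init__(self):
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.alpha2 = np.asarray(self.alpha2, dtype=float)
        self.Pi = _clip_prob(np.asarray(self.Pi, dtype=float))
        for name, a in (("alpha1", self.alpha1), ("alpha2", self.alpha2)):
            if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if self.Pi.shape != (self.B1, self.B2):
            raise ValueError("Pi shape does not match (B1, B2)")
        if self.nu0.family == "gaussian" and self.nu0.mean != 0.0:
            raise ValueError("null gaussian mean is fixed at 0")
        self.nu = [list(row) for row in self.nu]
        if len(self.nu) != self.B1 or any(len(r) != self.B2 for r in self.nu):
            raise ValueError("nu must be a B1 x B2 array of DensitySpec")

    @property
    def B1(self) -> int:
        return len(self.alpha1)

    @property
    def B2(self) -> int:
        return len(self.alpha2)

    @property
    def alt_means(self) -> np.ndarray:
        """B1 x B2 array of alternative means (Gaussian family)."""
        return np.array([[d.mean for d in row] for row in self.nu])

    @property
    def alt_vars(self) -> np.ndarray:
        return np.array([[d.variance for d in row] for row in self.nu])

    def check_identifiability(self) -> list[str]:
        """Diagnostics for parameter configurations that are not identifiable.

        The model is identifiable (up to label swapping) when the Gaussian
        parameter pairs (mu_ql, sigma_ql^2) and (0, sigma0^2) are all
        distinct; a fitted alternative block that collapses onto the null
        makes the corresponding edges undetectable. Returns a list of
        warning strings (also emitted via :mod:`warnings`).
        """
        msgs = []
        null_pair = (0.0, self.nu0.variance)
        seen: dict[tuple[float, float], tuple[int, int]] = {}
        for q in range(self.B1):
            for l in range(self.B2):
                pair = (round(self.nu[q][l].mean, 6), round(self.nu[q][l].variance, 6))
                if abs(pair[0] - null_pair[0]) < 1e-3 and abs(pair[1] - null_pair[1]) < 1e-3:
                    msgs.append(
                        f"alternative density of block ({q + 1},{l + 1}) nearly "
                        f"coincides with the null (mu={pair[0]}, var={pair[1]})"
                    )
                elif pair in seen:
                    msgs.append(
                        f"blocks {seen[pair]} and ({q + 1},{l + 1}) share the same "
                        "alternative parameters"
                    )
                seen.setdefault(pair, (q + 1, l + 1))
        for m in msgs:
            warnings.warn(m, RuntimeWarning, stacklevel=2)
        return msgs


@dataclass
class LatentTruth:
    """The latent graph and block memberships of a simulated instance.

    Memberships are stored 0-based; public identifiers, not indices, are used
    in all serialized output.
    """

    A: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=int)
        self.Z1 = np.asarray(self.Z1, dtype=int)
        self.Z2 = np.asarray(self.Z2, dtype=int)
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A entries must be binary")
        if self.A.shape != (len(self.Z1), len(self.Z2)):
            raise ValueError("A shape does not match membership lengths")


@dataclass
class VariationalState:
    """Factorized variational posterior over block memberships.

    ``beta1[i, q]`` is the variational probability that row vertex i belongs
    to block q (rows sum to 1); likewise ``beta2`` for columns. The edge
    responsibilities rho are not stored: they are a deterministic function of
    theta and are recomputed on demand, which keeps them consistent with the
    current parameters.
    """

    beta1: np.ndarray
    beta2: np.ndarray

    def __post_init__(self):
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        for name, b in (("beta1", self.beta1), ("beta2", self.beta2)):
            if b.ndim != 2:
                raise ValueError(f"{name} must be 2-dimensional")
            if np.any(b < 0) or np.max(np.abs(b.sum(axis=1) - 1.0)) > 1e-12:
                raise ValueError(f"every row of {name} must be a probability vector")


# ---------------------------------------------------------------------------
# per-entry quantities


def _log_odds(x, q: int, l: int, theta: BlockModelParams):
    """log [pi g(x; nu_ql)] - log [(1-pi) g0(x)] for block (q, l)."""
    pi = _clip_prob(theta.Pi[q, l])
    lg1 = density_eval(theta.nu[q][l], x)
    lg0 = density_eval(theta.nu0, x)
    return np.log(pi) - np.log1p(-pi) + lg1 - lg0


def responsibility(x, q: int, l: int, theta: BlockModelParams):
    """Edge responsibility rho = P(A_ij = 1 | Z_i1 = q, Z_j2 = l, x; theta).

    Equals ``pi g(x) / (pi g(x) + (1 - pi) g0(x))``, evaluated in log space.
    """
    return expit(_log_odds(x, q, l, theta))


def ell_value(x, q: int, l: int, theta: BlockModelParams):
    """Structured l-value: the posterior probability that the null holds.

    ``(1 - pi) g0(x) / (pi g(x) + (1 - pi) g0(x))``; complements
    :func:`responsibility` exactly (both are logistic in the same log-odds).
    """
    return expit(-_log_odds(x, q, l, theta))


def d_term(x: float, q: int, l: int, theta: BlockModelParams, rho: float) -> float:
    """Variational edge term d_ij^ql at a given responsibility value.

    ``rho log(pi g(x)/rho) + (1-rho) log((1-pi) g0(x)/(1-rho))`` with the
    convention ``0 log(./0) = 0``. As a function of rho it is maximized at
    rho = responsibility(x, q, l, theta), where it equals the log marginal
    mixture density ``log(pi g(x) + (1-pi) g0(x))``.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    pi = float(_clip_prob(theta.Pi[q, l]))
    lg1 = density_eval(theta.nu[q][l], x)
    lg0 = density_eval(theta.nu0, x)
    out = 0.0
    if rho > 0.0:
        out += rho * (np.log(pi) + lg1 - np.log(rho))
    if rho < 1.0:
        out += (1.0 - rho) * (np.log1p(-pi) + lg0 - np.log1p(-rho))
    return float(out)


# ---------------------------------------------------------------------------
# vectorized block arrays (shape (B1, B2, n1, n2)) used by the fitting loop


def log_null_matrix(X: ScoreMatrix, theta: BlockModelParams) -> np.ndarray:
    """(n1, n2) matrix of log g0(x_ij)."""
    return density_eval(theta.nu0, X.values)


def log_alt_matrix(X: ScoreMatrix, theta: BlockModelParams) -> np.ndarray:
    """(B1, B2, n1, n2) array of log g(x_ij; nu_ql)."""
    mu = theta.alt_means[:, :, None, None]
    var = theta.alt_vars[:, :, None, None]
    x = X.values[None, None, :, :]
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def log_odds_matrix(X: ScoreMatrix, theta: BlockModelParams) -> np.ndarray:
    """(B1, B2, n1, n2) array of the per-block log odds of an edge."""
    pi = _clip_prob(theta.Pi)[:, :, None, None]
    return np.log(pi) - np.log1p(-pi) + log_alt_matrix(X, theta) - log_null_matrix(X, theta)[None, None]


def responsibility_matrix(X: ScoreMatrix, theta: BlockModelParams) -> np.ndarray:
    """(B1, B2, n1, n2) array of responsibilities rho_ij^ql."""
    return expit(log_odds_matrix(X, theta))


def log_mixture_matrix(X: ScoreMatrix, theta: BlockModelParams) -> np.ndarray:
    """(B1, B2, n1, n2) array of log[pi g(x) + (1-pi) g0(x)].

    This equals d_ij^ql evaluated at the posterior responsibility, the
    quantity the E-step fixed-point updates and the ELBO both consume.
    """
    pi = _clip_prob(theta.Pi)[:, :, None, None]
    a = np.log(pi) + log_alt_matrix(X, theta)
    b = np.log1p(-pi) + log_null_matrix(X, theta)[None, None]
    return np.logaddexp(a, b)


def elbo(X: ScoreMatrix, theta: BlockModelParams, state: VariationalState) -> float:
    """Evidence lower bound of the factorized variational family.

    Membership terms ``sum beta (log alpha - log beta)`` for both axes plus
    the edge term ``sum_ij sum_ql beta1 beta2 d_ij^ql`` with d evaluated at
    the posterior responsibilities (where it reduces to the log mixture
    density). Uses the conventions 0 log 0 = 0 and 0 log(0/0) = 0. Always a
    lower bound on the exact log marginal likelihood; the gap is the KL
    divergence from the true posterior.
    """
    b1, b2 = state.beta1, state.beta2
    if b1.shape != (X.n1, theta.B1) or b2.shape != (X.n2, theta.B2):
        raise ValueError("variational state dimensions do not match X and theta")
    la1 = np.log(_clip_prob(theta.alpha1))
    la2 = np.log(_clip_prob(theta.alpha2))
    term1 = float(np.sum(b1 * la1) - np.sum(xlogy(b1, b1)))
    term2 = float(np.sum(b2 * la2) - np.sum(xlogy(b2, b2)))
    D = log_mixture_matrix(X, theta)
    term3 = float(np.einsum("iq,jl,qlij->", b1, b2, D, optimize=True))
    return term1 + term2 + term3
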