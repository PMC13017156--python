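"""Simulators: latent bipartite graphs and the score matrices they emit.

Three study scenarios are covered, all at default dimension 150 x 200 with a
standard-normal null:

(a) a modular bipartite stochastic block model with three equal-probability
    blocks per side, within-block edge probability 0.8 and between-block
    0.1; alternative scores are N(1, 1) on the three dense diagonal blocks
    and N(3, 1) elsewhere, so the sparser blocks carry the larger effect;
(b) a fixed fully nested graph with a single "generalist" per vertex type
    connected to every vertex of the other type; edge scores are N(2, 1);
(c) a bipartite preferential-attachment graph (new type-I vertices attach
    their 2-6 edges to existing type-II vertices proportionally to degree
    with probability lambda = 0.8, else to a brand-new vertex); edge scores
    N(2, 1).

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BlockModelParams, DensitySpec, LatentTruth, ScoreMatrix, gaussian


@dataclass
class ScenarioConfig:
    """Configuration for one simulation scenario."""

    scenario: str = "a"
    n1: int = 150
    n2: int = 200
    seed: int = 0
    # scenario (c) parameters
    pa_lambda: float = 0.8
    degree_choices: tuple[int, ...] = (2, 3, 4, 5, 6)
    # alternative density for scenarios (b) and (c)
    alt_mean: float = 2.0
    alt_var: float = 1.0

    def __post_init__(self):
        if self.scenario not in ("a", "b", "c"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("n1 and n2 must be >= 2")


def scenario_a_params() -> BlockModelParams:
    """Parameters of the modular scenario (a).

    Three blocks per side with equal mixing proportions; Pi = 0.8 on the
    diagonal and 0.1 off it; standard-normal null; alternatives N(mu, 1)
    with mu = 1 on diagonal blocks and mu = 3 elsewhere.
    """
    B = 3
    Pi = np.full((B, B), 0.1) + 0.7 * np.eye(B)
    mu = np.full((B, B), 3.0)
    np.fill_diagonal(mu, 1.0)
    return BlockModelParams(
        alpha1=np.full(B, 1.0 / B),
        alpha2=np.full(B, 1.0 / B),
        Pi=Pi,
        nu0=gaussian(0.0, 1.0, n_free_params=0),
        nu=[[gaussian(mu[q, l], 1.0) for l in range(B)] for q in range(B)],
    )


def sample_noisysbm(
    n1: int, n2: int, theta: BlockModelParams, seed: int
) -> tuple[ScoreMatrix, LatentTruth]:
    """Draw (X, truth) from the bipartite noisy SBM at parameters theta.

    Memberships are multinomial from the mixing proportions, edges Bernoulli
    from Pi given the block pair, and each score comes from the null density
    on a non-edge and from the block's alternative density on an edge.
    """
    rng = np.random.default_rng(seed)
    Z1 = rng.choice(theta.B1, size=n1, p=theta.alpha1)
    Z2 = rng.choice(theta.B2, size=n2, p=theta.alpha2)
    P = theta.Pi[np.ix_(Z1, Z2)]
    A = (rng.random((n1, n2)) < P).astype(int)
    mu = theta.alt_means[np.ix_(Z1, Z2)]
    sd = np.sqrt(theta.alt_vars[np.ix_(Z1, Z2)])
    null_draw = rng.normal(0.0, np.sqrt(theta.nu0.variance), size=(n1, n2))
    alt_draw = mu + sd * rng.standard_normal((n1, n2))
    X = np.where(A == 1, alt_draw, null_draw)
    return ScoreMatrix(X), LatentTruth(A=A, Z1=Z1, Z2=Z2)


def nested_graph(n1: int, n2: int) -> np.ndarray:
    """Minimal fully nested bipartite adjacency: one generalist per type.

    Edge iff the row is the first vertex or the column is the first vertex:
    the generalist row connects to every column and the generalist column to
    every row, while specialist-specialist pairs are unconnected. Every two
    neighborhoods are inclusion-comparable, so the graph is fully nested.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must be >= 2")
    A = np.zeros((n1, n2), dtype=int)
    A[0, :] = 1
    A[:, 0] = 1
    return A


def nested_graph_from_degrees(row_degrees, n2: int) -> np.ndarray:
    """General nested adjacency from a nonincreasing row-degree sequence.

    Row i connects to the first ``row_degrees[i]`` columns; with a
    nonincreasing degree sequence the neighborhoods are totally ordered by
    inclusion. Exposed for sensitivity checks around the minimal
    single-generalist construction.
    """
    d = np.asarray(row_degrees, dtype=int)
    if np.any(np.diff(d) > 0):
        raise ValueError("row_degrees must be nonincreasing")
    if np.any(d < 0) or np.any(d > n2):
        raise ValueError("degrees must lie in [0, n2]")
    A = np.zeros((len(d), n2), dtype=int)
    for i, di in enumerate(d):
        A[i, :di] = 1
    return A


def pa_graph(
    n1: int,
    lam: float = 0.8,
    degree_choices=(2, 3, 4, 5, 6),
    seed: int = 0,
    n2: int | None = None,
) -> tuple[np.ndarray, int]:
    """Bipartite preferential-attachment adjacency.

    Type-I vertices arrive one at a time; each draws a degree d uniformly
    from ``degree_choices`` and attaches each of its d edges to a brand-new
    type-II vertex with probability ``1 - lam``, otherwise to an existing
    type-II vertex chosen proportionally to its current degree. A duplicate
    (i, j) attachment is redrawn (up to 50 attempts, after which a new
    vertex is created instead). The first vertex necessarily creates all its
    neighbors.

    When ``n2`` is given, the type-II axis is padded with isolated vertices
    up to n2; if generation overshoots n2, it restarts with a derived
    sub-seed (up to 20 restarts, then an error advises changing parameters).
    Returns ``(adjacency, n_type2_before_padding)``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    degree_choices = list(degree_choices)
    if not degree_choices:
        raise ValueError("degree_choices must be non-empty")
    for restart in range(20):
        rng = np.random.default_rng(np.random.default_rng([seed, restart]).integers(2**31))
        edges: set[tuple[int, int]] = set()
        degree: list[int] = []  # current degree of each type-II vertex
        for i in range(n1):
            d = int(rng.choice(degree_choices))
            for _ in range(d):
                attached = False
                for _attempt in range(50):
                    if degree and rng.random() < lam:
                        total = sum(degree)
                        j = int(rng.choice(len(degree), p=np.asarray(degree) / total))
                        if (i, j) in edges:
                            continue
                    else:
                        j = len(degree)
                        degree.append(0)
                    edges.add((i, j))
                    degree[j] += 1
                    attached = True
                    break
                if not attached:  # fall back to a fresh vertex
                    j = len(degree)
                    degree.append(1)
                    edges.add((i, j))
        n_generated = len(degree)
        if n2 is None or n_generated <= n2:
            cols = n_generated if n2 is None else n2
            A = np.zeros((n1, cols), dtype=int)
            for i, j in edges:
                A[i, j] = 1
            return A, n_generated
    raise RuntimeError(
        f"could not generate <= {n2} type-II vertices in 20 restarts; "
        "decrease the degrees or increase lambda/n2"
    )


def scores_from_graph(
    A: np.ndarray, null: DensitySpec, alt: DensitySpec, seed: int
) -> ScoreMatrix:
    """Score matrix for a fixed adjacency: null draws off edges, alternative on."""
    A = np.asarray(A)
    rng = np.random.default_rng(seed)
    null_draw = null.mean + np.sqrt(null.variance) * rng.standard_normal(A.shape)
    alt_draw = alt.mean + np.sqrt(alt.variance) * rng.standard_normal(A.shape)
    return ScoreMatrix(np.where(A == 1, alt_draw, null_draw))


def generate_scenario(config: ScenarioConfig) -> tuple[ScoreMatrix, LatentTruth]:
    """Generate (X, truth) for a named scenario.

    Scenario (a) samples the full noisy SBM; (b) and (c) build their fixed /
    preferential-attachment graphs and emit N(0,1) / N(alt_mean, alt_var)
    scores. Membership vectors for (b) mark the generalists as block 0; for
    (c) all vertices share one block (the graph is not block-structured).
    """
    if config.scenario == "a":
        return sample_noisysbm(config.n1, config.n2, scenario_a_params(), config.seed)
    null = gaussian(0.0, 1.0, n_free_params=0)
    alt = gaussian(config.alt_mean, config.alt_var)
    if config.scenario == "b":
        A = nested_graph(config.n1, config.n2)
        Z1 = np.r_[0, np.ones(config.n1 - 1, dtype=int)]
        Z2 = np.r_[0, np.ones(config.n2 - 1, dtype=int)]
    else:
        A, _ = pa_graph(
            config.n1, config.pa_lambda, config.degree_choices, seed=config.seed, n2=config.n2
        )
        Z1 = np.zeros(config.n1, dtype=int)
        Z2 = np.zeros(config.n2, dtype=int)
    X = scores_from_graph(A, null, alt, seed=config.seed + 1)
    return X, LatentTruth(A=A, Z1=Z1, Z2=Z2)
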