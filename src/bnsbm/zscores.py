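"""Differential cross-correlation z-scores from paired omics tables.

Given two data blocks measured on the same samples (e.g. taxa and
metabolites) and a two-level group label, each (feature-i, feature-j) pair
is scored by a z-statistic for the null of equal cross-correlation in the
two groups:

    x_ij = 2 (rho1_ij - rho2_ij) / sqrt(s1_ij / m1 + s2_ij / m2),

where rho_d is the within-group Pearson cross-correlation of the
column-standardized blocks (variance denominator m, so rho is a true
correlation) and s_d its asymptotic variance from the influence-function
expansion. The resulting matrix is the input to the block-model inference.

For compositional count data a modified centered log-ratio (mclr) transform
is provided: clr over the positive entries of each sample plus a global
positive shift, leaving zeros exactly at zero and preserving ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ScoreMatrix


@dataclass
class OmicsBlock:
    """A samples x features data block with identifiers."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("omics block must be 2-dimensional")
        m, n = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != m or len(self.feature_ids) != n:
            raise ValueError("identifier lengths do not match block shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def mclr(counts: OmicsBlock, eps: float = 1.0) -> OmicsBlock:
    """Modified centered log-ratio transform preserving zeros.

    Per sample, positive entries get ``log y - mean(log y over positive
    entries)``; all positive results are then shifted by
    ``|global minimum| + eps`` so they are strictly positive, and zero
    measurements remain exactly zero. The shift is computed globally over
    the block (not per sample) so the ordering across samples is preserved.
    """
    Y = counts.values
    if np.any(Y < 0):
        raise ValueError("mclr requires nonnegative counts")
    out = np.zeros_like(Y)
    for k in range(Y.shape[0]):
        pos = Y[k] > 0
        if not pos.any():
            raise ValueError(f"sample {counts.sample_ids[k]!r} has no positive entries")
        logs = np.log(Y[k, pos])
        out[k, pos] = logs - logs.mean()
    pos_mask = Y > 0
    shift = abs(out[pos_mask].min()) + eps
    out[pos_mask] += shift
    return OmicsBlock(out, counts.sample_ids, counts.feature_ids)


def standardize(Y: OmicsBlock) -> OmicsBlock:
    """Center and scale each column to mean 0 and variance 1 (denominator m).

    With the m-denominator, ``sum of squares = m`` per column, which makes
    the cross-correlation below a true correlation in [-1, 1].
    """
    V = Y.values
    mean = V.mean(axis=0)
    sd = V.std(axis=0)  # population (m) denominator
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant column(s): {[Y.feature_ids[j] for j in bad]}")
    return OmicsBlock((V - mean) / sd, Y.sample_ids, Y.feature_ids)


def _check_paired(Y1t: OmicsBlock, Y2t: OmicsBlock):
    if Y1t.sample_ids != Y2t.sample_ids:
        raise ValueError("paired blocks must share identical sample identifiers")


def cross_corr(Y1t: OmicsBlock, Y2t: OmicsBlock) -> np.ndarray:
    """Pearson cross-correlation matrix of two standardized blocks.

    ``rho_ij = m^-1 sum_k Y1t[k, i] Y2t[k, j]``; entries lie in [-1, 1]
    because both blocks are standardized with the m denominator.
    """
    _check_paired(Y1t, Y2t)
    m = Y1t.n_samples
    return Y1t.values.T @ Y2t.values / m


def corr_variance(
    Y1t: OmicsBlock, Y2t: OmicsBlock, rho_hat: np.ndarray, form: str = "squared"
) -> np.ndarray:
    """Asymptotic variance of the cross-correlation estimates.

    Default ``form="squared"`` uses the delta-method influence function with
    squared standardized terms,

        s_ij = m^-1 sum_k (2 a_k b_k - rho a_k^2 - rho b_k^2)^2,

    which is zero at perfect correlation as it must be. ``form="as_printed"``
    keeps the unsquared variant ``(2 a b - rho a - rho b)^2`` for textual
    fidelity with the formula some sources display; the two disagree (the
    unsquared form is nonzero at rho = 1) and the squared form is the
    default.
    """
    _check_paired(Y1t, Y2t)
    m = Y1t.n_samples
    a = Y1t.values[:, :, None]  # (m, n1, 1)
    b = Y2t.values[:, None, :]  # (m, 1, n2)
    r = np.asarray(rho_hat)[None, :, :]
    if form == "squared":
        infl = 2.0 * a * b - r * a**2 - r * b**2
    elif form == "as_printed":
        infl = 2.0 * a * b - r * a - r * b
    else:
        raise ValueError(f"unknown form {form!r}; use 'squared' or 'as_printed'")
    return np.einsum("kij,kij->ij", infl, infl) / m


def differential_z(
    Y1: OmicsBlock,
    Y2: OmicsBlock,
    groups: dict[str, str] | list[str],
    variance_form: str = "squared",
) -> ScoreMatrix:
    """Two-group differential cross-correlation z-score matrix.

    ``groups`` maps each sample id to one of exactly two labels (or is a
    per-sample label list in sample order); the lexicographically smaller
    label is group 1, so relabeling the two sample sets swaps the sign of
    every score. Within each group both blocks are standardized, the
    cross-correlation and its asymptotic variance computed, and the entries
    combined as ``2 (rho1 - rho2) / sqrt(s1/m1 + s2/m2)``. Pairs whose
    difference and variance both vanish (e.g. the two groups are copies of
    the same data) score exactly 0.
    """
    _check_paired(Y1, Y2)
    if isinstance(groups, dict):
        labels = np.array([groups[s] for s in Y1.sample_ids])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != Y1.n_samples:
            raise ValueError("group label list length does not match sample count")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two group labels required, got {uniq}")
    stats = []
    for g in uniq:
        idx = np.nonzero(labels == g)[0]
        if idx.size < 3:
            raise ValueError(f"group {g!r} has {idx.size} samples; need at least 3")
        b1 = standardize(OmicsBlock(Y1.values[idx], [Y1.sample_ids[i] for i in idx], Y1.feature_ids))
        b2 = standardize(OmicsBlock(Y2.values[idx], [Y2.sample_ids[i] for i in idx], Y2.feature_ids))
        rho = cross_corr(b1, b2)
        s = corr_variance(b1, b2, rho, form=variance_form)
        stats.append((rho, s, idx.size))
    (r1, s1, m1), (r2, s2, m2) = stats
    num = 2.0 * (r1 - r2)
    denom = np.sqrt(s1 / m1 + s2 / m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return ScoreMatrix(z, Y1.feature_ids, Y2.feature_ids)
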