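"""Floated (group-specific) variances for categorical exposures.

A fitted model reports log rate ratios relative to a reference level, so the
reference carries no interval and comparisons between two non-reference levels
need the full covariance matrix. Floating replaces the covariance matrix with
one variance per level -- the reference included -- chosen so that the
variance of any between-level contrast is approximately the sum of the two
levels' floated variances.

Here the floated variances solve a non-negative least-squares problem over all
pairwise contrast-variance equations

    f_i + f_j ~= Var(log RR_i - log RR_j)        for every unordered pair i, j,

which reproduces contrast variances exactly whenever an exact non-negative
solution exists (e.g. a diagonal covariance matrix, where the reference floats
at zero) and otherwise minimises the total squared reconstruction error. The
achieved worst-case relative distortion is always reported so users can see
when floating misleads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["FloatedVariances", "float_variances", "floated_ci"]


@dataclass(frozen=True)
class FloatedVariances:
    """Per-level variances (reference first) and the worst-case contrast distortion."""

    levels: tuple
    variances: np.ndarray
    max_contrast_distortion: float

    def variance_of(self, level) -> float:
        return float(self.variances[self.levels.index(level)])

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "variances": [float(v) for v in self.variances],
            "max_contrast_distortion": self.max_contrast_distortion,
        }


def _contrast_variances(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and target vector of the pairwise contrast equations.

    Level 0 is the reference; cov is the (K-1)x(K-1) covariance of the
    non-reference log rate ratios, so C_{0j} = V_jj and
    C_{ij} = V_ii + V_jj - 2 V_ij.
    """
    K = cov.shape[0] + 1
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    A = np.zeros((len(pairs), K))
    c = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        A[row, i] = A[row, j] = 1.0
        if i == 0:
            c[row] = cov[j - 1, j - 1]
        else:
            c[row] = cov[i - 1, i - 1] + cov[j - 1, j - 1] - 2.0 * cov[i - 1, j - 1]
    return A, c


def float_variances(cov: np.ndarray, levels=None) -> FloatedVariances:
    """Compute floated variances from the covariance of the non-reference log RRs.

    Parameters
    ----------
    cov
        (K-1) x (K-1) covariance matrix of the estimated log rate ratios
        against the reference level.
    levels
        Optional level names, reference first (length K). Defaults to integer
        indices 0..K-1.

    Notes
    -----
    With K = 2 the single equation f_0 + f_1 = Var(log RR) leaves the split
    undetermined; the minimum-norm (equal-split) solution is returned, and the
    reconstructed contrast variance is exact.
    """
    V = np.asarray(cov, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1] or V.shape[0] < 1:
        raise ValueError("cov must be a square matrix over at least one non-reference level")
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("cov must be symmetric")
    eig = np.linalg.eigvalsh((V + V.T) / 2.0)
    if eig.min() < -1e-10 * max(eig.max(), 1.0):
        raise ValueError("cov must be positive semi-definite")
    K = V.shape[0] + 1
    if levels is None:
        levels = tuple(range(K))
    levels = tuple(levels)
    if len(levels) != K:
        raise ValueError(f"expected {K} level names (reference first), got {len(levels)}")

    if K == 2:
        v = float(V[0, 0])
        f = np.array([v / 2.0, v / 2.0])
        return FloatedVariances(levels, f, 0.0)

    A, c = _contrast_variances(V)
    f, _ = optimize.nnls(A, c)
    recon = A @ f
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(recon - c) / c
    rel = rel[np.isfinite(rel)]
    distortion = float(rel.max()) if rel.size else 0.0
    return FloatedVariances(levels, f, distortion)


def floated_ci(beta: float, variance: float, z: float = 1.959963984540054
               ) -> tuple[float, float]:
    """Wald interval on the rate-ratio scale from a floated variance.

    The reference level uses ``beta = 0`` and still receives an interval.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    half = z * np.sqrt(variance)
    return float(np.exp(beta - half)), float(np.exp(beta + half))
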