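"""Entropy and disequilibrium-based statistical complexity of feature densities.

A spatial pattern is summarized by a discrete distribution ``P = {P_i}`` over
``N`` features (here: shearlet scale/orientation bands).  Shannon entropy in
bits measures how spread the distribution is; the Jensen-Shannon divergence to
the equiprobable distribution ``P_e`` measures how far it sits from maximal
disorder.  Statistical complexity is their product,

    C = Q_JS[P, P_e] * H_s[P],

which vanishes both for perfectly ordered (degenerate) and perfectly random
(uniform) distributions and peaks in between — the regime of structured
randomness that branching biological patterns occupy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "shannon_entropy",
    "normalized_entropy",
    "js_disequilibrium",
    "complexity",
    "js_max",
    "EntropyComplexityResult",
    "ECMap",
    "entropy_complexity",
    "map_entropy_complexity",
]

_NORM_TOL = 1e-9


def _validate(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 1:
        raise ValueError("P must be a 1-D probability vector")
    if np.any(P < 0):
        raise ValueError("probabilities must be non-negative")
    s = P.sum()
    if abs(s - 1.0) > _NORM_TOL:
        raise ValueError(f"probabilities must sum to 1 (got {s!r})")
    return P


def shannon_entropy(P: np.ndarray) -> float:
    """Shannon information entropy ``-sum P_i log2 P_i`` in bits, with 0*log0 = 0."""
    P = _validate(P)
    nz = P[P > 0]
    return float(-(nz * np.log2(nz)).sum())


def normalized_entropy(P: np.ndarray) -> float:
    """Entropy normalized by its maximum log2(N); lies in [0, 1]."""
    P = _validate(P)
    n = P.size
    if n < 2:
        raise ValueError("normalized entropy undefined for a single feature")
    return shannon_entropy(P) / np.log2(n)


def js_max(n: int) -> float:
    """Maximum Jensen-Shannon divergence to the uniform distribution over n features.

    Attained when a single feature carries all the mass.  Closed form from
    evaluating J at the degenerate distribution: the mixture has one entry
    (1 + 1/n)/2 and n-1 entries 1/(2n).
    """
    if n < 2:
        raise ValueError("need at least two features")
    hi = (1.0 + 1.0 / n) / 2.0
    lo = 1.0 / (2.0 * n)
    s_mix = -(hi * np.log2(hi) + (n - 1) * lo * np.log2(lo))
    return float(s_mix - 0.5 * np.log2(n))


def _js_divergence(P: np.ndarray) -> float:
    n = P.size
    Pe = np.full(n, 1.0 / n)
    M = 0.5 * (P + Pe)
    nz = M[M > 0]
    s_mix = float(-(nz * np.log2(nz)).sum())
    return s_mix - 0.5 * (shannon_entropy(P) + np.log2(n))


def js_disequilibrium(P: np.ndarray) -> float:
    """Normalized Jensen-Shannon divergence Q_JS = J[P, P_e] / J_max, in [0, 1]."""
    P = _validate(P)
    if P.size < 2:
        raise ValueError("need at least two features")
    return _js_divergence(P) / js_max(P.size)


def complexity(P: np.ndarray) -> float:
    """Statistical complexity C = Q_JS[P, P_e] * H_s[P]."""
    return js_disequilibrium(P) * normalized_entropy(P)


@dataclass
class EntropyComplexityResult:
    """Entropy/complexity summary of one feature distribution.

    Attributes
    ----------
    S : Shannon entropy, bits.
    H_s : normalized entropy S / log2(N), dimensionless in [0, 1].
    J : Jensen-Shannon divergence to the equiprobable distribution, bits.
    Q_JS : normalized divergence J / J_max, in [0, 1].
    C : statistical complexity Q_JS * H_s.
    N : feature count.
    S_max : entropy of the equiprobable distribution, log2(N) bits.
    """

    S: float
    H_s: float
    J: float
    Q_JS: float
    C: float
    N: int
    S_max: float


def entropy_complexity(P: np.ndarray) -> EntropyComplexityResult:
    """Compute the full entropy/complexity summary of a probability vector."""
    P = _validate(P)
    n = P.size
    if n < 2:
        raise ValueError("need at least two features")
    S = shannon_entropy(P)
    s_max = float(np.log2(n))
    J = _js_divergence(P)
    Q = J / js_max(n)
    Hs = S / s_max
    return EntropyComplexityResult(S=S, H_s=Hs, J=J, Q_JS=Q, C=Q * Hs, N=n, S_max=s_max)


@dataclass
class ECMap:
    """Per-pixel entropy and complexity maps with a masked summary."""

    entropy_map: np.ndarray
    complexity_map: np.ndarray
    cell_mask: np.ndarray
    summary: tuple[float, float] = field(default=(np.nan, np.nan))

    @property
    def mean_entropy(self) -> float:
        return self.summary[0]

    @property
    def mean_complexity(self) -> float:
        return self.summary[1]


def _maps_from_density(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pixel H_s and C from a (K, H, W) density array."""
    K = P.shape[0]
    logP = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    S = -(P * logP).sum(axis=0)
    s_max = np.log2(K)
    Hs = S / s_max

    Pe = 1.0 / K
    M = 0.5 * (P + Pe)
    S_mix = -(M * np.log2(M)).sum(axis=0)
    J = S_mix - 0.5 * (S + s_max)
    Q = J / js_max(K)
    # clip tiny negative round-off
    Hs = np.clip(Hs, 0.0, 1.0)
    Q = np.clip(Q, 0.0, 1.0)
    return Hs, Q * Hs


def map_entropy_complexity(
    image: np.ndarray,
    system,
    sigmas=None,
    cell_mask: np.ndarray | None = None,
    reduction: str = "mean",
) -> ECMap:
    """Map local normalized entropy and statistical complexity over an image.

    The image is decomposed with the given shearlet ``system``; squared
    coefficient magnitudes are smoothed with scale-dependent Gaussian kernels
    and normalized per pixel into a feature density, from which H_s and C are
    evaluated pixelwise.  ``summary`` is the reduction (mean by default,
    median optional) of each map over ``cell_mask``.
    """
    from .shearlet import transform, local_power_density

    image = np.asarray(image, dtype=float)
    if cell_mask is None:
        cell_mask = np.ones(image.shape, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not cell_mask.any():
        raise ValueError("empty cell mask")

    stack = transform(image, system)
    density = local_power_density(stack, sigmas)
    Hs, C = _maps_from_density(density.P)

    red = np.mean if reduction == "mean" else np.median
    summary = (float(red(Hs[cell_mask])), float(red(C[cell_mask])))
    return ECMap(entropy_map=Hs, complexity_map=C, cell_mask=cell_mask, summary=summary)
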