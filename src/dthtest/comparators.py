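"""Baseline dispersion-homogeneity tests to benchmark DTH against.

Two classical single-parameter tests are reimplemented here:

* :func:`betadisper_test` — the PERMDISP approach: embed the
  dissimilarity matrix by principal coordinates, measure each sample's
  distance to its group centroid (with the sign-split correction for
  non-Euclidean dissimilarities), and compare groups with a one-way
  ANOVA F whose significance is assessed by label permutation.  This
  mirrors the permutation test of vegan's ``betadisper`` but is an
  independent reimplementation, not a reproduction of that package.

* :func:`go_perm_test` — a permutation test on per-group mean squared
  within-group dissimilarity (the U-statistic form of the variance:
  for Euclidean distances, ``mean(phi^2)/2`` over a group's pairs equals
  the group's total sample variance).  Only the permutation variant is
  provided; the asymptotic-null variant is not implemented here.

Both comparators target differences in a *single* dispersion parameter
(mean spread); DTH targets the full distribution of within-group
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable

import numpy as np

from .dissimilarity import DistanceMatrix, GroupLabels
from .permutation_engine import make_replicates, permutation_pvalue, seed_sequence

__all__ = [
    "EmbeddingResult",
    "ComparatorResult",
    "pcoa_embed",
    "betadisper_test",
    "go_perm_test",
]

logger = logging.getLogger("dthtest")

#: eigenvalues with |lambda| below this fraction of max|lambda| are dropped
_EIG_RTOL = 1e-10


@dataclass(frozen=True)
class EmbeddingResult:
    """Principal-coordinates embedding of a dissimilarity matrix.

    ``coordinates`` has one column per retained eigenvalue, scaled by
    ``sqrt(|lambda|)``; ``eigenvalues`` is sorted descending, so positive
    (real) axes come first and negative (imaginary) axes — present only
    for non-Euclidean input — last.
    """

    coordinates: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray

    @property
    def positive_axes(self) -> np.ndarray:
        return self.coordinates[:, self.eigenvalues > 0]

    @property
    def negative_axes(self) -> np.ndarray:
        return self.coordinates[:, self.eigenvalues < 0]


@dataclass(frozen=True)
class ComparatorResult:
    """Observed statistic and permutation p-value of a comparator test."""

    statistic: float
    p_value: float
    method: str
    R: int
    seed: object
    scheme: str | None = None
    group_stats: dict[Hashable, float] | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "R": int(self.R),
            "seed": self.seed if isinstance(self.seed, (int, type(None))) else str(self.seed),
            "scheme": self.scheme,
            "group_stats": None if self.group_stats is None else
                {str(g): float(v) for g, v in self.group_stats.items()},
        }


def pcoa_embed(D: DistanceMatrix) -> EmbeddingResult:
    """Principal-coordinates (classical MDS) embedding.

    Eigendecomposes the Gower-centered matrix ``-1/2 J (D o D) J`` with
    ``J = I - 11'/n``.  For a Euclidean dissimilarity all eigenvalues
    are nonnegative and pairwise distances among the coordinates
    reproduce the input; non-Euclidean input (e.g. Bray-Curtis) yields
    negative eigenvalues whose axes are kept separately by sign.
    Near-zero eigenvalues (relative magnitude below 1e-10) are dropped.
    """
    n = D.n_samples
    if n < 3:
        raise ValueError("principal-coordinates embedding needs at least 3 samples")
    D2 = D.values ** 2
    # J A J computed by double-centering rows/columns
    row = D2.mean(axis=1, keepdims=True)
    A = -0.5 * (D2 - row - row.T + D2.mean())
    eigvals, eigvecs = np.linalg.eigh(A)
    order = np.argsort(eigvals)[::-1]  # descending: positive first
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = np.abs(eigvals) > _EIG_RTOL * np.max(np.abs(eigvals))
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    coords = eigvecs * np.sqrt(np.abs(eigvals))
    return EmbeddingResult(coordinates=coords, eigenvalues=eigvals)


def _centroid_distances(pos: np.ndarray, neg: np.ndarray, codes: np.ndarray,
                        G: int) -> np.ndarray:
    """Distance of each sample to its group centroid, sign-split corrected.

    Squared distance = (squared distance on positive axes) - (squared
    distance on negative axes), clamped at 0 before the square root.
    """
    z = np.empty(codes.size)
    for c in range(G):
        idx = np.flatnonzero(codes == c)
        dp = pos[idx] - pos[idx].mean(axis=0)
        d2 = np.einsum("ij,ij->i", dp, dp)
        if neg.shape[1]:
            dn = neg[idx] - neg[idx].mean(axis=0)
            d2 = d2 - np.einsum("ij,ij->i", dn, dn)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, G: int) -> float:
    """One-way ANOVA F of values ``z`` across integer-coded groups."""
    n = z.size
    grand = z.mean()
    ssb = 0.0
    ssw = 0.0
    for c in range(G):
        zg = z[codes == c]
        m = zg.mean()
        ssb += zg.size * (m - grand) ** 2
        ssw += np.sum((zg - m) ** 2)
    if ssw == 0.0:
        return 0.0 if ssb == 0.0 else np.inf
    return float((ssb / (G - 1)) / (ssw / (n - G)))


def betadisper_test(D: DistanceMatrix, labels: GroupLabels, R: int = 999,
                    seed=None) -> ComparatorResult:
    """Levene-style test on distances to group centroids after embedding.

    The statistic is the one-way ANOVA F on per-sample distances to the
    group centroid in principal-coordinates space (F directly on the
    centroid distances, as in betadisper's permutation test, rather than
    on absolute deviations).  Group labels are permuted and centroids,
    distances and F recomputed per permutation;
    ``p = (1 + #{F_r > F_0})/(R + 1)``.
    """
    if len(labels) != D.n_samples:
        raise ValueError("labels length does not match distance matrix size")
    labels.require_min_size(2)
    if R < 1:
        raise ValueError("R must be >= 1")
    logger.info("betadisper_test: G=%d, R=%d, seed=%s (ANOVA F on centroid distances)",
                labels.n_groups, R, seed)

    emb = pcoa_embed(D)
    pos, neg = emb.positive_axes, emb.negative_axes
    codes, G = labels.codes, labels.n_groups

    z0 = _centroid_distances(pos, neg, codes, G)
    F0 = _anova_f(z0, codes, G)

    children = seed_sequence(seed).spawn(R)
    Fr = np.empty(R)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(codes)
        Fr[r] = _anova_f(_centroid_distances(pos, neg, perm, G), perm, G)

    zbar = {g: float(z0[codes == i].mean()) for i, g in enumerate(labels.groups)}
    return ComparatorResult(statistic=F0, p_value=permutation_pvalue(F0, Fr),
                            method="betadisper", R=R, seed=seed,
                            group_stats=zbar)


def _go_statistic(group_vals: list[np.ndarray], sizes: np.ndarray) -> float:
    """Between-group spread of per-group U-statistic dispersions.

    ``Vhat_g = mean over Phi_g of phi^2 / 2``; the statistic is
    ``sum_g n_g (Vhat_g - Vbar)^2`` with the size-weighted mean ``Vbar``.
    (Any positive rescaling of ``Vhat`` cancels in the permutation
    p-value.)
    """
    V = np.array([0.5 * np.mean(v * v) for v in group_vals])
    Vbar = float(np.dot(sizes, V) / sizes.sum())
    return float(np.dot(sizes, (V - Vbar) ** 2))


def go_perm_test(D: DistanceMatrix, labels: GroupLabels, R: int = 999,
                 scheme: str = "labels", seed=None) -> ComparatorResult:
    """Permutation test on per-group mean squared within-group dissimilarity.

    Dispersion of group ``g`` is ``Vhat_g``, the mean of
    ``phi_ij^2 / 2`` over its within-group pairs (for Euclidean
    distances this is the group's total sample variance).  The statistic
    is the size-weighted between-group sum of squares of the ``Vhat_g``,
    and significance comes from the shared replicate engine
    (``p = (1 + #{T_r > T_0})/(R + 1)``).
    """
    if len(labels) != D.n_samples:
        raise ValueError("labels length does not match distance matrix size")
    labels.require_min_size(2)
    if R < 1:
        raise ValueError("R must be >= 1")
    logger.info("go_perm_test: G=%d, R=%d, scheme=%s, seed=%s",
                labels.n_groups, R, scheme, seed)

    groups = labels.groups
    sizes = np.array([labels.group_sizes[g] for g in groups], dtype=float)

    originals = []
    for i, g in enumerate(groups):
        idx = np.flatnonzero(labels.codes == i)
        originals.append(D.values[np.ix_(idx, idx)][np.triu_indices(idx.size, k=1)])
    T0 = _go_statistic(originals, sizes)

    stream = make_replicates(D, labels, R, scheme=scheme, seed=seed)
    Tr = np.array([_go_statistic([fam[g] for g in groups], sizes) for fam in stream])

    V = {g: float(0.5 * np.mean(v * v)) for g, v in zip(groups, originals)}
    return ComparatorResult(statistic=T0, p_value=permutation_pvalue(T0, Tr),
                            method="go_perm", R=R, seed=seed, scheme=scheme,
                            group_stats=V)
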