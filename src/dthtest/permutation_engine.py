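"""Null replicate generation and p-value machinery for permutation tests.

Within-group distances are mutually dependent (each sample contributes to
``n_g - 1`` of them), so null distributions are obtained by resampling at
the level of the distance matrix rather than from asymptotics.  Two
schemes generate replicate within-group distance sets with homogeneous
dispersion:

``labels``
    Uniformly permute the group labels over the samples and re-extract
    the within-group sets from the fixed distance matrix.  This
    preserves the dependence structure among distances and is exact
    whenever the samples are exchangeable under the null (identical
    group distributions).  Default.

``pooled``
    Pool the original within-group distance multisets and randomly
    partition the pooled values back into sets of the original
    cardinalities.  Between-group distances are never touched, making
    this a location-robust option when group centroids may differ.

Replicates are generated from per-replicate RNG substreams spawned
deterministically from the master seed, so results are bit-identical
whether replicates are computed sequentially or concurrently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import numpy as np
from scipy.stats import rankdata

from .dissimilarity import DistanceMatrix, GroupLabels

__all__ = [
    "SCHEMES",
    "ReplicateStream",
    "make_replicates",
    "permutation_pvalue",
    "replicate_pvalues",
]

SCHEMES = ("labels", "pooled")


def seed_sequence(seed) -> np.random.SeedSequence:
    """Normalize ``None | int | SeedSequence`` to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class ReplicateStream:
    """``R`` families of null within-group distance sets.

    ``replicates[r]`` maps each group id to a sorted 1-D array with the
    original cardinality ``n_g (n_g - 1) / 2``.
    """

    R: int
    scheme: str
    seed: object
    groups: tuple[Hashable, ...]
    replicates: list[dict[Hashable, np.ndarray]] = field(repr=False)

    def __len__(self) -> int:
        return self.R

    def __iter__(self):
        return iter(self.replicates)


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = np.triu_indices(n, k=1)
    return _TRIU_CACHE[n]


def _extract_sets(D: np.ndarray, codes: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Sorted within-group distance arrays for integer-coded labels."""
    out = []
    for c in range(n_groups):
        idx = np.flatnonzero(codes == c)
        iu, ju = _triu(idx.size)
        vals = D[idx[:, None], idx[None, :]][iu, ju]
        vals.sort()
        out.append(vals)
    return out


def make_replicates(
    D: DistanceMatrix,
    labels: GroupLabels,
    R: int,
    scheme: str = "labels",
    seed=None,
) -> ReplicateStream:
    """Generate ``R`` replicate families of null within-group distance sets.

    Parameters
    ----------
    D : DistanceMatrix
    labels : GroupLabels
        Every group must have at least 2 members.
    R : int
        Number of replicates, >= 1.
    scheme : {'labels', 'pooled'}
    seed : None, int or numpy.random.SeedSequence
        Master seed; identical seeds yield identical streams.

    Returns
    -------
    ReplicateStream
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if R < 1:
        raise ValueError("R must be >= 1")
    if len(labels) != D.n_samples:
        raise ValueError("labels length does not match distance matrix size")
    labels.require_min_size(2)

    groups = labels.groups
    G = len(groups)
    codes = labels.codes
    children = seed_sequence(seed).spawn(R)
    Dv = D.values

    replicates: list[dict[Hashable, np.ndarray]] = []
    if scheme == "labels":
        for child in children:
            rng = np.random.default_rng(child)
            perm_codes = rng.permutation(codes)
            sets = _extract_sets(Dv, perm_codes, G)
            replicates.append(dict(zip(groups, sets)))
    else:  # pooled
        originals = _extract_sets(Dv, codes, G)
        pooled = np.concatenate(originals)
        bounds = np.cumsum([v.size for v in originals])[:-1]
        for child in children:
            rng = np.random.default_rng(child)
            shuffled = pooled[rng.permutation(pooled.size)]
            parts = [np.sort(p) for p in np.split(shuffled, bounds)]
            replicates.append(dict(zip(groups, parts)))
    return ReplicateStream(R=R, scheme=scheme, seed=seed, groups=groups,
                           replicates=replicates)


def permutation_pvalue(T0: float, Treps) -> float:
    """Permutation p-value ``(1 + #{r : T_r > T0}) / (R + 1)``.

    The strict inequality and the "+1" (the observed statistic counts as
    one replicate) guarantee ``p in [1/(R+1), 1]`` and validity under
    exchangeability.
    """
    T = np.asarray(Treps, dtype=float).ravel()
    if T.size == 0:
        raise ValueError("empty replicate list")
    return float((1 + np.count_nonzero(T > T0)) / (T.size + 1))


def replicate_pvalues(Treps) -> np.ndarray:
    """Rank-based p-values for the null replicates themselves.

    ``p_r = rank(-T_r) / R``: the largest statistic gets ``1/R``, the
    smallest gets 1.  Each replicate is compared only to the other
    replicates, hence the denominator ``R``.  Ties receive the maximum
    rank within the tied block (the conservative choice; with continuous
    distances ties have probability ~0).
    """
    T = np.asarray(Treps, dtype=float).ravel()
    if T.size == 0:
        raise ValueError("empty replicate list")
    return rankdata(-T, method="max") / T.size
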