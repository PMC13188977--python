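"""Pairwise dissimilarities and the distribution of within-group distances.

A group's *dispersion* is characterized here not by a single scalar (such
as the mean distance to a centroid) but by the full multiset of its
within-group pairwise dissimilarities

    Phi_g = {phi_ij : g_i = g_j = g, i < j},

whose mean empirical CDF

    Fbar_g(z) = 2 / (n_g (n_g - 1)) * #{(i < j) in group g : phi_ij <= z}

is the proportion of same-group sample pairs lying within distance ``z``
of one another.  Equality of these distance distributions across groups
is the null hypothesis of the homogeneity test in :mod:`dthtest.dth`.

This module provides the containers (:class:`FeatureTable`,
:class:`GroupLabels`, :class:`DistanceMatrix`, :class:`WithinGroupSet`,
:class:`EmpiricalDistanceCDF`) and the three operations that build them:
:func:`pairwise_dissimilarity`, :func:`within_group_set` and
:func:`mean_ecdf`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "METRICS",
    "FeatureTable",
    "GroupLabels",
    "DistanceMatrix",
    "WithinGroupSet",
    "EmpiricalDistanceCDF",
    "pairwise_dissimilarity",
    "within_group_set",
    "mean_ecdf",
]

#: Dissimilarity measures understood by :func:`pairwise_dissimilarity`.
METRICS = ("euclidean", "braycurtis", "jaccard")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTable:
    """A samples x features data matrix.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        One row per sample, one column per feature (counts or continuous
        measurements).  Must be finite with no missing entries.
    sample_ids : sequence of str
        Unique identifiers for the ``n`` samples (rows).
    feature_ids : sequence of str
        Unique identifiers for the ``d`` features (columns).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __init__(self, values, sample_ids=None, feature_ids=None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("feature table must be a 2-D samples x features matrix")
        n, d = values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if d < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing/non-finite entry at sample index {i}, feature index {j}"
            )
        if sample_ids is None:
            sample_ids = tuple(f"s{i + 1}" for i in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
        if feature_ids is None:
            feature_ids = tuple(f"f{j + 1}" for j in range(d))
        else:
            feature_ids = tuple(str(f) for f in feature_ids)
        if len(sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(feature_ids) != d:
            raise ValueError("feature_ids length does not match number of columns")
        if len(set(sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(feature_ids)) != d:
            raise ValueError("feature ids must be unique")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


class GroupLabels:
    """Assignment of each sample to one of ``G >= 2`` groups.

    Group identity is preserved as given (strings, ints, ...); groups are
    ordered by first appearance.  Integer codes are kept alongside for
    fast vectorized extraction.
    """

    def __init__(self, labels: Sequence[Hashable]):
        labels = list(labels)
        if len(labels) < 2:
            raise ValueError("need at least 2 labelled samples")
        order: dict[Hashable, int] = {}
        for lab in labels:
            if lab not in order:
                order[lab] = len(order)
        if len(order) < 2:
            raise ValueError("need at least 2 distinct groups")
        self._labels = labels
        self.groups: tuple[Hashable, ...] = tuple(order)
        self.codes: np.ndarray = np.fromiter(
            (order[lab] for lab in labels), dtype=np.intp, count=len(labels)
        )
        self.group_sizes: dict[Hashable, int] = {
            g: int(np.sum(self.codes == i)) for i, g in enumerate(self.groups)
        }

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self):
        return iter(self._labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupLabels) and self._labels == other._labels

    @property
    def labels(self) -> list[Hashable]:
        return list(self._labels)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def indices(self, g: Hashable) -> np.ndarray:
        """Positions of the samples belonging to group ``g``."""
        if g not in self.group_sizes:
            raise KeyError(f"unknown group {g!r}")
        return np.flatnonzero(self.codes == self.groups.index(g))

    def require_min_size(self, k: int = 2) -> None:
        for g, ng in self.group_sizes.items():
            if ng < k:
                raise ValueError(
                    f"group {g!r} has {ng} sample(s); at least {k} are required"
                )


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, hollow (zero-diagonal), nonnegative dissimilarity matrix."""

    values: np.ndarray
    sample_ids: tuple[str, ...]

    def __init__(self, values, sample_ids=None):
        values = np.array(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        n = values.shape[0]
        if n < 2:
            raise ValueError("distance matrix must have at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix contains non-finite entries")
        asym = np.max(np.abs(values - values.T)) if n else 0.0
        if asym > 1e-12:
            raise ValueError(
                f"matrix is not symmetric (max |D - D.T| = {asym:.3g}); "
                "use dthtest.io.read_distance_matrix to symmetrize near-symmetric input"
            )
        # mirror the upper triangle for bit-exact symmetry
        values = np.triu(values, 1)
        values = values + values.T
        if np.any(values < 0):
            raise ValueError("distance matrix contains negative entries")
        if sample_ids is None:
            sample_ids = tuple(f"s{i + 1}" for i in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
        if len(sample_ids) != n or len(set(sample_ids)) != n:
            raise ValueError("sample_ids must be unique and match the matrix size")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """Strict upper triangle in scipy's condensed (pdist) order."""
        return squareform(self.values, checks=False)


@dataclass(frozen=True)
class WithinGroupSet:
    """The multiset ``Phi_g`` of within-group dissimilarities of one group.

    ``distances`` holds all ``n_g (n_g - 1) / 2`` strict-upper-triangle
    entries among the members of ``group``, stored sorted ascending
    (multiset semantics; order carries no information).
    """

    group: Hashable
    distances: np.ndarray = field(repr=False)

    def __init__(self, group, distances):
        distances = np.sort(np.asarray(distances, dtype=float).ravel())
        if distances.size == 0:
            raise ValueError("within-group distance set must be nonempty")
        if np.any(distances < 0) or not np.all(np.isfinite(distances)):
            raise ValueError("within-group distances must be finite and nonnegative")
        distances.setflags(write=False)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "distances", distances)

    def __len__(self) -> int:
        return self.distances.size


@dataclass(frozen=True)
class EmpiricalDistanceCDF:
    """The step function ``Fbar_g(z)``: fraction of within-group distances <= z."""

    jump_points: np.ndarray
    cumulative_fractions: np.ndarray

    def __call__(self, z) -> np.ndarray | float:
        """Evaluate ``Fbar_g`` at ``z`` (right-continuous, weak inequality)."""
        idx = np.searchsorted(self.jump_points, np.asarray(z, dtype=float), side="right")
        vals = np.concatenate([[0.0], self.cumulative_fractions])[idx]
        return float(vals) if np.isscalar(z) or np.ndim(z) == 0 else vals


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def pairwise_dissimilarity(table: FeatureTable, metric: str = "braycurtis") -> DistanceMatrix:
    """Compute the pairwise dissimilarity matrix of a feature table.

    Parameters
    ----------
    table : FeatureTable
    metric : {'euclidean', 'braycurtis', 'jaccard'}
        ``braycurtis``: ``sum|x - y| / sum(x + y)`` on nonnegative
        abundances.  ``jaccard``: binary (presence/absence, presence
        meaning value > 0) dissimilarity ``1 - shared/union``.

    Returns
    -------
    DistanceMatrix

    Raises
    ------
    ValueError
        For an unknown metric, or — under braycurtis/jaccard — for
        negative entries or an all-zero sample (for which these measures
        are undefined).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = table.values
    if metric in ("braycurtis", "jaccard"):
        if np.any(X < 0):
            i, j = np.argwhere(X < 0)[0]
            raise ValueError(
                f"{metric} requires nonnegative values; sample "
                f"{table.sample_ids[i]!r} has a negative entry in feature "
                f"{table.feature_ids[j]!r}"
            )
        zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
        if zero_rows.size:
            bad = ", ".join(repr(table.sample_ids[i]) for i in zero_rows[:5])
            raise ValueError(
                f"{metric} is undefined for all-zero samples: {bad}"
            )
    if metric == "jaccard":
        condensed = pdist(X > 0, metric="jaccard")
    else:
        condensed = pdist(X, metric=metric)
    return DistanceMatrix(squareform(condensed), table.sample_ids)


def within_group_set(D: DistanceMatrix, labels: GroupLabels, g: Hashable) -> WithinGroupSet:
    """Extract ``Phi_g``, the multiset of distances among members of group ``g``."""
    if len(labels) != D.n_samples:
        raise ValueError("labels length does not match distance matrix size")
    idx = labels.indices(g)
    if idx.size < 2:
        raise ValueError(
            f"group {g!r} too small to define within-group distances "
            f"(n_g = {idx.size} < 2)"
        )
    sub = D.values[np.ix_(idx, idx)]
    return WithinGroupSet(g, sub[np.triu_indices(idx.size, k=1)])


def mean_ecdf(S: WithinGroupSet) -> EmpiricalDistanceCDF:
    """Build ``Fbar_g``, the mean empirical CDF of a within-group distance set.

    Averaging the per-sample CDFs ``F_ig`` over the group's members is
    identical to pooling: each unordered within-group pair (i, j) appears
    in exactly two of the ``n_g`` per-sample counts, so the average
    equals ``#{pairs with phi_ij <= z} / (n_g (n_g - 1) / 2)``.
    """
    vals = S.distances  # already sorted
    jumps, counts = np.unique(vals, return_counts=True)
    fractions = np.cumsum(counts) / vals.size
    fractions[-1] = 1.0  # exact by construction (integer count / total)
    return EmpiricalDistanceCDF(jumps, fractions)
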