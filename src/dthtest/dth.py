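"""The distance-based test of homogeneity of multivariate dispersions (DTH).

The test asks whether the *distribution* of within-group pairwise
dissimilarities is the same in every group — a broader null than
equality of mean dispersions, so it is sensitive to groups that match in
mean spread but differ in the shape or tails of their distance
distributions.

Workflow, for groups ``1..G``, ``R`` permutations and a dissimilarity
matrix ``Phi``:

1. Extract the within-group distance multisets ``Phi_g``.
2. For each pair (g, g'), compute the observed Kolmogorov-Smirnov and
   1-Wasserstein statistics ``K0``, ``W0`` between the mean ECDFs.
3. Generate ``R`` replicate families ``{Phi_g^(r)}`` from one shared
   replicate stream and compute ``K_r``, ``W_r`` for every pair inside
   the same replicate loop.
4. Per pair: permutation p-values ``p0K = (1 + #{K_r > K0})/(R+1)`` (and
   ``p0W`` likewise); rank-based replicate p-values
   ``prK = rank(-K_r)/R``, ``prW = rank(-W_r)/R``.
5. Omnibus statistic ``m_r = 1 - min(pK_r, pW_r)`` for ``r = 0..R``
   (r = 0 uses the observed p-values); larger ``m`` means more evidence
   against homogeneity.
6. If ``G = 2`` the test p-value is ``(1 + #{m_r > m_0})/(R+1)``.
   Otherwise the pairwise omnibus p-values are combined with Fisher's
   statistic ``f_r = -sum_{g<g'} ln p_r^m(g,g')`` and the final p-value
   is ``(1 + #{f_r > f_0})/(R+1)``.

A continuous covariate is handled by quantile-discretizing it into
groups first (:func:`discretize_covariate`).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping

import numpy as np
from scipy.stats import rankdata

from .dissimilarity import (
    DistanceMatrix,
    FeatureTable,
    GroupLabels,
    pairwise_dissimilarity,
)
from .divergence import ks_and_wasserstein
from .permutation_engine import (
    _extract_sets as _sorted_within_sets,
    make_replicates,
    permutation_pvalue,
    replicate_pvalues,
)

__all__ = [
    "DTHResult",
    "omnibus_m",
    "fisher_statistic",
    "dth_test",
    "dth_test_from_table",
    "discretize_covariate",
]

logger = logging.getLogger("dthtest")

Pair = tuple[Hashable, Hashable]


@dataclass(frozen=True)
class DTHResult:
    """Full output of one DTH run.

    Per-pair dictionaries are keyed by group-id pairs ``(g, g')`` in
    first-appearance order.  ``fisher_f0`` is ``None`` on the dedicated
    two-group path.
    """

    p_value: float
    K0: dict[Pair, float]
    W0: dict[Pair, float]
    p0K: dict[Pair, float]
    p0W: dict[Pair, float]
    m0: dict[Pair, float]
    p0m: dict[Pair, float]
    fisher_f0: float | None
    R: int
    scheme: str
    seed: object
    metric: str | None
    groups: tuple[Hashable, ...]
    group_sizes: dict[Hashable, int]
    #: replicate omnibus values m_r per pair, kept only on request
    m_replicates: dict[Pair, np.ndarray] | None = None

    @property
    def pairs(self) -> list[Pair]:
        return list(self.K0)

    def to_dict(self) -> dict:
        """JSON-serializable summary (all fields, pairs flattened to strings)."""

        def flat(d: Mapping[Pair, float]) -> dict[str, float]:
            return {f"{a}|{b}": float(v) for (a, b), v in d.items()}

        return {
            "method": "dth",
            "p_value": float(self.p_value),
            "per_pair": {
                "K0": flat(self.K0),
                "W0": flat(self.W0),
                "p0K": flat(self.p0K),
                "p0W": flat(self.p0W),
                "m0": flat(self.m0),
                "p0m": flat(self.p0m),
            },
            "fisher_f0": None if self.fisher_f0 is None else float(self.fisher_f0),
            "R": int(self.R),
            "scheme": self.scheme,
            "seed": self.seed if isinstance(self.seed, (int, type(None))) else str(self.seed),
            "metric": self.metric,
            "groups": [str(g) for g in self.groups],
            "group_sizes": {str(g): int(n) for g, n in self.group_sizes.items()},
        }


def omnibus_m(pK: float, pW: float) -> float:
    """Omnibus combination ``m = 1 - min(pK, pW)`` of the two p-values.

    Monotone decreasing in each argument: smaller p-values (stronger
    evidence from either statistic) give larger ``m``.
    """
    for name, p in (("pK", pK), ("pW", pW)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {p}")
    return 1.0 - min(pK, pW)


def fisher_statistic(pmap) -> float:
    """Fisher combination ``f = -sum ln p`` over pairwise p-values.

    Accepts a mapping keyed by group pairs or a plain iterable of
    p-values, each in (0, 1] (the +1 permutation p-value convention
    guarantees p > 0).
    """
    ps = list(pmap.values()) if isinstance(pmap, Mapping) else list(pmap)
    if not ps:
        raise ValueError("no p-values to combine")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    return float(-np.sum(np.log(ps)))




def dth_test(
    D: DistanceMatrix,
    labels: GroupLabels,
    R: int = 999,
    scheme: str = "labels",
    seed=None,
    metric: str | None = None,
    force_fisher: bool = False,
    keep_replicates: bool = False,
) -> DTHResult:
    """Run the DTH permutation test on a precomputed dissimilarity matrix.

    Parameters
    ----------
    D : DistanceMatrix
    labels : GroupLabels
        ``G >= 2`` groups, each with at least 2 members.
    R : int
        Number of permutation replicates (p-value resolution is
        ``1/(R+1)``).
    scheme : {'labels', 'pooled'}
        Replicate-generation scheme (see
        :mod:`dthtest.permutation_engine`).
    seed : None, int or numpy.random.SeedSequence
        Identical seeds give bit-identical results.
    metric : str, optional
        Recorded in the result for provenance (set automatically by
        :func:`dth_test_from_table`).
    force_fisher : bool
        Run the multi-group Fisher-combination path even for ``G = 2``
        (consistency check; gives the same p-value as the dedicated
        two-group path whenever that p-value is below 1 — at the
        boundary the rank scale ``/R`` and permutation scale ``/(R+1)``
        disagree).
    keep_replicates : bool
        Store the per-pair replicate omnibus values ``m_r`` on the
        result (diagnostics; off by default to keep results small).

    Returns
    -------
    DTHResult
    """
    if len(labels) != D.n_samples:
        raise ValueError("labels length does not match distance matrix size")
    labels.require_min_size(2)
    if R < 1:
        raise ValueError("R must be >= 1")

    groups = labels.groups
    G = len(groups)
    pairs: list[Pair] = list(combinations(groups, 2))
    logger.info(
        "dth_test: G=%d groups %s, R=%d, scheme=%s, seed=%s, metric=%s",
        G, dict(labels.group_sizes), R, scheme, seed, metric,
    )

    sets0 = _sorted_within_sets(D.values, labels.codes, G)
    gindex = {g: i for i, g in enumerate(groups)}

    K0: dict[Pair, float] = {}
    W0: dict[Pair, float] = {}
    for a, b in pairs:
        K0[(a, b)], W0[(a, b)] = ks_and_wasserstein(sets0[gindex[a]], sets0[gindex[b]])

    stream = make_replicates(D, labels, R, scheme=scheme, seed=seed)
    P = len(pairs)
    Kr = np.empty((P, R))
    Wr = np.empty((P, R))
    for r, family in enumerate(stream):
        for p_i, (a, b) in enumerate(pairs):
            Kr[p_i, r], Wr[p_i, r] = ks_and_wasserstein(family[a], family[b])

    # all distances identical: every statistic is 0 and no ordering exists
    if max(max(K0.values()), max(W0.values()), Kr.max(initial=0.0), Wr.max(initial=0.0)) == 0.0:
        warnings.warn(
            "all within-group distance statistics are zero (degenerate "
            "distance matrix); returning p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        ones = {p: 1.0 for p in pairs}
        return DTHResult(
            p_value=1.0, K0=K0, W0=W0, p0K=ones, p0W=dict(ones), m0={p: 0.0 for p in pairs},
            p0m=dict(ones), fisher_f0=0.0 if (G > 2 or force_fisher) else None,
            R=R, scheme=scheme, seed=seed, metric=metric,
            groups=groups, group_sizes=dict(labels.group_sizes),
        )

    p0K = {p: permutation_pvalue(K0[p], Kr[i]) for i, p in enumerate(pairs)}
    p0W = {p: permutation_pvalue(W0[p], Wr[i]) for i, p in enumerate(pairs)}
    prK = np.vstack([replicate_pvalues(Kr[i]) for i in range(P)])
    prW = np.vstack([replicate_pvalues(Wr[i]) for i in range(P)])

    m0 = {p: omnibus_m(p0K[p], p0W[p]) for p in pairs}
    mr = 1.0 - np.minimum(prK, prW)  # (P, R)

    if G == 2 and not force_fisher:
        pair = pairs[0]
        p_final = float((1 + np.count_nonzero(mr[0] > m0[pair])) / (R + 1))
        p0m = {pair: p_final}
        f0 = None
    else:
        p0m = {
            p: float((1 + np.count_nonzero(mr[i] > m0[p])) / (R + 1))
            for i, p in enumerate(pairs)
        }
        prm = rankdata(-mr, method="max", axis=1) / R  # (P, R)
        f0 = fisher_statistic(p0m)
        fr = -np.log(prm).sum(axis=0)  # (R,)
        p_final = float((1 + np.count_nonzero(fr > f0)) / (R + 1))

    return DTHResult(
        p_value=p_final, K0=K0, W0=W0, p0K=p0K, p0W=p0W, m0=m0, p0m=p0m,
        fisher_f0=f0, R=R, scheme=scheme, seed=seed, metric=metric,
        groups=groups, group_sizes=dict(labels.group_sizes),
        m_replicates={p: mr[i] for i, p in enumerate(pairs)}
        if keep_replicates else None,
    )


def dth_test_from_table(
    table: FeatureTable,
    labels: GroupLabels,
    metric: str = "braycurtis",
    R: int = 999,
    scheme: str = "labels",
    seed=None,
    force_fisher: bool = False,
) -> DTHResult:
    """Compute a dissimilarity matrix from a feature table, then run DTH."""
    D = pairwise_dissimilarity(table, metric=metric)
    return dth_test(D, labels, R=R, scheme=scheme, seed=seed, metric=metric,
                    force_fisher=force_fisher)


def discretize_covariate(x, bins: int = 3) -> GroupLabels:
    """Quantile-bin a continuous covariate into near-equal-size groups.

    Bin edges are the ``k/bins`` quantiles; values equal to an edge go to
    the lower bin.  Every resulting group must contain at least 2
    samples, otherwise an error suggests using fewer bins.

    Parameters
    ----------
    x : array-like of shape (n,)
    bins : int >= 2

    Returns
    -------
    GroupLabels
        Labels ``'bin1' .. 'bin<bins>'`` ordered by covariate value.
    """
    x = np.asarray(x, dtype=float).ravel()
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if x.size < 2 * bins:
        raise ValueError(
            f"need at least {2 * bins} samples for {bins} bins of >= 2 "
            f"samples each; got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains missing/non-finite values")
    edges = np.quantile(x, [k / bins for k in range(1, bins)])
    codes = np.searchsorted(edges, x, side="left")  # ties -> lower bin
    sizes = np.bincount(codes, minlength=bins)
    if np.any(sizes < 2):
        distinct = np.unique(x).size
        raise ValueError(
            f"quantile binning into {bins} groups leaves a group with < 2 "
            f"samples (sizes {sizes.tolist()}, {distinct} distinct value(s)); "
            "try fewer bins"
        )
    ndigits = int(math.log10(bins)) + 1
    return GroupLabels([f"bin{c + 1:0{ndigits}d}" if bins > 9 else f"bin{c + 1}"
                        for c in codes])
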