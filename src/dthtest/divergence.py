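"""Kolmogorov-Smirnov and 1-Wasserstein distances between distance ECDFs.

Both statistics compare the mean empirical CDFs of two within-group
distance multisets.  The KS distance ``sup_z |FA(z) - FB(z)|`` is
sensitive to location-scale differences; the 1-Wasserstein distance
``integral |FA(z) - FB(z)| dz`` is sensitive to tail and outlier
differences.  The two multisets almost always have unequal cardinalities
(``n_g (n_g - 1) / 2`` differs across groups), so both statistics are
evaluated exactly on the merged piecewise-constant step functions —
never by subsampling.

Only statistics are returned: the within-group distances are mutually
dependent, so the classical asymptotic null distributions of these
statistics do not apply.  Significance is assessed by permutation in
:mod:`dthtest.permutation_engine`.
"""

from __future__ import annotations

import numpy as np

from .dissimilarity import WithinGroupSet

__all__ = ["ks_statistic", "wasserstein1", "ks_and_wasserstein"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, WithinGroupSet):
        return x.distances
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty distance set")
    return arr


def ks_and_wasserstein(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Both statistics in one pass over the merged support.

    ``a`` and ``b`` are 1-D value arrays (any order).  Each pooled value
    carries a signed ECDF weight (+1/|A| for members of A, -1/|B| for
    members of B); after a stable sort of the pooled values, the running
    sum of those weights is exactly ``FA(z) - FB(z)`` at every merged
    point.  The ECDF difference is a step function that can only change
    at pooled values, so its maximum over those points is the supremum,
    and its width-weighted sum is the integral (duplicated pooled values
    contribute zero width).
    """
    m, n = a.size, b.size
    if m == 0 or n == 0:
        raise ValueError("empty distance set")
    z = np.concatenate([a, b])
    w = np.empty(m + n)
    w[:m] = 1.0 / m
    w[m:] = -1.0 / n
    order = np.argsort(z, kind="stable")
    zs = z[order]
    diff = np.abs(np.cumsum(w[order]))
    # running sums inside a block of tied pooled values are not ECDF
    # evaluations; only each block's last entry is
    widths = np.diff(zs)
    if zs[0] == zs[-1]:
        return 0.0, 0.0
    block_end = np.append(widths > 0, True)
    K = float(diff[block_end].max())
    W = float(np.dot(diff[:-1], widths))
    return K, W


def ks_statistic(A, B) -> float:
    """Kolmogorov-Smirnov distance between the ECDFs of two distance multisets.

    Parameters
    ----------
    A, B : WithinGroupSet or array-like
        Nonempty multisets of distances.

    Returns
    -------
    float in [0, 1]
    """
    return ks_and_wasserstein(_as_array(A), _as_array(B))[0]


def wasserstein1(A, B) -> float:
    """1-Wasserstein distance between the ECDFs of two distance multisets.

    Computed exactly as the integral of the absolute ECDF difference over
    the merged step functions; for equal cardinalities this reduces to
    the mean absolute difference of the sorted values (quantile
    matching).

    Returns
    -------
    float >= 0
    """
    return ks_and_wasserstein(_as_array(A), _as_array(B))[1]
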