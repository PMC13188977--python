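"""Synthetic benchmark generators and the empirical size/power study driver.

Two families of multi-group datasets with identical group locations but
group-specific *dispersion distributions* are provided, matching the
benchmark conditions under which DTH and the comparator tests are
evaluated:

**Normal scale mixtures** (:func:`simulate_normal`).  Each sample ``i``
in group ``g`` draws a dispersion ``v_i`` from a group-specific mixing
distribution and then ``Y_i ~ N_d(0, v_i I_d)``.  Four scenarios grade
from ones only a distribution-level test can detect to ones any
mean-dispersion test detects:

* ``S0`` — ``v_i ~ Gamma(alpha_g, kappa_g)`` with ``kappa_g`` chosen by
  :func:`gamma_kappa` so the *expected within-group Euclidean distance*
  is identical across groups (mean-distance tests should have
  negligible power).
* ``S1`` — ``v_i ~ LogNormal(mu_g, sigma_g^2)`` with
  ``mu_g + sigma_g^2/2 = 3/2`` for every ``g``, so the mean dispersion
  ``E(v_i) = e^{3/2}`` is constant while its distribution varies.
* ``S2`` — log-normal with common ``mu`` and group-varying
  ``sigma_g^2``: mean dispersion differs (favours classical tests).
* ``S3`` — deterministic ``v_g`` per group: a pure scale shift.

**Negative-binomial counts** (:func:`simulate_negbin`).  Count data for
``d`` taxa: ``Y_ij ~ NB`` with per-sample size parameter
``r_i ~ InvGamma(alpha_g, beta_g)`` (scenarios S1, S2) or fixed per
group (S3), success probability ``p = r/(mu + r)`` so that
``E(Y|r) = mu`` and ``Var(Y|r) = mu + mu^2/r``; unconditionally
``Var(Y) = mu + mu^2 (alpha_g/beta_g)``.  In S1, ``beta_g = alpha_g``
keeps ``E(1/r) = alpha_g/beta_g`` — the mean overdispersion — constant
while its distribution varies across groups.

Every scenario collapses to identical groups at ``theta = 0``
(exchangeable samples), so label-permutation tests are exactly valid
there and empirical size is a meaningful calibration check.  Default
dimensions and sample sizes are ``d = 500`` features and ``n = 150``
samples split evenly among ``G`` in ``{2, 3, 5}`` groups; the deviation
parameter ``theta`` runs over 0..2 (normal) or 0..3 (counts) in steps
of 0.5.

:func:`run_study` drives grids of (scenario, G, theta) cells over any
subset of {dth, go_perm, betadisper} and reports empirical rejection
rates, one row per cell x method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.spatial.distance import pdist, squareform

from .comparators import betadisper_test, go_perm_test
from .dissimilarity import DistanceMatrix, FeatureTable, GroupLabels
from .dth import dth_test
from .permutation_engine import seed_sequence

__all__ = [
    "NormalScenario",
    "NBScenario",
    "gamma_kappa",
    "simulate_normal",
    "simulate_negbin",
    "simulate_continuous",
    "run_study",
]

logger = logging.getLogger("dthtest")

NORMAL_SCENARIOS = ("S0", "S1", "S2", "S3")
NB_SCENARIOS = ("S1", "S2", "S3")
STUDY_METHODS = ("dth", "go_perm", "betadisper")


def gamma_kappa(alpha: float) -> float:
    """Scale ``kappa`` making ``E[sqrt(v_i + v_j)] = 1`` for Gamma dispersions.

    With ``v ~ Gamma(shape a, scale k)``, ``E[sqrt(v)] = sqrt(k) *
    Gamma(a + 1/2) / Gamma(a)``, and ``v_i + v_j ~ Gamma(2 alpha, k)``
    for independent draws.  Setting ``E[sqrt(v_i + v_j)] = 1`` gives

        kappa = (Gamma(2 alpha + 1/2) / Gamma(2 alpha))^{-2}.

    Since the expected Euclidean distance between two samples with
    dispersions ``v_i, v_j`` is proportional to ``E[sqrt(v_i + v_j)]``,
    this choice equalizes expected within-group distances across groups
    with different ``alpha_g`` (scenario S0).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return float(exp(-2.0 * (gammaln(2.0 * alpha + 0.5) - gammaln(2.0 * alpha))))


def _balanced_sizes(n_total: int, G: int) -> tuple[int, ...]:
    base, extra = divmod(n_total, G)
    return tuple(base + (1 if g < extra else 0) for g in range(G))


# Table rows are defined for G in {2, 3, 5}; in G=5 rows the deviating
# groups are 3 and 5 (groups 1, 2, 4 stay at the null value).
def _normal_mixing_params(scenario: str, G: int, theta: float) -> dict:
    t = theta
    if scenario == "S0":
        alphas = {
            2: [1.0, 1.0 + 3 * t],
            3: [1.0, 1.0 + 6 * t, 1.0 + 3 * t],
            5: [1.0, 1.0, 1.0 + 6 * t, 1.0, 1.0 + 3 * t],
        }[G]
        return {"alpha": alphas, "kappa": [gamma_kappa(a) for a in alphas]}
    if scenario == "S1":
        mus = {
            2: [1.0, 1.0 - t],
            3: [1.0, 1.0 - t / 2, 1.0 - t],
            5: [1.0, 1.0, 1.0 - t / 2, 1.0, 1.0 - t],
        }[G]
        return {"mu": mus, "sigma2": [3.0 - 2.0 * m for m in mus]}
    if scenario == "S2":
        sig2 = {
            2: [1.0, 1.0 + 2 * t],
            3: [1.0, 1.0 + t, 1.0 + 2 * t],
            5: [1.0, 1.0, 1.0 + t, 1.0, 1.0 + 2 * t],
        }[G]
        return {"mu": [1.0] * G, "sigma2": sig2}
    if scenario == "S3":
        vs = {
            2: [1.0, exp(t / 80)],
            3: [1.0, exp(t / 40), exp(t / 80)],
            5: [1.0, 1.0, exp(t / 40), 1.0, exp(t / 80)],
        }[G]
        return {"v": vs}
    raise ValueError(f"unknown normal scenario {scenario!r}")


def _nb_mixing_params(scenario: str, G: int, theta: float) -> dict:
    t = theta
    if scenario == "S1":
        alphas = {
            2: [1.0, exp(-t)],
            3: [1.0, exp(-t / 2), exp(-t)],
            5: [1.0, 1.0, exp(-t / 2), 1.0, exp(-t)],
        }[G]
        alphas = [5.0 * a for a in alphas]
        return {"alpha": alphas, "beta": list(alphas)}  # alpha/beta = 1 in all groups
    if scenario == "S2":
        betas = {
            2: [1.0, exp(-t / 10)],
            3: [1.0, exp(-t / 20), exp(-t / 10)],
            5: [1.0, 1.0, exp(-t / 20), 1.0, exp(-t / 10)],
        }[G]
        return {"alpha": [3.0] * G, "beta": [5.0 * b for b in betas]}
    if scenario == "S3":
        rs = {
            2: [1.0, exp(t / 30)],
            3: [1.0, exp(t / 60), exp(t / 30)],
            5: [1.0, 1.0, exp(t / 60), 1.0, exp(t / 30)],
        }[G]
        return {"r": rs}
    raise ValueError(f"unknown negative-binomial scenario {scenario!r}")


@dataclass(frozen=True)
class NormalScenario:
    """Parameter set for one normal-scale-mixture simulation cell."""

    scenario: str
    G: int
    theta: float
    group_sizes: tuple[int, ...]
    d: int = 500

    def __post_init__(self):
        if self.scenario not in NORMAL_SCENARIOS:
            raise ValueError(f"scenario must be one of {NORMAL_SCENARIOS}")
        if self.G not in (2, 3, 5):
            raise ValueError("parameter tables are defined for G in {2, 3, 5}")
        if len(self.group_sizes) != self.G:
            raise ValueError("group_sizes length must equal G")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.d < 1:
            raise ValueError("d must be >= 1")

    @classmethod
    def balanced(cls, scenario: str, G: int, theta: float, n_total: int = 150,
                 d: int = 500) -> "NormalScenario":
        return cls(scenario, G, theta, _balanced_sizes(n_total, G), d)

    @property
    def mixing_params(self) -> dict:
        return _normal_mixing_params(self.scenario, self.G, self.theta)


@dataclass(frozen=True)
class NBScenario:
    """Parameter set for one negative-binomial simulation cell.

    ``mu_mean`` is the common NB mean for every taxon and group (held
    constant so only dispersion varies across groups).
    """

    scenario: str
    G: int
    theta: float
    group_sizes: tuple[int, ...]
    d: int = 500
    mu_mean: float = 10.0

    def __post_init__(self):
        if self.scenario not in NB_SCENARIOS:
            raise ValueError(f"scenario must be one of {NB_SCENARIOS}")
        if self.G not in (2, 3, 5):
            raise ValueError("parameter tables are defined for G in {2, 3, 5}")
        if len(self.group_sizes) != self.G:
            raise ValueError("group_sizes length must equal G")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.mu_mean <= 0:
            raise ValueError("mu_mean must be > 0")

    @classmethod
    def balanced(cls, scenario: str, G: int, theta: float, n_total: int = 150,
                 d: int = 500, mu_mean: float = 10.0) -> "NBScenario":
        return cls(scenario, G, theta, _balanced_sizes(n_total, G), d, mu_mean)

    @property
    def mixing_params(self) -> dict:
        p = _nb_mixing_params(self.scenario, self.G, self.theta)
        if "alpha" in p and (min(p["alpha"]) <= 0 or min(p["beta"]) <= 0):
            raise ValueError("inverse-gamma parameters must be > 0")
        return p


def _labels_for(sizes: tuple[int, ...]) -> GroupLabels:
    return GroupLabels([f"g{g + 1}" for g, ng in enumerate(sizes) for _ in range(ng)])


def simulate_normal(spec: NormalScenario, seed=None) -> tuple[FeatureTable, GroupLabels]:
    """Draw one normal-scale-mixture dataset.

    Each sample's dispersion ``v_i`` comes from its group's mixing
    distribution (Gamma for S0, log-normal for S1/S2, a constant for
    S3); its ``d`` features are then independent N(0, v_i).
    """
    rng = np.random.default_rng(seed_sequence(seed))
    params = spec.mixing_params
    n = sum(spec.group_sizes)
    v = np.empty(n)
    start = 0
    for g, ng in enumerate(spec.group_sizes):
        sl = slice(start, start + ng)
        if spec.scenario == "S0":
            v[sl] = rng.gamma(shape=params["alpha"][g], scale=params["kappa"][g],
                              size=ng)
        elif spec.scenario in ("S1", "S2"):
            v[sl] = rng.lognormal(mean=params["mu"][g],
                                  sigma=np.sqrt(params["sigma2"][g]), size=ng)
        else:  # S3
            v[sl] = params["v"][g]
        start += ng
    Y = np.sqrt(v)[:, None] * rng.standard_normal((n, spec.d))
    return FeatureTable(Y), _labels_for(spec.group_sizes)


def simulate_negbin(spec: NBScenario, seed=None) -> tuple[FeatureTable, GroupLabels]:
    """Draw one negative-binomial count dataset.

    Per sample: size parameter ``r_i`` ~ InvGamma(alpha_g, beta_g)
    (shape/rate parameterization: ``1/r ~ Gamma(alpha, rate beta)``, so
    ``E(1/r) = alpha/beta``) or the fixed per-group value in S3; then
    ``d`` iid counts with mean ``mu_mean`` and conditional variance
    ``mu_mean + mu_mean^2 / r_i``.
    """
    rng = np.random.default_rng(seed_sequence(seed))
    params = spec.mixing_params
    n = sum(spec.group_sizes)
    r = np.empty(n)
    start = 0
    for g, ng in enumerate(spec.group_sizes):
        sl = slice(start, start + ng)
        if spec.scenario == "S3":
            r[sl] = params["r"][g]
        else:
            # r ~ InvGamma(alpha, beta): reciprocal of Gamma(alpha, rate beta)
            r[sl] = 1.0 / rng.gamma(shape=params["alpha"][g],
                                    scale=1.0 / params["beta"][g], size=ng)
        start += ng
    p = r / (spec.mu_mean + r)  # E(Y|r) = mu, Var(Y|r) = mu + mu^2/r
    Y = rng.negative_binomial(n=r[:, None], p=p[:, None],
                              size=(n, spec.d)).astype(float)
    return FeatureTable(Y), _labels_for(spec.group_sizes)


def simulate_continuous(n: int, d: int, dispersion_slope: float,
                        seed=None) -> tuple[FeatureTable, np.ndarray]:
    """Dataset whose dispersion depends on a continuous covariate.

    ``x_i ~ Uniform(0, 1)`` and ``Y_i ~ N_d(0, exp(slope * x_i) I_d)``;
    a slope of 0 is the null of no covariate-dispersion association.

    Returns
    -------
    (FeatureTable, ndarray)
        The data and the covariate vector.
    """
    if n < 6:
        raise ValueError("need n >= 6 for a meaningful discretized test")
    rng = np.random.default_rng(seed_sequence(seed))
    x = rng.uniform(0.0, 1.0, size=n)
    v = np.exp(dispersion_slope * x)
    Y = np.sqrt(v)[:, None] * rng.standard_normal((n, d))
    return FeatureTable(Y), x


def _run_methods(D: DistanceMatrix, labels: GroupLabels, methods, R: int,
                 scheme: str, ss: np.random.SeedSequence) -> dict[str, float]:
    children = ss.spawn(len(methods))
    out = {}
    for method, child in zip(methods, children):
        if method == "dth":
            out[method] = dth_test(D, labels, R=R, scheme=scheme, seed=child).p_value
        elif method == "go_perm":
            out[method] = go_perm_test(D, labels, R=R, scheme=scheme,
                                       seed=child).p_value
        elif method == "betadisper":
            out[method] = betadisper_test(D, labels, R=R, seed=child).p_value
        else:
            raise ValueError(f"unknown method {method!r}; choose from {STUDY_METHODS}")
    return out


def run_study(
    family: str,
    scenarios,
    G_values,
    thetas,
    methods=STUDY_METHODS,
    n_reps: int = 500,
    R: int = 999,
    alpha: float = 0.05,
    n_total: int = 150,
    d: int = 500,
    scheme: str = "labels",
    mu_mean: float = 10.0,
    seed=None,
) -> pd.DataFrame:
    """Empirical rejection rates over a (scenario x G x theta) grid.

    For each grid cell, ``n_reps`` datasets are simulated, each method
    is run with ``R`` permutations, and the fraction of p-values
    ``<= alpha`` is recorded.  The distance is Euclidean for the normal
    family and Bray-Curtis for the count family.  ``theta = 0`` cells
    estimate empirical size; ``theta > 0`` cells estimate power.

    Returns
    -------
    pandas.DataFrame
        Tidy table, one row per cell x method, with columns
        ``family, scenario, G, theta, method, n_reps, R, alpha,
        rejections, rate``.
    """
    if family not in ("normal", "negbin"):
        raise ValueError("family must be 'normal' or 'negbin'")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    methods = list(methods)
    for m in methods:
        if m not in STUDY_METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {STUDY_METHODS}")
    metric = "euclidean" if family == "normal" else "braycurtis"

    master = seed_sequence(seed)
    rows = []
    cells = [(s, int(G), float(t)) for s in scenarios for G in G_values for t in thetas]
    cell_seeds = master.spawn(len(cells))
    for (scenario, G, theta), cell_ss in zip(cells, cell_seeds):
        logger.info("study cell: family=%s scenario=%s G=%d theta=%.2f "
                    "(n_reps=%d, R=%d, metric=%s)",
                    family, scenario, G, theta, n_reps, R, metric)
        rej = {m: 0 for m in methods}
        rep_seeds = cell_ss.spawn(n_reps)
        for rep_ss in rep_seeds:
            data_ss, test_ss = rep_ss.spawn(2)
            if family == "normal":
                spec = NormalScenario.balanced(scenario, G, theta, n_total, d)
                table, labels = simulate_normal(spec, seed=data_ss)
            else:
                spec = NBScenario.balanced(scenario, G, theta, n_total, d, mu_mean)
                table, labels = simulate_negbin(spec, seed=data_ss)
            D = DistanceMatrix(squareform(pdist(table.values, metric=metric)),
                               table.sample_ids)
            pvals = _run_methods(D, labels, methods, R, scheme, test_ss)
            for m, p in pvals.items():
                rej[m] += p <= alpha
        for m in methods:
            rows.append({
                "family": family, "scenario": scenario, "G": G, "theta": theta,
                "method": m, "n_reps": n_reps, "R": R, "alpha": alpha,
                "rejections": rej[m], "rate": rej[m] / n_reps,
            })
    return pd.DataFrame(rows)
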