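"""Permutation inference on group-level covariance networks.

Group-level structural covariance has one network per group, not per
subject, so group differences are tested by permuting subjects between the
two groups, rebuilding both covariance matrices and networks for every
permutation, and re-evaluating the statistic.  Two-sided p-values use the
standard add-one convention p = (1 + #{|null| >= |observed|}) / (1 + B), so
the smallest attainable p is 1/(1+B).

A registry of named statistics (wiring cost, nodal degree, hub mean
morphometry, cumulative degree at k, rich club at k) covers the group
comparisons of the analysis; any callable over two group contexts works.
FDR control is provided as Benjamini-Hochberg or Benjamini-Yekutieli
(default BY, valid under the dependency typical of network metrics), and a
max-statistic family-wise correction is available for vector statistics
such as the cumulative degree distribution over a degree range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from statsmodels.stats.multitest import multipletests

from .metrics import degree_profile, hub_set, rich_club, wiring_cost
from .netbuild import CovarianceNetwork, build_network
from .preprocess import GroupCovariance, pearson_correlation
from .synth import Subject


@dataclass
class GroupContext:
    """Everything a statistic may need about one (pseudo-)group."""

    cov: GroupCovariance
    net: CovarianceNetwork
    D: np.ndarray
    region_means: np.ndarray


@dataclass
class PermutationTest:
    statistic: str
    observed: float | np.ndarray
    null: np.ndarray                  # (B,) or (B, m)
    p_value: float | np.ndarray
    n_permutations: int
    n_retries: int = 0


@dataclass
class FdrResult:
    p_raw: np.ndarray
    q: np.ndarray
    rejected: np.ndarray
    alpha: float
    method: str


Statistic = Callable[[GroupContext, GroupContext], "float | np.ndarray"]


def stat_wiring_cost(a: GroupContext, b: GroupContext) -> float:
    return wiring_cost(a.net, a.D).wc - wiring_cost(b.net, b.D).wc


def stat_nodal_degree(a: GroupContext, b: GroupContext) -> np.ndarray:
    return a.net.degrees().astype(float) - b.net.degrees().astype(float)


def make_hub_mean_thickness(top_fraction: float = 0.10) -> Statistic:
    def stat(a: GroupContext, b: GroupContext) -> float:
        ha = np.array(sorted(hub_set(degree_profile(a.net), top_fraction))) - 1
        hb = np.array(sorted(hub_set(degree_profile(b.net), top_fraction))) - 1
        return float(a.region_means[ha].mean() - b.region_means[hb].mean())
    return stat


def make_cumulative_degree_at_k(k: int) -> Statistic:
    def stat(a: GroupContext, b: GroupContext) -> float:
        return (degree_profile(a.net).cumulative_at(k)
                - degree_profile(b.net).cumulative_at(k))
    return stat


def make_rich_club_at_k(k: int) -> Statistic:
    def stat(a: GroupContext, b: GroupContext) -> float:
        pa, pb = rich_club(a.net), rich_club(b.net)
        if k not in pa or k not in pb:
            raise ValueError(f"rich-club coefficient undefined at k={k}")
        return pa[k] - pb[k]
    return stat


STATISTICS: dict[str, Callable[..., Statistic]] = {
    "wiring_cost": lambda: stat_wiring_cost,
    "nodal_degree": lambda: stat_nodal_degree,
    "hub_mean_thickness": make_hub_mean_thickness,
    "cumulative_degree_at_k": make_cumulative_degree_at_k,
    "rich_club_at_k": make_rich_club_at_k,
}


def get_statistic(name: str, **kwargs) -> Statistic:
    if name not in STATISTICS:
        raise KeyError(f"unknown statistic {name!r}; known: {sorted(STATISTICS)}")
    return STATISTICS[name](**kwargs)


def _context(values: np.ndarray, group: str, D: np.ndarray, density: float,
             build_kwargs: dict) -> GroupContext:
    cov = GroupCovariance(group=group, n_subjects=len(values),
                          R=pearson_correlation(values, group))
    net = build_network(cov, density, **build_kwargs)
    return GroupContext(cov=cov, net=net, D=D,
                        region_means=values.mean(axis=0))


def permute_groups(cohort_a: list[Subject], cohort_b: list[Subject],
                   stat: str | Statistic, D: np.ndarray, *,
                   B: int = 1000, density: float = 0.10,
                   rng_seed: int = 0, build_kwargs: dict | None = None,
                   stat_kwargs: dict | None = None,
                   max_retry_factor: int = 10) -> PermutationTest:
    """Two-group permutation test of a network-level statistic.

    Subjects are shuffled between the groups preserving group sizes; both
    covariance matrices and networks are rebuilt per permutation.  Draws on
    which the statistic is undefined (e.g. a zero-variance region) are
    redrawn, up to ``max_retry_factor * B`` retries in total.
    """
    if B < 1:
        raise ValueError("need at least 1 permutation")
    build_kwargs = build_kwargs or {}
    if isinstance(stat, str):
        name = stat
        stat_fn = get_statistic(stat, **(stat_kwargs or {}))
    else:
        name = getattr(stat, "__name__", "custom")
        stat_fn = stat

    va = np.vstack([s.values for s in cohort_a])
    vb = np.vstack([s.values for s in cohort_b])
    ga = cohort_a[0].group
    gb = cohort_b[0].group
    na = len(va)
    pooled = np.vstack([va, vb])

    observed = stat_fn(_context(va, ga, D, density, build_kwargs),
                       _context(vb, gb, D, density, build_kwargs))
    observed = np.asarray(observed, dtype=float)

    rng = np.random.default_rng(rng_seed)
    null = np.empty((B,) + observed.shape)
    retries = 0
    b = 0
    while b < B:
        perm = rng.permutation(len(pooled))
        try:
            val = stat_fn(
                _context(pooled[perm[:na]], ga, D, density, build_kwargs),
                _context(pooled[perm[na:]], gb, D, density, build_kwargs))
        except ValueError:
            retries += 1
            if retries > max_retry_factor * B:
                raise RuntimeError(
                    "permutation retry budget exhausted; statistic undefined "
                    "on too many draws")
            continue
        null[b] = np.asarray(val, dtype=float)
        b += 1

    exceed = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + B)
    if observed.shape == ():
        observed = float(observed)
        p = float(p)
    return PermutationTest(statistic=name, observed=observed, null=null,
                          p_value=p, n_permutations=B, n_retries=retries)


def fdr_adjust(p: np.ndarray, alpha: float = 0.025,
               method: str = "BY") -> FdrResult:
    """Step-up FDR adjustment (BH, or BY which is valid under dependency)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    method = method.upper()
    if method not in ("BH", "BY"):
        raise ValueError("method must be 'BH' or 'BY'")
    rejected, q, _, _ = multipletests(
        p, alpha=alpha, method="fdr_bh" if method == "BH" else "fdr_by")
    return FdrResult(p_raw=p, q=q, rejected=rejected, alpha=alpha,
                     method=method)


def max_statistic_pvalues(test: PermutationTest,
                          indices: np.ndarray | None = None) -> np.ndarray:
    """Family-wise corrected p-values for a vector statistic.

    Each element's corrected p compares |observed_i| with the permutation
    distribution of the maximum |null| over the (optionally restricted)
    family — the classic max-statistic correction, used here for the
    cumulative degree distribution over a degree range.
    """
    null = np.atleast_2d(test.null)
    obs = np.atleast_1d(np.asarray(test.observed, dtype=float))
    if indices is not None:
        null = null[:, indices]
        obs = obs[indices]
    max_null = np.abs(null).max(axis=1)
    exceed = (max_null[:, None] >= np.abs(obs)[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + test.n_permutations)
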