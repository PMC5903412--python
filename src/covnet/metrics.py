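"""Nodal and global metrics of binary covariance networks.

Degree, cumulative degree distribution P(k) = sum_{k' >= k} p(k'), hub sets
(top fraction of nodes by degree), wiring cost (mean Euclidean length of
connected region pairs, mm), group-mean morphometry profiled over degree
thresholds, and the rich-club coefficient phi(k) — the edge density among
nodes of degree strictly greater than k, optionally normalised by
degree-preserving rewired surrogates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import CovarianceNetwork
from .synth import Subject

logger = logging.getLogger(__name__)


@dataclass
class DegreeProfile:
    """Per-node degrees with the empirical and cumulative distributions."""

    k: np.ndarray        # degree per node
    ks: np.ndarray       # sorted unique degrees
    p: np.ndarray        # P(degree == ks[i])
    P: np.ndarray        # P(degree >= ks[i]), non-increasing

    def cumulative_at(self, k0: int) -> float:
        """P(k) at an arbitrary degree threshold k0."""
        return float(self.p[self.ks >= k0].sum())


@dataclass
class WiringCost:
    """Mean connection distance of a network."""

    wc: float            # mm
    n_connections: int


def degree_profile(net: CovarianceNetwork) -> DegreeProfile:
    k = net.degrees()
    ks, counts = np.unique(k, return_counts=True)
    p = counts / counts.sum()
    P = np.cumsum(p[::-1])[::-1]
    return DegreeProfile(k=k, ks=ks, p=p, P=P)


def hub_set(profile: DegreeProfile, top_fraction: float) -> set[int]:
    """Region ids (1-based) of the ceil(f*N) highest-degree nodes.

    Ties at the cut are broken toward the lower region id.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    n = len(profile.k)
    n_hubs = math.ceil(top_fraction * n)
    order = np.lexsort((np.arange(n), -profile.k))
    return set((order[:n_hubs] + 1).tolist())


def wiring_cost(net: CovarianceNetwork, D: np.ndarray) -> WiringCost:
    if net.n_edges == 0:
        raise ValueError("network has no edges; wiring cost undefined")
    if D.shape[0] != net.n_regions:
        raise ValueError("distance matrix does not match the network")
    lengths = D[net.edges[:, 0], net.edges[:, 1]]
    return WiringCost(wc=float(lengths.mean()), n_connections=net.n_edges)


def thickness_by_degree(net: CovarianceNetwork, cohort: list[Subject],
                        mode: str = "percentile",
                        percentiles: np.ndarray | None = None) -> pd.DataFrame:
    """Mean group-mean regional value over nodes with degree >= threshold.

    ``mode='absolute'`` sweeps every observed degree value; ``'percentile'``
    sweeps degree quantiles from 0% to 100% of nodes.  Group-level networks
    carry no subject-level degree, so the profiled value is the group mean
    of each region's morphometry.  Thresholds with no qualifying nodes are
    omitted (logged).
    """
    groups = {s.group for s in cohort}
    if net.group and groups != {net.group}:
        raise ValueError(
            f"cohort groups {sorted(groups)} do not match network group "
            f"{net.group!r}")
    region_means = np.vstack([s.values for s in cohort]).mean(axis=0)
    k = net.degrees()

    if mode == "absolute":
        thresholds = [(float(t), float(t)) for t in np.unique(k)]
        if k.min() > 0:
            thresholds.insert(0, (0.0, 0.0))
    elif mode == "percentile":
        pcts = np.arange(0, 101, 5) if percentiles is None else np.asarray(percentiles)
        thresholds = [(float(p), float(np.percentile(k, p))) for p in pcts]
    else:
        raise ValueError("mode must be 'absolute' or 'percentile'")

    rows = []
    for label, cutoff in thresholds:
        mask = k >= cutoff
        if not mask.any():
            logger.info("no nodes with degree >= %s; threshold omitted", cutoff)
            continue
        rows.append({"threshold": label, "degree_cutoff": cutoff,
                     "n_nodes": int(mask.sum()),
                     "mean_value": float(region_means[mask].mean())})
    return pd.DataFrame(rows)


def rich_club(net: CovarianceNetwork) -> dict[int, float]:
    """Raw rich-club coefficient phi(k) for each defined degree level.

    phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)) over the subgraph of nodes
    with degree strictly greater than k; undefined levels (fewer than two
    qualifying nodes) are omitted.
    """
    k = net.degrees()
    A = net.A
    out: dict[int, float] = {}
    for level in range(int(k.max())):
        nodes = np.flatnonzero(k > level)
        if len(nodes) < 2:
            break
        sub = A[np.ix_(nodes, nodes)]
        e = int(sub.sum()) // 2
        out[level] = 2.0 * e / (len(nodes) * (len(nodes) - 1))
    return out


def rich_club_normalized(net: CovarianceNetwork, n_rewires: int = 100,
                         rng_seed: int = 0) -> dict[int, float]:
    """phi(k) divided by its mean over degree-preserving rewired surrogates.

    Each surrogate applies 5E double-edge swaps to a copy of the network
    with a seeded RNG; levels where the surrogate mean is zero or undefined
    are omitted.
    """
    raw = rich_club(net)
    G0 = nx.from_numpy_array(net.A.astype(int))
    n_swaps = 5 * net.n_edges
    sums: dict[int, float] = {level: 0.0 for level in raw}
    counts: dict[int, int] = {level: 0 for level in raw}
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_rewires)
    for s in seeds:
        G = G0.copy()
        try:
            nx.double_edge_swap(G, nswap=n_swaps, max_tries=100 * n_swaps,
                                seed=int(s % (2**31)))
        except nx.NetworkXError:
            pass  # too few swappable edges; use graph as-is
        A = nx.to_numpy_array(G, nodelist=range(net.n_regions)) > 0
        surrogate = rich_club(CovarianceNetwork(
            group=net.group, density=net.density, A=A,
            edges=np.column_stack(np.triu_indices(net.n_regions, 1)),
            edge_r=np.zeros(0)))
        for level, val in surrogate.items():
            if level in sums:
                sums[level] += val
                counts[level] += 1
    out = {}
    for level, phi in raw.items():
        if counts[level] and sums[level] > 0:
            out[level] = phi / (sums[level] / counts[level])
    return out


def metrics_table(group: str, density: float, net: CovarianceNetwork,
                  D: np.ndarray, cohort: list[Subject],
                  hub_fraction: float = 0.10) -> pd.DataFrame:
    """Tidy long-format metric rows keyed by (group, density, metric, threshold)."""
    rows = []
    prof = degree_profile(net)
    for ks, P in zip(prof.ks, prof.P):
        rows.append({"group": group, "density": density,
                     "metric": "cumulative_degree", "threshold": float(ks),
                     "value": float(P)})
    wc = wiring_cost(net, D)
    rows.append({"group": group, "density": density, "metric": "wiring_cost",
                 "threshold": np.nan, "value": wc.wc})
    hubs = hub_set(prof, hub_fraction)
    rows.append({"group": group, "density": density, "metric": "n_hubs",
                 "threshold": hub_fraction, "value": float(len(hubs))})
    for level, phi in rich_club(net).items():
        rows.append({"group": group, "density": density, "metric": "rich_club",
                     "threshold": float(level), "value": phi})
    for _, r in thickness_by_degree(net, cohort, "percentile").iterrows():
        rows.append({"group": group, "density": density,
                     "metric": "thickness_by_degree_pct",
                     "threshold": r["threshold"], "value": r["mean_value"]})
    return pd.DataFrame(rows)
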