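"""Modular structure and pair-counting agreement against constrained nulls.

Community structure of each group's covariance network is found by repeated
Louvain runs (best modularity Q wins).  Agreement between two groups'
partitions is a pair-counting index: the Jaccard overlap between the two
sets of co-assigned region pairs (a conditional-proportion variant is
available).  Because any such index is inflated by trivial features of the
partitions (module count, module sizes, spatial compactness, bilateral
symmetry), significance is assessed against surrogate partitions that
preserve exactly those features: random partitions with the template's
module count and sizes, spatially contiguous on the parcellation neighbour
graph, and hemisphere-symmetric (homotopic regions share a label).

Surrogates are generated by seeded region growth on one hemisphere at half
the module sizes and mirrored to the other; modules therefore span the two
hemispheres as mirror images, and contiguity is assessed on the neighbour
graph augmented with mirror-pair edges (each module's restriction to each
hemisphere is connected).  Templates with odd module sizes — possible for
raw Louvain output — are accommodated by transferring one region between a
pair of odd-sized modules before halving (the number of odd modules is
always even).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import CovarianceNetwork
from .perm import FdrResult, fdr_adjust
from .synth import Parcellation


@dataclass
class Partition:
    """Module labels (1..n_modules) per region, with source modularity Q."""

    labels: np.ndarray
    n_modules: int
    Q: float

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules + 1)[1:]


@dataclass
class AgreementResult:
    raw: float
    null_mean: float
    null_sd: float
    z: float                      # nan when the null is degenerate
    q95: float
    p: float
    significant: bool             # raw > null 95th quantile
    null: np.ndarray
    index: str = "jaccard"


# ---------------------------------------------------------------------------
# Louvain partitions


def louvain_partition(net: CovarianceNetwork, n_restarts: int = 100,
                      rng_seed: int = 0) -> Partition:
    """Best-of-``n_restarts`` Louvain partition of a covariance network.

    Deterministic for a fixed seed; restarts use distinct sub-seeds and the
    partition with maximal modularity is returned, labels renumbered
    1..n_modules by each module's lowest region index.
    """
    G = nx.from_numpy_array(net.A.astype(int))
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_restarts)
    best_q = -np.inf
    best = None
    for s in seeds:
        comms = nx.community.louvain_communities(G, seed=int(s % (2**31)))
        q = nx.community.modularity(G, comms)
        if q > best_q:
            best_q = q
            best = comms
    return partition_from_communities(best, net.n_regions, float(best_q))


def partition_from_communities(comms, n_regions: int, Q: float = float("nan")
                               ) -> Partition:
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.zeros(n_regions, dtype=int)
    for m, nodes in enumerate(comms, start=1):
        labels[list(nodes)] = m
    return Partition(labels=labels, n_modules=len(comms), Q=Q)


def partition_from_labels(labels: np.ndarray, Q: float = float("nan")
                          ) -> Partition:
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    remap = {old: new for new, old in enumerate(uniq, start=1)}
    relabeled = np.array([remap[v] for v in labels])
    return Partition(labels=relabeled, n_modules=len(uniq), Q=Q)


def modularity_of(net: CovarianceNetwork, partition: Partition) -> float:
    G = nx.from_numpy_array(net.A.astype(int))
    comms = [set(np.flatnonzero(partition.labels == m))
             for m in range(1, partition.n_modules + 1)]
    return float(nx.community.modularity(G, comms))


# ---------------------------------------------------------------------------
# Pair-counting agreement


def _co_pair_counts(l1: np.ndarray, l2: np.ndarray) -> tuple[int, int, int]:
    """(pairs co-assigned in both, in p1, in p2) via the contingency table."""
    _, inv1 = np.unique(l1, return_inverse=True)
    _, inv2 = np.unique(l2, return_inverse=True)
    k2 = inv2.max() + 1
    nij = np.bincount(inv1 * k2 + inv2)
    a = np.bincount(inv1)
    b = np.bincount(inv2)

    def pairs(c):
        return int((c.astype(np.int64) * (c - 1) // 2).sum())

    return pairs(nij), pairs(a), pairs(b)


def agreement_index(p1: Partition, p2: Partition,
                    index: str = "jaccard") -> float:
    """Pair-counting agreement between two partitions of the same regions.

    ``jaccard``: |co-pairs(p1) ∩ co-pairs(p2)| / |co-pairs(p1) ∪ co-pairs(p2)|.
    ``conditional``: the same intersection divided by |co-pairs(p1)|.
    Equals 1 iff the co-assigned pair sets are identical.
    """
    if len(p1.labels) != len(p2.labels):
        raise ValueError("partitions cover different region sets")
    both, in1, in2 = _co_pair_counts(p1.labels, p2.labels)
    if in1 == 0 or in2 == 0:
        raise ValueError("all-singleton partition: no co-assigned pairs")
    if index == "jaccard":
        return both / (in1 + in2 - both)
    if index == "conditional":
        return both / in1
    raise ValueError("index must be 'jaccard' or 'conditional'")


# ---------------------------------------------------------------------------
# Constrained random partitions (the null model)


def _evened_sizes(sizes: np.ndarray) -> np.ndarray:
    """Make all module sizes even by pairing up odd-sized modules."""
    sizes = np.asarray(sizes, dtype=int).copy()
    odd = np.flatnonzero(sizes % 2 == 1)
    assert len(odd) % 2 == 0  # total region count is even (mirrored)
    for a, b in zip(odd[0::2], odd[1::2]):
        sizes[a] += 1
        sizes[b] -= 1
    if np.any(sizes < 2):
        bad = int(sizes.min())
        raise ValueError(
            f"module size {bad} cannot satisfy hemispheric symmetry")
    return sizes


def _hemisphere_graph(parc: Parcellation, hemi: str = "R"):
    """Local adjacency lists of one hemisphere, plus the global index map."""
    idx = parc.hemisphere_indices(hemi)
    local = {int(g): i for i, g in enumerate(idx)}
    adj: list[list[int]] = [[] for _ in idx]
    for i, g in enumerate(idx):
        for rid in parc.neighbors[g]:
            j = local.get(rid - 1)
            if j is not None:
                adj[i].append(j)
    return idx, adj


def _grow_half_partition(adj: list[list[int]], half_sizes: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray | None:
    """One rejection-sampling attempt at a contiguous partition of one
    hemisphere with the given per-module sizes; None on failure."""
    n = len(adj)
    labels = np.zeros(n, dtype=int)
    remainder = int(np.argmax(half_sizes)) + 1
    order = [m + 1 for m in range(len(half_sizes)) if m + 1 != remainder]
    rng.shuffle(order)
    unassigned = n
    for m in order:
        target = int(half_sizes[m - 1])
        free = np.flatnonzero(labels == 0)
        seed = int(free[rng.integers(len(free))])
        labels[seed] = m
        grown = 1
        frontier = [v for v in adj[seed] if labels[v] == 0]
        while grown < target:
            frontier = [v for v in frontier if labels[v] == 0]
            if not frontier:
                return None
            v = frontier.pop(int(rng.integers(len(frontier))))
            labels[v] = m
            grown += 1
            frontier.extend(w for w in adj[v] if labels[w] == 0)
        unassigned -= target
    # remainder module = whatever is left; must be connected
    rest = np.flatnonzero(labels == 0)
    if len(rest):
        rest_set = set(rest.tolist())
        stack = [rest[0]]
        seen = {int(rest[0])}
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w in rest_set and w not in seen:
                    seen.add(w)
                    stack.append(w)
        if len(seen) != len(rest):
            return None
        labels[rest] = remainder
    return labels


def draw_constrained_partition(parc: Parcellation, sizes: np.ndarray,
                               rng: np.random.Generator,
                               max_attempts: int = 2000) -> Partition:
    """One random partition with the given (even) module sizes, contiguous
    and hemisphere-symmetric, by half-size growth on the right hemisphere
    mirrored to the left."""
    sizes = np.asarray(sizes, dtype=int)
    if sizes.sum() != parc.n_regions:
        raise ValueError("module sizes must sum to the region count")
    half = sizes // 2
    r_idx, adj = _hemisphere_graph(parc, "R")
    for _ in range(max_attempts):
        half_labels = _grow_half_partition(adj, half, rng)
        if half_labels is not None:
            labels = np.zeros(parc.n_regions, dtype=int)
            labels[r_idx] = half_labels
            for i, g in enumerate(r_idx):
                labels[parc.mirror_index(g)] = half_labels[i]
            return Partition(labels=labels, n_modules=len(sizes),
                             Q=float("nan"))
    raise RuntimeError(
        f"could not grow a contiguous symmetric partition with sizes "
        f"{sizes.tolist()} in {max_attempts} attempts")


def random_constrained_partitions(parc: Parcellation, template: Partition,
                                  B: int, rng_seed: int) -> list[Partition]:
    """B surrogate partitions preserving the template's module count, module
    sizes (evened for symmetry), spatial contiguity and hemispheric
    symmetry."""
    sizes = _evened_sizes(template.module_sizes())
    rng = np.random.default_rng(rng_seed)
    return [draw_constrained_partition(parc, sizes, rng) for _ in range(B)]


def symmetric_partition(parc: Parcellation, n_modules: int,
                        rng_seed: int) -> Partition:
    """A random equal-sized contiguous symmetric partition (for planting)."""
    n_half = parc.n_regions // 2
    base, extra = divmod(n_half, n_modules)
    half_sizes = np.array([base + (1 if m < extra else 0)
                           for m in range(n_modules)])
    rng = np.random.default_rng(rng_seed)
    return draw_constrained_partition(parc, 2 * half_sizes, rng)


def check_constrained_partition(partition: Partition, parc: Parcellation,
                                template: Partition) -> list[str]:
    """Independent verifier of the four preserved null-model properties.

    Returns a list of violated properties (empty = all pass): module count,
    module sizes (against the evened template sizes), spatial contiguity on
    the neighbour graph plus mirror edges, and hemispheric symmetry.
    Uses networkx connectivity, independent of the generator's growth logic.
    """
    issues = []
    if partition.n_modules != template.n_modules:
        issues.append("module count differs from template")
    expected = sorted(_evened_sizes(template.module_sizes()).tolist())
    if sorted(partition.module_sizes().tolist()) != expected:
        issues.append("module sizes differ from (evened) template sizes")
    lab = partition.labels
    for i in range(parc.n_regions):
        if lab[i] != lab[parc.mirror_index(i)]:
            issues.append("hemispheric symmetry violated")
            break
    G = nx.Graph()
    G.add_nodes_from(range(parc.n_regions))
    for i, nb in enumerate(parc.neighbors):
        for rid in nb:
            G.add_edge(i, rid - 1)
        G.add_edge(i, parc.mirror_index(i))
    for m in range(1, partition.n_modules + 1):
        nodes = np.flatnonzero(lab == m)
        if len(nodes) == 0:
            issues.append(f"module {m} empty")
        elif not nx.is_connected(G.subgraph(nodes.tolist())):
            issues.append(f"module {m} not spatially contiguous")
    return issues


# ---------------------------------------------------------------------------
# Agreement tests


def agreement_test(p1: Partition, p2: Partition, parc: Parcellation,
                   B: int = 1000, rng_seed: int = 0,
                   index: str = "jaccard") -> AgreementResult:
    """Test modular agreement against matched constrained surrogates.

    The null distribution is the agreement index between surrogate
    partitions matched to p1's and p2's templates respectively; z-score,
    95th-quantile threshold and an add-one permutation p are reported.
    """
    raw = agreement_index(p1, p2, index)
    s1, s2 = np.random.SeedSequence(rng_seed).spawn(2)
    nulls1 = random_constrained_partitions(parc, p1, B,
                                           int(s1.generate_state(1)[0] % 2**31))
    nulls2 = random_constrained_partitions(parc, p2, B,
                                           int(s2.generate_state(1)[0] % 2**31))
    null = np.array([agreement_index(a, b, index)
                     for a, b in zip(nulls1, nulls2)])
    sd = float(null.std())
    z = (raw - null.mean()) / sd if sd > 0 else float("nan")
    q95 = float(np.quantile(null, 0.95))
    p = float((1 + (null >= raw).sum()) / (1 + B))
    return AgreementResult(raw=float(raw), null_mean=float(null.mean()),
                           null_sd=sd, z=float(z), q95=q95, p=p,
                           significant=bool(raw > q95), null=null,
                           index=index)


@dataclass
class AgreementDifference:
    pair_a: str
    pair_b: str
    diff: float                   # agreement(pair_a) - agreement(pair_b)
    q95_abs: float                # 95th quantile of |null difference|
    p: float
    significant: bool


@dataclass
class AgreementDifferenceResults:
    differences: list[AgreementDifference]
    fdr: FdrResult

    def frame(self) -> pd.DataFrame:
        rows = [{"pair_a": d.pair_a, "pair_b": d.pair_b, "diff": d.diff,
                 "q95_abs": d.q95_abs, "p": d.p,
                 "significant_raw": d.significant}
                for d in self.differences]
        df = pd.DataFrame(rows)
        df["q"] = self.fdr.q
        df["significant_fdr"] = self.fdr.rejected
        return df


def agreement_difference_test(pairs: list[tuple[str, AgreementResult]],
                              B: int | None = None, alpha: float = 0.025,
                              fdr_method: str = "BY"
                              ) -> AgreementDifferenceResults:
    """Compare modular agreement between pairs of group-pairs.

    Each input element is (pair name, AgreementResult); the observed
    difference of agreement indices is referred to the matched null
    distribution of differences of the surrogate agreement values, with a
    95th-quantile threshold on |difference| and FDR across comparisons.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 group-pairs to compare")
    n_null = min(len(res.null) for _, res in pairs)
    if B is not None:
        n_null = min(n_null, B)
    diffs: list[AgreementDifference] = []
    for (name_a, res_a), (name_b, res_b) in combinations(pairs, 2):
        obs = res_a.raw - res_b.raw
        null = res_a.null[:n_null] - res_b.null[:n_null]
        q95 = float(np.quantile(np.abs(null), 0.95))
        p = float((1 + (np.abs(null) >= abs(obs)).sum()) / (1 + n_null))
        diffs.append(AgreementDifference(
            pair_a=name_a, pair_b=name_b, diff=float(obs), q95_abs=q95,
            p=p, significant=bool(abs(obs) > q95)))
    fdr = fdr_adjust(np.array([d.p for d in diffs]), alpha=alpha,
                     method=fdr_method)
    return AgreementDifferenceResults(differences=diffs, fdr=fdr)
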