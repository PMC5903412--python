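"""Binary covariance networks: spanning-tree backbone plus density top-up.

A group's correlation matrix is thresholded into a binary undirected graph
by first taking the maximum spanning tree on correlation weights (the
minimum spanning tree on 1 - r), which guarantees a connected network, and
then adding the remaining strongest correlations until a target edge density
is reached.  Density is the fraction of the N(N-1)/2 possible edges present.

By default the target edge count includes the tree's edges
(round(density * N(N-1)/2)); set ``density_excludes_mst`` to add
round(density * N(N-1)/2) edges on top of the tree instead.  Edges are
ranked by signed correlation (``rank_by='abs'`` ranks by magnitude); ties
are broken by lexicographic (i, j) order for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import GroupCovariance


@dataclass
class CovarianceNetwork:
    """Binary, connected covariance network at a stated edge density."""

    group: str
    density: float
    A: np.ndarray            # (N, N) bool adjacency, zero diagonal
    edges: np.ndarray        # (E, 2) int, i < j, 0-based
    edge_r: np.ndarray       # source correlation per edge

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return self.A.sum(axis=0).astype(int)


def _ranked_edges(R: np.ndarray, rank_by: str):
    """All i<j edges ordered by descending rank weight, lex ties."""
    n = R.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    r = R[iu, ju]
    key = np.abs(r) if rank_by == "abs" else r
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order], r[order]


def _kruskal_tree(ii, jj, n: int) -> np.ndarray:
    """Indices (into the ranked edge arrays) of the maximum spanning tree."""
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    picked = np.zeros(len(ii), dtype=bool)
    count = 0
    for e in range(len(ii)):
        ra, rb = find(ii[e]), find(jj[e])
        if ra != rb:
            parent[ra] = rb
            picked[e] = True
            count += 1
            if count == n - 1:
                break
    if count != n - 1:
        raise ValueError("correlation graph is not connected")
    return picked


def build_network(cov: GroupCovariance, density: float, *,
                  density_excludes_mst: bool = False,
                  rank_by: str = "signed") -> CovarianceNetwork:
    """Threshold a covariance matrix into a connected binary network."""
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    if rank_by not in ("signed", "abs"):
        raise ValueError("rank_by must be 'signed' or 'abs'")
    n = cov.R.shape[0]
    m_possible = n * (n - 1) // 2
    m_extra = int(np.floor(density * m_possible + 0.5))
    m_target = (n - 1) + m_extra if density_excludes_mst else m_extra
    m_target = min(m_target, m_possible)
    if m_target < n - 1:
        min_density = (n - 1) / m_possible
        raise ValueError(
            f"density {density} yields {m_target} edges < the spanning "
            f"tree's {n - 1}; minimum achievable density is {min_density:.4f}")

    ii, jj, rr = _ranked_edges(cov.R, rank_by)
    in_tree = _kruskal_tree(ii, jj, n)

    keep = in_tree.copy()
    n_kept = n - 1
    for e in range(len(ii)):
        if n_kept == m_target:
            break
        if not keep[e]:
            keep[e] = True
            n_kept += 1

    ei, ej, er = ii[keep], jj[keep], rr[keep]
    order = np.lexsort((ej, ei))
    ei, ej, er = ei[order], ej[order], er[order]
    A = np.zeros((n, n), dtype=bool)
    A[ei, ej] = True
    A[ej, ei] = True
    return CovarianceNetwork(group=cov.group, density=float(density), A=A,
                             edges=np.column_stack([ei, ej]), edge_r=er)


def density_sweep(cov: GroupCovariance, densities: list[float],
                  **kwargs) -> list[CovarianceNetwork]:
    """Build networks at each density; lower-density edge sets nest in
    higher ones whenever both contain the tree and ranks are unchanged."""
    return [build_network(cov, d, **kwargs) for d in densities]
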