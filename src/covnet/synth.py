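"""Synthetic parcellations and cohorts for structural covariance analysis.

Real studies of this kind start from surface-based cortical parcellations
(~300 equal-area parcels) and per-subject regional morphometry (mean cortical
thickness per parcel, in mm).  This module generates stand-ins with the same
statistical structure the downstream analysis relies on:

* a bilateral parcellation with mirrored (homotopic) region pairs, MNI-scale
  centroid coordinates, and a spatial neighbour graph that is connected
  within each hemisphere;
* cohorts of subjects whose inter-regional correlation decays exponentially
  with Euclidean centroid distance at a group-specific rate, optionally with
  a planted modular structure, multi-site additive offsets and subject noise.

Everything is driven by a single integer seed per call and is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: canonical diagnostic group labels (neurotypical, autism, ADHD)
DEFAULT_GROUPS = ("NT", "AUT", "ADHD")


@dataclass(frozen=True)
class Parcellation:
    """Bilateral cortical parcellation: geometry plus adjacency.

    Region ids are 1..N; index ``i`` of every array refers to region
    ``i + 1``.  ``mirror`` maps each region to its homotopic partner in the
    other hemisphere; ``neighbors`` lists spatially adjacent regions within
    the same hemisphere.
    """

    region_ids: np.ndarray          # int, 1..N
    hemisphere: np.ndarray          # 'L' / 'R' per region
    mirror: np.ndarray              # region id of homotopic partner
    centroids: np.ndarray           # (N, 3) in MNI mm
    neighbors: tuple[frozenset, ...]  # region ids, per region

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, region_id: int) -> int:
        return int(region_id) - 1

    def mirror_index(self, i: int) -> int:
        return int(self.mirror[i]) - 1

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        n = self.n_regions
        if not np.array_equal(self.region_ids, np.arange(1, n + 1)):
            raise ValueError("region ids must be 1..N in order")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        for i in range(n):
            m = self.mirror_index(i)
            if self.mirror_index(m) != i:
                raise ValueError("mirror map is not an involution")
            if self.hemisphere[i] == self.hemisphere[m]:
                raise ValueError("mirror map must cross hemispheres")
            if not np.allclose(self.centroids[i, 0], -self.centroids[m, 0]):
                raise ValueError("mirrored centroids must be x-reflected")
            if not np.allclose(self.centroids[i, 1:], self.centroids[m, 1:]):
                raise ValueError("mirrored centroids must share y/z")
        for i, nb in enumerate(self.neighbors):
            rid = i + 1
            if rid in nb:
                raise ValueError("neighbor relation must be irreflexive")
            for j in nb:
                if rid not in self.neighbors[j - 1]:
                    raise ValueError("neighbor relation must be symmetric")
        for hemi in ("L", "R"):
            idx = self.hemisphere_indices(hemi)
            if len(idx) and not _is_connected(idx, self.neighbors):
                raise ValueError(f"hemisphere {hemi} neighbor graph disconnected")


def _is_connected(indices: np.ndarray, neighbors) -> bool:
    """BFS connectivity over a subset of regions (0-based indices)."""
    allowed = set(int(i) for i in indices)
    start = next(iter(allowed))
    seen = {start}
    stack = [start]
    while stack:
        i = stack.pop()
        for rid in neighbors[i]:
            j = rid - 1
            if j in allowed and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(allowed)


@dataclass
class Subject:
    """One subject's record: labels plus the regional morphometry vector."""

    subject_id: str
    group: str
    site: str
    values: np.ndarray  # mm, length n_regions, strictly positive


@dataclass
class SynthSpec:
    """Parameters of the synthetic cohort generator.

    ``decay_length`` (mm, per group) sets how fast inter-regional correlation
    falls with centroid distance: corr(i, j) = exp(-d_ij / L).  Smaller L
    means steeper decay.  ``subject_noise_sd`` is the marginal SD (mm) of the
    structured between-subject variation; ``iid_noise_sd`` adds independent
    measurement noise on top.  ``planted_partition`` optionally plants a
    modular correlation structure per group: within-module correlations are
    raised by ``module_boost``.
    """

    n_regions: int
    n_per_group: dict[str, int]
    decay_length: dict[str, float]          # mm, per group
    sites: tuple[str, ...] = ("siteA",)
    site_offsets: dict[str, float] = field(default_factory=dict)  # mm
    mean_ct: float = 2.75                   # mm, mid cortical-thickness range
    subject_noise_sd: float = 0.25          # mm
    iid_noise_sd: float = 0.0               # mm
    planted_partition: dict[str, np.ndarray] | None = None
    module_boost: float = 0.0
    coupling_heterogeneity: float = 0.0     # 0 = pure distance decay
    coupling_df: int = 12                   # latent draws behind the coupling
    rng_seed: int = 0

    def validate(self, parc: Parcellation) -> None:
        if self.n_regions != parc.n_regions:
            raise ValueError("spec n_regions does not match parcellation")
        for g, n in self.n_per_group.items():
            if n < 3:
                raise ValueError(f"group {g!r} needs >=3 subjects, got {n}")
            if g not in self.decay_length:
                raise ValueError(f"no decay_length for group {g!r}")
            if self.decay_length[g] <= 0:
                raise ValueError("decay_length must be positive")
        if self.subject_noise_sd <= 0:
            raise ValueError("subject_noise_sd must be positive")
        if self.planted_partition is not None:
            for g, labels in self.planted_partition.items():
                if len(labels) != self.n_regions:
                    raise ValueError(f"planted partition for {g!r} has wrong length")


def make_parcellation(n_per_hemisphere: int, rng_seed: int, *,
                      k_neighbors: int = 6) -> Parcellation:
    """Generate a mirrored two-hemisphere parcellation.

    Centroids are sampled on two hemispheric shells at MNI scale (radius
    ~70 mm), the left hemisphere an exact x-reflection of the right.  The
    neighbour graph is a symmetrised k-nearest-neighbour graph on centroids
    within each hemisphere, patched to be connected; both hemispheres share
    the same (mirrored) adjacency structure.

    Region ids 1..n are left-hemisphere, n+1..2n right-hemisphere; region i
    mirrors region i+n.
    """
    n = int(n_per_hemisphere)
    if n < 2:
        raise ValueError("n_per_hemisphere must be >= 2")
    rng = np.random.default_rng(rng_seed)

    # right-hemisphere shell: unit directions with a clear positive x
    # component (keeps the two shells separated), radius jittered ~70 mm
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.standard_normal((2 * n, 3))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        cand[:, 0] = np.abs(cand[:, 0])
        cand = cand[cand[:, 0] > 0.12]
        take = min(len(cand), n - got)
        pts[got:got + take] = cand[:take]
        got += take
    # shell radius 48 mm: compact enough that the linear fit of
    # exp(-d/L) against d steepens monotonically as L shrinks over the
    # working decay-length range (>= ~50 mm); see docs/methods.md
    radius = rng.normal(48.0, 2.5, size=n)
    right = pts * radius[:, None]
    left = right.copy()
    left[:, 0] *= -1.0

    centroids = np.vstack([left, right])
    region_ids = np.arange(1, 2 * n + 1)
    hemisphere = np.array(["L"] * n + ["R"] * n)
    mirror = np.concatenate([region_ids[n:], region_ids[:n]])

    adj = _knn_adjacency(right, min(k_neighbors, n - 1))
    neighbors: list[set[int]] = [set() for _ in range(2 * n)]
    for a, b in adj:
        neighbors[a].add(b + 1)            # left hemisphere, ids 1..n
        neighbors[b].add(a + 1)
        neighbors[n + a].add(n + b + 1)    # mirrored right hemisphere
        neighbors[n + b].add(n + a + 1)

    parc = Parcellation(
        region_ids=region_ids,
        hemisphere=hemisphere,
        mirror=mirror,
        centroids=centroids,
        neighbors=tuple(frozenset(s) for s in neighbors),
    )
    parc.validate()
    return parc


def _knn_adjacency(points: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Symmetrised kNN edges (0-based), patched to a connected graph."""
    n = len(points)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k + 1)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))

    # bridge components greedily via the closest inter-component pair
    while True:
        comp = _components(n, edges)
        if len(comp) == 1:
            break
        c0 = comp[0]
        best = None
        for other in comp[1:]:
            for i in c0:
                for j in other:
                    d = np.linalg.norm(points[i] - points[j])
                    if best is None or d < best[0]:
                        best = (d, min(i, j), max(i, j))
        edges.add((best[1], best[2]))
    return sorted(edges)


def _components(n: int, edges) -> list[list[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=len, reverse=True)


def coupling_matrix(n_regions: int, heterogeneity: float, df: int,
                    rng_seed: int) -> np.ndarray:
    """Intrinsic inter-regional coupling strengths, shared across groups.

    A pure distance-decay correlation ranks every region pair by distance
    alone, so thresholded networks would be identical across decay rates.
    Real structural covariance has strong and weak couplings at every
    distance; this emulates that by blending a wide-spread random
    correlation matrix (sample correlation of ``df`` latent draws — small
    df, wide spread) into the uniform coupling:
    S = (1 - h) * 1 + h * corr.  S is PSD, so the Schur product with the
    decay kernel stays PSD.  h = 0 recovers the pure decay model.
    """
    if not (0 <= heterogeneity <= 1):
        raise ValueError("coupling heterogeneity must be in [0, 1]")
    if heterogeneity == 0:
        return np.ones((n_regions, n_regions))
    rng = np.random.default_rng(rng_seed)
    X = rng.standard_normal((df, n_regions))
    S = np.corrcoef(X, rowvar=False)
    return (1 - heterogeneity) * np.ones_like(S) + heterogeneity * S


def population_correlation(parc: Parcellation, decay_length: float,
                           planted_labels: np.ndarray | None = None,
                           module_boost: float = 0.0,
                           coupling: np.ndarray | None = None) -> np.ndarray:
    """Population inter-regional correlation matrix for one group.

    Exponential distance decay exp(-d_ij / L), optionally modulated by an
    intrinsic coupling matrix (Schur product) and/or an additive
    within-module boost; repaired to positive definiteness by diagonal
    loading if the boost breaks it.
    """
    D = squareform(pdist(parc.centroids))
    if np.isinf(decay_length):
        C = np.ones_like(D)
    else:
        C = np.exp(-D / float(decay_length))
    if coupling is not None:
        C = C * coupling
    if planted_labels is not None and module_boost != 0.0:
        labels = np.asarray(planted_labels)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(C), dtype=bool)
        C = C + module_boost * (same & off)
        np.clip(C, -0.995, 0.995, out=C)
    np.fill_diagonal(C, 1.0)
    return _ensure_psd(C)


def _ensure_psd(C: np.ndarray, floor: float = 1e-10, max_iter: int = 50) -> np.ndarray:
    """Diagonal-loading repair: shrink toward the identity until PSD."""
    for _ in range(max_iter):
        w_min = float(np.linalg.eigvalsh(C)[0])
        if w_min > floor:
            return C
        lam = abs(w_min) + 1e-6
        logger.info("correlation matrix not PSD (min eig %.3g); diagonal loading %.3g",
                    w_min, lam)
        C = (C + lam * np.eye(len(C))) / (1.0 + lam)
    raise RuntimeError("positive-definiteness repair failed")


def simulate_cohort(parc: Parcellation, spec: SynthSpec) -> list[Subject]:
    """Draw a cohort of subjects from the generator defined by ``spec``.

    Per group, subject vectors are multivariate normal with the group's
    distance-decay (plus planted-module) correlation, marginal SD
    ``subject_noise_sd``, mean ``mean_ct`` plus the subject's site offset,
    and optional iid measurement noise.
    """
    spec.validate(parc)
    rng = np.random.default_rng(spec.rng_seed)
    # intrinsic coupling drawn once: the same latent connectome for every
    # group, with only the decay rate differing between groups
    S = None
    if spec.coupling_heterogeneity > 0:
        S = coupling_matrix(parc.n_regions, spec.coupling_heterogeneity,
                            spec.coupling_df, rng_seed=spec.rng_seed + 777)
    subjects: list[Subject] = []
    for group in spec.n_per_group:
        n_sub = spec.n_per_group[group]
        labels = None
        if spec.planted_partition is not None:
            labels = spec.planted_partition.get(group)
        C = population_correlation(parc, spec.decay_length[group],
                                   labels, spec.module_boost, coupling=S)
        L = np.linalg.cholesky(C)
        z = rng.standard_normal((n_sub, parc.n_regions))
        structured = spec.subject_noise_sd * (z @ L.T)
        if spec.iid_noise_sd > 0:
            structured = structured + rng.normal(
                0.0, spec.iid_noise_sd, size=structured.shape)
        for s in range(n_sub):
            site = spec.sites[s % len(spec.sites)]
            offset = spec.site_offsets.get(site, 0.0)
            values = spec.mean_ct + offset + structured[s]
            if np.any(values <= 0) or not np.all(np.isfinite(values)):
                raise RuntimeError(
                    "generated morphometry not strictly positive; lower the "
                    "noise SDs or raise mean_ct")
            subjects.append(Subject(
                subject_id=f"{group}-{s:04d}", group=group, site=site,
                values=values))
    return subjects


# ---------------------------------------------------------------------------
# TSV round-trip — the pipeline's canonical on-disk inputs


def write_parcellation_tsv(parc: Parcellation, path) -> None:
    df = pd.DataFrame({
        "region_id": parc.region_ids,
        "hemisphere": parc.hemisphere,
        "mirror_id": parc.mirror,
        "x": parc.centroids[:, 0],
        "y": parc.centroids[:, 1],
        "z": parc.centroids[:, 2],
        "neighbors": [",".join(str(j) for j in sorted(nb))
                      for nb in parc.neighbors],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_parcellation_tsv(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("region_id").reset_index(drop=True)
    neighbors = tuple(
        frozenset(int(t) for t in str(s).split(",") if t)
        for s in df["neighbors"]
    )
    parc = Parcellation(
        region_ids=df["region_id"].to_numpy(int),
        hemisphere=df["hemisphere"].to_numpy(str),
        mirror=df["mirror_id"].to_numpy(int),
        centroids=df[["x", "y", "z"]].to_numpy(float),
        neighbors=neighbors,
    )
    parc.validate()
    return parc


def write_cohort_tsv(cohort: list[Subject], path) -> None:
    n_regions = len(cohort[0].values)
    cols = {"subject_id": [s.subject_id for s in cohort],
            "group": [s.group for s in cohort],
            "site": [s.site for s in cohort]}
    values = np.vstack([s.values for s in cohort])
    for r in range(n_regions):
        cols[f"v_{r + 1}"] = values[:, r]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_cohort_tsv(path) -> list[Subject]:
    df = pd.read_csv(path, sep="\t")
    vcols = [c for c in df.columns if c.startswith("v_")]
    vcols.sort(key=lambda c: int(c.split("_")[1]))
    return [
        Subject(subject_id=str(row["subject_id"]), group=str(row["group"]),
                site=str(row["site"]),
                values=row[vcols].to_numpy(float))
        for _, row in df.iterrows()
    ]
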