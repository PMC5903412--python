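"""Distance decay of structural covariance: ANCOVA on group slopes.

Inter-regional correlation strength falls off with the Euclidean distance
between region centroids.  This module quantifies that decay per group and
tests whether the slopes differ: all unordered region pairs (i < j) are
stacked as observations (r_ij, d_ij, group), a linear model with a separate
intercept and slope per group is fitted, and slope homogeneity is tested
with an F-test of the full model against a common-slope model.  Post hoc
pairwise slope t-tests identify which groups differ.

Pair observations are treated as independent in the F-test; the dependence
among correlations sharing a region is a known property of this design and
is documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import pdist, squareform

from .preprocess import GroupCovariance
from .synth import Parcellation


@dataclass
class SlopeModel:
    """Per-group linear decay fits plus the slope-homogeneity test."""

    groups: tuple[str, ...]
    intercept: dict[str, float]
    slope: dict[str, float]                  # correlation units per mm
    slope_se: dict[str, float]
    F_stat: float
    df_num: int
    df_den: int
    p_overall: float
    posthoc: dict[tuple[str, str], tuple[float, float]]  # (t, p two-sided)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"group": g, "intercept": self.intercept[g],
                 "slope": self.slope[g], "slope_se": self.slope_se[g]}
                for g in self.groups]
        return pd.DataFrame(rows)


def centroid_distances(parc: Parcellation) -> np.ndarray:
    """Euclidean distance (mm) between region centroids, (N, N)."""
    return squareform(pdist(parc.centroids))


def pair_table(covs: list[GroupCovariance], D: np.ndarray,
               fisher_z: bool = False) -> pd.DataFrame:
    """Stack all unordered region pairs per group as (group, d, r) rows."""
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    frames = []
    for cov in covs:
        if cov.R.shape != D.shape:
            raise ValueError("covariance and distance matrices differ in size")
        r = cov.R[iu]
        if fisher_z:
            r = np.arctanh(np.clip(r, -0.999999, 0.999999))
        frames.append(pd.DataFrame({"group": cov.group, "d": D[iu], "r": r}))
    return pd.concat(frames, ignore_index=True)


def slope_ancova(covs: list[GroupCovariance], D: np.ndarray, *,
                 fisher_z: bool = False) -> SlopeModel:
    """Test homogeneity of the correlation-vs-distance slopes across groups.

    Full model: one intercept and one slope per group (the per-group slope
    equals a per-group OLS fit).  Reduced model: per-group intercepts,
    common slope.  F has (G - 1, n_obs - 2G) degrees of freedom.  Post hoc:
    pairwise slope-difference t-tests from the full model's covariance.
    """
    if len(covs) < 2:
        raise ValueError("need at least 2 groups")
    table = pair_table(covs, D, fisher_z=fisher_z)
    groups = tuple(cov.group for cov in covs)
    G = len(groups)
    n_obs = len(table)

    # design: [indicator_g ... , indicator_g * d ...]
    X = np.zeros((n_obs, 2 * G))
    for k, g in enumerate(groups):
        mask = (table["group"] == g).to_numpy()
        X[mask, k] = 1.0
        X[mask, G + k] = table.loc[mask, "d"].to_numpy()
    y = table["r"].to_numpy()

    beta, rss_full, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2 * G:
        raise ValueError("rank-deficient design (degenerate distances?)")
    rss_full = float(rss_full[0])
    df_den = n_obs - 2 * G

    Xr = np.column_stack([X[:, :G], X[:, G:].sum(axis=1)])
    _, rss_red, rank_r, _ = np.linalg.lstsq(Xr, y, rcond=None)
    if rank_r < G + 1:
        raise ValueError("rank-deficient reduced design")
    rss_red = float(rss_red[0])

    df_num = G - 1
    sigma2 = rss_full / df_den
    F = ((rss_red - rss_full) / df_num) / sigma2
    p_overall = float(sstats.f.sf(F, df_num, df_den))

    XtX_inv = np.linalg.inv(X.T @ X)
    cov_beta = sigma2 * XtX_inv

    intercept = {g: float(beta[k]) for k, g in enumerate(groups)}
    slope = {g: float(beta[G + k]) for k, g in enumerate(groups)}
    slope_se = {g: float(np.sqrt(cov_beta[G + k, G + k]))
                for k, g in enumerate(groups)}

    posthoc: dict[tuple[str, str], tuple[float, float]] = {}
    for (ka, ga), (kb, gb) in combinations(enumerate(groups), 2):
        c = np.zeros(2 * G)
        c[G + ka] = 1.0
        c[G + kb] = -1.0
        se = float(np.sqrt(c @ cov_beta @ c))
        t = float((beta[G + ka] - beta[G + kb]) / se)
        p = float(2 * sstats.t.sf(abs(t), df_den))
        posthoc[(ga, gb)] = (t, p)

    return SlopeModel(groups=groups, intercept=intercept, slope=slope,
                      slope_se=slope_se, F_stat=float(F), df_num=df_num,
                      df_den=df_den, p_overall=p_overall, posthoc=posthoc)


def plot_decay(covs: list[GroupCovariance], D: np.ndarray, model: SlopeModel,
               path=None):
    """Scatter of correlation vs distance with per-group linear fits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = pair_table(covs, D)
    fig, ax = plt.subplots(figsize=(6, 4))
    for g in model.groups:
        sub = table[table["group"] == g]
        ax.scatter(sub["d"], sub["r"], s=2, alpha=0.15, label=None)
        xs = np.linspace(sub["d"].min(), sub["d"].max(), 50)
        ax.plot(xs, model.intercept[g] + model.slope[g] * xs, label=g, lw=2)
    ax.set_xlabel("inter-centroid distance (mm)")
    ax.set_ylabel("inter-regional correlation")
    ax.legend(title="group")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
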