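"""Cohort preprocessing and group-wise structural covariance.

Three stages, mirroring the standard structural-covariance workflow on
multi-site morphometry:

1. ``regress_site`` — remove additive scanner-site effects per region,
   pooling all groups, and restore the pooled region mean so values stay on
   the original (mm) scale.
2. ``exclude_outliers`` — drop subjects whose across-region variability is
   more than 2 group-SDs from their group's mean variability.
3. ``group_covariance`` — per-group inter-regional Pearson correlation
   matrix, the "structural covariance" of the group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synth import Subject


@dataclass
class GroupCovariance:
    """Inter-regional Pearson correlation matrix for one group."""

    group: str
    n_subjects: int
    R: np.ndarray  # (N, N), symmetric, unit diagonal


def _values_matrix(cohort: list[Subject]) -> np.ndarray:
    return np.vstack([s.values for s in cohort])


def regress_site(cohort: list[Subject],
                 known_sites: set[str] | None = None) -> list[Subject]:
    """Regress site out of each region's values, restoring the pooled mean.

    Fits ``value ~ site`` (categorical) per region with all groups pooled,
    and returns residuals plus the pooled sample mean of that region.  With
    OLS on a saturated categorical design this is exactly: subtract the
    site mean, add the grand mean.  Sites with a single subject get a zero
    residual; a single-site cohort is returned unchanged.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects for site regression")
    sites = np.array([s.site for s in cohort])
    if known_sites is not None:
        unknown = set(sites) - set(known_sites)
        if unknown:
            raise ValueError(f"unknown site labels: {sorted(unknown)}")
    X = _values_matrix(cohort)
    grand_mean = X.mean(axis=0)
    adjusted = np.empty_like(X)
    for site in np.unique(sites):
        mask = sites == site
        adjusted[mask] = X[mask] - X[mask].mean(axis=0) + grand_mean
    return [replace(s, values=adjusted[i]) for i, s in enumerate(cohort)]


def exclude_outliers(cohort: list[Subject],
                     n_sd: float = 2.0) -> tuple[list[Subject], list[str]]:
    """Remove subjects with extreme across-region variability.

    A subject's variability is the SD of their regional values.  Within each
    group, subjects whose variability deviates from the group mean
    variability by strictly more than ``n_sd`` group-SDs are excluded (a
    subject at exactly the threshold is kept).  The rule is applied once,
    not iterated.
    """
    groups = sorted({s.group for s in cohort})
    kept: list[Subject] = []
    excluded: list[str] = []
    for g in groups:
        members = [s for s in cohort if s.group == g]
        if len(members) < 4:
            raise ValueError(f"group {g!r} needs >=4 subjects for screening")
        variability = np.array([np.std(s.values) for s in members])
        mu, sd = variability.mean(), variability.std()
        cut = n_sd * sd * (1 + 1e-9)  # "exactly n_sd SDs" is kept
        for s, v in zip(members, variability):
            if sd > 0 and abs(v - mu) > cut:
                excluded.append(s.subject_id)
            else:
                kept.append(s)
        n_left = sum(1 for s in kept if s.group == g)
        if n_left < 3:
            raise ValueError(
                f"group {g!r} reduced to {n_left} subjects after exclusion; "
                "correlation undefined")
    order = {s.subject_id: i for i, s in enumerate(cohort)}
    kept.sort(key=lambda s: order[s.subject_id])
    return kept, excluded


def pearson_correlation(values: np.ndarray, group: str = "") -> np.ndarray:
    """Inter-regional Pearson correlation of a subjects x regions matrix."""
    sd = values.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(
            f"zero-variance region(s) {[int(z) + 1 for z in zero]}"
            + (f" in group {group!r}" if group else ""))
    R = np.corrcoef(values, rowvar=False)
    R = (R + R.T) / 2.0
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    return R


def group_covariance(cohort: list[Subject]) -> dict[str, GroupCovariance]:
    """Group-wise structural covariance (Pearson correlation) matrices."""
    out: dict[str, GroupCovariance] = {}
    for g in sorted({s.group for s in cohort}):
        members = [s for s in cohort if s.group == g]
        if len(members) < 3:
            raise ValueError(f"group {g!r} needs >=3 subjects")
        values = _values_matrix(members)
        out[g] = GroupCovariance(group=g, n_subjects=len(members),
                                 R=pearson_correlation(values, g))
    return out
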