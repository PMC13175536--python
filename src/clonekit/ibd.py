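"""Isolation-by-distance tests.

Within patches: a Mantel test (Spearman rank correlation, permutation null)
between Bruvo genetic distances of MLLs and Euclidean distances between their
ramet centroids.  Among patches: ordinary least squares of linearized
pairwise differentiation ``D/(1-D)`` on great-circle (haversine) distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

from .core import GenotypeTable, PatchGeo
from .distances import DistanceMatrix, euclidean_matrix
from .mll import MLLPartition

#: Sphere radius used for great-circle distances (WGS84 equatorial radius, m).
EARTH_RADIUS_M = 6_378_137.0


@dataclass
class CentroidSet:
    """Per-MLL mean ramet coordinates within one patch."""

    patch: str
    mll_ids: np.ndarray
    xy: np.ndarray  # (n_mll, 2)
    n_ramets: np.ndarray
    multi_ramet: np.ndarray  # True where the MLL has >= 2 ramets in the patch


def mll_centroids(partition: MLLPartition, table: GenotypeTable, patch: str) -> CentroidSet:
    """Arithmetic-mean ramet coordinates per MLL within ``patch``."""
    mask = table.patch_id == patch
    if not mask.any():
        raise ValueError(f"no stems in patch {patch!r}")
    labels = partition.labels[mask]
    xs = table.x[mask].astype(float)
    ys = table.y[mask].astype(float)
    mlls = np.unique(labels)
    xy = np.empty((len(mlls), 2))
    n_ramets = np.empty(len(mlls), dtype=int)
    for i, m in enumerate(mlls):
        sel = labels == m
        xy[i] = (xs[sel].mean(), ys[sel].mean())
        n_ramets[i] = int(sel.sum())
    return CentroidSet(
        patch=patch, mll_ids=mlls, xy=xy, n_ramets=n_ramets, multi_ramet=n_ramets >= 2
    )


@dataclass
class MantelResult:
    statistic: float
    n_perm: int
    p_value: float
    seed: int | None = None


def mantel_spearman(
    d_gen: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> MantelResult:
    """Mantel test with Spearman's rank correlation.

    The null distribution comes from simultaneously permuting the rows and
    columns of the geographic matrix; the one-sided p-value for positive
    association is ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if list(d_gen.ids) != list(d_geo.ids):
        raise ValueError("distance matrices must share the same ids in order")
    n = d_gen.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 ids")
    iu = np.triu_indices(n, k=1)
    a = d_gen.values[iu]
    if np.ptp(a) == 0 or np.ptp(d_geo.values[iu]) == 0:
        warnings.warn("constant distance matrix; Mantel statistic undefined")
        return MantelResult(float("nan"), n_perm, float("nan"))
    ra = rankdata(a)
    ra = (ra - ra.mean()) / ra.std()

    def stat(mat: np.ndarray) -> float:
        rb = rankdata(mat[iu])
        rb = (rb - rb.mean()) / rb.std()
        return float((ra * rb).mean())

    observed = stat(d_geo.values)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(d_geo.values[np.ix_(perm, perm)]) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(statistic=observed, n_perm=n_perm, p_value=p)


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres on a sphere of radius 6,378,137 m."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def haversine_matrix(geo: PatchGeo) -> DistanceMatrix:
    k = len(geo.patch_id)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = haversine_m(
                geo.latitude[i], geo.longitude[i], geo.latitude[j], geo.longitude[j]
            )
    return DistanceMatrix(ids=geo.patch_id, values=values, metric="haversine")


@dataclass
class IbdRegression:
    slope: float
    slope_se: float
    p_value: float
    intercept: float
    r_squared: float
    n_pairs: int


def ibd_regression(
    pairwise_diff: np.ndarray, pairwise_dist: np.ndarray
) -> IbdRegression:
    """OLS of linearized differentiation ``D/(1-D)`` on pairwise distance.

    Both arguments are symmetric k x k matrices over the same patch order;
    each unordered pair enters once.  Pairs with ``D = 1`` (infinite
    linearized value) are excluded with a warning.
    """
    k = pairwise_diff.shape[0]
    if k < 3:
        raise ValueError("need >= 3 patches (>= 3 pairs)")
    iu = np.triu_indices(k, k=1)
    d = np.asarray(pairwise_diff, dtype=float)[iu]
    dist = np.asarray(pairwise_dist, dtype=float)[iu]
    keep = np.isfinite(d) & np.isfinite(dist) & (d < 1.0)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} pair(s) excluded (D = 1 or non-finite)")
    d, dist = d[keep], dist[keep]
    if len(d) < 3:
        raise ValueError("fewer than 3 usable pairs")
    if np.ptp(dist) == 0:
        warnings.warn("all pairwise distances equal; slope undefined")
        return IbdRegression(float("nan"), float("nan"), float("nan"),
                             float("nan"), float("nan"), len(d))
    y = d / (1.0 - d)
    X = sm.add_constant(dist)
    fit = sm.OLS(y, X).fit()
    return IbdRegression(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n_pairs=len(d),
    )


def within_patch_mantel(
    table: GenotypeTable,
    partition: MLLPartition,
    patch: str,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    multi_ramet_only: bool = False,
) -> MantelResult:
    """Mantel IBD test inside one patch: Bruvo distances between MLL
    representatives vs Euclidean distances between MLL ramet centroids.

    ``multi_ramet_only`` restricts to MLLs with two or more ramets (strict
    mode); by default every MLL enters, singletons at their own sample point.
    """
    from .distances import pairwise_matrix
    from .popgen import mll_representatives

    cents = mll_centroids(partition, table, patch)
    sel = cents.multi_ramet if multi_ramet_only else np.ones(len(cents.mll_ids), bool)
    mlls = cents.mll_ids[sel]
    if len(mlls) < 4:
        raise ValueError(f"patch {patch!r}: fewer than 4 MLLs for a Mantel test")
    mask = np.isin(partition.labels, mlls) & (table.patch_id == patch)
    sub = table.subset(np.flatnonzero(mask))
    sub_part = MLLPartition(
        labels=partition.labels[mask],
        threshold=partition.threshold,
        ids=sub.sample_id,
        patch_id=sub.patch_id,
    )
    reps = mll_representatives(sub, sub_part)
    # order representatives to match centroid order
    order = []
    rep_labels = []
    for i in range(reps.n_stems):
        lab = sub_part.labels[list(sub.sample_id).index(reps.sample_id[i])]
        rep_labels.append(int(lab))
    rep_labels = np.array(rep_labels)
    order = np.array([int(np.flatnonzero(rep_labels == m)[0]) for m in mlls])
    reps = reps.subset(order)
    d_gen = pairwise_matrix(reps, metric="bruvo")
    d_gen.ids = np.asarray([str(m) for m in mlls], dtype=object)
    d_geo = euclidean_matrix([str(m) for m in mlls], cents.xy[sel])
    return mantel_spearman(d_gen, d_geo, n_perm=n_perm, seed=seed)
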