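"""Pairwise genetic distances between diploid multilocus genotypes.

Two microsatellite distances built on the stepwise mutation model:

* **stepwise** — per locus, the minimum over the two diploid allele pairings
  of the summed absolute repeat-count differences; multilocus value is the
  sum over loci scored in both genotypes.  Integer-valued; this is the scale
  on which the multilocus-lineage threshold is expressed.
* **bruvo** — per-allele distance ``1 - 2**(-|x - y|)``, per-locus value the
  minimum over the two pairings of the mean of the two allele distances,
  multilocus value the mean over shared loci.  Bounded in [0, 1].

Loci missing in either genotype are skipped.  A pair with no shared scored
locus is *incomparable*: its distance is recorded as ``inf`` and
``n_loci_used`` is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeTable

METRICS = ("stepwise", "bruvo", "euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair locus counts."""

    ids: np.ndarray
    values: np.ndarray
    metric: str
    n_loci_used: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def incomparable_pairs(self) -> np.ndarray:
        """Boolean matrix: True for off-diagonal pairs with no shared locus."""
        if self.n_loci_used is None:
            return np.zeros_like(self.values, dtype=bool)
        out = self.n_loci_used == 0
        np.fill_diagonal(out, False)
        return out

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def histogram(self) -> np.ndarray:
        """Integer-binned histogram of finite pairwise distances (stepwise scale)."""
        d = self.condensed()
        d = d[np.isfinite(d)]
        if d.size == 0:
            return np.zeros(1, dtype=int)
        return np.bincount(np.rint(d).astype(int))

    def subset(self, index: np.ndarray) -> "DistanceMatrix":
        index = np.asarray(index)
        return DistanceMatrix(
            ids=self.ids[index],
            values=self.values[np.ix_(index, index)],
            metric=self.metric,
            n_loci_used=None
            if self.n_loci_used is None
            else self.n_loci_used[np.ix_(index, index)],
        )


def _locus_pair_distances(a: np.ndarray, b: np.ndarray, power: int = 1) -> float:
    """Stepwise distance at one locus: min over the two diploid pairings."""
    same = abs(a[0] - b[0]) ** power + abs(a[1] - b[1]) ** power
    cross = abs(a[0] - b[1]) ** power + abs(a[1] - b[0]) ** power
    return min(same, cross)


def stepwise_distance(
    g1: np.ndarray, g2: np.ndarray, power: int = 1
) -> float:
    """Summed stepwise distance between two diploid multilocus genotypes.

    ``g1``/``g2`` are ``(n_loci, 2)`` arrays in repeat units with -1 marking
    missing alleles.  Loci missing in either genotype are skipped; if no locus
    is shared the pair is incomparable and ``inf`` is returned.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    total = 0.0
    used = 0
    for j in range(g1.shape[0]):
        if (g1[j] < 0).any() or (g2[j] < 0).any():
            continue
        total += _locus_pair_distances(g1[j], g2[j], power)
        used += 1
    return float(total) if used else float("inf")


def bruvo_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Bruvo's distance (mean over shared loci) between two diploid genotypes."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    vals = []
    for j in range(g1.shape[0]):
        if (g1[j] < 0).any() or (g2[j] < 0).any():
            continue

        def m(x: int, y: int) -> float:
            return 1.0 - 2.0 ** (-abs(int(x) - int(y)))

        same = 0.5 * (m(g1[j, 0], g2[j, 0]) + m(g1[j, 1], g2[j, 1]))
        cross = 0.5 * (m(g1[j, 0], g2[j, 1]) + m(g1[j, 1], g2[j, 0]))
        vals.append(min(same, cross))
    return float(np.mean(vals)) if vals else float("inf")


def _pairwise_genetic(
    table: GenotypeTable, metric: str, power: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized all-pairs computation, one locus at a time."""
    n = table.n_stems
    acc = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for j in range(table.n_loci):
        a = table.alleles[:, j, :].astype(float)  # (n, 2)
        ok = (a >= 0).all(axis=1)
        if metric == "stepwise":
            d00 = np.abs(a[:, None, 0] - a[None, :, 0]) ** power
            d11 = np.abs(a[:, None, 1] - a[None, :, 1]) ** power
            d01 = np.abs(a[:, None, 0] - a[None, :, 1]) ** power
            d10 = np.abs(a[:, None, 1] - a[None, :, 0]) ** power
            loc = np.minimum(d00 + d11, d01 + d10)
        else:  # bruvo
            m00 = 1.0 - 2.0 ** (-np.abs(a[:, None, 0] - a[None, :, 0]))
            m11 = 1.0 - 2.0 ** (-np.abs(a[:, None, 1] - a[None, :, 1]))
            m01 = 1.0 - 2.0 ** (-np.abs(a[:, None, 0] - a[None, :, 1]))
            m10 = 1.0 - 2.0 ** (-np.abs(a[:, None, 1] - a[None, :, 0]))
            loc = np.minimum(0.5 * (m00 + m11), 0.5 * (m01 + m10))
        pair_ok = ok[:, None] & ok[None, :]
        acc += np.where(pair_ok, loc, 0.0)
        used += pair_ok
    with np.errstate(invalid="ignore"):
        values = np.where(used > 0, acc if metric == "stepwise" else acc / np.maximum(used, 1), np.inf)
    np.fill_diagonal(values, 0.0)
    return values, used


def pairwise_matrix(
    table: GenotypeTable, metric: str = "stepwise", power: int = 1
) -> DistanceMatrix:
    """Full symmetric pairwise distance matrix over the stems of ``table``.

    ``metric="euclidean"`` operates on the grid coordinates instead of the
    genotypes (used for spatial distances between stems or centroids).
    ``power`` applies to the per-allele step differences of the stepwise
    metric (1 = absolute steps, 2 = squared steps).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if table.n_stems < 2:
        raise ValueError("need at least 2 rows for a pairwise matrix")
    if metric == "euclidean":
        xy = np.column_stack([table.x, table.y]).astype(float)
        diff = xy[:, None, :] - xy[None, :, :]
        values = np.sqrt((diff**2).sum(axis=2))
        return DistanceMatrix(ids=table.sample_id, values=values, metric=metric)
    values, used = _pairwise_genetic(table, metric, power)
    return DistanceMatrix(
        ids=table.sample_id, values=values, metric=metric, n_loci_used=used
    )


def euclidean_matrix(ids: np.ndarray, xy: np.ndarray) -> DistanceMatrix:
    """Euclidean distance matrix over arbitrary 2-D points (e.g. MLL centroids)."""
    xy = np.asarray(xy, dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(ids=np.asarray(ids, dtype=object), values=values, metric="euclidean")
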