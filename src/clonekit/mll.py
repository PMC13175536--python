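"""Multilocus-lineage (MLL) assignment and ramets-per-genet summaries.

Sampled stems are grouped into MLLs — putative genets — by thresholding the
pairwise stepwise distance matrix: any two stems at distance less than or
equal to the threshold belong to the same MLL, and the grouping is the
single-linkage (connected-component) closure of that pairwise rule.  The
threshold absorbs fragment-scoring error, null alleles and recent somatic
mutation among ramets of one genet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import GenotypeTable
from .distances import DistanceMatrix


@dataclass
class ThresholdSuggestion:
    """Suggested MLL threshold plus the evidence behind it."""

    threshold: int
    histogram: np.ndarray
    smoothed: np.ndarray
    clonal_mode: int
    sexual_mode: int
    unimodal: bool = False

    def __int__(self) -> int:
        return self.threshold


def suggest_threshold(hist: np.ndarray, smooth_window: int = 3) -> ThresholdSuggestion:
    """Pick an MLL threshold from the histogram of pairwise stepwise distances.

    The histogram of a partially clonal sample is bimodal: a clonal peak at or
    near zero (ramet pairs, scoring error, somatic mutation) and a sexual peak
    at large distances (genet pairs).  The suggestion is the first local
    minimum of the lightly smoothed histogram between the two modes; when the
    valley is an empty gap, the smallest zero-count distance after the clonal
    peak.  A unimodal histogram yields 0 (strict genotype identity) with a
    warning.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.size == 0 or hist.sum() == 0:
        warnings.warn("empty distance histogram; threshold 0")
        return ThresholdSuggestion(0, hist, hist, 0, 0, unimodal=True)
    smoothed = uniform_filter1d(hist, size=smooth_window, mode="nearest")

    # clonal mode: local maximum nearest zero
    clonal = 0
    while clonal + 1 < len(smoothed) and smoothed[clonal + 1] > smoothed[clonal]:
        clonal += 1
    # descend from the clonal mode to the valley floor
    valley = clonal
    while valley + 1 < len(smoothed) and smoothed[valley + 1] <= smoothed[valley]:
        valley += 1
    if valley + 1 >= len(smoothed):
        warnings.warn("unimodal distance histogram; threshold 0 (strict identity)")
        return ThresholdSuggestion(0, hist, smoothed, clonal, clonal, unimodal=True)
    sexual = valley + 1 + int(np.argmax(smoothed[valley + 1 :]))
    if smoothed[sexual] <= smoothed[valley]:
        warnings.warn("unimodal distance histogram; threshold 0 (strict identity)")
        return ThresholdSuggestion(0, hist, smoothed, clonal, sexual, unimodal=True)
    # prefer the first empty raw bin on the descent; else the valley floor
    for i in range(clonal + 1, sexual):
        if hist[i] == 0:
            return ThresholdSuggestion(i, hist, smoothed, clonal, sexual)
    return ThresholdSuggestion(valley, hist, smoothed, clonal, sexual)


@dataclass
class MLLPartition:
    """Assignment of every stem to an MLL.

    ``labels[i]`` is the MLL id of stem ``i``; ids are assigned in order of
    first-encountered stem.  ``incomparable`` flags stems that shared no
    scored locus with any other stem and were forced into singleton MLLs.
    """

    labels: np.ndarray
    threshold: int
    ids: np.ndarray
    patch_id: np.ndarray
    incomparable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.incomparable is None:
            self.incomparable = np.zeros(len(self.labels), dtype=bool)

    @property
    def n_stems(self) -> int:
        return len(self.labels)

    @property
    def n_mll(self) -> int:
        return len(np.unique(self.labels))

    @property
    def ramet_counts(self) -> dict[int, int]:
        u, c = np.unique(self.labels, return_counts=True)
        return dict(zip(u.tolist(), c.tolist()))

    def per_patch_mlls(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for p in dict.fromkeys(self.patch_id):
            mask = self.patch_id == p
            out[p] = np.unique(self.labels[mask]).tolist()
        return out

    @property
    def shared_mlls(self) -> list[int]:
        """MLLs observed in more than one patch."""
        seen: dict[int, set] = {}
        for lab, p in zip(self.labels, self.patch_id):
            seen.setdefault(int(lab), set()).add(p)
        return sorted(m for m, ps in seen.items() if len(ps) > 1)

    def patch_counts(self, patch: str) -> np.ndarray:
        """Ramets per MLL within one patch (MLLs present in that patch)."""
        mask = self.patch_id == patch
        _, c = np.unique(self.labels[mask], return_counts=True)
        return c


def assign_mlls(dm: DistanceMatrix, threshold: int) -> MLLPartition:
    """Single-linkage MLL assignment at a stepwise-distance threshold.

    Connected components of the graph with an edge between every comparable
    pair at distance <= threshold.  Because the pairwise rule chains, stems
    further apart than the threshold can share an MLL through intermediates
    (documented transitive-closure behaviour).  Incomparable stems (no shared
    locus with anyone) become flagged singletons.
    """
    n = dm.n
    comparable = (
        np.ones((n, n), dtype=bool) if dm.n_loci_used is None else dm.n_loci_used > 0
    )
    adj = (dm.values <= threshold) & comparable
    np.fill_diagonal(adj, True)
    _, raw = connected_components(csr_matrix(adj), directed=False)
    # relabel in order of first-encountered stem
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    incomparable = (
        np.zeros(n, dtype=bool)
        if dm.n_loci_used is None
        else (dm.n_loci_used > 0).sum(axis=1) <= 1  # only the diagonal
    )
    # re-derive patch ids lazily: caller attaches them
    return MLLPartition(
        labels=labels,
        threshold=int(threshold),
        ids=dm.ids,
        patch_id=np.asarray(["?"] * n, dtype=object),
        incomparable=incomparable,
    )


def assign_mlls_table(
    table: GenotypeTable, dm: DistanceMatrix, threshold: int
) -> MLLPartition:
    """As :func:`assign_mlls` but carrying the table's patch labels."""
    p = assign_mlls(dm, threshold)
    p.patch_id = table.patch_id
    return p


def _boot_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int) -> tuple[float, float]:
    if len(values) == 0:
        return (float("nan"), float("nan"))
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return tuple(np.percentile(means, [2.5, 97.5]))  # type: ignore[return-value]


def ramet_summary(
    partition: MLLPartition,
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-patch max/mean/median ramets per MLL, overall and for MLLs with
    two or more ramets, with percentile-bootstrap 95% CIs for the means
    (normal-theory CIs are also emitted for comparison)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    patches = list(dict.fromkeys(partition.patch_id))
    for patch in patches + ["__total__"]:
        if patch == "__total__":
            _, counts = np.unique(partition.labels, return_counts=True)
        else:
            counts = partition.patch_counts(patch)
        counts = np.asarray(counts, dtype=float)
        multi = counts[counts >= 2]
        lo, hi = _boot_ci(counts, rng, n_boot)
        lo2, hi2 = _boot_ci(multi, rng, n_boot)

        def _norm_ci(v: np.ndarray) -> tuple[float, float]:
            if len(v) < 2:
                return (float("nan"), float("nan"))
            se = v.std(ddof=1) / np.sqrt(len(v))
            return (v.mean() - 1.96 * se, v.mean() + 1.96 * se)

        nlo, nhi = _norm_ci(counts)
        rows.append(
            {
                "patch": "total" if patch == "__total__" else patch,
                "n_mll": len(counts),
                "max_ramets": counts.max() if len(counts) else np.nan,
                "mean_ramets": counts.mean() if len(counts) else np.nan,
                "mean_ci_lo": lo,
                "mean_ci_hi": hi,
                "mean_ci_lo_normal": nlo,
                "mean_ci_hi_normal": nhi,
                "median_ramets": np.median(counts) if len(counts) else np.nan,
                "mean_ramets_ge2": multi.mean() if len(multi) else np.nan,
                "mean_ge2_ci_lo": lo2,
                "mean_ge2_ci_hi": hi2,
                "median_ramets_ge2": np.median(multi) if len(multi) else np.nan,
            }
        )
    return pd.DataFrame(rows)
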