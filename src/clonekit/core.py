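"""Core containers for clonal population-genetic data.

A sampled stem (ramet) is one row of a :class:`GenotypeTable`: an id, a patch,
integer grid coordinates in metres, and a diploid genotype at each
microsatellite locus with allele states recorded in repeat units.  Missing
data are whole-locus: if either allele of a locus is unscored the locus
genotype is treated as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Internal marker for a missing allele (files use a configurable sentinel, 0
#: by default, in the GenAlEx tradition).
MISSING: int = -1


class GenotypeTableError(ValueError):
    """Raised when a genotype table violates its structural invariants."""


@dataclass
class GenotypeTable:
    """Stems x loci diploid allele-state matrix with patch and grid coordinates.

    Parameters
    ----------
    sample_id, patch_id
        One entry per stem.
    x, y
        Integer-valued grid coordinates in metres.  ``x`` indexes the parallel
        transects, ``y`` the position along a transect (increasing toward the
        tidal creek in the field layout this emulates).
    alleles
        Integer array of shape ``(n_stems, n_loci, 2)``; allele states are
        positive repeat counts, :data:`MISSING` (=-1) marks a missing allele.
    locus_names
        Ordered locus labels, one per locus.
    """

    sample_id: np.ndarray
    patch_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    alleles: np.ndarray
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.patch_id = np.asarray(self.patch_id, dtype=object)
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        self.alleles = np.asarray(self.alleles, dtype=int)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise GenotypeTableError(
                f"alleles must have shape (n, n_loci, 2), got {self.alleles.shape}"
            )
        n = self.alleles.shape[0]
        for name, arr in (
            ("sample_id", self.sample_id),
            ("patch_id", self.patch_id),
            ("x", self.x),
            ("y", self.y),
        ):
            if len(arr) != n:
                raise GenotypeTableError(f"{name} has {len(arr)} entries, expected {n}")
        if not self.locus_names:
            self.locus_names = [f"L{i + 1}" for i in range(self.alleles.shape[1])]
        if len(self.locus_names) != self.alleles.shape[1]:
            raise GenotypeTableError(
                f"{len(self.locus_names)} locus names for {self.alleles.shape[1]} loci"
            )
        self._normalize_missing()
        self._validate()

    def _normalize_missing(self) -> None:
        # Half-missing locus genotypes are promoted to whole-locus missing.
        a = self.alleles
        half = (a == MISSING).sum(axis=2) == 1
        n_half = int(half.sum())
        if n_half:
            a[half] = MISSING
            warnings.warn(
                f"{n_half} half-missing locus genotype(s) promoted to missing",
                stacklevel=3,
            )

    def _validate(self) -> None:
        a = self.alleles
        bad = (a != MISSING) & (a <= 0)
        if bad.any():
            i, j, _ = np.argwhere(bad)[0]
            raise GenotypeTableError(
                f"non-positive allele state at row {i} ({self.sample_id[i]}), "
                f"locus {self.locus_names[j]}"
            )
        coords = list(zip(self.patch_id, self.x, self.y))
        if len(set(coords)) != len(coords):
            seen: set = set()
            for i, c in enumerate(coords):
                if c in seen:
                    raise GenotypeTableError(
                        f"duplicate (patch, x, y) = {c} at row {i}"
                    )
                seen.add(c)

    # -- basic introspection -------------------------------------------------

    @property
    def n_stems(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_stems, n_loci)``: True where the locus genotype is missing."""
        return (self.alleles == MISSING).all(axis=2)

    def patches(self) -> list[str]:
        """Patch ids in order of first appearance."""
        seen: dict = {}
        for p in self.patch_id:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, index: Sequence[int] | np.ndarray) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(
            sample_id=self.sample_id[index],
            patch_id=self.patch_id[index],
            x=self.x[index],
            y=self.y[index],
            alleles=self.alleles[index].copy(),
            locus_names=list(self.locus_names),
        )

    def by_patch(self) -> dict[str, "GenotypeTable"]:
        return {
            p: self.subset(np.flatnonzero(self.patch_id == p)) for p in self.patches()
        }

    def genotype_key(self, i: int) -> tuple:
        """Order-invariant hashable multilocus genotype of stem ``i``."""
        return tuple(
            tuple(sorted(self.alleles[i, j])) for j in range(self.n_loci)
        )

    def copy(self) -> "GenotypeTable":
        return self.subset(np.arange(self.n_stems))

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            list(self.sample_id) == list(other.sample_id)
            and list(self.patch_id) == list(other.patch_id)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.alleles, other.alleles)
            and self.locus_names == other.locus_names
        )


@dataclass
class PatchGeo:
    """Patch geolocations in decimal degrees."""

    patch_id: np.ndarray
    latitude: np.ndarray
    longitude: np.ndarray

    def __post_init__(self) -> None:
        self.patch_id = np.asarray(self.patch_id, dtype=object)
        self.latitude = np.asarray(self.latitude, dtype=float)
        self.longitude = np.asarray(self.longitude, dtype=float)
        if len(set(self.patch_id)) != len(self.patch_id):
            raise ValueError("patch ids must be unique")
        if np.any(np.abs(self.latitude) > 90):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(np.abs(self.longitude) > 180):
            raise ValueError("longitude outside [-180, 180]")

    def coords(self, patch: str) -> tuple[float, float]:
        i = int(np.flatnonzero(self.patch_id == patch)[0])
        return float(self.latitude[i]), float(self.longitude[i])


AUTO = "auto"


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow the study's stated analysis settings
    (5,000 bootstrap draws, 9,999 Mantel permutations, 1,000 spatial
    permutations per patch, 5,000 genotype-null iterations)."""

    mll_threshold: int | str = AUTO
    n_boot: int = 5000
    n_mantel_perm: int = 9999
    n_spatial_perm: int = 1000
    n_genotype_null: int = 5000
    rng_seed: int = 0
    missing_sentinel: int = 0

    def __post_init__(self) -> None:
        for name in ("n_boot", "n_mantel_perm", "n_spatial_perm", "n_genotype_null"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mll_threshold != AUTO:
            self.mll_threshold = int(self.mll_threshold)
            if self.mll_threshold < 0:
                raise ValueError("mll_threshold must be non-negative or 'auto'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)
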