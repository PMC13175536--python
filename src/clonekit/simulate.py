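"""Forward simulator for partially clonal grass populations on transect grids.

Each patch is an independent gene pool (microsatellite allele frequencies
drawn from a symmetric Dirichlet per locus).  Founder genets arise from a
mixed mating system — with probability ``s`` an individual is the selfed
offspring of a random member of the previous generation, otherwise the
random union of two gametes from the pool — iterated for a burn-in number of
generations so the inbreeding coefficient reaches its mixed-mating
equilibrium ``F = s/(2 - s)``.  Each founder genet then spreads by a rhizome
random walk on the 4-neighbour lattice of 1 m cells, marking the cells it
visits as its ramets; every visited cell is sampled once, with ties between
genets resolved in favour of the earliest-founded genet (a priority effect).
Stepwise mutation (allele +-1 repeat per transmitted copy) acts at every
gamete transmission.  The observation model then masks alleles as nulls
(a heterozygote with one null allele is recorded as a visible homozygote;
two nulls make the locus missing) and drops whole locus genotypes at a
missingness rate, leaving the stem set itself untouched.

Walk lengths are Poisson(``clonal_spread_rate``) by default; setting
``clonal_dispersion`` mixes the Poisson mean with a gamma of that shape
(negative-binomial walk lengths), which reproduces the heavy ramet-count
skew of real clonal stands — many singleton genets alongside a few very
large ones — that a fixed-mean Poisson cannot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import MISSING, GenotypeTable, PatchGeo


@dataclass
class SimParams:
    """Simulation settings; defaults emulate the sampled salt-marsh stand."""

    n_patches: int = 10
    transects_per_patch: int = 5
    transect_length_range: tuple[int, int] = (10, 31)
    n_loci: int = 10
    alleles_per_locus: tuple[int, int] = (7, 29)
    selfing_rate: float = 0.5
    clonal_spread_rate: float = 12.0
    clonal_dispersion: float | None = None  # None -> pure Poisson walk lengths
    founder_genets_per_patch: int = 40
    generations: int = 20
    null_allele_rate: float = 0.0
    missing_rate: float = 0.0165
    mutation_rate: float = 0.0
    share_one_genet: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("selfing_rate", "null_allele_rate", "missing_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.clonal_spread_rate < 0:
            raise ValueError("clonal_spread_rate must be non-negative")
        lo, hi = self.transect_length_range
        if not (1 <= lo <= hi <= 1000):
            raise ValueError("transect_length_range must lie within [1, 1000]")
        if self.founder_genets_per_patch < 1:
            raise ValueError("need at least one founder genet per patch")


def field_like(seed: int = 0, **overrides) -> SimParams:
    """Preset emulating the study stand: ten patches of five 1 m transects
    (length 10-31 m), ten loci with 7-29 alleles, mixed mating (s = 0.5),
    overdispersed rhizome spread, null alleles and 1.65% missing data.

    Tuned so that, across seeds, total stems land near 935, genet richness
    near ~220 MLLs, and the ramets-per-MLL distribution is heavily skewed
    (median 1 with occasional very large genets)."""
    params = SimParams(
        n_patches=10,
        selfing_rate=0.5,
        clonal_spread_rate=25.0,
        clonal_dispersion=0.09,
        founder_genets_per_patch=110,
        generations=20,
        null_allele_rate=0.02,
        missing_rate=0.0165,
        mutation_rate=0.001,
        share_one_genet=True,
        rng_seed=seed,
    )
    return replace(params, **overrides)


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    stem_genet: np.ndarray  # global genet id per stem (object)
    genet_selfed: dict[str, bool]
    true_genotypes: np.ndarray  # (n_stems, n_loci, 2), never missing


def equilibrium_F(s: float) -> float:
    """Equilibrium inbreeding coefficient under constant mixed mating.

    The fixed point of ``F' = s (1 + F) / 2``: outcrossed offspring reset to
    F = 0, selfed offspring average the parental identity; at equilibrium
    ``F = s / (2 - s)`` (0.333... at 50% selfing)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError("selfing rate must lie in [0, 1]")
    return s / (2.0 - s)


def _mutate(alleles: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Stepwise mutation: each allele copy shifts +-1 repeat with prob ``rate``."""
    if rate <= 0:
        return alleles
    hit = rng.random(alleles.shape) < rate
    step = rng.choice([-1, 1], size=alleles.shape)
    out = alleles + np.where(hit, step, 0)
    return np.maximum(out, 1)  # repeat counts stay positive


def _found_genets(
    n: int,
    freq_alleles: list[np.ndarray],
    freq_probs: list[np.ndarray],
    s: float,
    generations: int,
    mutation_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve ``n`` genotypes for ``generations`` of mixed mating.

    Returns (genotypes (n, L, 2), selfed flag of the final generation)."""
    L = len(freq_alleles)

    def _pool_draw(size: int) -> np.ndarray:
        out = np.empty((size, L, 2), dtype=int)
        for j in range(L):
            out[:, j, :] = rng.choice(freq_alleles[j], size=(size, 2), p=freq_probs[j])
        return out

    pop = _pool_draw(n)
    selfed = np.zeros(n, dtype=bool)
    for _ in range(max(generations, 1)):
        self_mask = rng.random(n) < s
        new = _pool_draw(n)  # outcrossed template
        if self_mask.any():
            parents = rng.integers(0, n, size=int(self_mask.sum()))
            pg = pop[parents]  # (m, L, 2)
            # two independent gametes from the same parent: each output slot
            # picks one of the parent's two alleles
            picks = rng.integers(0, 2, size=(len(parents), L, 2))
            new[self_mask] = np.take_along_axis(pg, picks, axis=2)
        new = _mutate(new, mutation_rate, rng)
        pop = new
        selfed = self_mask
    return pop, selfed


def _rhizome_walk(
    origin: tuple[int, int],
    n_steps: int,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> set[tuple[int, int]]:
    """4-neighbour lattice walk; off-grid steps are discarded (walker stays)."""
    nx, ny = shape
    x, y = origin
    visited = {(x, y)}
    if n_steps <= 0:
        return visited
    moves = ((1, 0), (-1, 0), (0, 1), (0, -1))
    dirs = rng.integers(0, 4, size=n_steps)
    for d in dirs:
        dx, dy = moves[d]
        px, py = x + dx, y + dy
        if 0 <= px < nx and 0 <= py < ny:
            x, y = px, py
            visited.add((x, y))
    return visited


def simulate_population(
    params: SimParams,
) -> tuple[GenotypeTable, PatchGeo, TruthRecord]:
    """Simulate a sampled partially clonal population; see module docstring."""
    rng = np.random.default_rng(params.rng_seed)
    L = params.n_loci
    a_lo, a_hi = params.alleles_per_locus
    # shared allele state space per locus; per-patch frequencies
    n_alleles = rng.integers(a_lo, a_hi + 1, size=L)
    base = rng.integers(8, 35, size=L)
    allele_states = [np.arange(base[j], base[j] + n_alleles[j]) for j in range(L)]

    patch_names = [f"P{i + 1:02d}" for i in range(params.n_patches)]
    rows_id: list[str] = []
    rows_patch: list[str] = []
    rows_x: list[int] = []
    rows_y: list[int] = []
    observed: list[np.ndarray] = []
    truth_geno: list[np.ndarray] = []
    stem_genet: list[str] = []
    genet_selfed: dict[str, bool] = {}
    shared_genotype: np.ndarray | None = None
    shared_id: str | None = None

    serial = 0
    for pi, patch in enumerate(patch_names):
        probs = [rng.dirichlet(np.ones(n_alleles[j])) for j in range(L)]
        genotypes, selfed = _found_genets(
            params.founder_genets_per_patch,
            allele_states,
            probs,
            params.selfing_rate,
            params.generations,
            params.mutation_rate,
            rng,
        )
        genet_ids = [f"{patch}:g{j}" for j in range(len(genotypes))]
        if params.share_one_genet and pi == 0:
            shared_genotype = genotypes[0].copy()
            shared_id = genet_ids[0]
        if params.share_one_genet and pi == 1 and shared_genotype is not None:
            genotypes = np.concatenate([shared_genotype[None], genotypes], axis=0)
            genet_ids = [shared_id] + genet_ids
            selfed = np.concatenate([[genet_selfed.get(shared_id, False)], selfed])
        for gid, sf in zip(genet_ids, selfed):
            genet_selfed[gid] = bool(sf)

        lo_t, hi_t = params.transect_length_range
        ylen = int(rng.integers(lo_t, hi_t + 1))
        shape = (params.transects_per_patch, ylen)
        if params.clonal_dispersion is None:
            steps = rng.poisson(params.clonal_spread_rate, size=len(genotypes))
        else:
            lam = rng.gamma(
                params.clonal_dispersion,
                params.clonal_spread_rate / params.clonal_dispersion,
                size=len(genotypes),
            )
            steps = rng.poisson(lam)
        owner = np.full(shape, -1, dtype=int)
        for j in range(len(genotypes)):
            origin = (int(rng.integers(shape[0])), int(rng.integers(shape[1])))
            for cell in _rhizome_walk(origin, int(steps[j]), shape, rng):
                if owner[cell] == -1:
                    owner[cell] = j
        occ = np.argwhere(owner >= 0)
        # deterministic sampling order along transects
        occ = occ[np.lexsort((occ[:, 1], occ[:, 0]))]
        for x, y in occ:
            j = owner[x, y]
            serial += 1
            rows_id.append(f"S{serial:04d}")
            rows_patch.append(patch)
            rows_x.append(int(x) + 1)
            rows_y.append(int(y) + 1)
            truth_geno.append(genotypes[j].copy())
            stem_genet.append(genet_ids[j])
            observed.append(_observe(genotypes[j], params, rng))

    table = GenotypeTable(
        sample_id=np.array(rows_id, dtype=object),
        patch_id=np.array(rows_patch, dtype=object),
        x=np.array(rows_x),
        y=np.array(rows_y),
        alleles=np.stack(observed),
        locus_names=[f"Spar{j + 1:02d}" for j in range(L)],
    )
    geo = _place_patches(patch_names, rng)
    truth = TruthRecord(
        stem_genet=np.array(stem_genet, dtype=object),
        genet_selfed=genet_selfed,
        true_genotypes=np.stack(truth_geno),
    )
    return table, geo, truth


def _observe(genotype: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Apply the per-stem observation model (null alleles, then missingness).

    Random draws are consumed whether or not the rates are zero, so the
    generator stream — and hence the sampled stem set — is identical across
    observation-rate settings at a fixed seed."""
    g = genotype.copy()
    null = rng.random(g.shape) < params.null_allele_rate
    for j in range(g.shape[0]):
        if null[j].all():
            g[j] = MISSING
        elif null[j, 0]:
            g[j, 0] = g[j, 1]
        elif null[j, 1]:
            g[j, 1] = g[j, 0]
    drop = rng.random(g.shape[0]) < params.missing_rate
    g[drop] = MISSING
    return g


def _place_patches(patch_names: list[str], rng: np.random.Generator) -> PatchGeo:
    """Patches 250-1,000 m apart along a line of constant latitude."""
    lat0, lon0 = 39.5268, -74.3200
    spacing = rng.uniform(250.0, 1000.0, size=len(patch_names) - 1) if len(patch_names) > 1 else []
    east = np.concatenate([[0.0], np.cumsum(spacing)]) if len(patch_names) > 1 else np.zeros(1)
    radius = 6_378_137.0
    lon = lon0 + np.degrees(east / (radius * math.cos(math.radians(lat0))))
    return PatchGeo(
        patch_id=np.array(patch_names, dtype=object),
        latitude=np.full(len(patch_names), lat0),
        longitude=lon,
    )
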