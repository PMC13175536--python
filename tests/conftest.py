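import numpy as np
import pytest

from clonekit.core import GenotypeTable


def make_table(rows, patches=None, coords=None, locus_names=None, ids=None):
    """Build a GenotypeTable from per-row lists of (a, b) allele pairs.

    Use -1 for a missing allele.  Coordinates default to one stem per metre
    along a single transect.
    """
    n = len(rows)
    alleles = np.array(rows, dtype=int)
    if alleles.ndim == 2:  # single locus rows like [(10, 12), ...]
        alleles = alleles[:, None, :]
    if patches is None:
        patches = ["A"] * n
    if coords is None:
        coords = [(1, i + 1) for i in range(n)]
    # make coordinates unique across patches
    seen = {}
    fixed = []
    for p, (x, y) in zip(patches, coords):
        while (p, x, y) in seen:
            y += 1000
        seen[(p, x, y)] = True
        fixed.append((x, y))
    if ids is None:
        ids = [f"s{i + 1}" for i in range(n)]
    return GenotypeTable(
        sample_id=np.array(ids, dtype=object),
        patch_id=np.array(patches, dtype=object),
        x=np.array([c[0] for c in fixed]),
        y=np.array([c[1] for c in fixed]),
        alleles=alleles,
        locus_names=locus_names or [f"L{k + 1}" for k in range(alleles.shape[1])],
    )


@pytest.fixture(scope="session")
def field_sim():
    """One field-like simulated population shared across tests."""
    from clonekit.simulate import field_like, simulate_population

    return simulate_population(field_like(seed=11))


@pytest.fixture(scope="session")
def field_partition(field_sim):
    """Distance matrix + MLL partition at the suggested threshold."""
    from clonekit.distances import pairwise_matrix
    from clonekit.mll import assign_mlls_table, suggest_threshold

    table, geo, truth = field_sim
    dm = pairwise_matrix(table, metric="stepwise")
    sug = suggest_threshold(dm.histogram())
    part = assign_mlls_table(table, dm, sug.threshold)
    return dm, sug, part


def draw_ztp(lam, n, rng):
    """Zero-truncated Poisson sample by rejection (test oracle helper)."""
    out = []
    while len(out) < n:
        d = rng.poisson(lam, size=max(n, 16))
        out.extend(d[d > 0].tolist())
    return np.array(out[:n])
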