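"""Genotype-frequency, diversity and differentiation statistics.

Statistics are ordinarily computed on one representative stem per multilocus
lineage (clone correction): including every ramet would pseudo-replicate
genets.  The representative of an MLL is its member with the fewest missing
loci, ties broken by the lowest sample id (deterministic).

Estimators
----------
* ``G_IS`` — within-population fixation index from Nei's gene diversities:
  per locus ``H_O`` (observed heterozygote fraction) and unbiased
  ``H_S = n/(n-1) * (1 - sum p_i^2 - H_O/(2n))``; multilocus
  ``G_IS = 1 - sum(H_O)/sum(H_S)`` (ratio of sums over loci).
* ``G''_ST`` — allele-frequency differentiation standardized by the maximum
  ``G_ST`` can reach given within-patch diversity, with a correction for a
  small number of patches ``k``:
  ``G''_ST = k (H_T - H_S) / ((k H_T - H_S)(1 - H_S))``.
* ``R_ST`` — stepwise-mutation differentiation from allele-size variances:
  ``R_ST = (S_bar - S_W) / S_bar`` with ``S_bar`` the pooled allele-size
  variance and ``S_W`` the sample-size-weighted mean within-patch variance.
* ``p_sex(F)`` — expected frequency of a multilocus genotype under sexual
  reproduction with inbreeding ``F``; its complement across ``N`` trials
  gives the probability of exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeTable
from .mll import MLLPartition


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class AlleleFreqs:
    """Per-locus allele-frequency maps."""

    freqs: dict[str, dict[int, float]]
    scope: str = "total"
    method: str = "plain"
    n_gene_copies: dict[str, int] = field(default_factory=dict)

    def p(self, locus: str, allele: int) -> float:
        try:
            return self.freqs[locus][int(allele)]
        except KeyError:
            raise KeyError(
                f"allele {allele} at locus {locus} absent from frequency table; "
                "frequencies must come from the same data"
            ) from None


def plain_freqs(table: GenotypeTable, scope: str = "total") -> AlleleFreqs:
    """Allele frequencies counting every gene copy of every stem."""
    freqs: dict[str, dict[int, float]] = {}
    copies: dict[str, int] = {}
    for j, locus in enumerate(table.locus_names):
        a = table.alleles[:, j, :].ravel()
        a = a[a != MISSING]
        if a.size == 0:
            warnings.warn(f"locus {locus} entirely missing; excluded")
            continue
        vals, counts = np.unique(a, return_counts=True)
        freqs[locus] = {int(v): c / a.size for v, c in zip(vals, counts)}
        copies[locus] = int(a.size)
    return AlleleFreqs(freqs=freqs, scope=scope, method="plain", n_gene_copies=copies)


def round_robin_freqs(table: GenotypeTable, scope: str = "total") -> AlleleFreqs:
    """Clone-corrected allele frequencies by the round-robin method.

    For each locus, lineages are defined by strict genotype identity over all
    *other* loci; the locus's alleles are then pooled from one representative
    per lineage.  This avoids circularity between frequency estimation and
    clone identification.
    """
    if table.n_loci < 2:
        raise ValueError("round-robin frequencies need at least 2 loci")
    freqs: dict[str, dict[int, float]] = {}
    copies: dict[str, int] = {}
    for j, locus in enumerate(table.locus_names):
        others = [k for k in range(table.n_loci) if k != j]
        seen: dict[tuple, int] = {}
        for i in range(table.n_stems):
            key = tuple(tuple(sorted(table.alleles[i, k])) for k in others)
            if key not in seen:
                seen[key] = i
        pooled: list[int] = []
        for i in seen.values():
            g = table.alleles[i, j]
            if (g == MISSING).any():
                continue
            pooled.extend(int(v) for v in g)
        if not pooled:
            warnings.warn(f"locus {locus} entirely missing; excluded")
            continue
        arr = np.asarray(pooled)
        vals, counts = np.unique(arr, return_counts=True)
        freqs[locus] = {int(v): c / arr.size for v, c in zip(vals, counts)}
        copies[locus] = int(arr.size)
    return AlleleFreqs(freqs=freqs, scope=scope, method="round_robin", n_gene_copies=copies)


def imputed_copy(
    table: GenotypeTable, freqs: AlleleFreqs, seed: int | np.random.Generator = 0
) -> GenotypeTable:
    """Copy of ``table`` with every missing locus genotype replaced by two
    independent draws from the supplied (total-population) frequencies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    for j, locus in enumerate(table.locus_names):
        if locus not in freqs.freqs:
            continue
        alleles = np.array(sorted(freqs.freqs[locus]))
        p = np.array([freqs.freqs[locus][a] for a in alleles])
        p = p / p.sum()
        missing_rows = np.flatnonzero(table.missing_mask[:, j])
        if missing_rows.size:
            draws = rng.choice(alleles, size=(missing_rows.size, 2), p=p)
            out.alleles[missing_rows, j, :] = draws
    return out


# ---------------------------------------------------------------------------
# p_sex and exclusion


def psex_F(genotype: np.ndarray, freqs: AlleleFreqs, F: float,
           locus_names: list[str] | None = None) -> float:
    """Expected frequency of a fully observed multilocus genotype under sexual
    reproduction with fixation index ``F``.

    Per locus: homozygote ``p^2 + F p (1-p)``; heterozygote ``2 p q (1-F)``;
    per-locus probabilities are clamped at zero (relevant for F < 0)."""
    genotype = np.asarray(genotype)
    if not -1.0 <= F <= 1.0:
        raise ValueError("F must lie in [-1, 1]")
    names = locus_names or list(freqs.freqs)
    if genotype.shape[0] != len(names):
        raise ValueError("genotype and frequency table disagree on locus count")
    prob = 1.0
    for j, locus in enumerate(names):
        a, b = int(genotype[j, 0]), int(genotype[j, 1])
        if a == MISSING or b == MISSING:
            raise ValueError("psex_F needs a fully observed (imputed) genotype")
        if a == b:
            p = freqs.p(locus, a)
            term = p * p + F * p * (1 - p)
        else:
            p, q = freqs.p(locus, a), freqs.p(locus, b)
            term = 2 * p * q * (1 - F)
        prob *= max(term, 0.0)
    return prob


@dataclass
class ExclusionResult:
    """The chance-identity calculation both ways round.

    ``p_no_identity = (1 - p)^N`` is the probability that no other sampled
    genotype matches by chance; ``p_any_identity`` is its complement, the
    headline "probability of exclusion" figure."""

    p_max: float
    n: int
    p_no_identity: float
    p_any_identity: float


def exclusion_probability(p_max: float, N: int) -> ExclusionResult:
    """Chance-identity probability for the most probable genotype in ``N`` trials."""
    if not 0.0 <= p_max <= 1.0:
        raise ValueError("p_max must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    if p_max >= 1.0:
        no_id = 0.0
    else:
        no_id = float(np.exp(N * np.log1p(-p_max)))
    any_id = float(-np.expm1(N * np.log1p(-p_max))) if p_max < 1.0 else 1.0
    return ExclusionResult(p_max=p_max, n=N, p_no_identity=no_id, p_any_identity=any_id)


# ---------------------------------------------------------------------------
# clone correction


def mll_representatives(table: GenotypeTable, partition: MLLPartition) -> GenotypeTable:
    """One stem per MLL: fewest missing loci, ties by lowest sample id."""
    miss = table.missing_mask.sum(axis=1)
    chosen: dict[int, int] = {}
    for i in range(table.n_stems):
        lab = int(partition.labels[i])
        if lab not in chosen:
            chosen[lab] = i
            continue
        c = chosen[lab]
        if (miss[i], str(table.sample_id[i])) < (miss[c], str(table.sample_id[c])):
            chosen[lab] = i
    idx = np.array(sorted(chosen.values()))
    return table.subset(idx)


# ---------------------------------------------------------------------------
# G_IS


@dataclass
class GisResult:
    h_o: dict[str, float]
    h_s: dict[str, float]
    g_is: float
    per_locus_gis: dict[str, float]
    jackknife_lo: float
    jackknife_hi: float
    h_o_multilocus: float
    h_s_multilocus: float


def _locus_h(table: GenotypeTable, j: int) -> tuple[float, float, int] | None:
    """(H_O, unbiased H_S, n) for locus ``j``; None if monomorphic-or-empty."""
    a = table.alleles[:, j, :]
    ok = ~(a == MISSING).any(axis=1)
    n = int(ok.sum())
    if n < 2:
        return None
    g = a[ok]
    h_o = float((g[:, 0] != g[:, 1]).mean())
    copies = g.ravel()
    _, counts = np.unique(copies, return_counts=True)
    p = counts / copies.size
    h_s = (n / (n - 1)) * (1 - float((p**2).sum()) - h_o / (2 * n))
    return h_o, h_s, n


def nei_gis(table: GenotypeTable) -> GisResult:
    """Within-population fixation index from Nei's gene diversities.

    Multilocus ``G_IS = 1 - sum(H_O) / sum(H_S)`` over polymorphic loci, with
    2.5%/97.5% quantiles from a delete-one-locus jackknife.  The sample size
    ``n`` inside the unbiased ``H_S`` is the per-locus count of stems scored
    at that locus.
    """
    h_o: dict[str, float] = {}
    h_s: dict[str, float] = {}
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(table.locus_names):
        res = _locus_h(table, j)
        if res is None:
            continue
        ho, hs, _ = res
        if hs <= 0:
            continue  # monomorphic locus carries no information about F
        h_o[locus] = ho
        h_s[locus] = hs
        per_locus[locus] = 1 - ho / hs
    if not h_s:
        warnings.warn("all loci monomorphic; G_IS undefined")
        return GisResult({}, {}, float("nan"), {}, float("nan"), float("nan"),
                         float("nan"), float("nan"))
    loci = list(h_s)
    sum_ho = sum(h_o.values())
    sum_hs = sum(h_s.values())
    g_is = 1 - sum_ho / sum_hs
    if len(loci) > 1:
        jack = np.array(
            [1 - (sum_ho - h_o[l]) / (sum_hs - h_s[l]) for l in loci]
        )
        lo, hi = np.percentile(jack, [2.5, 97.5])
    else:
        lo = hi = g_is
    return GisResult(
        h_o=h_o,
        h_s=h_s,
        g_is=float(g_is),
        per_locus_gis=per_locus,
        jackknife_lo=float(lo),
        jackknife_hi=float(hi),
        h_o_multilocus=float(np.mean(list(h_o.values()))),
        h_s_multilocus=float(np.mean(list(h_s.values()))),
    )


# ---------------------------------------------------------------------------
# differentiation


@dataclass
class DiffResult:
    statistic: str
    value: float
    per_locus: dict[str, float]
    ci_lo: float
    ci_hi: float
    pairwise: "np.ndarray"
    patch_ids: list[str]
    pairwise_spread: "np.ndarray | None" = None


def _patch_locus_freqs(tables: dict[str, GenotypeTable], locus_index: int):
    """Per-patch allele frequency vectors (aligned) + H_O + n at one locus."""
    alleles: set[int] = set()
    per_patch = {}
    for pid, t in tables.items():
        a = t.alleles[:, locus_index, :]
        ok = ~(a == MISSING).any(axis=1)
        g = a[ok]
        if g.shape[0] == 0:
            continue
        per_patch[pid] = g
        alleles.update(int(v) for v in g.ravel())
    allele_list = sorted(alleles)
    out = {}
    for pid, g in per_patch.items():
        copies = g.ravel()
        counts = np.array([(copies == v).sum() for v in allele_list], dtype=float)
        p = counts / copies.size
        h_o = float((g[:, 0] != g[:, 1]).mean())
        out[pid] = (p, h_o, g.shape[0])
    return out, allele_list


def _gpp_from_hs_ht(h_s: float, h_t: float, k: int) -> float:
    if h_t <= 0:
        return float("nan")
    denom = (k * h_t - h_s) * (1 - h_s)
    if denom == 0:
        return float("nan")
    return k * (h_t - h_s) / denom


def _hs_ht_components(
    tables: dict[str, GenotypeTable], unbiased: bool
) -> dict[str, tuple[float, float]]:
    """Per-locus (H_S, H_T) across patches."""
    names = next(iter(tables.values())).locus_names
    comp: dict[str, tuple[float, float]] = {}
    for j, locus in enumerate(names):
        data, _ = _patch_locus_freqs(tables, j)
        if len(data) < 2:
            continue
        ps = np.array([d[0] for d in data.values()])
        hs_i = []
        for p, h_o, n in data.values():
            raw = 1 - float((p**2).sum())
            if unbiased and n > 1:
                raw = (n / (n - 1)) * (raw - h_o / (2 * n))
            hs_i.append(raw)
        h_s = float(np.mean(hs_i))
        p_bar = ps.mean(axis=0)
        h_t = 1 - float((p_bar**2).sum())
        if unbiased:
            ns = np.array([d[2] for d in data.values()], dtype=float)
            n_harm = len(ns) / (1.0 / ns).sum()
            h_o_bar = float(np.mean([d[1] for d in data.values()]))
            h_t = h_t + h_s / (n_harm * len(ns)) - h_o_bar / (2 * n_harm * len(ns))
        comp[locus] = (h_s, h_t)
    return comp


def gst_double_prime(
    tables: dict[str, GenotypeTable],
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
    unbiased: bool = False,
) -> DiffResult:
    """Standardized differentiation G''_ST among patches.

    ``tables`` maps patch id to its (normally clone-corrected) genotype
    table.  Multilocus value combines per-locus H_S/H_T by averaging the
    components before applying the formula; the total CI is a percentile
    bootstrap over patches.  ``unbiased=True`` switches both diversities to
    Nei–Chesser small-sample estimators (slightly negative values for
    identical finite samples are then expected).
    """
    k = len(tables)
    if k < 2:
        raise ValueError("need at least 2 patches")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = _hs_ht_components(tables, unbiased)
    per_locus = {
        locus: _gpp_from_hs_ht(h_s, h_t, k) for locus, (h_s, h_t) in comp.items()
    }
    informative = {l: v for l, v in comp.items() if v[1] > 0}
    if not informative:
        value = float("nan")
    else:
        h_s = float(np.mean([v[0] for v in informative.values()]))
        h_t = float(np.mean([v[1] for v in informative.values()]))
        if h_s >= 1.0:
            warnings.warn("H_S = 1; G''_ST undefined")
            value = float("nan")
        else:
            value = _gpp_from_hs_ht(h_s, h_t, k)

    pids = list(tables)

    def _multi(sub: dict[str, GenotypeTable]) -> float:
        c = {l: v for l, v in _hs_ht_components(sub, unbiased).items() if v[1] > 0}
        if not c:
            return float("nan")
        hs = float(np.mean([v[0] for v in c.values()]))
        ht = float(np.mean([v[1] for v in c.values()]))
        return _gpp_from_hs_ht(hs, ht, len(sub))

    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, k, size=k)
        sub = {f"b{i}": tables[pids[p]] for i, p in enumerate(pick)}
        boots.append(_multi(sub))
    boots = np.array(boots, dtype=float)
    boots = boots[np.isfinite(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots.size else (np.nan, np.nan))

    pw = np.full((k, k), np.nan)
    for i in range(k):
        for jj in range(i + 1, k):
            sub = {pids[i]: tables[pids[i]], pids[jj]: tables[pids[jj]]}
            pw[i, jj] = pw[jj, i] = _multi(sub)
        pw[i, i] = 0.0
    return DiffResult("G''_ST", float(value), per_locus, float(lo), float(hi), pw, pids)


def _rst_components(tables: dict[str, GenotypeTable], locus_index: int):
    """(between, total) allele-size variance components at one locus.

    ``total`` is the pooled population variance S-bar of allele sizes over all
    gene copies; ``within`` is the n_i/N-weighted mean of within-patch
    population variances; ``between = total - within`` (exact decomposition).
    """
    sizes = []
    labels = []
    for pid, t in tables.items():
        a = t.alleles[:, locus_index, :]
        ok = ~(a == MISSING).any(axis=1)
        g = a[ok].ravel().astype(float)
        if g.size:
            sizes.append(g)
            labels.append(pid)
    if len(sizes) < 2:
        return None
    pooled = np.concatenate(sizes)
    n_total = pooled.size
    s_bar = float(pooled.var())  # ddof=0
    s_w = float(sum((g.size / n_total) * g.var() for g in sizes))
    return s_bar - s_w, s_bar


def rst(
    tables: dict[str, GenotypeTable],
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
) -> DiffResult:
    """Stepwise-mutation differentiation R_ST among patches.

    Multilocus value sums the between-patch and total allele-size variance
    components over loci.  Total CI: ``n_boot`` bootstrap iterations over
    patches with replacement.  Pairwise estimates carry a delete-one-locus
    jackknife standard deviation.
    """
    k = len(tables)
    if k < 2:
        raise ValueError("need at least 2 patches")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = next(iter(tables.values())).locus_names

    def _multi(sub: dict[str, GenotypeTable], skip: int | None = None):
        between = total = 0.0
        per_locus = {}
        for j, locus in enumerate(names):
            if j == skip:
                continue
            c = _rst_components(sub, j)
            if c is None:
                continue
            b, t = c
            per_locus[locus] = (b / t) if t > 0 else float("nan")
            between += b
            total += t
        if total <= 0:
            return float("nan"), per_locus
        return between / total, per_locus

    value, per_locus = _multi(tables)
    if np.isnan(value):
        warnings.warn("all loci monomorphic; R_ST undefined")

    pids = list(tables)
    boots = []
    for _ in range(n_boot):
        pick = rng.integers(0, k, size=k)
        sub = {f"b{i}": tables[pids[p]] for i, p in enumerate(pick)}
        boots.append(_multi(sub)[0])
    boots = np.array(boots, dtype=float)
    boots = boots[np.isfinite(boots)]
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots.size else (np.nan, np.nan))

    pw = np.zeros((k, k))
    spread = np.zeros((k, k))
    for i in range(k):
        for jj in range(i + 1, k):
            sub = {pids[i]: tables[pids[i]], pids[jj]: tables[pids[jj]]}
            pw[i, jj] = pw[jj, i] = _multi(sub)[0]
            jack = [
                _multi(sub, skip=s)[0] for s in range(len(names))
            ]
            jack = np.array([v for v in jack if np.isfinite(v)])
            spread[i, jj] = spread[jj, i] = jack.std(ddof=1) if jack.size > 1 else np.nan
    return DiffResult("R_ST", float(value), per_locus, float(lo), float(hi), pw, pids,
                      pairwise_spread=spread)


# ---------------------------------------------------------------------------
# sexual-reproduction genotype-count null


@dataclass
class GenotypeNullResult:
    expected_distinct: float
    sd_distinct: float
    p_value: float | None
    observed: int | None
    n_iter: int


def expected_genotype_null(
    freqs: AlleleFreqs,
    N: int,
    n_iter: int = 5000,
    seed: int | np.random.Generator = 0,
    observed: int | None = None,
) -> GenotypeNullResult:
    """Distinct multilocus genotypes expected under sexual random mating.

    Each iteration draws ``N`` genotypes (two independent alleles per locus
    from the supplied frequencies) and counts distinct multilocus genotypes.
    Returns the mean over iterations and, when ``observed`` (the MLL count) is
    given, the one-sided p-value
    ``(1 + #{iterations with count <= observed}) / (n_iter + 1)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = list(freqs.freqs)
    allele_arrays = []
    prob_arrays = []
    for locus in loci:
        al = np.array(sorted(freqs.freqs[locus]))
        p = np.array([freqs.freqs[locus][a] for a in al], dtype=float)
        allele_arrays.append(al)
        prob_arrays.append(p / p.sum())
    counts = np.empty(n_iter, dtype=int)
    for it in range(n_iter):
        cols = []
        for al, p in zip(allele_arrays, prob_arrays):
            draws = rng.choice(al, size=(N, 2), p=p)
            draws.sort(axis=1)
            cols.append(draws)
        geno = np.concatenate(cols, axis=1)
        counts[it] = np.unique(geno, axis=0).shape[0]
    p_value = None
    if observed is not None:
        p_value = (1 + int((counts <= observed).sum())) / (n_iter + 1)
    return GenotypeNullResult(
        expected_distinct=float(counts.mean()),
        sd_distinct=float(counts.std(ddof=1)) if n_iter > 1 else 0.0,
        p_value=p_value,
        observed=observed,
        n_iter=n_iter,
    )
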