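# clonekit

Clonal ecological genetics for partially clonal plant populations sampled
on metre-grid transects and genotyped at microsatellite loci — written for
population geneticists and ecologists studying foundation species (salt
marsh grasses, seagrasses, riparian trees) whose stands mix sexual
reproduction, self-fertilization and vegetative spread.

Given a table of stems (one row per sampled stem: patch, grid x/y in
metres, two alleles per locus in repeat units), `clonekit`:

1. **identifies genets** — multilocus lineages (MLLs) — by thresholding
   the pairwise stepwise-mutation distance
   `d(g₁,g₂) = Σ_loci min over pairings Σ|aᵢ − bᵢ|`,
   with the threshold read off the valley of the distance histogram and
   single-linkage closure of the pairwise rule;
2. **quantifies the mating portfolio**: round-robin (clone-corrected)
   allele frequencies, the expected genotype frequency under sexual
   reproduction `p_sex(F) = Π_loci [p² + Fp(1−p)` or `2pq(1−F)]`, the
   exclusion probability `1 − (1−p_sex)^N`, and the fixation index
   `G_IS = 1 − ΣH_O/ΣH_S` with its mixed-mating equilibrium benchmark
   `F̂ = s/(2−s)`;
3. **measures differentiation** among patches with the standardized
   `G''_ST = k(H_T−H_S)/((kH_T−H_S)(1−H_S))` and the allele-size measure
   `R_ST = (S̄−S_W)/S̄`, with patch-bootstrap intervals, plus Mantel and
   regression tests of isolation by distance;
4. **tests neutral count models**: zero-truncated Poisson
   `P(Y=y) = λ^y e^{−λ}/(y!(1−e^{−λ}))` fitted by maximum likelihood with
   one rate or a rate per patch, likelihood-ratio and Pearson
   goodness-of-fit tests, and a flagged zero-truncated negative-binomial
   alternative;
5. **scores clonal spatial patterns** with FRAGSTATS-style class
   cohesion and interspersion/juxtaposition indices against
   label-permutation nulls; and
6. **simulates** partially clonal populations (mixed mating at
   equilibrium, rhizome random walks, priority effects, null alleles,
   missing data) so every stage is testable against known truth.

## Worked example

```python
import numpy as np
from clonekit import (field_like, simulate_population, pairwise_matrix,
                      suggest_threshold, assign_mlls_table,
                      mll_representatives, nei_gis)

table, geo, truth = simulate_population(field_like(seed=7))
dm   = pairwise_matrix(table, metric="stepwise")
part = assign_mlls_table(table, dm, suggest_threshold(dm.histogram()).threshold)
gis  = nei_gis(mll_representatives(table, part))
counts = np.array(list(part.ramet_counts.values()))
print(table.n_stems, part.n_mll, np.median(counts), round(gis.g_is, 3))
```

prints

```
1015 270 1.0 0.354
```

— 1,015 stems resolve into 270 genets; the median genet was sampled once
(most genets are singletons, a few spread widely by rhizomes — the
clonal signature); and the clone-corrected fixation index of 0.35 shows
the homozygote excess expected from 50% selfing at equilibrium
(s/(2−s) = 0.33) plus a small null-allele inflation.  The scripts in
`examples/` walk through each capability (genet identification, diversity
and differentiation, isolation by distance, count null models, spatial
patterns) with printed, annotated output.

A thin CLI mirrors the library:

```bash
clonekit simulate --seed 7 --out sim/
clonekit run --genotypes sim/genotypes.csv --geo sim/geo.csv --out out/
```

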