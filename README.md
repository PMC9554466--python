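# mycassembly

Community-assembly inference for abundant and rare soil fungi (or any
amplicon-surveyed microbial community).

Large-scale surveys of soil fungi routinely find a handful of abundant
taxa holding most of the reads and a long tail of rare ones, and the
central question is *why* their composition varies from place to place:
deterministic environmental selection, dispersal limitation, or neutral
drift. `mycassembly` implements the standard inference toolkit for that
question as a tested, seeded, end-to-end pipeline:

- **Classification** — taxa are split by relative-abundance thresholds:
  regionally *abundant* (mean relative abundance > 0.1% across samples)
  vs. regionally *rare* (< 0.005%), with local (per-sample) thresholds of
  > 1% and < 0.01%.
- **Niche breadth** — Levins' `B = 1 / Σⱼ pⱼ²` per taxon over its
  across-sample use proportions, and the abundance-weighted community mean
  `Bcom`.
- **Null-model β-deviations** — each sample is re-assembled by drawing its
  observed richness from the regional pool (probabilities proportional to
  regional abundance, without replacement) and re-allocating its observed
  reads; the standardized effect size per pair is
  `β-dev = (BC_obs − mean BC_null) / sd BC_null`. Strongly positive values
  indicate heterogeneous selection or dispersal limitation, ≈ 0 indicates
  stochastic assembly.
- **Sloan neutral community model** — expected occurrence frequency
  `F(p) = 1 − I_d(Nmp, Nm(1−p))` (regularized incomplete beta at the
  detection limit `d = 1/N`), with the migration rate `m` fitted by least
  squares and R² reporting neutral-fit quality.
- **Distance decay** — OLS slope of compositional similarity
  (1 − Bray–Curtis) against great-circle distance.
- **MRM / VPA / hierarchical partitioning** — multiple regression on
  distance matrices with label-permutation inference and forward
  selection; variance of β-deviations partitioned into pure-spatial,
  pure-environmental and shared fractions; exact Shapley-style independent
  contributions per predictor group (space / soil / climate / plant).
- **Recursive path analysis** — standardized direct, indirect and total
  effects of space, soil, climate and plant variables on β-deviations over
  a declared DAG.
- **Synthetic survey generator** — 30 sites × 3 quadrats along a ~2,500 km
  arid transect, 4 vegetation types, lognormal species-abundance
  distribution, with explicit knobs for selection strength, dispersal
  decay, and neutral drift, so every inference above is falsifiable at
  desk scale.

## Worked example

```python
from mycassembly import (SimConfig, mixed_scenario, relative_abundance,
                         classify_regional, fit_ncm, beta_deviation,
                         community_bcom)

table, meta = mixed_scenario(SimConfig(seed=1))   # 90 samples x 1000 taxa
cls = classify_regional(relative_abundance(table))
print(len(cls.abundant), len(cls.rare))           # -> 152 403

abundant = table.subset_taxa(cls.abundant)
fit = fit_ncm(abundant, N=int(abundant.depth.mean()))
print(round(fit.r2, 2))                           # -> 0.53

dev = beta_deviation(abundant, reps=299, seed=1)
print(round(dev.deviations.mean(), 1))            # -> 55.9
```

152 of 1,000 taxa are regionally abundant yet hold ~88% of reads; the
abundant subcommunity's occurrence frequencies track the neutral curve
(R² 0.53 here, and far better than the rare subcommunity's), and its
strongly positive mean β-deviation reflects the dispersal limitation
built into the scenario.

Or from the shell:

```bash
mycassembly all --out run --seed 1 --reps 299 --perms 199
cat run/summary.json
```

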