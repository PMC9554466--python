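# Methods

This note documents the models implemented in `mycassembly`, the numerical
and design choices behind them, what the synthetic-data generator does and
does not emulate, and known limitations.

## Preprocessing

The pipeline begins at an ASV-by-sample count table. Taxa with fewer than
8 reads in total are discarded (the conventional guard against spurious
singleton-level ASVs), then every sample is rarefied to a common depth by
an exact multivariate-hypergeometric subsample (default target 9,080
reads, capped at the post-filter minimum depth). Rarefaction is seeded and
performed once; the pipeline order is fixed (filter, then rarefy).
Aridity is derived as `1 − MAP/PET`. Collinear covariates are pruned
greedily: while any pair has |Pearson r| > 0.6, the member of the worst
pair with the higher mean absolute correlation to all remaining covariates
is dropped; the drop log is emitted so a user can override with a
keep-list.

## Classification

Regional labels use the unweighted mean of per-sample relative abundances
over *all* samples (zeros included): abundant above 0.1%, rare below
0.005%, both strict, boundary values falling to intermediate. Local labels
(> 1%, < 0.01% within one sample) are emitted but not consumed downstream;
taxa absent from a sample are labelled `absent` locally because a
non-detection has no abundance to classify. Downstream analyses run on the
regional abundant and rare subsets. Samples holding no reads of a subset
are dropped from that subset's pairwise analyses (reported in the run
summary).

## Levins' niche breadth

`B = 1 / Σⱼ pⱼ²` where `pⱼ` is the fraction of a taxon's reads found in
sample *j*; the resource states are the samples themselves. B is computed
on rarefied counts (equivalent to relative abundances up to rounding).
`Bcom` is the abundance-weighted mean B over the taxa present in a sample,
weights renormalized within the analyzed subset.

## The abundance null model and β-deviation

Each null replicate rebuilds every sample independently under two exact
constraints — observed richness `S_k` and observed total `N_k`:

1. draw `S_k` distinct taxa by successive sampling without replacement,
   probability proportional to regional abundance (the table's column
   sums, or an explicit `pool`);
2. allocate `N_k` reads among the drawn taxa proportionally to regional
   abundance. The default *seeded* allocator gives each drawn taxon one
   read and distributes the remaining `N_k − S_k` multinomially — O(N),
   no rejection loops. A *rejection* allocator (redraw the full
   multinomial until every drawn taxon is non-empty) is available behind
   a flag.

Per pair, `deviation = (BC_obs − mean BC_null)/sd BC_null` over the
replicate ensemble (sample SD, n−1; 999 replicates by default; replicates
use independent seed substreams so they are reproducible independent of
execution order). Pairs with a degenerate (constant) null ensemble are
reported as missing, never ±∞.

Two measured properties of this procedure worth knowing:

- **Allocator marginals.** The seeded allocator slightly over-represents
  rare taxa in expected column totals (up to a few percent on small,
  high-inclusion fixtures) because of the guaranteed single read; the
  rejection allocator matches pool proportions to within sampling error.
  At survey scale (thousands of reads per sample) the distortion is
  negligible, and the seeded allocator is the only one that terminates
  reliably there (the rejection probability explodes when many drawn taxa
  expect < 1 read).
- **Own-pool conditioning.** Estimating the regional pool from the single
  observed table (the field convention) conditions the null on that
  realization; on data *generated by the null process itself* the
  procedure then scores a small negative mean deviation (≈ −0.3 with the
  seeded allocator at a 20-sample × 50-taxon scale) rather than exactly
  zero. When the generating pool is supplied explicitly the deviations
  calibrate to mean ≈ 0, SD ≈ 1, which is how the calibration test is
  constructed. Practical effect sizes (deviations of 5–50+ under real
  selection or dispersal limitation) dwarf this bias.

## Sloan neutral community model

Under neutral immigration at rate `m` into a local community of `N`
individuals, local relative abundance is Beta(Nmp, Nm(1−p)) for a taxon of
regional mean abundance `p`, so its expected occurrence frequency is
`F(p) = 1 − I_d(Nmp, Nm(1−p))` with detection limit `d = 1/N` (one read at
the rarefied depth; `N` is the rarefied depth, or the mean subset depth
for subcommunities). `m` is fitted by bounded scalar least squares on
occurrence frequencies (log-scale parameterization, multi-start, tolerance
1e-8); R² is computed on untransformed frequencies. R² can be negative
when occupancy is anti-monotone in abundance; fits with R² < 0.3 carry a
warning because `m` is then unidentified in practice. A 95% binomial
prediction band around the fitted curve is emitted for plotting.

**Estimation bias.** When `p` is estimated from the same table that
provides the occurrence frequencies, per-taxon sampling noise enters both
axes with positive correlation and the fitted `m` is biased upward
(measured ≈ +0.1–0.18 at 90 samples with a lognormal SAD, independent of
SAD spread). This is intrinsic to the standard fitting convention, not an
implementation artifact; the parameter-recovery test therefore generates
occurrence at the model's own detection limit and supplies the regional
abundances, which isolates estimator correctness (recovery within ±0.01
of the true `m` there). Published `m` values estimated the conventional
way should be read as upper bounds.

## Distances and tests

Bray–Curtis via `scipy.pdist`; geographic distance by haversine on a
spherical Earth (R = 6371 km); environmental distances are Euclidean on
z-scored covariates, entered per-variable so forward selection can prune
them. Mantel and PERMANOVA delegate to scikit-bio (seeded; two-sided
Mantel with +1-corrected p). The DDR is the OLS slope of (1 − BC) on km
over the lower triangle, within-site pairs retained; because pairs are
non-independent the naive OLS p is optimistic, so a label-permutation p is
offered alongside it.

## MRM, VPA, hierarchical partitioning

MRM is OLS on unfolded lower triangles. Significance permutes the
*sample labels* of the response matrix (rows and columns jointly) and
refits — permuting raw pair entries would break the distance dependence
structure. Forward selection greedily adds the candidate with the largest
R² gain whose coefficient permutation-p is below α (0.05), ties broken by
name for determinism. Two-set VPA: `pure_space = R²_full − R²_env`,
`pure_env = R²_full − R²_space`, `shared = R²_space + R²_env − R²_full`
(negative shared fractions are reported as-is; they indicate suppression),
`unexplained = 1 − R²_full`. Hierarchical partitioning computes each
group's independent contribution exactly via the subset-average (Shapley)
formula over all 2^(k−1) subsets, k ≤ 5 groups; contributions sum to the
full-model R² to 1e-10 by construction. The joint VPA design may be
deliberately collinear; R² there is computed by least squares without a
rank requirement.

## Path analysis

A recursive observed-variable path model over pairwise (distance-scale)
variables: every endogenous variable is regressed on its declared parents
after standardization, effects decompose by path tracing (total = sum over
directed paths of coefficient products; indirect = total − direct, an
exact identity). The default DAG is
space → {soil, climate, plant} → fungal β-deviation, plus a direct
space → deviation edge, and plant compositional distance as an additional
parent for the rare subcommunity. This gives the same point estimates as a
covariance-based SEM for this saturated recursive structure while staying
honest about what is identifiable from observed variables; latent
constructs and covariance fit indices are out of scope. Pair
non-independence inflates nominal precision, so a permutation p for the
outcome equation is available.

## Synthetic survey generator

The generator emulates a 30-site × 3-quadrat survey along a ~2,500 km
arid transect: a latent environmental axis is a weighted mixture of
spatial position (weight `env_spatial_corr`, default 0.7) and site noise;
soil, climate and plant covariates load on that axis with realistic signs
(e.g. soil moisture and plant cover decline toward the arid end); the
aridity index spans 0.03–0.32; vegetation types are quantile bins of the
axis; a small plant community with Gaussian niches supplies plant
compositional distances.

The ASV table combines three mechanisms, one knob each:

- **selection** — per-taxon Gaussian niches on the latent axis
  (`selection_strength` ≥ 0 exponentiates the niche factor);
- **dispersal limitation** — per-taxon home sites with exponential
  immigration decay (`dispersal_decay_km`; ∞ disables);
- **drift** — local relative abundances are Dirichlet(depth·m·p) around
  the immigration-weighted expectation (the Sloan mechanism;
  `m_immigration`, default 0.45, a realistic mid-range migration rate for
  soil fungi). `m = 1` is the exact no-drift limit whose data-generating
  process coincides with the fixed-richness multinomial null model — the
  reference point for null-model calibration. Note that genuine drift
  (m < 1) produces *positive* β-deviations: drift adds compositional
  variance beyond multinomial sampling, which the abundance null model
  correctly detects as non-sampling structure.

Regional abundances are lognormal (meanlog 0, sdlog 2 over 1,000 taxa),
chosen so threshold classification yields an abundant minority (< 15% of
taxa) holding most reads (> 50%), the empirical signature of soil fungal
surveys. Reads are multinomial at exactly `depth` (default 9,080) per
sample. The `mixed_scenario` contrasts the two tails: the abundant tail
assembles neutrally with moderate dispersal limitation (decay 800 km), the
rare tail under strong selection (strength 5) with unrestricted dispersal.
Under that configuration the pipeline reproduces the canonical field
contrasts — better neutral fit and broader niches for abundant taxa, a
much larger pure-environment fraction for rare β-deviations, steeper
distance decay for the dispersal-limited subcommunity.

What the generator does **not** emulate: phylogenetic or taxonomic
structure, guild composition, sequencing error and chimeras, compositional
biases of PCR, temporal dynamics, and interaction networks. Passing tests
demonstrate that the inference machinery recovers known mechanisms from
data with the right statistical geometry, not that any particular real
survey is driven by those mechanisms.

## Problem sizes and numerical choices

Calibration tests use deliberately small fixtures chosen for statistical
sufficiency: null-model self-calibration at 20 samples × 50 taxa with
299-replicate ensembles over 200 trials; permutation-test calibration at
n = 12 with 199 permutations over 500 null runs (the +1-corrected p makes
the nominal 0.05 level exact at these sizes); neutral-model recovery at
the full survey scale (90 samples, 1,000 taxa, depth 9,080, 20
replicates). Algebraic identities are asserted to 1e-10; hand-checked
values to 1e-6; the quadrature cross-check of the incomplete-beta
frequency curve to 1e-6 over a 100-point grid. All randomness flows from
explicit seeds; the pipeline derives per-stage seeds by stable hashing of
(master seed, stage name), and a rerun with the same configuration and
seed is byte-identical.

## Known limitations

- β-deviation pairs are mutually dependent; all downstream inference on
  them uses matrix-permutation schemes, but parametric standard errors
  printed by the path model are optimistic.
- The NCM `m` estimate is only as good as the frequency–abundance
  relationship (see bias note above); compare R² before interpreting `m`.
- The null model is taxonomic only; phylogenetic null models (βNTI,
  RCbray) are out of scope because ITS sequences cannot be reliably
  aligned across the community.
- PERMANOVA assumes exchangeability under the null; strong dispersion
  differences between groups can masquerade as location effects.
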