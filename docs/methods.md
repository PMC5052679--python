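# Methods

This note documents the models, conventions and numerical choices behind
`saltmarsh`, and what the synthetic generators do and do not emulate.

## Activity ratios and dormancy classification

For taxon *i* in one biological sample with RNA (16S rRNA, via cDNA) count
`rna_i` and DNA (16S rRNA gene) count `dna_i`, the activity ratio is

    r_i = rna_i / (dna_i + 1)

The `+1` is applied to the DNA denominator only: a taxon observed in the
rRNA pool must be present in the community, so a zero gene count is read
as "below sequencing depth", giving RNA-only taxa a finite, large ratio
rather than an infinity. A detected taxon (nonzero in at least one
library) is **dormant** when `r_i ≤ θ` and **active** when `r_i > θ`; the
boundary `r = θ` is dormant. The default threshold θ = 1 says a taxon is
active only when its rRNA exceeds its (presumed) gene abundance; the
threshold sweep re-runs classification over θ = 1…50 and is monotone by
construction, so a dormancy contrast that holds across the sweep is not a
threshold artefact. The per-sample dormant proportion is richness-based
(fraction of detected taxa; undetected taxa are excluded from the
denominator); an abundance-weighted variant is available behind a flag.

**Depth normalization.** DNA and RNA library sizes differ for technical
reasons, and the ratio is directly proportional to that imbalance. By
default every library (column) is rescaled to the mean library size of
the paired table before the `+1` is added; raw-count mode
(`normalize=False`) reproduces pipelines that skip this step. Because the
+1 is added after scaling, normalized counts are real-valued; this is
intentional (rounding would re-quantize the boundary).

**Compositional caveat.** Sequencing depth is fixed, so RNA relative
abundances are constrained to sum to one: ratios measure activity
*relative to the community average*. When dormancy is genuinely prevalent
(the regime this method targets) active taxa sit well above the average
and classification is reliable — the recovery tests show the estimator
stays within ±0.05 of truth at true dormant fractions 0.45 and 0.90. In
the degenerate limit where every taxon is similarly active, ratios centre
on 1 and roughly half of the taxa fall below any threshold near 1; no
depth-normalized ratio method escapes this, and the all-active generator
test asserts the identity (estimate = classifier false-positive rate)
rather than pretending the rate is small. Per-taxon ribosome-copy-number
variation is likewise not corrected for — ratios are comparable within a
taxon across samples, less so across taxa.

**Order-level display ratios.** For order-level summaries, OTU counts are
summed per order and the display ratio is `(Σrna + 1) / (Σdna + 1)` — the
+1 on *both* sides is a deliberate visualization-only deviation that keeps
log₁₀ finite for orders absent from one library; classification never uses
it. Orders are ranked by total reads and kept until they jointly cover 90%
(configurable) of all reads; means and s.e.m. are reported per treatment
group.

**Dormancy ANOVA.** Differences in per-sample dormant proportions across
treatments use a classical one-way ANOVA; the all-values-identical
degenerate case returns F = 0, p = 1 by convention.

## Rarefaction and Shannon diversity

Rarefaction is exact subsampling without replacement: each column is drawn
from the multivariate hypergeometric distribution at the target depth
(samples shallower than the depth are dropped with a warning, never
up-sampled). Shannon diversity is `H = −Σ p_i log₂ p_i` over positive
counts, reported in bits (the base is configurable). `mean_rarefied_shannon`
averages H over independent restarts at a fixed depth; its variance
shrinks roughly as 1/restarts. The "abundant active" census counts taxa
with at least `min_count` (default 100) RNA reads — summed within the
comparison group by default, with per-sample and whole-dataset readings
behind a flag, since "present at least 100 times" is ambiguous — whose
mean activity ratio across the group's samples exceeds θ.

## Community structure

Bray–Curtis dissimilarity `Σ|x−y| / Σ(x+y)` is computed on
relative-abundance-normalized columns by default (rarefied or raw modes
are the caller's choice of input table). Weighted UniFrac uses scikit-bio
on a rooted tree, defaulting to the normalized variant (bounded [0, 1]);
the test suite checks it against an explicit per-branch mass-summation
oracle.

PCoA eigendecomposes the double-centred Gram matrix −J D² J / 2;
coordinates come from positive eigenvalues only, the full spectrum
(including negative eigenvalues, which flag non-Euclidean distances) is
reported, and axis variance fractions divide by the total absolute
eigenvalue mass so they sum to at most 1.

PERMANOVA computes the adonis-style pseudo-F
`(SS_B/(a−1)) / (SS_W/(N−a))` with sums of squares decomposed from squared
distances, and a permutation p-value `(#{F_perm ≥ F_obs} + 1)/(n_perm + 1)`
(never exactly zero) under a seeded generator; permutations are evaluated
vectorized in chunks. Single-factor tests are the default, matching the
per-factor reporting style of distance-based analyses. An optional
`strata` argument permutes labels only within strata: when a balanced
nuisance factor (habitat, season) structures the distances, unrestricted
permutation is conservative for the tested factor because random
relabelings break the balance and inflate the permuted F; within-stratum
permutation keeps the null exchangeable and the type-I error nominal (the
calibration tests demonstrate both behaviours). Per-taxon differential
abundance uses Kruskal–Wallis on relative abundances with the chi-square
reference (constant taxa return H = 0, p = 1), and p-values are adjusted
by Bonferroni or Benjamini–Hochberg step-up.

## Tidal-creek net ecosystem metabolism

For a control volume of unit creek length with a trapezoidal cross-section
(bottom width b, bank slope s per side): surface width `w(h) = b + 2sh`,
wetted volume `V(h) = bh + sh²`. The oxygen budget

    d(VC)/dt = Q_adv · C_b + F_gas + NEM

is solved for NEM (mmol O₂ m⁻¹ min⁻¹, positive = net autotrophy) with:

- `Q_adv = dV/dt` — freshwater, porewater and platform-drainage volume
  fluxes are ~1% of the tidal flux in these creeks and are not modelled;
- `C_b = C`, the in-creek concentration — a single-sensor, well-mixed
  control volume (an upstream/downstream two-concentration mode would
  need a second sensor);
- `F_gas = k·(C_sat − C)·w(h)`, positive into the water.

Derivatives are central differences with one-sided stencils at the record
ends, evaluated on a grid (default 10 min) that must subdivide the sensor
step. The budget identity NEM + Q_adv·C + F_gas = d(VC)/dt holds to
machine precision at every timestep by construction, so integrated mass is
conserved at the resolution the estimator defines.

**Solubility.** Equilibrium O₂ concentration uses the combined fit of the
Benson & Krause solubility data (Garcia–Gordon functional form), with both
volumetric (mmol m⁻³, default) and per-mass (µmol kg⁻¹) coefficient sets,
valid for −2…40 °C and salinity 0…42; the tests verify the published
check value at T = 10 °C, S = 35 against an independently coded
polynomial.

**Gas exchange.** The transfer velocity is a registered parameterization
`k600 = c·√(u/h) + a·U²` (cm h⁻¹; surface-renewal current term plus
quadratic wind term, the standard forms for shallow limited-fetch
channels), rescaled to O₂ by `(Sc/600)^−0.5` with the seawater Schmidt
number polynomial. The default coefficients (c = 0.77, a = 0.266) are
configuration, not physics constants — published estuarine fits differ —
and every registered model must satisfy k ≥ 0, non-decreasing in wind and
current. Wind-only and current-only variants are registered and produce
directionally smaller fluxes. Bubble injection by rising tides is not
modelled; a constant-bias hook (`apply_bias_correction`) subtracts a
user-supplied bias (for example 0.35 mmol O₂ m⁻¹ min⁻¹ for
platform-drainage import) from flagged windows only.

**High-tide summaries.** High tides are local depth maxima separated by at
least 6 h (semidiurnal); NEM is averaged over a 60-min window centred on
each peak (truncated windows are dropped with a warning). Windows whose
peak depth exceeds the marsh-platform flooding elevation are flagged
`peak_flood_bias`, because the single-channel volume model is biased when
the platform floods. Creek differencing matches windows by tide time and
propagates s.d. as √(s_a² + s_b²).

## Synthetic data

**Communities.** Taxon base abundances follow a lognormal rank-abundance
law (σ = 1.1 over 250 taxa by default). A fraction *p* of taxa (default
0.45) is dormant with activity multipliers log-uniform on (0.02, 0.6];
active taxa draw multipliers lognormal(median 25, σ_log 0.15) — order 10
ratios are what clearly active taxa show in rRNA:rDNA surveys, and the
narrow spread keeps the two classes separated on the ratio scale after
compositional renormalization. RNA relative abundances are base × 
multiplier, renormalized; DNA and RNA reads are multinomial draws (depth
5 × 10⁴ per library) after a Dirichlet perturbation of the per-sample
proportions (concentration 10⁵, i.e. mild overdispersion ~doubling
multinomial variance for mid-abundance taxa). Enrichment is modelled as
*activity reassignment only*: all but a bloom cohort (18% of active taxa)
are demoted to dormancy and the bloom multipliers are boosted ×5, giving
an effective dormant fraction of 0.45 + 0.55·0.82 ≈ 0.90 while the DNA
table stays treatment-invariant by construction. The full experiment
crosses 2 treatments × 2 habitats × 6 months × 3 replicates (72 paired
samples); habitat tilts base abundances identically in both treatments
(so habitat, but not treatment, structures the DNA community) and month
jitters activity multipliers (seasonal structure in RNA). Taxonomy
assigns taxa to real order names (bloom taxa to Desulfobacterales /
Oscillatoriales) and a random coalescent-style tree with exponential
branch lengths covers the taxa for UniFrac.

What the generator does **not** emulate: per-taxon 16S copy-number
variation, PCR/primer bias, chimeras, sequence-level errors, spatial
autocorrelation between replicate cores, and taxon-taxon interactions.
Passing recovery tests therefore show the *estimator* is correct under
the stated statistical model, not that real marsh data are free of those
biases.

**Tidal creek.** Depth is offset 1.0 m + a 0.8 m semidiurnal sine
(12.0 h period — an idealized M2; the lunar 12.42 h would work equally
but not give a whole number of tides in 6 days) + a 0.15 m diurnal
inequality so successive high tides alternate in height and only the
higher ones flood the platform (elevation 1.8 m). Gross production is a
daylight half-sine (amplitude 1.5 mmol O₂ m⁻¹ min⁻¹, sunrise 06:00, 12 h
of light; a `constant_light` switch enables the analytic equilibrium
limits); respiration is constant 0.5. The oxygen state is integrated with
Heun's method at a 1-min internal step, reported at the 10-min sensor
step as saturation percent with optional Gaussian noise. Because the
forward model and the inverse estimator share the budget equation, the
inversion recovers the prescribed NEM to a fraction of a percent of its
range on noise-free records (the residual is the O(Δt²) finite-difference
error), and a 6-day run yields exactly 12 high-tide windows.

## Problem sizes and reproducibility

Every stochastic path takes an explicit integer seed (numpy Generator
streams) and is bit-reproducible. The test suite validates the dormancy
classifier against exhaustive re-computation on 200 random tables,
parameter recovery at p ∈ {0.45, 0.90} over 20 seeds × 20 samples at
depth 5 × 10⁴, treatment-detection power over 50 replicate experiments and
null calibration over 1,000 replicates (10,000 permutations each where
power/calibration is asserted), and the NEM forward–inverse loop on 6-day
records. `scripts/acceptance.py` re-runs the pipeline at these same sizes
from a single command-line seed.

## Known limitations

- Ratios inherit all compositional and copy-number caveats above; the
  dormant proportion is an operational, threshold-dependent quantity.
- PERMANOVA is single-factor; multi-factor decomposition beyond separate
  per-factor runs (and within-stratum permutation) is not implemented.
- The NEM control volume absorbs sediment oxygen demand implicitly; no
  hydrodynamics, salinity or heat budgets, and no bubble-injection model.
- BIOM support is the dense JSON dialect only.
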