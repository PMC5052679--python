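# saltmarsh

Dormancy, diversity and ecosystem-metabolism analysis for paired 16S rRNA /
16S rRNA-gene surveys of salt marsh sediments, plus a non-steady-state
dissolved-oxygen estimator of net ecosystem metabolism (NEM) in tidal
creeks.

## The scientific problem

Most cells in sediment microbial communities are not active at any given
moment. Sequencing the 16S rRNA **gene** (DNA) censuses the *total*
community — active, dormant and dead alike — while sequencing the 16S rRNA
itself (via cDNA) tracks the *potentially active* fraction, because
ribosome content rises with protein synthesis. Comparing the two libraries
taxon by taxon therefore separates activity shifts from compositional
shifts, which matters when a perturbation (for example chronic nitrogen
loading of a marsh) changes *who is active* without changing *who is
there*.

This package provides the full analysis chain for such paired surveys:

- **Activity ratios and dormancy** — for each taxon *i* in each sample,
  `r_i = rna_i / (dna_i + 1)` on depth-normalized counts; a detected taxon
  with `r_i ≤ θ` (default θ = 1) is classified dormant. The `+1` on the
  gene count encodes the assumption that a taxon observed in the rRNA pool
  is present even when its gene fell below the sequencing depth. A
  threshold sweep (θ = 1…50) shows whether conclusions depend on θ.
- **Diversity of the active community** — exact rarefaction (multivariate
  hypergeometric subsampling) and Shannon diversity `H = −Σ p log₂ p` in
  bits, with restart averaging; the census of abundant active taxa
  (≥ 100 RNA reads, mean ratio > θ).
- **Community structure** — Bray–Curtis and branch-length-weighted UniFrac
  distances, principal coordinate analysis, one-factor PERMANOVA
  (adonis-style pseudo-F with seeded permutations, optionally stratified),
  per-taxon Kruskal–Wallis with Bonferroni or Benjamini–Hochberg
  correction.
- **Tidal-creek metabolism** — for a creek control volume of unit length,
  the oxygen budget `d(VC)/dt = Q_adv·C_b + F_gas + NEM` is solved for NEM
  (mmol O₂ m⁻¹ min⁻¹; positive = net autotrophy) from sonde records of
  depth, temperature, salinity, O₂ saturation, wind and current, then
  summarized over the hour of each high tide and differenced between
  creeks.
- **Synthetic data with ground truth** — a Dirichlet-multinomial community
  generator with a controllable true dormant fraction and
  treatment/habitat/season structure, and a forward tidal-creek oxygen
  model with prescribed production and respiration, so every stage of the
  pipeline is validated against known truth.

## Worked example

```python
import numpy as np
from saltmarsh import (CommunitySimConfig, simulate_experiment,
                       dormant_proportion, bray_curtis, permanova)

data = simulate_experiment(CommunitySimConfig(seed=1))
paired = data.paired
props = np.array([dormant_proportion(paired, s) for s in paired.sample_ids])
treatment = paired.metadata["treatment"].to_numpy()
print("dormant % (reference):", round(100 * props[treatment == "reference"].mean(), 1))
print("dormant % (enriched): ", round(100 * props[treatment == "enriched"].mean(), 1))

res = permanova(bray_curtis(paired.rna_table()),
                paired.metadata["treatment"], n_perm=10_000, seed=2)
print(f"active community vs treatment: F = {res.pseudo_f:.1f}, p = {res.p_value:.4f}")
```

prints

```
dormant % (reference): 45.5
dormant % (enriched):  90.0
active community vs treatment: F = 1962.8, p = 0.0001
```

Here the generator was told that 45% of taxa are dormant under reference
conditions and that enrichment demotes most active taxa while boosting a
small bloom cohort (effective dormancy 90%); the estimator recovers both
from the simulated read counts alone, and PERMANOVA on the RNA-based
distances detects the treatment while the DNA (total-community) table is
treatment-invariant by construction. The `examples/` directory walks
through each capability (dormancy, community structure, creek metabolism)
as a short narrative script.

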