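# medrefugia

Tools for asking where Mediterranean-scale genetic diversity came from when
humans have scrambled the map. The package joins two analysis arms that are
usually run with separate point-and-click programs into one tested,
scriptable pipeline:

1. **Single-locus phylogeography** — haplotype handling and diversity
   statistics for a geo-referenced mitochondrial alignment (e.g. *cox1*),
   objective lineage delimitation by statistical-parsimony networks and
   single-threshold GMYC, neutrality tests with coalescent-simulation
   significance, Mantel tests of isolation by distance, and grid-based
   bootstrap maps of haplotype diversity, richness and rarity.
2. **Paleo-niche refugium mapping** — bioclim variables from monthly
   climatologies, change-factor downscaling of paleoclimate anomalies
   (Last Glacial Maximum, mid-Holocene, present), an environmental PCA
   enforced across time slices, a regularized maximum-entropy niche model
   with partial-ROC evaluation and MOP extrapolation masking, and
   delimitation of glacial refugia as areas continuously suitable through
   time, under two orders of operations (M1: per-slice model consensus
   then temporal intersection; M2: per-model temporal intersection then
   consensus) across an ensemble of AOGCMs.

A synthetic-data module generates every input with known truth —
coalescent genealogies, infinite-sites alignments placed on a map with or
without spatial structure, and multi-GCM monthly climate suites with a
known suitability function — so each stage, and the pipeline end to end,
is verified at desk scale.

## The statistics at the core

* **Haplotype diversity** `Hd = n(1 − Σ pᵢ²)/(n − 1)`; **nucleotide
  diversity** π as the mean per-site pairwise difference; p-distances with
  pairwise deletion.
* **Fu's Fs** from the Ewens sampling formula:
  `S′ = Pr(K ≥ H_obs | θ̂ = k̄, n)` with unsigned Stirling numbers of the
  first kind computed in log space, `Fs = ln(S′/(1 − S′))`; **R2** =
  `sqrt(mean (Uᵢ − k̄/2)²)/S`. Significance for both comes from
  fixed-S neutral coalescent simulation.
* **Statistical parsimony connection limit**: the largest number of
  mutational steps j for which a connection is parsimonious with stated
  probability, using the finite-sites collision estimate
  `P(j; L) = (3/4)^(j²/L)` (for L = 1016 sites: 13 steps at 95%, 5 at
  99%). Haplotypes connected within the limit form networks; connected
  components are putative evolutionary units.
* **GMYC (single threshold)**: on an ultrametric gene tree, maximize
  `Σᵢ [ln bᵢ − bᵢ xᵢ]` with mixed hazard
  `bᵢ = λ₁ n_Y^p₁ + λ₂ Σ_c [n_c(n_c − 1)]^p₂` over the threshold age and
  parameters; likelihood-ratio test against a single-process null.
* **Maxent**: maximize `(1/m) Σ η·f(xᵢ) − log Z(η) − Σ βⱼ|ηⱼ|` over
  presences, features f = polynomial terms of the environmental PCA
  scores, `βⱼ = r·sⱼ/√m`; the raw output `exp(η·f)/Z` sums to one over
  the background.
* **Refugium consensus**: with binary suitability maps indexed by model g
  and time slice t, `M1(k) = ⋂_t [Σ_g map_{g,t} ≥ k]` and
  `M2(k) = [Σ_g ⋂_t map_{g,t} ≥ k]`; M2(k) ⊆ M1(k) always.

## Worked example

Simulate a four-lineage geo-referenced dataset under the default study
conditions and run the molecular arm:

```sh
medrefugia popgen --seed 11 --outdir demo_run
```

`demo_run/summary_stats.csv` then holds (rounded):

```
scope  n  L_eff   S  H     Hd     pi    kbar      Fs     R2
  all 60   1016 136 33 0.9734 0.0359 36.5045
   A1 15   1016  16 10 0.9143 0.0034  3.4667 -3.5184 0.1051
   A2 15   1016  12  8 0.8667 0.0034  3.4095 -1.2976 0.1254
   A3 15   1016  33  8 0.9143 0.0075  7.6571  1.0616 0.1509
   A4 15   1016  10  7 0.8571 0.0030  3.0286 -0.6703 0.1422
```

Each lineage of 15 samples carries 7–10 haplotypes at high haplotype but
low nucleotide diversity (π ≈ 0.3–0.8%), the signature of shallow
within-lineage genealogies; negative Fs values lean toward demographic
expansion. `demo_run/parsimony_networks.csv` shows the connection limits
and resulting network counts:

```
 confidence  max_steps  n_networks
       0.95         13           5
       0.99          5           7
```

At the 95% limit (13 steps for 1016 sites) the 33 haplotypes fall into 5
independent networks; the stricter 99% limit (5 steps) splits them into
7 — lineages separated by more steps than the limit can never connect.
The Mantel test on locality-level matrices reports r = 0.632,
p = 0.001 (999 permutations): the simulated lineages are spatially
structured, as configured (`mixing_fraction = 0`). Re-running with
`mixing_fraction = 1` erases the correlation.

The niche arm runs the full climate → ENM → refugia chain on the
synthetic suite:

```sh
medrefugia refugia --seed 11 --outdir demo_niche
```

writing per-GCM binary suitability maps, refugium maps for every
stringency (ESRI ASCII grids), component tables, and a manifest with the
Jaccard overlap between recovered and true refugia.

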