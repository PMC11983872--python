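# microturn

Analytics for **longitudinal 16S rRNA amplicon surveys of the gut
microbiota**, built around the question of how quickly a host's microbial
community turns over and how its oxygen-tolerance composition differs
between host environments (e.g. wild versus laboratory house mice).

The package takes an ASV count table (amplicon sequence variants × samples)
with taxonomy, per-sample metadata and a phylogeny, and provides:

* **Table processing** — per-source read-depth filtering, singleton/doubleton
  ASV removal, relative-abundance normalisation, and the centred log-ratio
  (CLR) transform with a global half-minimum pseudocount.
* **Alpha diversity** — observed richness/Shannon, bias-corrected Chao1
  richness, and the Chao–Jost asymptotic Shannon estimator (Hill number
  q = 1).
* **Beta diversity** — binary Jaccard, Aitchison (Euclidean on CLR), and
  unweighted/weighted-normalised UniFrac, plus classical PCoA.
* **Aerotolerance classification** — a three-tier rule (genus → family
  consensus → species-level override for mixed genera) assigning each ASV
  to obligate anaerobe / aerotolerant / unknown, with per-sample community
  summaries and category-partitioned re-analysis.
* **Turnover modelling** — within-individual (Δt, distance) pairs fitted
  with a (log-)linear model and a quadratic-plateau model, compared by AIC;
  plus origin tracking of newly detected vs persisting ASVs, start-to-end
  retention, persistent-ASV sets, and shared-ASV fractions.
* **Permutation statistics** — permutational Wilcoxon rank-sum tests on
  dissimilarities (sample-level label permutation), single-factor PERMANOVA,
  and a beta-dispersion test.
* **A synthetic-cohort generator** that emulates the longitudinal structure
  the analysis assumes (persistent core + transient replacement, arm-specific
  aerotolerant abundance, multinomial depth noise), used throughout the test
  suite and runnable from the CLI.

## The turnover model

Within one individual sampled repeatedly, community dissimilarity d (e.g.
binary Jaccard) is modelled as a function of the time Δt between samples:

* linear: `d(t) = β₀ + β₁·t` (optionally on log t), and
* quadratic plateau:

  ```
  d(t) = a + b·t + c·t²        for t ≤ t* ,   c < 0
  d(t) = a − b²/(4c)           for t > t* ,   t* = −b/(2c)
  ```

The two pieces join at the vertex, so the curve is continuous with
continuous slope; `t*` (the *critical point of inflexion*) marks where
turnover saturates and the plateau `a − b²/(4c)` is the asymptotic
dissimilarity. Models are compared by `AIC = n·log(RSS/n) + 2k` with the
error variance counted in k (k = 3 linear, k = 4 plateau); a community that
keeps diverging over the window selects the linear model, one that
decorrelates and saturates selects the plateau model.

## Worked example

Simulate a two-arm cohort (5 individuals per arm, 5 roughly weekly samples
each) and run the full pipeline:

```bash
microturn simulate --seed 1 --out cohort
microturn run --input-dir cohort --out report --seed 1 --n-perm 999
```

The run prints the stage summary (`load`, `depth_filter`,
`rare_asv_removal`, `normalise`, `diversity`, `distances`, `group_tests`,
`aerotolerance`, `turnover`, all `OK`) and writes every intermediate to
`report/`. With this seed, `report/turnover_report.json` contains:

```
lab   selected: linear    n_pairs: 46   slope=0.0085  R²=0.763
wild  selected: plateau   n_pairs: 50   t_crit=26.3 d R²=0.670
lab   shared ASV fraction 0.839   persistent ASVs: 11
wild  shared ASV fraction 0.339   persistent ASVs: 0
```

The wild-like arm saturates (plateau selected, inflexion ≈ 26 days inside
the 0–31-day window) while the slow lab-like arm keeps rising (linear
selected); lab-like repeat samples share ~84% of their combined ASVs versus
~34% in the wild-like arm, and persistent taxa (detected in every sample of
every individual) are plentiful in the lab-like arm and absent in the
wild-like one. `report/group_tests.json` shows the two arms are
compositionally distinct (PERMANOVA on Jaccard: F = 4.07, R² = 0.080,
p = 0.001), and `report/aerotolerance_profile.tsv` gives mean aerotolerant
relative abundance 0.116 (lab-like) versus 0.347 (wild-like), reflecting
the configured targets of 0.112 and 0.377.

The same operations are available as library functions:

```python
from microturn import (SimulationConfig, simulate_dataset, jaccard_matrix,
                       within_individual_pairs, fit_linear_turnover,
                       fit_quadratic_plateau, select_turnover_model)

ds = simulate_dataset(SimulationConfig(seed=1))
d = jaccard_matrix(ds.table)
pairs = within_individual_pairs(d, ds.table.metadata)
best, delta_aic = select_turnover_model(
    [fit_linear_turnover(pairs), fit_quadratic_plateau(pairs)]
)
```

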