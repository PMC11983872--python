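# Methods

This note documents the models, estimators, and design decisions behind
`microturn`, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and table processing

The central object (`AsvTable`) is an integer count matrix of amplicon
sequence variants (ASVs) × samples with per-ASV taxonomy
(domain … genus, optional species; missing ranks are empty strings) and
per-sample metadata (animal, group, source `lab`/`wild`, collection day,
read count). Invariants enforced at construction: unique row/column labels,
non-negative counts, metadata coverage of every sample.

Processing steps follow the standard longitudinal 16S workflow:

* **Depth filtering** removes samples whose total read count falls below a
  source-specific threshold (defaults 7 500 for lab, 5 000 for wild — the
  depths at which sample-completeness curves for such data typically
  plateau). The threshold is inclusive: a sample at exactly the threshold
  is retained.
* **Rare-ASV removal** drops ASVs whose *total* count across the table
  passed in is 1 or 2 (singletons/doubletons). Rarity is defined on total
  read count, not prevalence, matching the frequency-count framework of the
  asymptotic diversity estimators; the caller applies it separately per
  dataset partition (wild and lab), since an ASV rare in one partition may
  be abundant in the other. Prevalence-based rarity would be a defensible
  alternative reading; the count-based rule is the one implemented.
* **Relative abundance** divides each sample column by its sum (zero-sum
  columns are an error naming the sample).
* **CLR transform**: zeros are replaced by half the smallest nonzero
  relative abundance taken over the *whole matrix* (a single global
  replacement value, as in the common compositional-analysis
  implementations), then each column x becomes log x − mean(log x). No
  renormalisation is performed after the pseudocount: CLR is invariant to
  positive scaling, so the small departure from unit sum is immaterial.
  Output columns sum to zero within 1e-9.

## Alpha diversity

Two asymptotic Hill-number estimators, natural logs throughout:

* **Chao1 (q = 0), bias-corrected**:
  `S_obs + ((n−1)/n) · f₁(f₁−1) / (2(f₂+1))`, with f₁/f₂ the
  singleton/doubleton counts and n the read total. With f₁ = 0 it collapses
  to observed richness. (Note the `(n−1)/n` factor: some library
  implementations omit it; the form here is the one used by the standard
  asymptotic-diversity tooling.)
* **Chao–Jost asymptotic Shannon (q = 1)**: observed part
  `Σ (Xᵢ/n)(ψ(n) − ψ(Xᵢ))` (the inner sum of reciprocals written with
  digamma functions for numerical stability at large n) plus the
  unseen-species correction
  `(f₁/n)(1−A)^{1−n} [−ln A − Σ_{r=1}^{n−1} (1/r)(1−A)^r]`, with
  A = 2f₂/((n−1)f₁ + 2f₂) when f₂ > 0, A = 2/((n−1)(f₁−1) + 2) when f₂ = 0
  and f₁ > 1, and A = 1 otherwise. The Hill number is exp(entropy). In the
  degenerate all-singletons case (f₁ = n) the estimator is unstable and the
  plug-in entropy is returned with a logged warning. Both the entropy and
  its Hill number are emitted, since reports of "Shannon diversity" are
  ambiguous between the two.

Both estimators converge to the plug-in values as sample completeness
approaches one (tested by simulation).

## Beta diversity

* **Jaccard (binary)**: 1 − |A∩B|/|A∪B| on presence sets (count > 0).
  Samples with empty presence sets are rejected by name.
* **Aitchison**: Euclidean distance between CLR-transformed columns.
* **UniFrac** over a rooted phylogeny with non-negative branch lengths,
  computed by one post-order traversal that accumulates per-branch
  descendant abundance for all samples simultaneously (O(#branches) per
  pair afterwards). Unweighted: unique branch length over the union branch
  length of the two samples. Weighted, *normalised* form:
  `Σ l_b·|p_A − p_B| / Σ l_b·(p_A + p_B)` — this keeps the metric in
  [0, 1]; published weighted-UniFrac variants differ in normalisation, so
  the choice is asserted here rather than inferred.
* **PCoA**: classical scaling of the doubly centred −½d² matrix. Axes with
  positive eigenvalues are returned (scaled by √λ) in decreasing order;
  negative eigenvalues are reported to the caller and their axes dropped —
  no Lingoes/Cailliez correction is applied.

## Aerotolerance classification

Each ASV is assigned `obligate_anaerobe`, `aerotolerant` (anything other
than an obligate anaerobe for which tolerance information exists, including
facultative anaerobes), or `unknown`, by rule order:

1. **genus tier** — assigned genus present in the genus table with a single
   category;
2. **family tier** — consulted *only when the genus tier fails* (genus
   unassigned or absent from the table): the family's category is used only
   if every genus recorded for that family shares it;
3. **species-override tier** — a genus recorded as `mixed` (containing both
   obligate anaerobes and aerotolerant species) defers to an exact
   species-level override table keyed by ASV id or binomial name. The
   override table stands in for live full-identity/full-coverage 16S
   matches, which are irreproducible as network queries; the table is built
   upstream under that criterion. A miss, and any other fall-through, is
   `unknown` with tier `unresolved`.

Classification is a pure function of (taxonomy, database); removing
information from the database can only move calls toward `unknown`.

Per-sample summaries report summed relative abundance per category (summing
to one), detected-ASV richness per category, and the proportion of
aerotolerant taxa among taxa of known tolerance. That proportion is
abundance-based by default with a richness-based switch — the two readings
are both plausible for this kind of response variable, and they are one
flag apart. It is reported missing when no taxa of known tolerance are
present. Category subtables (for re-running richness/beta-diversity
analyses on the anaerobic or aerotolerant fraction) keep the full sample
set; samples left empty are flagged and excluded from downstream distance
calls.

## Turnover analysis

All unordered within-individual sample pairs enter the analysis, not only
consecutive ones: an individual with c samples contributes c(c−1)/2 (Δt,
distance) observations. Pairs are treated as independent in fitting; the
pseudo-replication this entails is a property of the analysis design and is
documented, not corrected.

* **Linear model**: OLS of distance on Δt or log Δt. Both time scales are
  implemented because "(log-)linear" is ambiguous; neither is privileged.
* **Quadratic plateau**: the vertex-joined piecewise model above, fitted by
  bounded nonlinear least squares (`scipy.optimize.least_squares`, trust
  region) initialised from an unconstrained quadratic OLS fit, with c < 0
  and b ≥ 0 enforced (so the vertex t* = −b/(2c) is positive). On strictly
  linear data the fitted vertex migrates past the upper end of the observed
  Δt range (flagged on the result, not rejected) and the model degenerates
  to a gentle quadratic.
* **Model selection**: minimal `AIC = n·log(RSS/n) + 2k` with k counting
  coefficients plus the error variance (3 linear, 4 plateau). Absolute AIC
  differs from other conventions by an additive constant that cancels in
  ΔAIC. Fits are tagged with a hash of the data they were fitted to;
  comparing fits across different data is an error. On linear-truth data
  the one-sided c < 0 constraint gives a plateau false-selection rate of
  roughly the halved χ²₁ tail, ~7–8% at n = 300 (measured by simulation in
  the acceptance suite).
* **Origin tracking** labels every detected ASV by its first-detection
  timepoint within the individual (detection is count > 0, no abundance
  threshold) and reports, per timepoint, the fraction of detected ASVs and
  of relative abundance carried by each origin bin (each summing to one).
* **Retention** compares first and last timepoints: fraction of initial
  ASVs still detected, and share of final relative abundance carried by
  initially present ASVs. **Persistent ASVs** are those detected in every
  sample of every listed animal; reported with per-animal combined relative
  abundance (averaged over timepoints) and prevalence in a reference sample
  set (full set, and ≥ k members). **Shared-ASV fraction** is
  |A∩B|/|A∪B| = 1 − binary Jaccard, exactly.

## Permutation statistics

Pairwise dissimilarities are not independent, so group comparisons permute
**sample-level** labels, never pairs: that is the only scheme that respects
the dependence between pairs sharing a sample.

* **Permutational Wilcoxon**: Mann–Whitney U comparing within-group-A
  against within-group-B distances; the null permutes the sample labels
  (group sizes fixed, so the pair layout and U's null centre nm/2 are
  invariant) and recomputes; two-sided via |U − nm/2|.
* **PERMANOVA (one factor)**: SS_total = (1/N)Σ_{i<j}d²ᵢⱼ, SS_within =
  Σ_g (1/n_g)Σ_{i<j∈g}d²ᵢⱼ, pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)),
  R² = SS_between/SS_total; significance by label permutation. Multi-factor
  marginal designs are intentionally out of scope.
* **Beta dispersion**: samples are embedded by principal coordinates
  keeping *all* axes, negative-eigenvalue axes contributing negatively to
  squared distances (signed combination; negative squared distances are
  clipped at zero before the root). Distances to the **group centroid**
  (not the spatial median — the simplest published variant) feed a one-way
  ANOVA F, with p obtained by permuting the group labels of the
  distance-to-centroid values.

All permutation p-values use the add-one convention
p = (1 + #{at least as extreme})/(1 + n_perm), bounded below by
1/(n_perm + 1), with an explicit seed; default 1 000 permutations.
Calibration under the null (uniform p-values, nominal type-I error) is
verified by simulation in the acceptance suite.

## Synthetic cohort generator

The generator produces the data structure the analysis assumes, for two
contrasting arms (`lab_like`, `wild_like`):

* a **metacommunity pool** (default 400 ASVs) with lognormal base
  abundances (σ = 1.2, a typical taxon-abundance skew), a random rooted
  binary phylogeny with Exp(1) branch lengths, ground-truth aerotolerance
  labels allocated by largest-remainder rounding of the configured
  fractions (default 0.5/0.3/0.2 anaerobe/aerotolerant/unknown), and a
  taxonomy deliberately stratified so that every classifier tier is
  exercised (genus-resolved, family-concordant, family-discordant, mixed
  genera with and without species overrides, and DB-absent genera for
  truly-unknown taxa);
* per individual, a **fixed core** (never replaced; default 35 taxa holding
  62% of abundance in the lab-like arm, 8 taxa holding 9% in the wild-like
  arm — anchored to the persistent-taxon counts and abundance shares
  reported for laboratory vs wild house mice) plus **transient taxa**
  (default 90), each independently replaced between consecutive timepoints
  with an arm-specific probability (defaults 0.06 lab-like, 0.45 wild-like,
  chosen so the wild-like arm decorrelates within ~3 weeks while the
  lab-like arm rises slowly over the month-long window). Replacements are
  drawn from the pool proportional to base abundance, excluding currently
  present taxa, which keeps richness approximately stationary — consistent
  with repeat samples showing no richness trend;
* an imposed arm-specific **aerotolerant abundance share** (defaults 0.112
  lab-like, 0.377 wild-like, the reported mean relative abundances), applied
  by rescaling the category blocks of the latent weights *after* the
  core/transient split — the realised core abundance share is therefore
  approximate while the aerotolerant share is exact by construction;
* observed counts drawn **multinomially** at a depth uniform on
  [5 000, 60 000] (uniform rather than lognormal for simplicity; the bounds
  match the depth range the filters assume). Sampling schedules default to
  five roughly weekly visits over a month (days 0, 9, 15, 23, 29 lab-like;
  0, 7, 14, 23, 31 wild-like); within-individual schedules beyond that
  pattern are unconstrained by any external anchor and are left
  configurable.

A **latent mode** bypasses multinomial noise for exact oracles: weights are
emitted as deterministic integer counts `rint(w·10⁹)`, so presence sets and
relative abundances are exact to 1e-9 while every downstream path still
sees integer counts.

The analytic expected Jaccard distance between timepoints k steps apart,
`1 − (C + m·s)/(C + 2m − m·s)` with s = (1−r)ᵏ, ignores re-acquisition of
previously held taxa and is therefore an upper bound; with skewed base
abundances the realised distance runs a few hundredths lower (validated by
simulation). The generator has no sharp plateau-onset parameter: the
curve-level generator (`simulate_plateau_pairs`) draws (Δt, distance) pairs
directly from a quadratic-plateau mean with Gaussian noise and is the tool
for parameter-recovery experiments; the community generator's recovery is
checked against the plateau fit of its own latent expected curve.

**What passing tests do and do not show.** The simulator reproduces the
longitudinal dependence structure (repeat-sampled individuals, core
persistence, geometric transient decay, depth noise) but not sequencing
error, chimeras, contamination, taxonomic misassignment, seasonal or
dietary covariates, or cage social structure. Tests passing on synthetic
cohorts demonstrate the estimators and fits are correct under the stated
model, not that the model captures every feature of real gut-microbiota
data.

## Numerical choices and degenerate inputs

* Symmetry of distance matrices enforced to 1e-12; diagonals forced to
  zero; PCoA eigenvalues below a relative 1e-10 threshold treated as null.
* Largest-remainder allocation breaks remainder ties by category order.
* The plateau fit requires ≥ 5 pairs and ≥ 3 distinct intervals; the linear
  fit ≥ 3 pairs and a non-degenerate design; log time requires Δt > 0.
* RSS is floored at 1e-300 inside AIC so perfect fits do not produce −∞.
* Zero-depth samples, all-zero matrices, empty presence sets, duplicate
  within-individual days, and empty animal lists are rejected with errors
  naming the offender.
* Pipeline manifests contain no absolute paths or timestamps and all JSON
  is written with sorted keys, so re-runs under the same seed are
  byte-identical; the free-form run log carries timestamps and is excluded
  from the manifest's file list.

## Known limitations

* Treating all within-individual pairs as independent overstates effective
  sample size; mixed-effects turnover models are out of scope.
* AIC selection between linear and plateau has an irreducible ~7–8%
  false-plateau rate on linear-truth data at n = 300; ΔAIC should be read
  alongside the vertex-location flag.
* The family tier trusts the curated family table's genus list; a family
  concordant in the table but heterogeneous in reality will be
  over-confidently classified.
* The asymptotic Shannon estimator degrades when nearly all taxa are
  singletons (it falls back to the plug-in value with a warning).
* Chao1's variance is not reported; no bootstrap confidence intervals.
* The aerotolerant-share rescaling slightly distorts the configured core
  abundance share in simulated communities (both constraints cannot hold
  exactly at once).
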