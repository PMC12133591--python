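# Methods

## Scope and model

`surfacer` analyzes cell-surface biotinylation LFQ screens: per-sample
protein-group tables with intensities and specific-peptide counts for
B biotinylated runs and C non-biotinylated control runs (defaults B = 4,
C = 2, matching the standard screen design), plus a protein annotation
table, a gene × tissue expression matrix (nTPM-like) and a gene ×
cell-type summary (fraction expressing, mean level). The output is a
ranked candidate antigen table with per-stage flags and a waterfall of
surviving counts.

## Surface calling

**Normalization.** Each run is shifted so its median over observed values
equals the grand median of the runs' pre-normalization medians. Missing
cells stay missing; a run with no observed values is an error.

**Imputation.** Missing LFQ values are treated as left-censored and
replaced by draws from `Normal(mu_r − d·sd_r, (w·sd_r)^2)` per run, with
`mu_r`, `sd_r` the run's observed mean and sample sd, downshift `d = 1.8`
and width `w = 0.3` (the Perseus convention). Both conditions are imputed.
Draws are seeded and consumed run by run in column order, so results are
bit-reproducible. A run with fewer than two observed values has no sd and
is an error.

**Test statistic.** For each protein,
`t = (m_biot − m_nb) / (se + s0)` with `se` the Welch standard error
`sqrt(v_b/B + v_n/C)` and moderation constant `s0 = 0.1`. With `s0 = 0`
and complete data this is exactly the classical Welch statistic.

**Permutation null.** All distinct assignments of the B + C runs to a
pseudo-biot group of size B are considered (complete enumeration when
there are ≤ 1000, otherwise `n_perm` seeded random draws). The null
distribution pools |t| from every *non-observed* labeling of *every*
protein in the table; a protein's two-sided p-value is the fraction of
pooled null values ≥ its |t| (ties counted, conservatively), clamped below
at one over the pool size. Benjamini–Hochberg over these pooled p-values
is algebraically identical to the SAM permutation-FDR estimate. Two
consequences drove this design:

* For the 4-vs-2 design there are only 15 labelings. A *per-protein*
  permutation p-value would be confined to the grid {1/15, …, 1}, making
  any q ≤ 0.05 decision unattainable by construction. Pooling across
  proteins removes the grid while keeping the null exact.
* The observed labeling must be excluded from the pool: each protein's
  own observed |t| would otherwise bound its p from below at (rank)/(15m)
  and reinstate the 1/15 floor on the BH-adjusted values of the top block.

Calibration was verified by simulation: on null cohorts the fraction of
proteins with p ≤ 0.05 is 0.0502 ± 0.0007 (40 cohorts × 2000 proteins,
full censor → normalize → impute path).

**Detection.** The intensity rule requires q ≤ 0.05, log2 fold change
≥ 1 and ≥ 3 quantified (pre-imputation) biot runs. The peptide rule
requires ≥ 2 specific peptides in ≥ 3 biot runs and ≤ 1 in every control
run — the count-based evidence pattern a clean surface hit shows. The
default `mode="either"` takes the disjunction; `intensity` and `peptide`
restrict to one evidence type.

## Triage cascade

Stages run in fixed order on the survivors of the previous stage, so the
per-protein flags are nested and the waterfall is non-increasing:

1. **surface_any** — detected in ≥ 1 sample.
2. **membrane** — membrane-annotated; detected proteins missing from the
   annotation table are excluded but reported, never silently dropped.
3. **prevalent** — detected in ≥ `min_pdx` samples (default 3).
4. **lymphoid_specific** — tau ≥ 0.8, top tissue lymphoid, lymphoid/non-
   lymphoid fold ≥ 4, non-lymphoid maximum ≤ 10 nTPM-like units. Each
   conjunct can be toggled. tau is scale-invariant, 0 for uniform and 1
   for single-tissue expression, and undefined (an error) for all-zero
   vectors or fewer than two tissues. Default lymphoid set: bone marrow,
   spleen, blood, lymph node, thymus, tonsil.
5. **not_excluded** — dropped if `frac_expressing` exceeds 0.10 in any
   excluded cell type (default: CD4/CD8/regulatory T cells, neutrophils,
   basophils, eosinophils, HSC). This codifies the manual curation step
   of removing T-cell- and granulocyte-expressed proteins; judgments that
   genuinely need literature review are surfaced in the report rather
   than automated. HSC exclusion is on by default but toggleable.

**Ranking.** `rank_score = z(n_detected) + z(mean log2FC) + z(tau) −
z(max excluded fraction)`, standardized within the final survivors
(zero-variance terms contribute 0); ties break lexicographically on gene
symbol. The score is a transparent composite for ordering a shortlist,
not a calibrated probability.

## Synthetic cohorts

The generator emulates the screen's statistical structure:

* log2 intensity = protein baseline `Normal(25, 2)` + condition effect +
  run noise `Normal(0, 0.5)`. Planted surface proteins gain +3 log2 units
  in the biot runs of each sample they are planted in; each planting
  drops out per sample with probability 0.15 (emulating biological
  heterogeneity such as a target present in 5 of 6 samples). Non-surface
  proteins have equal means in both conditions (background binders).
* Censoring: within each run, proteins whose noise-free intensity falls
  below the run's 0.2 quantile are missing. This makes missingness
  deterministic given the true intensity — monotone left-censoring in its
  starkest form.
* Peptide counts: Poisson with rate `2^(x − 23)` capped at 30, zero when
  the intensity is missing. Only the threshold logic consumes these, so
  the exact law is a plausible coupling, not a claim about real data.
* A default cohort plants 20 lymphoid-restricted targets and 5 enriched
  surface decoys of each other archetype (t_cell, myeloid,
  single_nonlymphoid, ubiquitous) among 2000 proteins. Decoys are tied to
  target planting so that a cohort with `n_true_targets=0` is a genuine
  null. Tissue and cell-type profiles follow the archetypes; every
  lymphoid-restricted profile has tau ≥ 0.8 by construction.
* One global seed drives a per-sample seed stream (seed + 1-based sample
  index) plus separate streams for truth assignment and the atlas, so
  appending a sample never perturbs existing ones and identical
  configuration yields byte-identical serialized cohorts.

What the generator does **not** emulate: correlated protein complexes,
batch effects, match-between-runs artifacts, peptide-level identity,
shared peptides/razor proteins, or realistic background binding profiles.
Passing tests therefore demonstrate correctness of the pipeline's logic
and calibration under the stated model, not performance on any real
dataset.

## Numerical choices

* Permutation ties count toward the tail (conservative); p is clamped at
  1/(pool size) and never 0.
* The sampling path (designs with > 1000 labelings) draws labelings with
  replacement, excluding the observed one, and converges to the
  enumerated p-values.
* Floats are serialized with shortest round-trip repr; missing values as
  `NA`. Read∘write is identity on every dialect, missing-for-missing.
* Test-suite and acceptance simulations use 10 seeds × default-size
  cohorts (2000 proteins × 6 samples) and 100 randomized small cohorts
  for structural fuzzing; these sizes give Monte-Carlo standard errors
  well below the tolerances being checked.

## Known limitations

* With only two control replicates the Welch statistic has ≈ 2 effective
  degrees of freedom; its null tails are heavy, and a +3 log2 effect at
  noise sd 0.5 sits at t ≈ 5.7, which the pooled null still produces at
  the ~1% rate. After BH correction over 2000 proteins, per-sample
  detection power at q ≤ 0.05 is ≈ 0.75, and end-to-end recovery of
  planted targets (detection in ≥ 3 of 6 samples) averages ≈ 0.8. This is
  a property of the design size, not an implementation artifact: more
  control replicates, a larger s0, or a milder q threshold would all
  raise power.
* The cascade reproduces the *shape* of a real screen's waterfall, not
  any particular published count: real counts depend on the raw deposit
  and versioned annotation/atlas snapshots, which are out of scope.
* Gene-level joins are case-sensitive exact matches on gene symbol;
  unmatched genes are reported, not resolved.
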