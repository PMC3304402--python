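# Methods

## Model and assumptions

The method assumes that subtype-specific drivers are *locally coherent* on a
combined interactome: a recurrently amplified (or deleted) gene whose dosage
reaches its transcript will sit next to genes that are overexpressed in the
subtype or whose pairwise co-expression is subtype-specific. It makes no
attempt to model causality or direction of effect; directed regulatory edges
are traversed in both directions during expansion (arrows are annotation, not
traversal constraints), with a `respect_direction` switch for downstream-only
traversal.

Inputs are taken as preprocessed: log-scale expression intensities and
gene-level copy-number log-ratios (or ready-made −1/0/+1 calls). Array
normalisation, segmentation and probe re-annotation are out of scope. All
statistics run on the intersection of expression and CNA sample identifiers,
and subtype labels must cover every analysed sample.

## Parameters

| parameter | default | meaning |
|---|---|---|
| gain/loss thresholds | ±0.3 | log-ratio cutoffs for −1/0/+1 calls (data-set dependent; configurable) |
| `top_frac_cna` | 0.05 | seed filter: fraction of genes kept by subtype-average CNA score |
| `top_frac_corr` | 0.10 | seed filter: fraction kept by pooled CNA–expression correlation |
| seed ranking mode | absolute | rank by \|score\| so deletion-driven seeds qualify; `amplification` restricts to gains |
| `top_frac_p` | 0.02 | probes kept by Welch-t p-value rank (subtype vs rest) |
| `top_frac_median` | 0.01 | probes kept by median-difference rank |
| `top_frac_coexpr` | 0.002 | edges kept by differential-correlation rank (upper tail) |
| `sample_frac`, `reps` | 0.8, 1000 | stratified resampling of samples per repetition |
| `membership_min` | 0.5 | fraction of repetitions required for final membership |

Selection is by rank, not by fixed significance levels: cutoffs use
`ceil(frac·N)` (probes/genes) or the `max(1, floor(frac·N))`-th largest value
(edge deltas, so that close to `frac·N` edges qualify), retaining boundary
ties in both cases. Bonferroni significance (α = 0.05/#probes) is recorded
per probe and can be required via a strict mode, but the operative selector
is the rank rule. Only positive median differences expand networks
(overexpression); downregulated genes enter via seeds or co-expression.

## Numerical and procedural choices

* **Welch t-test** (unequal variances) for subtype-vs-rest, two-tailed;
  degenerate probes (no variance anywhere, equal means) get p = 1. A pooled
  t is available via `equal_var`.
* **Correlations** are Pearson, computed as standardized row products;
  a constant vector on either side yields r = 0 with a degeneracy flag, so
  the delta distribution stays defined. Missing values are handled
  pairwise-complete; probes with > 20 % missing are dropped at load time.
* **Multi-probe genes**: differential-expression testing runs at probe level
  and maps selected probes to genes afterwards; for correlations (seed
  selection and edge deltas) the probe (pair) with the largest relevant
  absolute correlation is used — for edges, the pair maximising |r_in|, the
  within-subtype correlation that drives inclusion, reused for r_out so both
  correlations describe the same probe pair.
* **Pooled correlation for seeds**: correlations use all samples because a
  gene amplified in every sample of one subtype has a constant call vector
  within that subtype, making the within-subtype correlation undefined;
  constant-call genes are omitted.
* **Delta threshold scope**: the 0.2 % threshold is computed once per
  subtype over *all* network edges with expression on both endpoints, then
  applied as a fixed constant during expansion. This makes the fixed point
  order-independent (verified by randomised-order tests and a brute-force
  oracle).
* **Resampling** draws `floor(0.8·n_s)` samples per subtype (stratified, so
  no class vanishes), recomputes the DE selection and the delta threshold
  per repetition, and keeps seeds fixed. Seeds are exempt from the ≥ 50 %
  membership filter by default (they are data-anchored rather than
  expansion-derived); `keep_seeds=False` applies the filter to all. Satellite
  components are retained; `DriverNetwork.largest_component()` restricts when
  needed. One integer seed drives the whole schedule through spawned child
  generators, making runs bit-reproducible.
* **Empirical p-values** use the add-one estimator
  `(1 + #{null ≥ observed}) / (1 + reps)`, never exactly zero at finite
  repetitions; the raw exceedance count is reported alongside.
* **Expression-randomisation nulls** exploit the fact that shuffling probe
  labels changes neither row statistics nor row-pair correlations: the
  standardized matrices and the selected row set are computed once, and only
  the label→row assignment varies per repetition. This is algebraically
  identical to relabelling the matrix and rerunning (asserted in tests).
  Nulls use single-run expansion per repetition; the full inner resampling
  loop can be enabled (`resample_reps`) at roughly reps× the cost.

## What the synthetic generator emulates

`GeneratorConfig` defaults describe a mid-sized two-channel microarray study:
2000 genes on a preferential-attachment interactome (mean degree 4, 30 %
directed regulatory edges), 60 samples in three subtypes (20/10/30), and a
planted module around 4 mid-degree seed genes (degree 3–8, radius 1 —
roughly 20–35 genes):

* seeds gain copies (log-ratio 1.0) with probability 0.9 in target-subtype
  samples; their expression adds 2 noise-SD per copy-number call (dosage
  drives expression);
* non-seed module genes add the same 2-SD shift in target samples
  (differential expression);
* half of the module's internal edges share a latent factor in target
  samples whose loading `sqrt(r/(1−r))·σ` induces a within-subtype Pearson
  correlation of r = 0.8 (differential co-expression);
* the copy-number background mimics CGH structure: 10 % of genes sit in
  recurrently altered regions with gene-specific rates (uniform 0.05–0.4)
  and a fixed direction across *all* samples, the rest only pick up rare
  (0.2 %) sporadic events. Background alterations are passengers — they have
  no expression coupling. A homogeneous background would pile the
  subtype-average score onto a few discrete values and explode the top-5 %
  boundary tie group;
* 10 % of genes get a second, independently noisy probe.

Features of real data the generator does **not** model: batch and spatial
array artefacts, stromal contamination, segment-level (multi-gene) CNA
correlation along chromosomes, dosage-sensitive passengers, and
heavy-tailed expression noise. Passing recovery tests therefore shows the
pipeline's machinery is correct under its own assumptions, not that the
method is robust to those artefacts.

## Calibration and demonstration scales

Two analyses need conditions chosen with some care because the normalised
overlap of *seed-anchored* networks is a coarsely discrete statistic when
networks barely grow past their (shared) seed set:

* **Null calibration** (no planted expression signal): the empirical p is
  exchangeability-exact at any parameterisation, but resolving the 5 % tail
  of a 199-permutation null requires the overlap to take many distinct
  values. The calibration studies therefore use 1000-gene graphs of mean
  degree 8, 8 seeds, and generous selection fractions (10 % by p, 5 % by
  median), under which null networks are large and variable (typical sizes
  10–40). 200 generator repetitions × 199 nulls run in ≈ 4 minutes; the
  fraction of p < 0.05 sits near 0.03 — slightly conservative, as expected
  for a discrete statistic with `≥`-tie counting.
* **Cross-cohort demonstration** (planted module shared by two cohorts):
  expression-randomisation null networks must grow well past the seeds or
  their overlap saturates near 1 and the comparison is uninformative. The
  demonstration uses a 6000-gene graph of mean degree 20 with 12 seeds of
  degree 10–13 (module ≈ 150 genes, comfortably inside the ~200-probe
  selection capacity); observed overlaps ≈ 0.95 against expression nulls of
  0.35 ± 0.12 and seed nulls ≈ 0.9, both at the minimal add-one p.

Other stated problem sizes: planted-module recovery runs the full pipeline at
generator defaults with 200 resampling repetitions; statistic cross-checks
use 1000 random probes/edges; screen scoring uses 15 genes × 13 cell lines.

## Known limitations

* Rank-based selection always selects ~3 % of probes, signal or not; the
  resampling filter removes most, but not all, noise members adjacent to the
  module — planted-module precision is typically 0.83–0.96, not 1.
* Seed selection retains boundary ties, so cohorts whose subtype-average
  score distribution is heavily tied near the top-5 % cutoff can produce
  large seed sets; inspect the seed table before expanding.
* The normalised overlap degenerates for seed-dominated networks (see
  above); interpret cross-cohort p-values only when networks are
  substantially larger than the seed set.
* The evaluation module scores screens; it does not model plate effects,
  off-target silencing or control-construction choices beyond a pooled
  per-line control.
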