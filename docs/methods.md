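# Methods

## Background and model

Allohexaploid bread wheat (*Triticum aestivum*, genome BBAADD) carries three
related subgenomes, so most genes exist as a **triad**: one A, one B and one D
**homeolog**. The relative expression value (REV) of a homeolog is its share
of the triad's total expression, e.g. for the D homeolog

    D% = TPM_D · 100 / (TPM_A + TPM_B + TPM_D)

computed per condition from replicate-mean TPM. The triple (A%, B%, D%) is a
point on the 2-simplex, which makes the analysis compositional: only relative
information matters, and all downstream statistics are invariant to rescaling
a condition's TPM values by any positive constant.

### Bias categories

Each composition is assigned to one of seven **homeolog expression bias
categories (HEBC)** by nearest centroid under Euclidean distance on the
fraction scale:

| category | centroid (A, B, D) |
|---|---|
| balanced | (1/3, 1/3, 1/3) |
| A-dominant / B-dominant / D-dominant | (1,0,0) / (0,1,0) / (0,0,1) |
| A-suppressed / B-suppressed / D-suppressed | (0,½,½) / (½,0,½) / (½,½,0) |

Measuring distance on the 3-vector of fractions is equivalent, for the argmin,
to measuring it on the ternary-plot plane: the barycentric→Cartesian map is a
similarity transform (a fixed isometry up to scale), so it cannot reorder
distances. Ties have measure zero on real data but occur on grid-like
synthetic input; they are broken deterministically by the fixed category order
above (the order of the table, row by row). Assignment is hard (no fuzzy
membership or expression-level refinements): every composition gets exactly
one label plus its centroid distance, so borderline calls can be filtered by
distance downstream if desired.

### Stress-induced REV shifts

For each homeolog, a condition effect on relative expression is called when
the control/stress REV ratio r satisfies `max(r, 1/r) >= 1.2`, i.e. a ≥ 20 %
change in either direction. The rule is symmetric deliberately: a one-sided
ratio would call decreases but miss equally large increases, and the two
orientations are equivalent up to relabelling the conditions. The boundary is
inclusive (a ratio of exactly 1.2 is a shift). When exactly one condition has
REV = 0 the ratio is undefined; such triads are flagged (`undefined_ratio`)
and counted as shifted, since an expressed↔silent transition is the strongest
possible change. When both REVs are 0 the homeolog is unexpressed in both
conditions and the call is negative.

### Expressed-triad detection

A triad enters the analysis when its summed homeolog mean TPM exceeds
`min_total_tpm` (default 0.5) in at least one condition. The default is a
conventional low-expression floor for TPM data; because detection criteria
vary between studies the threshold is a first-class parameter of both the
API and the run configuration. Triads with a homeolog missing from the
matrix are reported and excluded — never silently treated as zero.

### Differential expression and enrichment

A gene is a DEG when adjusted p ≤ 0.05 **and** |log2 fold change| ≥ 1, both
boundaries inclusive; the thresholds are the fields of `DEGFilter`. The filter
is monotone in both thresholds. Gene-set enrichment uses the exact upper-tail
hypergeometric probability of the observed DEG/set overlap within a declared
universe (default: all genes of the DE table), with Benjamini–Hochberg
adjustment across the tested sets. DE tables are normally produced by a
dedicated count-model tool and consumed via `read_de_table`; `naive_de`
(two-sample t-test on log2(count+0.5), fold change on pseudocounted means, BH
adjustment) exists so the synthetic pipeline is self-contained, is labelled as
such in its output metadata, and holds its type-I error near nominal under a
null negative-binomial simulation — but it models no count dispersion and is
not a substitute for a proper DE analysis of real data.

### Bench statistics

* **Percent contribution** of a solute = mean molarity × 100 / total mean
  molarity (μmol g⁻¹ DW), per condition; contributions always sum to 100 and
  are scale-invariant.
* **Significant solute change**: stress/control mean ratio ≥ 1.5 (up) or
  ≤ 2/3 (down) together with a two-sample t-test p < 0.05. The 50 %-change
  rule is symmetrized because both accumulation and depletion are reported
  under the same rule; the test uses Welch's correction by default (equal
  variances are rarely defensible at n = 3), switchable to the pooled test.
  The rule is applied to concentrations, with contributions reported
  alongside.
* **ΔΔCt**: fold = 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_treated −
  (Ct_target − Ct_ref)_control. Replicates are aggregated by mean Ct before
  differencing; a per-replicate mode propagates each treated replicate's ΔCt
  against the mean control ΔCt and returns the individual folds. With several
  reference genes the per-sample reference Ct is their arithmetic mean. The
  statistic is invariant to a constant Ct offset applied to a whole sample
  (plate effects).

## Synthetic data generator

`simulate_dataset` produces a complete, ground-truthed dataset emulating the
design the analysis assumes: 3 biological replicates × {control, stress} of a
single tissue.

Per triad:

1. a category is drawn from `category_mix`;
2. the control composition is drawn from a Dirichlet centred on that
   category's centroid with parameters `centroid × concentration`; zero
   centroid coordinates are floored at `0.01 × concentration` (a Dirichlet
   parameter of 0 is undefined), so vertex and edge categories keep full
   simplex support;
3. total control expression is lognormal (`abundance_log_mean`,
   `abundance_log_sd`, natural-log scale, in TPM units);
4. a shared log2 condition effect ~ N(0, `shared_effect_sd`) scales all three
   homeologs — it changes absolute expression but never the composition;
5. with probability `homeolog_effect_prob`, one uniformly chosen homeolog is
   additionally scaled by 2^`homeolog_effect_log2` — this is the only
   mechanism that changes the true stress composition, so it is what creates
   true bias-category changes and true REV shifts (at most one per triad,
   which suffices to realise every single-step category transition);
6. counts per replicate are negative binomial with mean
   `expected TPM × library_size / 10⁶` and variance `μ + dispersion·μ²`
   (Poisson when dispersion = 0); the TPM matrix is each sample's counts
   rescaled to sum to 10⁶, i.e. equal effective gene lengths — homeologs are
   near-identical in length, and length variation adds nothing to what the
   pipeline tests.

All draws come from a single `numpy.random.Generator`; the seed is a
mandatory config field, so identical configs give identical datasets.

**Defaults** (chosen once as a realistic regime for hexaploid wheat triads):
category mix 0.70 balanced / 0.035, 0.035, 0.04 dominant (A, B, D) / 0.07,
0.07, 0.05 suppressed (A, B, D) — mostly balanced triads, suppressed
categories more common than dominant ones, D-suppressed the rarest of the
suppressed group; Dirichlet concentration 50 (visible scatter around the
centroids without losing category structure); lognormal total TPM with
log-mean 3.0 and log-sd 1.0 (median ≈ 20 TPM per triad, a heavy right tail);
NB dispersion 0.05 (typical bulk RNA-seq biological variability at n = 3);
library size 2 × 10⁷ reads; shared effect SD 1.0 (condition responses of a
few fold are common under long-term stress); homeolog-specific effects in
10 % of triads at log2 = 2.

The truth table records the sampled category, the category of the actual
(noisy) control composition — the recovery target, since the pipeline can
only ever see the composition — both true compositions, the effects, whether
a true category change was induced, and the per-homeolog truth of the ≥ 20 %
shift rule applied to the noise-free compositions. `truth_report` scores
pipeline outputs against this: category recovery and confusion matrix, and
sensitivity/specificity/false-positive rate for shift calls and category
changes.

**What the generator does not emulate:** read-level artefacts (mapping bias
between subgenomes, multi-mapping), gene-length variation, correlated
library-composition effects, batch structure, and any non-triad genes.
Passing tests therefore demonstrate that the statistics are implemented
correctly and recover truth under the stated generative model, not that the
biological conclusions of any particular wheat experiment are robust to those
real-data complications.

## Numerical choices

* Composition closure is asserted to 1e-9 absolute — pure double-precision
  arithmetic headroom, not a statistical tolerance.
* REV is undefined when a triad's total TPM is 0 in a condition; the record
  is omitted and logged, not an exception (downstream category-change
  comparisons then exclude and count those triads).
* `write_table` serializes floats at `%.17g`, so write→read round trips are
  exact and repeated runs are byte-identical.
* log2 fold changes of 0-fold genes are kept as −inf rather than clipped;
  the DE table validator treats a stated fold change of 0 as exactly that
  (a stress mean of 0) and keeps such records distinct.
* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
  hypergeometric tails to `scipy.stats.hypergeom.sf` — both are cross-checked
  in the tests against exhaustive enumeration / a hand-rolled step-up.

## Pipeline and problem sizes

`run_pipeline` executes: load/simulate → replicate means → expressed-triad
detection → REV → shift calls (all three homeologs) → HEBC assignment,
summary and condition changes → optional DE filter, enrichment and per-set
category-change fractions → optional solute report → truth scoring (simulated
runs). Every stage logs inputs, outputs and exclusion counts; any failure
aborts with the stage name. `summary.json` contains only numbers exactly
recomputable from the emitted TSVs; `manifest.json` carries the config hash,
package and library versions, and the timestamp (the only non-deterministic
output).

The test-suite and acceptance-script simulations use 150–2,000 triads with
3 replicates per condition — enough for the Monte-Carlo assertions'
tolerances (e.g. the 2,000-triad recovery check has a binomial SE well below
the margin asserted) while keeping the default runs fast.

## Known limitations

* The nearest-centroid scheme assigns every composition a label, however far
  from all centroids; consumers who want an "unclassified" band should filter
  on the emitted distance.
* `naive_de` underuses the count nature of the data (no dispersion shrinkage);
  its power at n = 3 is limited, which is visible in the acceptance summary's
  DEG counts relative to the number of truly perturbed genes.
* The ≥ 20 % shift rule is a pure effect-size rule on point estimates of the
  compositions; it carries no replicate-level significance test, so its
  false-positive behaviour depends on expression level (noisier low-TPM
  triads shift more easily). The expressed-triad threshold is the only guard.
* Solute significance at n = 3 with Welch's test is conservative; the pooled
  t-test switch exists for users who prefer the classical convention.
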