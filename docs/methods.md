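# Methods

## Data model and preprocessing

Both omics layers arrive as features × samples intensity tables with
explicit missingness (empty cell, `NA`, `NaN`; optionally literal 0, since
DIA export conventions differ). The design is two groups; fold changes are
always oriented treatment over control, with the orientation recorded in the
run summary.

**Missingness filter.** A feature is kept only if every replicate group has
at most `max_missing` missing detections (defaults 2 for proteins, 3 for
peptides under 4 replicates per group). The filter is per-group, so a
feature detected in all control but no treatment replicates is dropped —
which also bounds what any downstream recovery experiment can see (below).

**Quantile normalisation with missing cells.** Classical quantile
normalisation is defined for complete matrices; here each sample's observed
values are mapped by mid-rank quantile onto a reference curve: the
across-sample mean of per-sample sorted-value curves, interpolated onto a
common grid whose length is the largest observed count. Ties receive the
mean of their rank range. On complete data this reduces exactly to the
classical procedure (every sample's sorted vector becomes the cross-sample
mean of sorted vectors), which the test suite asserts. Normalisation runs
per omics layer — proteome and ubiquitinome have different intensity
distributions, so they are never pooled into one reference.

**Left-censored imputation.** Missing cells are drawn per sample from
N(mean − shift·SD, (width·SD)²) of that sample's observed log2 values, with
shift 1.8 and width 0.3 — the de facto convention for intensities below the
detection limit. Observed cells are never touched; the generator state is
seeded, so a run is a deterministic function of (input, parameters, seed).

**Metabolomics QC.** Two univariate filters: presence in ≥ 80% of the
samples of at least one group (the within-group reading of the "80% rule",
which preserves group-specific metabolites), then removal of features whose
relative SD over QC injections exceeds 30%. Multivariate modelling
(OPLS-DA/VIP) is out of scope.

## Differential abundance

Per feature, log2FC = mean(treatment) − mean(control) on the normalised,
imputed log2 matrix; the geometric-mean fold change, standard after log2
normalisation. The default test is the pooled-variance Student t; Welch is
available. Significance = p < α (default 0.05, optionally BH-adjusted,
default none) **and** |log2FC| ≥ log2(1.5), applied symmetrically in both
directions.

**Moderated mode.** An empirical-Bayes option shrinks per-feature pooled
variances toward a prior fitted by the method of moments on log sample
variances: with z = log s², E[z] and Var[z] under the scaled
inverse-chi-square model identify the prior degrees of freedom d₀ (via a
Newton inversion of the trigamma function) and prior variance s₀²; the
posterior variance (d₀s₀² + d s²)/(d₀ + d) enters a t statistic with d + d₀
degrees of freedom. The implementation is our own; the test suite
cross-checks it against the R reference implementation (limma::eBayes,
driven through Rscript) to 1e-9 on t and p and recovers d₀ = 0 ⇒ ordinary
Student t exactly.

## Site classification

For each significant differential site, with parent protein looked up
through the site annotation:

1. parent absent from the quantified proteome → `protein_unquantified`.
   This is a first-class outcome, not silently `non_degradative`: at n = 4
   with left-censoring it is common, and hiding it would bias class counts.
2. parent significantly differential with the same-signed trend **and**
   Spearman ρ(site profile, protein profile) ≥ `rho_min` (default 0.7,
   computed on the normalised imputed log2 profiles over all shared
   samples; Pearson of mid-ranks, undefined-on-constant treated as 0) →
   `removed_confounded`. The conjunction matters: correlation alone would
   discard genuinely regulated sites on stably co-varying proteins.
3. site trend opposite in sign to the protein trend → `degradative`.
4. otherwise → `non_degradative`.

The classes are exhaustive and mutually exclusive, so they partition the
significant-site set — asserted property-style on random inputs — and are
invariant under swapping the group labels (both layers' signs flip
together).

**What counts as a protein "trend" (design choice).** The opposite-trend
rule is gated on the parent protein being significantly differential
(`require_protein_significant`, default on), with an additional
`protein_trend_epsilon` magnitude floor (default 0, i.e. the significance
gate does the work). The ungated alternative — raw sign of the protein
log2FC — makes the degradative call depend on pure noise whenever the
parent is flat: a flat protein's measured fold change has a random sign, so
roughly half of all genuinely protein-independent sites would be labelled
degradative. Gating keeps the degradative class small and specific, which
is also the regime reported for this class of analysis in practice. Both
knobs are configurable for users who want the permissive rule.

## Chain-linkage quantification

Remnant peptides on ubiquitin's own lysines (positions 6, 11, 27, 29, 33,
48, 63; M1/linear chains leave no diGly remnant and are excluded by
construction) are aggregated per linkage by mean log2 intensity — robust to
peptide response factors. Per-group shares are computed per sample on the
linear scale (so a per-sample scale factor cancels exactly) and averaged
within group; shares over detected linkages sum to 1, and absent linkages
are absent rather than zero. Because "coverage" can mean intensity share or
detected-peptide share, both columns are reported. Per-linkage log2FC and p
come from the same two-group test as the main analysis, run on the
aggregated profiles.

## Enzyme–substrate mapping

Candidates are the triple join: library record (enzyme, class, substrate,
confidence) × significant differential enzyme × significant differential
site on that substrate. Enzyme class (E3 vs DUB) is a user-supplied
annotation, not inferred. A candidate is retained when directions are
consistent with catalysis — E3 up & site up, E3 down & site down, DUB up &
site down, DUB down & site up — and retained pairs are ranked by descending
confidence with a deterministic (enzyme, substrate, site) lexicographic
tie-break, so ranking is invariant to input order and to any monotone
rescaling of confidences. Site-level pairs aggregate to (enzyme, substrate)
pairs by best rank for reporting, since one substrate can carry several
differential sites from one library record.

## Biomarker statistics

* Two-sample t from summary statistics (pooled by default, matching the
  common clinical reporting; Welch available), identical to the raw-data
  test when summaries are computed from the data.
* AUC as the Mann–Whitney U with half-credit ties over n₊·n₋ — provably
  identical to trapezoidal integration of the empirical ROC, which the test
  suite checks exactly on randomized fixtures. Score orientation is fixed
  (higher score → case class) rather than auto-flipped, so sign errors
  surface instead of hiding.
* Pearson correlation matrix with pairwise deletion (a 20-subject cohort
  cannot afford listwise deletion); constant variables yield a missing cell
  rather than a fabricated value.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes:
two groups × 4 replicates; protein log2 intensities = baseline
(N(20, 1.5²)) + group effect ± 1.0 log2 + noise (SD 0.25); site archetypes
in configurable fractions (defaults: 5% degradative — site effect 2.0 log2
opposite in sign to a real parent effect; 15% non-degradative — independent
site effect on a flat parent; 5% confounded — the site copies its
differential parent's realised profile plus small noise (SD 0.1) with no
intrinsic effect, so the confound filter's removals are unambiguously right
or wrong; remainder null). Sites per protein average 2.9, matching the
observed ratio in deep diGly studies. Ubiquitin remnant peptides (3 per
linkage) get per-linkage multiplicative factors (defaults K63 ×2, K11 and
K27 ×0.5, all others ×1) on baselines drawn one unit above the global mean
with the usual spread — abundant, but not a degenerate block at the extreme
top of the distribution, where quantile normalisation's rank granularity
would distort planted effects at desk-scale feature counts. Planted
E3/DUB enzymes (10 pairs by default) are differential proteins whose
direction is wired to a directional substrate site consistently with the
retention rule; the library draws true pairs at confidence 0.8–0.99 and
decoys at 0.05–0.4. Missingness is left-censoring at each sample's 5%
raw-intensity quantile — not missing-completely-at-random — matching the
small-value imputation premise.

The clinical generator draws glutamine per group from the configured
summaries (defaults: normal 534.57 ± 58.50, case 656.87 ± 58.08 µmol/L,
n = 10) and imposes correlations of the other variables (femoral-neck BMD,
CTX, P1NP, age, BMI) to glutamine with a one-factor Gaussian copula
(loadings = target correlations; positive-definite for any loadings in
(−1, 1)). Defaults: BMD −0.79, CTX +0.6, P1NP −0.5. The BMD magnitude
follows the published report of a strong association; the sign follows its
stated *direction* (decreasing with BMD), since the printed positive
coefficient contradicts the accompanying prose — the analysis code reports
signed r and leaves interpretation to the user.

Not emulated: peptide sequences and spectra, retention-time structure,
batch effects, correlated (co-regulated) protein modules, non-Gaussian
heavy-tailed noise, and intensity-dependent variance. Passing recovery
tests therefore demonstrates correctness of the statistical machinery under
the stated generative model, not performance on real acquisitions.

## Recovery experiment and its metrics

The planted-truth experiment (20 seeds, default conditions) runs the full
pipeline on simulator output and scores:

* **Degradative sensitivity/precision** — against the planted archetypes.
  Sensitivity is computed over the *quantifiable* universe: planted
  degradative sites whose site and parent protein both survive
  left-censoring plus the missingness filter. A 4-fold-down site whose
  treatment intensities fall below the detection limit in all replicates is
  not in the data and cannot be recovered by any method; that loss is an
  instrument property, reported separately as `detection_rate` (~0.8 at
  default censoring) rather than folded into classifier performance.
* **Linkage sign pattern** — a seed succeeds when every planted-up linkage
  is called significantly up, planted-down significantly down, and no flat
  linkage is called in either direction, under the standard significance
  rule.
* **Enzyme–substrate recovery** — fraction of planted (enzyme, substrate)
  pairs, restricted to those whose enzyme and substrate site were
  quantified, found in the top-|truth| aggregated ranks.

Problem sizes (300 proteins, ~900 sites, 20 seeds; 1000 Monte-Carlo
cohorts for the AUC check) were chosen so the whole experiment runs in
seconds on one CPU while keeping the Monte-Carlo error well below the
decision margins.

## Numerical choices and degenerate inputs

* Zero-variance, zero-difference contrasts get p = 1 (no evidence), not NaN.
* Constant profiles make Spearman ρ undefined; it is reported as missing
  and treated as 0 by the confound filter (a constant profile cannot
  positively track anything).
* p-values are clipped away from exact 0 to keep downstream −log10 finite.
* Quantile-normalisation ties receive the mean of their rank range; a
  sample with a single observed value maps to the reference mean.
* The trigamma inversion in the moderated fit uses Newton iteration with
  the standard asymptotic starting point and falls back to an infinite-d₀
  (fully pooled) prior when the moment estimate of excess variance is ≤ 0.
* One global seed spawns independent per-stage substreams
  (`numpy.random.SeedSequence.spawn`), so adding a stage never perturbs
  earlier stages' draws and reruns are byte-identical.

## Known limitations

* Two-group designs only; no covariates, pairing, or >2 groups.
* The site→protein join is by opaque identifier; no sequence-level
  validation that a site's position exists in the parent.
* The confound filter's ρ threshold (0.7) is a convention, not estimated
  from data; at n = 8 samples the Spearman estimate is coarse.
* Linkage shares are relative within the detected linkage set; no absolute
  stoichiometry or branched-chain inference.
* The enzyme–substrate stage is only as good as the supplied interaction
  library; the predictor that produced the library is not re-implemented.
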