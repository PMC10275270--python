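# Methods

## The kinetic model and its assumptions

Each gene's RNA is modeled as a two-compartment linear system: premature
(intron-containing) RNA is produced at rate α (TPM/min), converted to mature
RNA at rate k_p (1/min), and mature RNA decays at rate k_d (1/min).  The
pipeline assumes:

1. **Steady state** — total RNA levels do not change over the assay, so
   P\* = α/k_p and M\* = α/k_d.  The `steady_state_check` utility quantifies
   this by the r² of log10 total RNA between two profiles (e.g. two
   incubation times), using a pseudocount equal to the minimum positive mean
   TPM across both inputs.
2. **Single timepoint** — one pulse length t; rates are identified from the
   labeled/total contrast at that one time.  Labeled pools follow the closed
   form P_L = P\*(1−e^(−k_p t)) and M_L = M\*·frac_m(k_p, k_d, t).  The
   implementation uses a cancellation-free `expm1` rearrangement with a series
   branch where |k_p−k_d|·t < 1e−8, verified against high-order ODE
   integration to 1e−8 relative over random parameter sets including
   near-degenerate k_p ≈ k_d.
3. **First-order decay** — no age structure, no autoregulation during the
   pulse.

Intronless genes have no observable premature signal; they are treated as a
single first-order pool (processing effectively instantaneous), their
processing rate is reported missing, and decay comes from total signal alone.

## Estimation

* **Scale s (pull-down → total TPM units).**  Both library types are
  internally TPM-normalized, so labeled abundances need a cross-library
  factor.  Default: thiolated spike-ins present at known amounts in both
  libraries; each spike's length-normalized signal is taken *relative to the
  analysis denominator* (all non-excluded rows), so s is consistent with the
  recomputed TPM used downstream; s is the median over spikes of the
  total/pull-down per-amount signal ratio.  Fallbacks: a fixed factor, or a
  factor chosen so the median half-life matches an anchor value (rates scale
  as 1/s, so this is a one-step solve).
* **Synthesis.**  Linear mode (default): α = s·(pull-down exonic TPM)/t, the
  short-pulse approximation; it underestimates α by a factor that decreases
  with k_d·t because labeled RNA decays during the pulse.  Exact mode
  inverts the closed-form pulse solution by fixed-point iteration
  (α ← α·L_obs/L_pred with k_p = α/premature, k_d = α/mature), initialized at
  the linear estimate; on noise-free input it recovers the generator's rates
  to machine precision.
* **Decay and processing.**  k_d = α/(total − premature), k_p = α/premature,
  on per-condition replicate means.  Genes whose mean premature signal
  reaches the mean total signal are flagged degenerate and excluded from all
  rate outputs (a negative mature pool would otherwise propagate).
* **Capping.**  Carryover of unlabeled RNA at ratio r mimics a labeled
  fraction r per pulse, i.e. an apparent decay floor r/t, bounding resolvable
  half-lives at ln2·t/r = 1386 min for r = 0.01, t = 20 min.  Reported
  half-lives above 1000 min are therefore set to 1000 with a `capped` flag;
  decay rates themselves are left untouched, and regression uses uncapped,
  winsorized rates.  The median half-life is computed after capping (capped
  genes count at 1000 min).
* **Uncertainty.**  Replicate sample variances (ddof = 1) are propagated by
  the first-order delta method assuming independent errors:
  cv_decay² = cv_α² + (var_total + var_premature)/(total − premature)².
  This is a single-replicate CV; a Monte-Carlo test confirms it tracks the
  empirical replicate CV in the moderate-noise regime (per-component CVs
  ≈ 15%); at high dispersion the first-order approximation underestimates
  the heavy tail of ratio estimates.

The expression filter keeps genes with ≥ 10 exonic counts in at least 2/3 of
the libraries (ceiling rule) of at least one (condition, fraction) library
group, applied to exonic counts only.  TPM is recomputed after removing
spike-in/rRNA rows so excluded reads do not contribute to the denominator.

## Feature annotation

* **TF** — membership in a supplied id list.
* **CTS** — some cell type with enrichment p < 0.05 and linear fold-change
  ≥ 2 in a gene × cell-type table.  Loosening either threshold can only add
  flags (monotonicity is property-tested).
* **H3K27me3 category** — GTF spans (1-based closed) and BED peaks (0-based
  half-open) are normalized to 0-based half-open; a gene is A if any peak
  lies within ±1 kb of its TSS, C within ±1 kb of its TES, B if any peak
  overlaps the span.  The ±1 kb windows are symmetric (the conservative
  reading of "within 1 kb"); strand determines which end is the TSS.  The
  category is the exact flag combination, so the 8 categories partition the
  gene set and are invariant to peak fragmentation.  The regression feature
  `me3` is the extended (ABC) category only.  The sparse AC category is
  computed and retained; display-level exclusion is left to the caller.

## Regression and bootstrap

log10 decay rates are winsorized at the 1st/99th percentiles
(linear-interpolation quantiles) and fit by OLS on [1, TF, me3, CTS], with
interactions adding TF·me3, TF·CTS, me3·CTS, TF·me3·CTS (β0…β7).  With
interactions the model is saturated: fitted values equal the 8 cell means to
machine precision, and an empty cell raises an error naming the cell.
Normal-theory two-sided p-values come from statsmodels OLS.

The stratified bootstrap draws, per iteration, n genes with replacement from
each of the 8 nonoverlapping groups (n = smallest group size by default,
10,000 iterations by default) and refits both models.  With equal counts per
cell both OLS solutions are exact linear maps of the 8 cell means
(β_int = D₈⁻¹·means; β_add = D₄⁺·means), so the loop is vectorized over cell
means; a test checks the reduction against a literal statsmodels refit of the
same resample.  Summaries report per-coefficient quantiles and the fraction
of draws above zero (a sign-test view) alongside the full-data normal-theory
p-values.  As the iteration count grows the bootstrap mean converges to the
equal-group-weight fit, not the raw-data fit — that re-weighting is the
purpose of the stratification.

Group stability tests use the two-sided Mann–Whitney U (exact null for
groups under 20 without ties, tie-corrected normal otherwise) on decay rates,
summarized by the group's median stability percentile (percentile =
100·rank(−decay)/n, average ranks for ties).  Composition enrichment uses the
two-sided Fisher exact test; odds-ratio confidence intervals use the Woolf
log-normal interval with a Haldane 0.5 correction when a cell is zero.
Significance stars follow the thresholds 0.05, 1e−9 and 1e−39.

## Derepression (nascent vs total response)

For a knockdown with nascent and total RNA measured in control and knockdown
conditions, Δ = log2(total fold-change) − log2(nascent fold-change) per gene,
with the pseudocount rule above.  Per-library normalization shifts every
gene's raw Δ by the same constant, so Δ is reported relative to the
background (non-target) median, which is anchored at zero; the target group's
median Δ and a two-sided Mann–Whitney test against background quantify a
stability signature.  A purely transcriptional response gives target Δ ≈ 0; a
halving of target decay gives Δ ≈ 1.

## The synthetic-data generator

`simulate` draws log10 synthesis and decay rates from normal distributions
(σ = 0.79 and 0.44 respectively) and recentres each vector so the sample
median equals the configured median exactly (median half-life 82 min; median
synthesis 0.5 TPM/min before TPM renormalization).  Defaults reproduce the
targeted experiment: t = 20 min pulse, 1:100 carryover in the pull-down,
3 replicates, negative-binomial dispersion 0.05, 15% intronless genes.
Choices where the experimental description leaves the design open:

* **Processing rates** — log-normal, median 10× the median decay rate,
  σ_log10 = 0.25: premature pools are then ~10% of mature pools, matching the
  strong intronic enrichment of pull-down over total libraries.
* **Feature plants** — TF/me3/CTS flags drawn independently (prevalences
  0.15/0.06/0.25) with additive log10 decay effects +0.25/+0.30/−0.05.  The
  TF effect reproduces a ~28th-percentile median TF stability under
  σ = 0.44; the CTS effect is slightly stabilizing.  Because effects shift
  the marginal decay distribution, the recentring above keeps the generator's
  median-half-life contract exact.  Real feature sets overlap strongly;
  independence is a simplification.
* **Count noise** — gamma-Poisson per library with var = μ(1 + φμ).
  Spike-ins are technical standards pipetted from one stock, so they carry
  Poisson counting noise only; gene rows carry the full dispersion.
  φ = 0 switches to noise-free mode, returning real-valued expectations
  unrounded.
* **Library depth** — 1e8 reads, chosen so the 10-count expression filter
  retains > 99% of simulated genes and parameter-recovery tests measure
  estimator fidelity rather than filter truncation.
* **TPM units** — synthesis rates are rescaled so the total-library analysis
  signal (exonic + intronic rows) sums to 1e6; simulated truth is then in
  exactly the TPM units the estimator reports, which is what makes
  machine-precision recovery checks possible.
* **Genome layout** — genes spaced 10 kb on 5 chromosomes; H3K27me3 peaks are
  planted per category with geometry guaranteeing that re-classification
  recovers the planted category exactly (and cannot leak into a neighbor's
  windows).
* **Labeling efficiency** — exposed as a parameter (fraction of nascent
  molecules labeled), default 1.

What the generator does **not** emulate: read-level effects (mappability,
positional bias), isoform structure, correlated feature memberships,
cell-type mixtures within a sample, 4sU toxicity, and synthesis–decay
correlation (true α and k_d are independent, so the decay-vs-level
correlation of simulated data is higher than in real tissue).  Passing
recovery tests therefore demonstrate correctness of the estimator under the
model's assumptions, not robustness to every artifact of real libraries.

## Numerical and policy details

* Degenerate pulse solution branch: series in (k_d−k_p)t below 1e−8; direct
  two-exponential form when |k_d−k_p|·t ≥ 1 (avoids `expm1` overflow).
* Exact-mode synthesis: fixed-point iteration, relative tolerance 1e−12,
  200 iterations max; nonconverged genes keep their last iterate and are
  flagged.
* Mature RNA is clipped at zero per library cell; whole genes are only
  excluded when mean premature ≥ mean total in the total-RNA libraries.
* The premature/mature ratio (decay/processing proxy) is reported missing
  for intronless genes and when mature is zero.
* The bootstrap seed, all generator draws and the pipeline seed derive from
  explicit integer seeds; identical seeds give bit-identical outputs.

## Known limitations

* Carryover is not subtracted from the pull-down signal; it acts as the
  resolution floor motivating the half-life cap.  A consequence worth noting:
  raising carryover *lowers* the fraction of genes reported at the cap,
  because the apparent-decay floor pushes genes with true half-lives just
  above the cap back below it.
* The delta-method CV understates uncertainty for genes with small mature
  pools.
* Scale estimation assumes spike-ins behave identically to endogenous RNA in
  purification and library construction.
* Problem sizes in the test-suite and the acceptance script (hundreds to
  5000 genes, 2000 bootstrap iterations) are chosen as the smallest sizes at
  which the statistical checks are stable; all stages scale linearly in genes
  and iterations.
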