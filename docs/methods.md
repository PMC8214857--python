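# Methods

## The model

A gene-pair signature is a set of ordered gene pairs (aᵢ, bᵢ) with Cox
log-hazard coefficients βᵢ and a scalar cutoff. For one sample the index is
IRGPI = Σᵢ βᵢ·I(aᵢ, bᵢ) with I(a, b) = 1 iff expr[a] < expr[b] (ties → 0,
missing member → missing indicator). The proportional-hazards assumption is
that a patient's hazard is baseline·exp(IRGPI-like linear predictor); the
index is a *relative* risk score, not a calibrated survival probability.

Two conventions are fixed package-wide and recorded in the signature file
so scoring is unambiguous: the indicator direction (1 means the first gene
is the lower-expressed one) and the risk-call boundary (HRisk iff score
strictly above the cutoff; a score exactly at the cutoff is LRisk). Either
direction convention is self-consistent once coefficients are trained
under it.

Within-sample order statistics are invariant under any per-sample strictly
increasing transform, which is the entire cross-platform argument: scores
computed on log-intensities, FPKM, TPM or ranks of the same sample are
*identical*, not merely correlated. The flip side is that any step that
mixes values across samples or across genes (per-gene batch centring,
cross-sample quantile pooling) is *not* order-preserving within samples
and would break the guarantee; the simulator's "adversarial" per-gene
shift exists to demonstrate exactly that failure.

## Training pipeline

Stages, in order, with their tunable parameters (all in `TrainConfig`):

1. **Variability prefilter** (`mad_threshold`, default 0.5): keep gene-set
   members whose raw median absolute deviation across training samples
   exceeds the threshold. Unscaled MAD on the training scale; the knob is
   scale-dependent and documented as such. Threshold 0 disables the
   filter entirely.
2. **Candidate pairs**: all unordered pairs within the (filtered) gene
   set, one lexicographic orientation each — g(g−1)/2 candidates.
3. **Informative-pair filter** (`f_min`, default 0.2): keep pairs whose
   indicator mean lies in [f_min, 1−f_min]. A pair whose order is fixed in
   nearly all samples cannot discriminate outcomes.
4. **Univariate screen** (`screen_p`, default 0.05): the score test of the
   Cox partial likelihood at β=0 with Efron tie handling, computed
   analytically and vectorised across all pairs at once. The score test
   needs no per-pair iterative fit, is exact under the null, and its
   calibration is verified by Monte Carlo (≈5% of null pairs pass at
   p<0.05).
5. **Redundancy prune** (`max_corr`, default 0.4): visiting pairs in
   decreasing screen statistic, keep a pair only if its indicator
   correlates at most `max_corr` in absolute value with every kept pair.
   Pairs sharing a gene are nearly collinear; without pruning the same
   contrast enters the penalised model many times and selection spreads
   over duplicates.
6. **Sparse selection** (`selection_rule`):
   - `"stability"` (default): a lasso-penalised Cox path (coordinate
     descent, l1 ratio 1) is fit once on the full training data to locate
     penalties whose active set is signature-sized (5–30 pairs); the
     lasso is then refit at those penalties on `stability_reps` = 60
     random subsamples of `stability_frac` = 60% of the cohort, and a
     pair is selected if it enters the active set in at least
     `stability_pi` = 70% of refits. Consistency under subsampling
     separates real signal from pairs that ride one particular cohort
     draw, and empirically yields signature-sized models whose members
     are mostly the hazard-driving pairs.
   - `"cv"`: one lasso path with the penalty chosen by k-fold
     cross-validated held-out partial likelihood (`cv_folds`, stratified
     by event status; `lambda_rule` `"min"` or `"1se"`). Provided for
     comparison and for users who want the classical estimator; it
     over-selects on pair spaces because of the collinearity noted above.
7. **Block-swap refinement** (`refine_swaps`, default on): the prune in
   stage 5 ranks pairs *marginally*, so under sampling noise a correlated
   surrogate (sharing a gene with the true prognostic pair) can win the
   block and get selected in its stead. For each selected pair, every
   screened pair correlated with it beyond `max_corr` is re-tested by the
   partial likelihood profiled over that pair's coefficient with the rest
   of the model fixed as an offset; the block's best member replaces the
   incumbent. Deterministic, no randomness.
8. **Refit**: final βᵢ from an unpenalised multivariate Cox fit (Efron
   ties) on the selected pairs. Lasso-shrunken coefficients would
   systematically compress the score scale that a fixed cutoff presumes.
9. **Cutoff**: median of the training scores by default (dataset-specific
   median stratification), or an externally fixed constant for
   cross-cohort use (`cutoff_mode="fixed"`, e.g. a published value such
   as 1.195).

A single integer seed drives fold assignment and subsample draws; the
signature metadata records sample counts, stage survivor counts, the full
config and a content hash, so a signature can be traced to its exact
inputs. Training is invariant to per-sample monotone distortion of the
expression matrix up to the MAD prefilter (which sees the raw scale); on
distorted views of the same data the selected pairs and coefficients are
unchanged whenever the prefilter survivor set is.

## Scoring

Samples are scored independently; a sample's score can never depend on
which other samples are in the file. Missing signature genes raise an
error under the default `strict` policy; under `drop` the affected pairs
are skipped and counted, and the remaining coefficients are *not*
rescaled — rescaling would silently shift the score scale against the
fixed cutoff. Ties at the cutoff go to LRisk.

## Evaluation statistics

- **Kaplan–Meier / log-rank** and the **multivariate Cox fit** (hazard
  ratios with Wald 95% CI, Efron ties) are delegated to lifelines.
- **Harrell's C** is the lifelines concordance index (higher score =
  higher risk; censoring-incomparable pairs excluded; score ties 1/2).
- **Time-dependent AUC** is the cumulative/dynamic IPCW estimator: cases
  are observed events up to the horizon weighted by 1/Ĝ(Tᵢ⁻), where Ĝ is
  the Kaplan–Meier estimate of the censoring distribution; controls are
  subjects still at risk past the horizon. Chosen over smoothed
  nearest-neighbour estimators because it has no bandwidth to tune; it
  agrees with scikit-survival's implementation to machine precision and
  with a brute-force double loop exactly.
- **RMS ratio**: area under each group's KM curve to a horizon τ, HRisk
  over LRisk. τ defaults to the shorter of the two groups' largest
  observed times; an explicit τ beyond a group's follow-up is accepted
  only when that group's curve has already reached zero (the extra area
  is exactly zero, not an extrapolation).
- **Resampling protocol**: draw ⌊0.8·n⌋ samples without replacement,
  recompute C and the median-split log-rank p (the split recomputed
  inside each resample), repeat; report mean/sd of C and the fraction of
  significant replicates. Fraction 1.0 is the degenerate case (sd exactly
  0).
- No multiple-testing correction is applied across statistics or cohorts;
  p-values are reported per analysis so users can correct downstream.

## The simulator

`simulate_cohort` emulates a multi-platform prognostic study: per-gene
log-normal expression (log2 locations ~ N(3, 1), spreads ~ U(0.4, 1.2)),
`n_true_pairs` disjoint pairs whose indicators drive the hazard
baseline·exp(Σβᵢ·Iᵢ) (β magnitudes uniform in `beta_range`, random signs),
event times exponential by default (Weibull shape exposed), independent
exponential censoring whose rate is found by bisection so the realised
censored fraction hits `censoring_rate_target`, follow-up rounded to 0.1
month (realistic ties), and per-platform views produced by per-sample
strictly monotone distortions (log / power / rank / positive-affine
families, cycled across platforms).

True-pair genes get matched locations (difference ~ N(0, 0.3)) so their
order flips in a substantial fraction of samples. This is a deliberate
design choice, not a convenience: a pair whose order is near-constant
cannot generate risk differences between patients, so "hazard-driving
pair" and "informative pair" are the same notion, and the generator keeps
them consistent.

The default scenario — 600 samples, 150 genes, 8 true pairs,
|β| ∈ [0.5, 1.0], ~30% censoring, 2 platforms, with a baseline hazard of
ln 2/60 per month (5-year median survival at η = 0) — gives a true-signal
concordance around 0.74, typical of a strong published prognostic index.
All problem sizes in the test-bench (20 training seeds, 500 resampling
replicates, ~100 random instances per oracle comparison) were chosen as
the smallest sizes at which the checked quantities are stable.

What the simulator does **not** model: between-gene correlation structure
(real transcriptomes are heavily co-regulated, so real candidate pairs are
more redundant than simulated ones), gene-specific platform effects that
are monotone per gene but not per sample (present only as the adversarial
negative control), informative censoring, and cohort-level heterogeneity
in baseline hazard. Passing tests therefore demonstrate correctness of the
machinery and recoverability under clean conditions, not clinical
performance on real cohorts.

## Numerical choices and degenerate inputs

- Ties: indicator ties → 0; score ties in C and AUC → 1/2; survival-time
  ties → Efron approximation in every Cox fit and screen (accurate for
  month-resolution follow-up), Breslow only in the held-out CV scorer
  where it coincides with Efron on tie-free folds and is cheaper.
- The screen skips constant-indicator pairs (zero information) with a
  warning rather than failing the run.
- Penalty paths: 50 alphas down to 2% of the maximal penalty for CV, 30
  alphas to 5% for the stability path; coordinate-descent tolerance 1e-7.
- Cox refits use a 1e-6 ridge for numerical stability on nearly-collinear
  selections; complete separation surfaces as an error naming the stage.
- Training requires at least one event (screen: at least two); fewer than
  10 events (or fewer than 10 per covariate in evaluation) warns.
- Empty intermediate stages (no informative pair, nothing past the
  screen, empty stability selection) raise stage-named errors rather than
  returning empty signatures.

## Known limitations

- The selection defaults were designed for pair spaces of 10³–10⁵
  candidates with a handful of true effects; very small candidate sets
  are better served by `selection_rule="cv"` or a fixed penalty.
- Harrell's C is reported unweighted (no IPCW correction à la Uno), so
  under heavy censoring it is mildly optimistic; the time-dependent AUC
  covers the censoring-robust view.
- The score is not calibrated to absolute risk; cutoffs transfer across
  platforms only because the score scale does (same pairs, same βᵢ).
- Gene identifiers are matched by exact string; probe-level microarray
  data must be collapsed to genes upstream (duplicate rows are collapsed
  by mean/max/max-variance, but probe-to-gene mapping is out of scope).
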