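# irgpi — immune-related gene-pair prognostic index

`irgpi` trains, applies and evaluates **rank-pair survival signatures**:
prognostic risk scores built entirely from *within-sample* comparisons of
gene expression. For a gene pair (a, b) and a sample *s* the feature is the
binary indicator

```
I(a, b; s) = 1  if  expr[a, s] < expr[b, s],   else 0
```

and the risk index of a single sample is the weighted sum over the
signature's pairs

```
IRGPI(s) = Σᵢ βᵢ · I(aᵢ, bᵢ; s)
```

with Cox-regression coefficients βᵢ and a fixed cutoff separating high-
(HRisk) from low-risk (LRisk) patients. Because the indicator depends only
on the *ordering* of two values inside one sample, the score is exactly
invariant to any per-sample strictly monotone transform — log, rank,
positive scaling, quantile normalisation — and therefore transfers across
microarray and RNA-seq platforms without renormalisation or batch
correction. Signatures of this kind (e.g. the published 29-pair bladder
cancer model with its cross-platform cutoff of 1.195) can be written to a
small JSON file and applied to one sample at a time.

The package is aimed at computational oncology / biostatistics users who
want to (1) train such a signature from an expression matrix and a
survival table, (2) score new cohorts or single samples on any platform,
and (3) evaluate prognostic performance with the standard battery:
Kaplan–Meier + log-rank, multivariate Cox adjustment, Harrell's C with an
80%-resampling stability protocol, IPCW time-dependent AUC at 3/5/10
years, and restricted-mean-survival-time ratios. A seeded simulator
generates multi-platform cohorts with a known pair-driven hazard so every
stage is testable without downloading patient data.

## Worked example

Simulate a 300-patient two-platform cohort with 5 true pairs, train on
platform 1, score platform 2 (a differently distorted view of the same
samples), and evaluate:

```console
$ irgpi simulate --config sim.yaml --seed 42 --outdir sim
wrote 2 platform view(s) of 300 samples to sim
$ irgpi train --expr sim/platform1_expression.tsv --surv sim/survival.tsv \
      --seed 42 --out sig.json
trained signature with 7 pair(s), cutoff 0.4194 -> sig.json
$ irgpi score --expr sim/platform2_expression.tsv --signature sig.json \
      --mode median --out scores.tsv
scored 300 sample(s) (148 HRisk) -> scores.tsv
$ irgpi evaluate --scores scores.tsv --surv sim/survival.tsv \
      --times 3,5,10 --reps 500 --seed 42 --out report.json
c_index=0.650 logrank_p=1.21e-10 -> report.json
```

where `sim.yaml` held `n_samples: 300`, `n_genes: 60`, `n_true_pairs: 5`,
`censoring_rate_target: 0.3`. The scores table lists one row per sample:

```
sample	irgpi	group	n_pairs_used
S0000	-0.15288161877533377	LRisk	7
S0001	0.19941192984949055	LRisk	7
```

`irgpi` is the risk index itself (higher = poorer expected survival),
`group` the median-split risk call, `n_pairs_used` how many signature
pairs could be evaluated in that sample. The report contains, among other
entries:

```json
{
  "c_index": 0.6500658116257002,
  "logrank_p": 1.2089386645399576e-10,
  "auc_at_times": {"36.0": 0.7022, "60.0": 0.7252, "120.0": 0.7486},
  "rms_ratio": 0.4395,
  "c_resample_mean": 0.6494,
  "c_resample_sd": 0.0108
}
```

A concordance of 0.65 means 65% of comparable patient pairs are ranked
correctly by the score; the log-rank p-value shows the two risk groups'
survival curves separate decisively; the AUCs are the discrimination of
36-, 60- and 120-month survival status; the RMS ratio says the high-risk
group accrues only ~44% of the low-risk group's survival time up to the
common follow-up horizon; and the resampled C (80% subcohorts, 500 reps)
shows the estimate is stable. Note the signature was trained on platform 1
but scored on platform 2 — the rank-pair construction makes that free.

The same workflow is available as library calls (`simulate_cohort`,
`train_signature`, `score_cohort`, `evaluate`); see the module docstrings.

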