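# ecpredict

Desk-scale pipeline for predicting individual behavioral/phenotypic scores
from task-fMRI **effective connectivity**:

1. **paradigm** — seeded spatial stimulus–response-compatibility (SRC) task
   designs (24 blocks, 12 Pro / 12 Anti, 13–16 trials of 0.2 s per block,
   2–4.5 s jittered onsets, 15–19 s rests, 2-s instructions) encoded as binary
   driving/modulatory inputs in an *event* or *block* dialect, plus the
   behavioral target (mean Anti-condition RT with the 150/1500 ms trial
   filter).
2. **cohort** — synthetic subject cohorts with ground-truth coupling
   matrices: an age-like score planted in the intrinsic matrix A and an
   RT-like score planted in the task-modulation matrix B on disjoint edges;
   forward-simulated ROI BOLD with white observation noise.
3. **dcm** — bilinear neural dynamics `dz/dt = (A + Σ_k u_k B_k) z + C u`
   (exact matrix-exponential stepping on a microtime grid, default TR/16),
   balloon-model hemodynamics (log-state Heun integration), and
   variational-Laplace inversion with Levenberg damping, per-node noise
   precisions, a monotone free-energy trace, explained variance, and the
   <10 % explained-variance exclusion rule.
4. **peb** — parametric empirical Bayes over subject posteriors with a
   two-column design matrix (ones; mean-centered covariate), per-parameter
   posterior probabilities via analytic reduced log evidence, PP > 0.95
   masks, and Bayesian model reduction (exhaustive ≤ 16 parameters, greedy
   beyond; BMA posterior probabilities).
5. **predict** — the CV workflow: k-fold/LOOCV splits, training-set-only
   PEB(/BMR) feature masks, LASSO/ridge with inner 5-fold penalty selection,
   per-repetition accuracy, label-shuffled permutation nulls, Cohen's d, and
   feature-selection frequency maps.
6. **fc** — the comparison arm: full and task-residual functional
   connectivity with CPM-style top-10 % edge selection feeding the same
   regression machinery.
7. **io / cli** — text formats (FSL 3-column EVs, tab-delimited time series
   with JSON sidecars, CSV scores, JSON posteriors/results), validated JSON/
   YAML run configs, a run manifest with machine-readable exclusions, and the
   `ecpredict` command-line interface.

## Accuracy conventions

Each repetition's accuracy `r_per_repetition` is the Pearson correlation
between predicted and empirical scores **averaged over the testing folds** of
one CV round; the pooled-across-subjects correlation is recorded alongside as
`r_pooled_per_repetition` (and is the primary value for LOOCV, whose folds
are singletons). Pooled correlations carry an inherent ≈ −1/√(fold size)
bias under the null, which matters at desk-scale cohort sizes.

Matrix orientation: in memory `A[i, j]` couples node *j* → node *i* (so
`dz = A z` reads conventionally); tab-separated matrix exports are written
row = source ("From"), column = target ("To") and transposed back on read.

## CLI

```sh
# simulate a 12-subject synthetic cohort (9-ROI SRC network)
ecpredict simulate --seed 1 --subjects 12 --blocks 8 --design event --out cohort/

# invert each subject's DCM (writes *_posterior.json + manifest with exclusions)
ecpredict invert --cohort cohort/ --out posteriors/ --max-iter 32

# group-level PEB on the modulatory matrix against RT
ecpredict peb --posteriors posteriors/ --scores cohort/scores.csv \
    --target rt_like --which B --out peb.json

# cross-validated prediction (LASSO, 5-fold, permutation test)
ecpredict predict --posteriors posteriors/ --scores cohort/scores.csv \
    --target rt_like --features mec --cv k5 --reps 10 --perms 100 \
    --seed 1 --out results/mec_rt.json

# FC comparison arm (CPM edge selection)
ecpredict fcpredict --cohort cohort/ --scores cohort/scores.csv \
    --target age_like --features fc --cv k5 --reps 10 --out results/fc_age.json

ecpredict report --results results/
```

## Acceptance

All acceptance checks are property-based and live in
`tests/test_acceptance.py` (forward-model closed forms, inversion recovery on
planted cohorts, free-energy monotonicity, BMR/PEB oracle equivalence,
prediction null calibration and power, counting rules, and a leakage guard).
The source study's cohort is not publicly shareable, so there are no numeric
headline targets to recompute;

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a small end-to-end self-check and writes an (intentionally empty) target
report.

## File formats

* **Time series**: tab-delimited, header row of node labels, one row per
  scan; TR/subject metadata in a same-stem `.json` sidecar.
* **Task timing**: FSL 3-column EV files (`onset<TAB>duration<TAB>amplitude`).
* **Scores**: CSV with `subject_id,rt_like,age_like`.
* **Posteriors / PEB / prediction results / manifests**: JSON (12
  significant digits for all text numerics).
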