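# plvcpm

Connectome-based predictive modelling (CPM) of depression severity from
band-limited phase-locking EEG networks.

The pipeline starts from regional time series (or pre-computed 68×68
phase-locking connectivity matrices, one per subject) and a subject
table of raw depression scores, and runs:

1. **connectivity** — 40-s epoch segmentation with ±100 μV amplitude
   rejection, zero-phase Butterworth band-pass (delta/theta/alpha/beta/
   gamma), analytic-signal phase extraction, and phase locking value
   (PLV) matrices averaged across epochs.
2. **cpm** — score Z-transformation (with cross-scale harmonization,
   e.g. BDI 0–63 ↔ HDRS 0–52 via proportional rescaling of mean/SD),
   per-edge standardization frozen on the training set, Pearson edge
   selection at p_FDR < 0.01 (Benjamini–Hochberg, optionally partial
   correlation controlling covariates), positive/negative tails, summed
   edge-strength features, and an epsilon-SVR regressor serialized to
   JSON.
3. **validation** — leakage-free k-fold × iteration cross-validation,
   a permutation MAE null, consensus networks (edges persisting in
   every fold of every iteration), external validation of the frozen
   model on an independent cohort, dummy-mean baseline and group-wise
   evaluation.
4. **confounds** — Pearson / point-biserial screening with an
   effect-size-or-significance flag rule and partial correlation.
5. **synthetic** — seeded generators for bimodal cohorts, connectomes
   with a planted edge-score signal (default 33 positive + 5 negative
   edges), and coupled alpha-band oscillator time series whose PLV
   tracks the score, so the whole pipeline is testable offline.

## CLI

```sh
# simulate a cohort with a planted signal
plvcpm simulate --n-hc 76 --n-mdd 45 --effect-size 0.1 --noise-sd 0.05 \
    --seed 1 --out-dir scratch/sim

# internal validation (CV + permutation null)
plvcpm validate --subjects scratch/sim/subjects.csv \
    --matrix-dir scratch/sim/matrices \
    --k 5 --iterations 20 --permutations 200 --seed 1 \
    --out scratch/report.json

# train and freeze a consensus-network model
plvcpm train --subjects scratch/sim/subjects.csv \
    --matrix-dir scratch/sim/matrices --iterations 20 --seed 1 \
    --out scratch/model.json

# predict scores for a (new) cohort
plvcpm predict --model scratch/model.json \
    --subjects scratch/sim/subjects.csv \
    --matrix-dir scratch/sim/matrices --out scratch/pred.csv

# build a PLV connectome from a regions-x-samples text recording
plvcpm connectome --timeseries ts.txt --fs 250 --band alpha --out conn.txt
```

`plvcpm --config config.yaml <command>` reads defaults from YAML/JSON;
flags override. Matrices are plain delimited text; models and reports
are JSON (reports also get an aligned `.txt` summary).

## Conventions

- Edge vectorization is the row-major strict upper triangle (i < j,
  0-based): 2278 edges for 68 regions, everywhere.
- Sample (ddof=1) standard deviations for all standardizations.
- Permutation p = (1 + #{null MAE ≤ observed}) / (1 + n_perm).
- Held-out R² = 1 − SS_res/SS_tot (can be negative).
- Folds with empty FDR selection fall back to the dummy mean predictor;
  constant predictions score r = 0.
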