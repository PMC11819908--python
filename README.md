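# icpredict

Intrinsic-capacity (IC) scoring and longitudinal IC prediction for
healthy-aging cohorts.

The package computes the five WHO IC domain scores — locomotion, sensory,
psychology, cognition, vitality — on the unit interval from standard
geriatric instruments (SPPB, self-rated hearing/vision, PHQ-9, MoCA, the
SF-12 energy item plus grip strength), builds supervised datasets that pair a
subject's wave-*t* features with their domain IC score at wave *t + h*
(waves are two years apart; *h* = 2 waves for locomotion and vitality, 1
otherwise), and benchmarks four regression families with 10-fold
cross-validation (MSE, MAE, R², median absolute error, on both test and
train partitions). A synthetic multi-wave cohort generator with controllable
decline, noise, missingness and dropout makes the whole pipeline exercisable
without any external data.

## Layout

| module | purpose |
|---|---|
| `icpredict.scoring` | five IC domain scores from questionnaire totals and measurements |
| `icpredict.preprocessing` | unit scaling, marital-status one-hot, z-standardization of MoCA/PHQ-9 totals, imputation |
| `icpredict.datasets` | wave pairing into per-domain supervised datasets |
| `icpredict.cohort` | synthetic cohort simulator and planted-linear-signal generator |
| `icpredict.models` | linear / random-forest / gradient-boosting / dense-NN harness, k-fold CV |
| `icpredict.pipeline` | end-to-end orchestration, profile export, run manifest |
| `icpredict.cli` | `icpredict` command-line interface |

Notes:

* Grip strength enters the vitality composite in raw kilograms, as
  published; roughly 11 kg alone saturates the score at 1. No
  renormalization is applied.
* Missing instruments yield an *unavailable* domain score (never imputed,
  never zero-filled), and prediction labels are never imputed — pairs with a
  missing label are dropped. Feature imputation (column mean/median or
  drop-incomplete) applies to features only.
* No aggregate "total IC" scalar is computed or exported; there is no
  standardized formula for one.
* The gradient-boosting family uses scikit-learn's
  `GradientBoostingRegressor`; the dense NN is a small NumPy implementation
  (hidden widths per domain, batch normalization after each hidden
  activation, single linear output unit, Adam + early stopping).

## CLI

```bash
# generate a synthetic cohort (CSV + metadata JSON)
icpredict simulate --seed 7 --out scratch/cohort.csv

# score one subject (flat JSON record) or a CSV batch
icpredict score --input record.json --out profile.json

# build the supervised dataset for a domain
icpredict build-dataset --input scratch/cohort.csv --domain cognition \
    --out scratch/cognition.csv

# train, evaluate, predict
icpredict train --input scratch/cognition.csv --domain cognition \
    --family random_forest --trees 100 --out scratch/model.pkl
icpredict evaluate --model scratch/model.pkl --input scratch/cognition.csv \
    --out scratch/eval.json
icpredict predict --model scratch/model.pkl --input scratch/cohort.csv \
    --out scratch/predictions.json

# cross-validate all four families
icpredict compare --input scratch/cognition.csv --domain cognition \
    --out scratch/metrics.csv

# full pipeline: simulate -> score -> datasets -> models -> export
icpredict run --seed 7 --out scratch/run
```

`icpredict run` writes per-domain metric CSVs, radar-ready per-subject
profile JSON (current + predicted scores with availability flags), dataset
summaries, and a `manifest.json` embedding the seed, a config hash, and
library versions; identical configs reproduce deterministic outputs.

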