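# survnet

Multi-task neural survival analysis for right-censored tabular data with
missing values.

A single small network is trained jointly on three tasks:

- **Input reconstruction** — missing covariates are zero-filled and an
  encoder/decoder pair learns latent features under an *incomplete-aware*
  loss that scores observed entries only (missing entries get exactly zero
  gradient).
- **Fixed-horizon survival classification** — a logistic head predicts the
  probability of surviving past a horizon `T` (36 months by default);
  patients censored before the horizon are masked out of the loss.
- **Cox regression** — a linear head produces a log hazard, trained with the
  negative log partial likelihood (Breslow ties, risk set `t_j >= t_i`).

A **context gating** mechanism fuses the last two: the deployed prognosis
index is `p_x = a_p * a_c`, the Cox log-hazard modulated elementwise by the
predicted survival probability. Disabling reconstruction, classification and
gating reduces the model exactly to the plain Cox-network baseline.

The package also ships censored-data evaluation (Harrell's C-index,
Kaplan–Meier curves with Greenwood bands, two-group log-rank test,
median-score risk dichotomization), an input-dropout robustness experiment,
and a Weibull proportional-hazards cohort simulator with calibrated
censoring and MCAR missingness so everything is testable without any
external data.

The network is implemented in plain numpy (hand-written backprop,
finite-difference checked), with an RMSProp optimizer (lr 0.01, smoothing
0.99, eps 1e-8) and weight decay on weight matrices only.

## CLI

```sh
# generate a synthetic cohort (CSV), its schema (YAML) and true risks
survnet simulate --n 1000 --seed 1 --censor-rate 0.6 --missing-rate 0.2 \
    --out cohort.csv --schema-out schema.yaml --truth-out truth.csv

# train (60/20/20 split), selecting the epoch with best validation C-index
survnet train --cohort cohort.csv --schema schema.yaml --seed 1 \
    --out model.json --history-out history.csv

# C-index, median-split risk groups, log-rank test, per-group KM tables
survnet evaluate --checkpoint model.json --cohort cohort.csv --out report.json

# per-patient prognosis index / survival probability / risk group
survnet predict --checkpoint model.json --cohort cohort.csv --out pred.csv

# input-dropout robustness of a frozen model
survnet robustness --checkpoint model.json --cohort cohort.csv \
    --dp 0.0 --dp 0.2 --dp 0.4 --repeats 100 --seed 1 --out robust.csv
```

Training defaults reproduce the reference protocol: 100 epochs, batch size
64, weight decay 1e-5, loss weights (alpha, beta, gamma) = (0.2, 1, 3),
horizon T = 36 months, best-validation-C model selection, 5-repeat
summaries. A YAML config file (`--config`) can override any of it; unknown
keys are rejected. Every output gets a `*.manifest.json` provenance sidecar.

Cohort files are plain CSV (`id, <covariates>, time, event`; empty or `NA`
fields mark missing covariates). Checkpoints are self-describing JSON
(parameters + architecture + schema + standardization statistics) and
restore bit-identical inference outputs.

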