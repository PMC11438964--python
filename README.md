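# stimarx

Switched-linear / bilinear autoregressive modeling of stimulation-evoked
multichannel recordings (1 kHz), with ridge estimation, hierarchical model
selection, shuffle-based causal-effect tests, distance-resolved network
analysis, and generalization experiments — exercised end-to-end on synthetic
recordings with known ground truth.

## The model

For each channel `k`, the one-step increment is predicted from lagged
observations:

```
dy_k(t) = (a_k + U(t) c_k)' y_k^L(t) + b_k' u^M(t) + sum_{i != k} d_{k,i}' y_i^P(t)
```

where `y_k^L(t) = [y_k(t-1), ..., y_k(t-L)]`, `u` encodes the stimulation
pulse train (amplitude at pulse samples), and the gate `U` is 0/1
(switched-linear), the stimulation amplitude (amplitude-weighted), or `u`
itself (bilinear).  Setting blocks to zero yields the AR / ARX / VAR / VARX
sub-families; a sparse delay-embedded variant replaces the autoregressive
lags with `t - tau, ..., t - L tau`.  Parameters are fit by ridge regression
of the per-sample mean squared error: `(X'X + N lam I) theta = X' dy`.

## Layout

| module | contents |
| --- | --- |
| `stimarx.synth` | stable ground-truth system sampling, factorial stimulation schedules, forward simulation |
| `stimarx.preprocess` | notch/detrend/z-score, input & gating encoding, onset correction, windowing & folds |
| `stimarx.model_family` | feature construction, one-step prediction, rollout, delay-time selection |
| `stimarx.estimation` | ridge solver, constrained fits, order grid search, network-lag selection |
| `stimarx.evaluation` | NMSE, win rates, Wilcoxon model comparison, statistical win rate |
| `stimarx.causal` | input/network shuffle tests, indirect linearity test |
| `stimarx.network` | distance-resolved MSE-advantage profile, backward elimination, sigmoid fit |
| `stimarx.generalize` | frequency-subset and cross-session experiments |
| `stimarx.io`, `stimarx.config`, `stimarx.cli` | HDF5/CSV containers, YAML config, command-line pipeline |

## CLI

```sh
stimarx --config demo.yaml --seed 1 --out results run     # full pipeline
stimarx --config demo.yaml --out results simulate         # single stage
stimarx --out results report
```

Stages: `simulate`, `preprocess`, `fit`, `select-order`, `compare-families`,
`causal`, `distance`, `eliminate`, `generalize`, `report`.  A config is a
flat YAML/JSON mapping; `seed` is required, everything else defaults (see
`stimarx.config.DEFAULTS`).  Rerunning with the same config and seed
reproduces all outputs bitwise.

Minimal config:

```yaml
seed: 1
n_channels: 8
frequencies: [25, 100]
reps: 5
```

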