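# festorque

Offline-replayable estimation of joint torque induced by functional
electrical stimulation (FES), using only the evoked EMG (M-wave) recorded
between stimulation pulses.

The package covers the full loop of a real-time FES torque-estimation
session, replayed deterministically:

- **signal_processing** — stimulation-artifact blanking, residual-spike
  removal by adjacent-difference thresholding, per-loop MAV / mean-torque
  feature extraction, MAV smoothing, Biodex analog-voltage scaling
  (8.64 Nm/V), normalization.
- **stim_protocol** — trapezoidal pulse-width trains (0.5 s ramp-up, 1 s
  plateau, 0.5 s ramp-down, 2 s rest by default): linearly swept plateaus
  for identification, seeded random plateaus for prediction.
- **muscle_sim** — synthetic session generator with known ground truth:
  saturating recruitment of a biphasic M-wave template, artifact spikes,
  second-order torque dynamics (exact zero-order-hold discretization),
  exponential fatigue, Gaussian channel noise.
- **kalman_phm** — recursive forgetting-factor Kalman estimation of a
  polynomial Hammerstein model (joint state/parameter EKF formulation, plus
  a linear-in-parameters RLS mode), and frozen-parameter free-run
  prediction.
- **narx_rnn** — NARX model with bilinear input-output cross terms:
  one-shot SVD-pseudoinverse identification of the stacked design matrix,
  then free-run prediction with frozen coefficients.
- **metrics** — RMSE, NRMSE (% of measured peak-to-peak range), VAF.
- **session_pipeline** — end-to-end orchestration (simulate/load →
  preprocess → identify → free-run predict → evaluate) with strict
  identification/prediction phase separation, CSV artifacts and a YAML
  config.

## CLI

```sh
fes-torque show-config                        # print the default config
fes-torque run --seed 1 --out-dir out/        # simulate + identify + predict
fes-torque simulate --out-dir sim/            # write raw recording CSVs
fes-torque preprocess --recording sim/recording.csv --pulses sim/pulses.csv \
    --out features.csv
fes-torque identify --features features.csv --estimator narx --out params.txt
fes-torque predict --features features.csv --params params.txt --out pred.csv
fes-torque evaluate --prediction pred.csv --estimator narx --out report.csv
```

All commands accept `--config cfg.yaml` (a flat key-value document; see
`fes-torque show-config` for every key and default). `run` writes the
feature series, parameter dumps, per-estimator prediction CSVs and a
summary report (subject, estimator, RMSE/NRMSE/VAF).

## Library use

```python
from festorque import SessionConfig, run_session

reports = run_session(SessionConfig(seed=1))
print(reports["narx"].vaf, reports["kalman"].vaf)
```

During the identification phase (default first 30 s) the estimators update
on measured torque; afterwards parameters are frozen and torque is
predicted from the eEMG MAV alone — measured torque past the boundary is
never read (tested bit-exactly). The Kalman path normalizes input/output to
[0, 1] by identification-phase maxima by default; the NARX path runs on
absolute scale.

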