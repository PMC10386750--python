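# radarvitals

A non-contact vital-sign monitoring toolkit built around calibrated
synthetic data. It covers the full computational chain of a UWB-radar
monitoring system:

- **`signal_sim`** — slow-time phase simulation of chest motion: a
  two-sinusoid displacement model (respiration + heartbeat) mapped to radar
  phase via `theta = 4*pi*x/lambda`, with Gaussian phase noise and optional
  gross body-motion transients.
- **`vitals`** — respiration/heart-rate recovery by band-restricted spectral
  peak picking, band-limited motion energy, four-level motion-status
  classification against three thresholds, and delay-to-distance conversion
  (`R = c*tD/2`).
- **`synth`** — synthetic data generators: (a) heart-rate correction records
  whose factor-vs-error Kendall tau-b dependence is calibrated to prescribed
  targets through a latent Gaussian construction, and (b) RR-interval
  sequences with inserted tachyarrhythmia-like abnormal segments.
- **`correction`** — a 9-input fully connected correction network
  (64/128/256/128/1, PReLU, dropout 0.2/0.3/0.4, MSE loss, Adagrad) mapping
  condition factors + radar heart rate to a corrected heart rate.
- **`anomaly`** — a 1-D CNN classifier over 1024-interval RR windows
  (2 conv blocks + FC head, cross-entropy, Adam), sliding-window inference,
  and the per-segment detection latency value `k`.
- **`metrics`** — MAE/MSE/MRE, percent-reduction summaries, Kendall tau-b.
- **`pipeline` / `cli`** — tabular I/O, experiment orchestration and a
  `radarvitals` command-line front end.

Neural networks, Adagrad and Adam are implemented in NumPy from first
principles (see `radarvitals/nn.py`); single optimizer steps are covered by
hand-computed unit tests.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` runs the full-scale experiments (10,400-record
correction run, CNN latency experiment) and takes a couple of minutes; the
rest of the suite runs in well under a minute.

## CLI

```bash
radarvitals simulate --seed 1 --out phase.csv
radarvitals extract phase.csv
radarvitals gen-data --n 10400 --seed 0 --out records.csv
radarvitals correlate records.csv
radarvitals train-corrector records.csv --epochs 200 --out corrector.json
radarvitals correct records.csv --model corrector.json --out corrected.csv
radarvitals evaluate corrected.csv
radarvitals gen-rr --n 1600 --segments "350:40,315:30,450:25,350:35,299.5:50,502:40" --out rr.csv
radarvitals train-detector --out detector.json
radarvitals detect rr.csv --model detector.json --out flags.csv
radarvitals eval-latency rr.csv --model detector.json --out latency.json
radarvitals run-all --seed 0 --out run/
```

Model checkpoints are versioned JSON files; all tabular formats are plain
CSV with a header row.

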