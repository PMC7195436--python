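# czdown

Critical-slowing-down biomarkers and phase-conditioned seizure forecasting
for long-term snapshot iEEG, plus a synthetic recording generator built on a
driven bistable state model — so every stage of the pipeline can be
exercised and validated without clinical data.

## What it does

A long-term recording is a stream of 1-s, 400-Hz snapshots taken every
2 minutes per channel. The pipeline:

1. **synthetic** — integrates the cubic bistable model
   `dz/dt = -z^3 + 1e-3*r*z + 1e-3*k(t)` (Euler–Maruyama; 1 time-unit =
   1 hour) with circadian + multidien drive, labels seizures at
   unstable-branch crossings, and renders AR(1) snapshots whose correlation
   time follows the linearized relaxation time — so autocorrelation width
   and variance provably grow on the approach to the fold. Also injects
   template-shaped epileptiform spikes (rhythm-modulated Poisson) and data
   dropouts, and can emit biomarker-level series directly
   (`synthesize_features`, `synthesize_rhythmic_features`) for fast
   experiments. Ground truth (drive, phases, spike times, catalog) is
   always returned.
2. **features** — 170-Hz FIR pre-processing, per-segment population
   variance, biased autocorrelation and its half-maximum width (ACFW),
   template-correlation spike detection, and fine-scale peri-seizure
   profiles (5-s windows, baseline-normalized, peak/trough extraction).
3. **rhythms** — causal (or zero-phase) moving-average decomposition into
   long (2-day MA) and short (residual, 40-min MA) cycles, Gaussian filling
   of sub-2-h gaps, Hilbert analytic phases with dropout/boundary validity,
   and FFT-based dominant-period detection (circadian / multidien flags).
4. **synchrony** — synchronization index (mean resultant length), seizure
   phase histograms, best-channel selection, cross-electrode similarity.
5. **forecaster** — 20-bin `P(seizure | phase)` tables per (signal, cycle),
   multiplied into a probability trace; brute-force two-threshold
   optimization into low/medium/high risk; Method **M1** (within-sample,
   anti-causal) and Method **M2** (pseudoprospective: bootstrap on 10
   seizures, refit per seizure on a trailing 50-day window, strictly causal
   phase estimation at the record edge); a random-Markov chance predictor;
   performance product and ROC scoring.
6. **clusters** — inter-seizure-interval histograms, the 5-in-a-day
   clustering rule, lead-time rules (exponential decay vs multi-peak),
   lead-seizure-aligned biomarker averages and follower density.
7. **pipeline / CLI** — one-config orchestration with seeded, bit-identical
   reruns.

## CLI

```bash
czdown simulate --config sim.yaml --out rec.h5 --seed 7   # + .seizures.csv, .truth.h5
czdown features --in rec.h5 --template tpl.json --out feats.csv
czdown forecast --features feats.csv --seizures sz.csv --method m1 --out report.json
czdown clusters --features feats.csv --seizures sz.csv --out clusters.json
czdown run --config pipeline.yaml
czdown summarize report1.json report2.json
```

`sim.yaml` holds `SimulatorConfig` fields (`duration_days`, `n_channels`,
`k_circadian_amp`, `k_multidien_amp`, `noise_sd`, `spike_rate_base`,
`dropout_spec`, `seed`, ...); `pipeline.yaml` nests per-stage configs under
`simulate:`/`forecast:`/`clusters:` with a top-level `seed` that drives all
randomness.

## Layout

```
src/czdown/
  model.py       # cubic bistable model: folds, branches, time constants
  synthetic.py   # simulator, renderers, spikes, dropouts, catalogs
  segments.py    # SegmentStream / SeizureCatalog containers + IO
  features.py    # variance, ACF(W), spike detection, peri-seizure profiles
  rhythms.py     # MA decomposition, gap fill, analytic/edge phases, spectra
  synchrony.py   # SI, histograms, channel selection, electrode similarity
  forecaster.py  # phase tables, thresholds, M1/M2, random predictor, scoring
  clusters.py    # ISI histogram, lead-time rules, aligned profiles
  pipeline.py    # staged orchestration
  cli.py         # `czdown` entry point
```
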