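# softsense

**Raman soft sensors and fed-batch simulation for CHO cell culture.**

Bioreactor runs of Chinese hamster ovary (CHO) cells are monitored offline:
an analyzer measures glucose, glutamine, glutamate, lactate, ammonium and
cell counts once or twice a day, while an in-situ Raman probe records a
spectrum every half hour. A *soft sensor* closes that gap: a regression
model calibrated on the sparse reference measurements turns every spectrum
into a real-time estimate of the process variables — the prerequisite for
automated nutrient feeding.

`softsense` implements the complete calibration workflow plus the process
simulator needed to develop feeding controllers:

- **Preprocessing** — Savitzky–Golay smoothing/derivatives with exact
  rational filter coefficients, and standard normal variate (SNV)
  normalisation (per spectrum: `x̂_j = (x_j − x̄)/σ`, population σ).
- **PLS calibration** — NIPALS partial least squares
  (`w = Xᵀu/uᵀu`, `t = Xw`, deflation `X ← X − tpᵀ`, coefficients
  `B = W(PᵀW)⁻¹Qᵀ`), with K-fold RMSECV model-order selection.
- **Variable selection** — VIP scores
  (`VIP_j = √(m·Σ_a SSY_a w_ja² / Σ_a SSY_a)`) and CARS (competitive
  adaptive reweighted sampling: Monte-Carlo subsampling, |b|-weighted
  channel competition, exponentially decreasing retained-channel count).
- **Outlier removal** — Monte-Carlo cross-validation error profiles per
  spectrum, robust median + 3.5·MAD flagging, guarded removal and refit.
- **Kinetic simulator** — a mechanistic fed-batch ODE model with four
  cell-cycle compartments (G0/G1/S/G2M, doubling at mitosis,
  `μ = ln 2/(t_G1+t_S+t_G2M)`), nutrient/byproduct balances in amount form,
  and bolus/sampling events.
- **PSO fitting** — global-best particle swarm estimation of kinetic
  parameters against observed trajectories with a variance-normalised RMSE
  criterion.
- **Synthetic data** — a generator producing 14-day batches with sawtooth
  nutrient profiles, Raman-like linear-mixture spectra with realistic
  nuisances (baseline, drift, gain, noise, corrupted spectra), and paired
  reference tables, since real batch data of this kind are proprietary.

## Worked example

Calibrating the glucose soft sensor on the synthetic 4-batch benchmark
(`examples/02_train_soft_sensor.py`):

```text
112 paired spectra x 3000 channels
RMSECV by components: 0.551 0.434 0.419 0.400 0.423 0.673 0.745 1.740 2.387 2.121
chosen latent variables: A = 3
validation RMSEP = 0.178 g/L, R^2 = 0.893
```

The RMSECV curve bottoms out around 3–4 latent variables and rises again as
the model starts fitting noise; the parsimony rule picks A = 3. The plain
PLS sensor predicts held-out glucose references to 0.18 g/L. Variable
selection and outlier removal then improve it further
(`examples/03_variable_selection.py`, `examples/04_outlier_removal.py`):

```text
method   channels    RMSEP     R^2
pls          3000    0.266   0.873
vip          1329    0.264   0.875
cars            2    0.210   0.921
```

CARS keeps a tiny channel subset yet beats the full-spectrum model — the
classic small-calibration-set result. The remaining examples simulate a
fed-batch (`05`) and recover kinetic parameters by PSO (`06`), e.g.:

```text
parameter       true     fitted  rel err
q_glc       1.8e-05   1.82e-05    1.03%
y_lac           0.5      0.495    0.90%
k_deg         0.004    0.00401    0.21%
```

## Data formats

- **Spectra CSV**: header `id,time_s,<wavenumber>,...`; one row per
  spectrum; timestamps in seconds since batch start (ISO-8601 accepted).
- **Reference CSV**: header `time_s,<variable>,...` with units fixed per
  column: glucose/glutamine/glutamate/lactate in g/L, ammonium in mmol/L,
  vcc/tcc in 10⁶ cells/mL.
- **Models**: JSON (centring/scaling constants, W/P/Q/B matrices, channel
  mask, metadata).

A thin CLI wraps the library:

```bash
softsense generate --preset paper-like --seed 42 --out data/
softsense preprocess --spectra data/spectra_batch0.csv --out prep.csv
softsense pair --spectra prep.csv --refs data/refs_batch0.csv \
               --variable glucose --out pairs.csv
softsense train --pairs pairs.csv --out model.json
softsense select --pairs pairs.csv --method cars --out cars_model.json
softsense outliers --pairs pairs.csv --report outliers.csv
softsense reconstruct --model model.json --spectra data/spectra_batch0.csv \
                      --out series.csv
softsense simulate --t-end 336 --out trajectory.csv
softsense run --seed 0 --out report_dir/   # full benchmark report
```

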