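"""Calibrate a glucose soft sensor with NIPALS PLS and cross-validation.

Builds the 4-batch benchmark, trains on 80% of the paired data and prints the
RMSECV curve (how prediction error depends on the number of latent
variables), the chosen model order, and validation RMSEP / R^2 — the numbers
a calibration report would quote.
"""

import numpy as np

from softsense.pls import cross_validate, fit_pls, predict, r2, rmse
from softsense.preprocess import preprocess_pipeline
from softsense.synth import benchmark_pairs, make_paired_benchmark

bench = make_paired_benchmark(seed=0)
X, y, ids, is_outlier = benchmark_pairs(bench, "glucose",
                                        preprocess_fn=preprocess_pipeline)
print(f"{X.shape[0]} paired spectra x {X.shape[1]} channels")

# hold out clean validation rows; corrupted spectra stay in calibration
rng = np.random.default_rng(0)
clean = rng.permutation(np.flatnonzero(~np.asarray(is_outlier)))
val = np.sort(clean[:22])
train = np.sort(np.setdiff1d(np.arange(len(y)), val))

curve = cross_validate(X[train], y[train], a_max=10, folds=5,
                       scheme="random", seed=1)
print("RMSECV by components:",
      " ".join(f"{v:.3f}" for v in curve.rmsecv))
print(f"chosen latent variables: A = {curve.chosen}")

model = fit_pls(X[train], y[train], A=curve.chosen)
pred = predict(model, X[val])
print(f"validation RMSEP = {rmse(y[val], pred):.3f} g/L, "
      f"R^2 = {r2(y[val], pred):.3f}")
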