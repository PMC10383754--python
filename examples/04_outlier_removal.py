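"""Find and remove corrupted calibration spectra by Monte-Carlo resampling.

The paired data are repeatedly split 4:1; each spectrum accumulates a mean
absolute prediction error over the test sets it lands in.  Spectra whose
errors sit far above the robust (median + 3.5 MAD) threshold are flagged and
removed, and the model is refit.
"""

import numpy as np

from softsense.outliers import flag_outliers, mc_error_profile, remove_and_refit
from softsense.pls import fit_pls, predict, r2, rmse
from softsense.synth import make_outlier_benchmark

X, y, planted = make_outlier_benchmark(seed=3)
print(f"{len(y)} spectra, planted outliers at rows {planted.tolist()}")

report = flag_outliers(mc_error_profile(X, y, n_repeats=200, seed=3))
print(f"flagged rows: {report.flagged.tolist()} "
      f"(mean-error threshold {report.thresholds['mean']:.3f})")

val = np.setdiff1d(np.arange(48, 60), planted)
train = np.setdiff1d(np.arange(60), val)
before = fit_pls(X[train], y[train], a_max=10, scheme="random", seed=3)
rep_tr = flag_outliers(mc_error_profile(X[train], y[train], n_repeats=200, seed=3))
after, cumulative = remove_and_refit(X[train], y[train], rep_tr, seed=3)

print(f"removed {cumulative.flagged.size} of {train.size} training spectra")
print(f"validation RMSEP before removal: {rmse(y[val], predict(before, X[val])):.3f}")
print(f"validation RMSEP after  removal: {rmse(y[val], predict(after, X[val])):.3f}")
print(f"validation R^2 after removal:    {r2(y[val], predict(after, X[val])):.3f}")
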