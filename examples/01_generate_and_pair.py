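"""Generate a synthetic fed-batch, preprocess its spectra, and pair by time.

A 14-day CHO fed-batch is simulated with daily manual nutrient dosing; Raman
spectra are emitted every 30 minutes and reference measurements twice a day.
Each reference row is matched to its nearest-in-time spectrum, which is the
calibration dataset a real campaign would produce.
"""

import numpy as np

from softsense.io import pair_by_time
from softsense.preprocess import preprocess_pipeline
from softsense.synth import (NuisanceModel, make_batch, make_component_library,
                             make_spectra)

traj, refs, schedule = make_batch(seed=42)
library = make_component_library(seed=42)
spectra, outlier_ids = make_spectra(traj, library, NuisanceModel(), seed=42)

print(f"batch: {traj.times[-1]:.0f} h, {spectra.n_spectra} spectra "
      f"({spectra.n_channels} channels), {len(refs)} reference rows")
print(f"planted outlier spectra: {len(outlier_ids)}")

processed = preprocess_pipeline(spectra)  # SG window 15, quadratic, + SNV
pairs = pair_by_time(processed, refs, "glucose", max_lag_s=1800)
print(f"paired {len(pairs)} glucose references "
      f"(max lag {pairs.pair_lags.max():.0f} s)")
print(f"glucose range in the references: "
      f"{pairs.y.min():.2f} - {pairs.y.max():.2f} g/L")
# every preprocessed spectrum is SNV-normalised: mean 0, population std 1
assert np.allclose(processed.intensities.mean(axis=1), 0, atol=1e-10)
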