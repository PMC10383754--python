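# Methods

This note documents the models and procedures implemented in `softsense`,
their assumptions, the defaults and why, and what the synthetic benchmark
does and does not establish.

## Spectrum preprocessing

**Savitzky–Golay.** Each spectrum is filtered by local least-squares
polynomial regression over a moving window of `2k + 1` channels,
`x*_j = (1/N) Σ_h c_h x_{j+h}`. `savgol_coefficients` derives the weights by
exact rational arithmetic (Fractions through the normal equations), so the
classic integer tables are reproduced bit-exactly — for the 5-point quadratic
window: smoothing (−3, 12, 17, 12, −3)/35, first derivative
(−2, −1, 0, 1, 2)/10, second derivative (2, −1, −2, −1, 2)/7. Derivative
weights include the factorial factor, i.e. they estimate the derivative
itself at unit channel spacing (matching `scipy.signal.savgol_filter`);
physical cm⁻¹ scaling is irrelevant downstream because PLS standardises the
channels. Defaults: window 15 (k = 7), quadratic, smoothing — the common
choice for Raman bioprocess spectra. **Edge policy:** length is preserved by
asymmetric least-squares fits over the edge windows (scipy's `mode="interp"`)
rather than discarding 2k channels of a 3000-channel spectrum.

**SNV.** Per spectrum, subtract the mean and divide by the *population*
standard deviation (divisor N). This removes multiplicative gain and
additive offset differences exactly (SNV is invariant under `x → a·x + b`,
a > 0). A zero-variance spectrum is a degenerate-input error, never NaN.

## NIPALS PLS

Components are extracted one at a time: `u` starts as the (standardised)
response column; `w = Xᵀu/uᵀu` normalised to unit length; `t = Xw`;
the response loading `q = Yᵀt/tᵀt` updates `u = Yq/qᵀq`; iteration stops
when the relative change of `t` falls below 1e-10 (for a single response
this converges in one pass). Deflation is rank-one:
`p = Xᵀt/tᵀt`, `X ← X − tpᵀ`, `Y ← Y − tqᵀ`. Coefficients on the
standardised scale are `B = W(PᵀW)⁻¹Qᵀ`; back-transformation happens at
prediction time. Both X and y are standardised (sample std, n−1); whether
to scale y as well as centre it is a free choice — standardising both keeps
the multi-variable pipeline symmetric and is recorded in model metadata.

Numerical guards: zero-variance predictor columns are dropped into the
variable mask; component extraction stops when a score vector's variance
falls below 1e-9 of the first component's (rank exhaustion) — beyond that
point "components" are numerical residue that destabilise the coefficients.

**Model-order selection.** RMSECV from K-fold cross-validation with
standardisation redone inside each training fold (no leakage). Default K = 5
with two schemes: contiguous blocks (default — spectra are a time series, so
blocks reduce leakage between temporal neighbours) and seeded random folds.
The verbal "no drastic drop after A" elbow is formalised as: the smallest A
whose RMSECV is within 5% of the curve minimum.

## Variable selection

**VIP.** Standard Wold formulation:
`VIP_j = √(m Σ_a SSY_a w_ja² / Σ_a SSY_a)` with `SSY_a = q_a² t_aᵀt_a`;
`mean(VIP²) = 1` exactly, and channels with `VIP ≥ 1` are kept.

**CARS.** Canonical recipe, since the method family is described verbally in
the literature this follows: each of `n_iterations` (default 100) Monte-Carlo
runs (i) fits PLS on a random 80% row subsample of the currently retained
channels, (ii) weights channels by |b| on the standardised scale (so units
cannot bias selection), (iii) enforces the exponentially decreasing retained
count `r(i) = m·exp(−λ(i−1))` calibrated to `r(1) = m`, `r(n) = 2`,
(iv) resamples channels with probability proportional to weight (adaptive
reweighted sampling), and (v) scores the candidate subset by 5-fold RMSECV.
The winner is the subset with the lowest RMSECV. Runs are bit-reproducible
per seed. The tail of the schedule can collapse a subset below two channels;
the loop then stops early and returns the best subset so far.

## Monte-Carlo outlier removal

Repeatedly split the paired data 4:1 at random, fit the PLS pipeline on the
training part, and record each test spectrum's absolute prediction error;
over many repeats every spectrum accumulates a mean error and a standard
deviation. The component count is selected once (by CV on the full data)
and reused across repeats, so the profile isolates the influence of
individual spectra rather than model-order jitter. Flagging uses robust
statistics because the error population is itself contaminated: a spectrum
is flagged when its mean error (or mean + std) exceeds
`median + 3.5 · MAD` (MAD scaled by 1.4826, so the factor reads in
σ-equivalents). Removal refits after dropping flagged rows, iterating at
most once by default, and never removes more than 20% of the rows in total —
an operationalisation of the risk that aggressive trimming overfits the
"typical" spectra.

## Fed-batch CHO kinetic model

States are integrated in **amount form** (concentration × volume), the
literal form of the balance equations; concentrations are derived views.
Units: cells in 10⁶-cell units, volume L, glutamine/glucose/lactate g,
ammonia mmol, antibody mg, time h.

Cell cycle: G2/M cells divide into two G1 daughters (`+2·k_G2M−G1·N_G2M` in
G1, `−k_G2M−G1·N_G2M` in G2/M, net one new cell per mitosis); the G1 efflux
`k_G1−S·N_G1` splits between S (fraction `m_stress`) and G0 (fraction
`1 − m_stress`), with an additional temperature-stress route `k_G1−G0`;
first-order death `k_d` acts on all compartments. Viable cells are the
compartment sum. Glutamine is consumed at `Q_Gln` per viable cell and
degrades thermally (`K_deg`) to ammonia; ammonia gains `Y_Amn` per unit
glutamine consumed plus the degradation flux. Glucose is consumed at
`Q_Glc` by cycling cells and at the maintenance rate `m_Glc` by quiescent
(G0) cells; lactate forms with yield `Y_Lac` from the same terms (with the
maintenance term entering the lactate balance with a negative sign, as the
balance set is written — hence the lactate–glucose conservation law
`A_Lac + Y_Lac·A_Glc = const` holds under no feed/outflow only when the
G0 maintenance term vanishes). Antibody formation is
`μ·[q_G1G0(N_G1+N_G0) + q_S N_S + q_G2M N_G2M]` with the constant
`μ = ln 2/(t_G1+t_S+t_G2M)` (an override hook exists). Outflow `F_OUT`
removes every species at its current concentration. The glutamine/ammonia
pair conserves `A_Gln + A_Amn` exactly when `Y_Amn = 1` in consistent
(molar) units; with the default gram/mmol units `Y_Amn` carries the
conversion for the uptake route while the degradation flux is transcribed
literally.

The model names three modifiers without specifying them — temperature stress
on `k_G1−G0`, temperature/lactate inhibition of `Q_Glc`, and a limiting
function on glutamine uptake. These are implemented as optional
multiplicative hooks defaulting to 1; the synthetic generator supplies
saturating (Monod-type) uptake hooks so draws stay physical as nutrients
approach zero.

**Integration.** Between events, `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-8 / atol 1e-10 by default). Boluses add volume and
stock-concentration × volume instantaneously; sample draws scale all
amounts by `(V − v)/V`. Events at the same timestamp commute for boluses.
Negative excursions below −1e-9 (relative) abort with a diagnostic; smaller
ones are clamped to zero.

**Parameter defaults.** The defaults are literature-magnitude CHO fed-batch
values chosen once: transition rates (0.054, 0.072, 0.108 1/h) set so the
cycle's dominant eigenvalue gives a net growth rate of ~0.0115 1/h
(doubling ≈ 60 h net of death, VCC 0.3 → ~11·10⁶ cells/mL in 14 days);
`k_d` = 0.005 1/h; `Q_Glc` = 1.8e-5 g/(10⁶ cells·h) (~2 pmol/cell/h);
`Y_Lac` = 0.5 g/g; `Q_Gln` = 2e-6 g/(10⁶ cells·h); `K_deg` = 0.004 1/h
(thermal glutamine decay); `Y_Amn` = 4.8 mmol/g (≈0.7 mol NH₄⁺ per mol
glutamine); feed stocks 400 g/L glucose and 30 g/L glutamine; phase
durations (20, 15, 10) h giving μ = 0.0154 1/h for product formation.

## PSO parameter estimation

Global-best PSO with constriction-style defaults (w = 0.729,
c1 = c2 = 1.494, 30 particles, 300 iterations), velocity clamped to half the
box range, positions reflected at the bounds. Box bounds are mandatory —
no unbounded search. The criterion is a weighted mean of per-variable
RMSEs, each normalised by the standard deviation of that variable's
observations, so signals in 10⁶ cells/mL, g/L and mmol/L combine on a
common scale (weights overridable). A failed simulation maps to a large
finite penalty (1e6) so the swarm continues. Runs are bit-reproducible per
seed, and the best-value trace is non-increasing by construction.

## Synthetic world

The generator defines the study conditions for every benchmark:

- **Trajectories**: 14-day batches in a 10 L reactor seeded at
  0.3·10⁶ cells/mL with 8 g/L glucose, 4 g/L glutamine. Daily-bolus mode
  emulates the manual protocol — once a day the operator doses glucose and
  glutamine stock back to setpoints (8 and 4 g/L) — producing the sawtooth
  nutrient profile; a continuous-rate mode also exists.
- **Spectra**: every 1800 s (672 per batch), on a 100–3400 cm⁻¹ axis with
  3000 channels. A spectrum is `gain·(Σ_a conc_a·profile_a + background +
  baseline + drift) + noise`: linear in the concentrations (the regime PLS
  assumes), with a dominant *constant* broth/water background — its
  constancy is what makes per-spectrum SNV scaling approximately linear in
  the analyte concentrations, as in real bioreactor spectra. Nuisances:
  per-spectrum random cubic baseline, slow fluorescence drift, lognormal
  gain (σ = 0.03), additive noise (σ = 0.02), and ~2% corrupted spectra
  (localised spikes, baseline jumps, gain bursts with waveform distortion so
  they survive SNV). Glutamine and glutamate profiles share ≥70% of their
  peaks (cosine similarity ≥ 0.7) to emulate their notorious spectral
  confusability. Glutamate, which the kinetic model does not carry as a
  state, is generated as an auxiliary series tied to cumulative glutamine
  turnover.
- **References**: 2 per day with jittered times and 2% (of series spread)
  measurement noise; the benchmark pools 4 batches, ≈112 usable pairs.
- **Planted outliers** carry ground-truth labels; the planting rate is also
  applied to the reference-adjacent spectra so corrupted spectra reliably
  enter the calibration pairs.
- Process dynamics, measurement noise and spectral nuisances use
  independent seed streams, so changing the noise seed never changes the
  underlying trajectory.

**Benchmark split convention.** When truth labels are available, corrupted
pairs are kept in the calibration set and validation uses clean rows only:
validation then measures recovery of trustworthy references, while the
contaminated rows are left for the outlier-removal step to find — the way
outlier spectra actually enter a calibration campaign. On this benchmark the
method ordering (plain PLS ≥ CARS ≥ CARS + outlier removal by validation
RMSEP) and the end-to-end glucose accuracy (R² ≥ 0.9) are reproduced.

**What the benchmark does not show.** The spectra are linear mixtures by
construction; real Raman spectra add nonlinear matrix effects, temperature
sensitivity, probe fouling and photobleaching dynamics that no linear
generator reproduces. Passing the suite demonstrates the *methods* are
implemented correctly and behave as expected in the regime they assume, not
that a particular real process would reach these accuracies. Problem sizes
in the tests (e.g. 50-channel selection benchmarks, 25-seed Monte-Carlo
repetitions, 16-particle swarms for the 3-parameter recovery) are chosen as
the smallest sizes at which the statistical claims are stable.

## Known limitations

- Dead cells are not a model state; TCC is a bookkeeping proxy (viable pool
  plus integrated death flux), and sampling events do not deplete it.
- The outlier detector is purely prediction-error based; spectral-space
  diagnostics (Hotelling T², Q residuals) are out of scope.
- PLS1 is the optimised path; multi-response fitting works but is not tuned.
- The CLI covers the workflow end to end but is a thin wrapper; programmatic
  use through the library API is the primary interface.
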