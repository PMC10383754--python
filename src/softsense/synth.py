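"""Synthetic fed-batch world: trajectories, Raman-like spectra, benchmarks.

The study data behind a real Raman soft sensor are proprietary, so this
module generates a stand-in world with the same structure: 14-day fed-batch
trajectories from the mechanistic kinetic model with daily manual bolus
dosing (producing the characteristic sawtooth glucose/glutamine profile),
half-hourly spectra that are *linear mixtures* of per-analyte pure-component
profiles plus nuisances (polynomial baseline, slow fluorescence drift,
multiplicative gain, additive noise, occasional outlier spectra), and sparse
daily reference tables with measurement noise.

The linear mixing model is deliberate: it is exactly the regime PLS assumes,
so a noise-free oracle regression achieves R^2 = 1 and the pipeline's losses
are attributable to the nuisances.  Glutamine and glutamate profiles share
most peak positions to emulate their near-identical Raman signatures.

Everything is reproducible per seed; process dynamics, reference-measurement
noise and spectral nuisances use independent sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReferenceTable, SpectraSet
from .kinetics import (Bolus, FeedSchedule, KineticParams, KineticState,
                       Trajectory, simulate)

__all__ = [
    "ComponentLibrary",
    "NuisanceModel",
    "Benchmark",
    "DEFAULT_ANALYTES",
    "make_component_library",
    "default_initial_state",
    "default_params",
    "make_batch",
    "concentration_frame",
    "make_spectra",
    "make_paired_benchmark",
    "benchmark_pairs",
    "make_sparse_linear",
    "make_outlier_benchmark",
]

#: the seven soft-sensor variables, in reporting order
DEFAULT_ANALYTES = ("glucose", "glutamine", "glutamate", "lactate",
                    "ammonium", "vcc", "tcc")


@dataclass
class ComponentLibrary:
    """Pure-component spectral profiles on a shared Raman-shift axis.

    ``background`` is the constant broth/water signature that dominates real
    bioreactor spectra; its (near-)constancy across a batch is what makes the
    per-spectrum SNV scaling approximately linear in the analyte
    concentrations.
    """

    axis: np.ndarray
    profiles: dict  # analyte -> non-negative profile, unit peak height
    background: np.ndarray | None = None
    background_scale: float = 60.0

    @property
    def analytes(self) -> list[str]:
        return list(self.profiles)

    def mix(self, concentrations: dict) -> np.ndarray:
        """Linear mixture sum_a conc_a * profile_a plus the constant background."""
        out = np.zeros_like(self.axis)
        for name, conc in concentrations.items():
            out += conc * self.profiles[name]
        if self.background is not None:
            out += self.background_scale * self.background
        return out


@dataclass
class NuisanceModel:
    """Distributions of the non-chemical spectral effects.

    Baseline: per-spectrum random polynomial (broad fluorescence background);
    drift: slow batch-scale growth of that background; gain: lognormal
    multiplicative factor around 1 (laser power / alignment); noise: additive
    white noise; outliers: rare corrupted spectra (localised spike, baseline
    jump, or gain burst) emulating bubbles, particles and fluorescence bursts.
    """

    baseline_amplitude: float = 1.0
    baseline_order: int = 3
    drift_amplitude: float = 0.8
    gain_sigma: float = 0.03
    noise_sigma: float = 0.02
    outlier_rate: float = 0.02
    outlier_magnitude: float = 10.0
    outlier_types: tuple = ("spike", "baseline-jump", "gain-burst")

    def __post_init__(self):
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")


def _peak_profile(axis, centres, widths, heights) -> np.ndarray:
    prof = np.zeros_like(axis)
    for c, w, h in zip(centres, widths, heights):
        prof += h * np.exp(-0.5 * ((axis - c) / w) ** 2)
    m = prof.max()
    return prof / m if m > 0 else prof


def make_component_library(seed: int | None = 0, analytes=DEFAULT_ANALYTES,
                           n_channels: int = 3000,
                           axis_range=(100.0, 3400.0)) -> ComponentLibrary:
    """Reproducible random pure-component profiles.

    Glutamine and glutamate are generated with >= 70% shared peak centres so
    their profiles are strongly collinear (cosine similarity >= 0.7),
    mirroring their confusability in real spectra.
    """
    if len(analytes) < 1:
        raise ValueError("need at least one analyte")
    rng = np.random.default_rng(seed)
    axis = np.linspace(axis_range[0], axis_range[1], n_channels)
    span = axis_range[1] - axis_range[0]
    profiles: dict[str, np.ndarray] = {}

    def random_peaks(n):
        centres = rng.uniform(axis_range[0] + 0.02 * span,
                              axis_range[1] - 0.02 * span, n)
        widths = rng.uniform(8.0, 18.0, n)
        heights = rng.uniform(0.3, 1.0, n)
        return centres, widths, heights

    base_gln = None
    for name in analytes:
        if name == "glutamate" and "glutamine" in profiles and base_gln is not None:
            # amide vs carboxyl: nearly identical vibrational fingerprints,
            # so share most peaks with slight shifts plus a couple own bands
            centres, widths, heights = base_gln
            n_shared = max(1, int(np.ceil(0.85 * len(centres))))
            keep = rng.choice(len(centres), size=n_shared, replace=False)
            extra_c, extra_w, extra_h = random_peaks(max(1, len(centres) - n_shared))
            centres = np.concatenate([centres[keep] + rng.normal(0, 1.0, n_shared),
                                      extra_c])
            widths = np.concatenate([widths[keep] * rng.uniform(0.95, 1.05, n_shared),
                                     extra_w])
            heights = np.concatenate([heights[keep] * rng.uniform(0.9, 1.1, n_shared),
                                      0.25 * extra_h])
            profiles[name] = _peak_profile(axis, centres, widths, heights)
            continue
        n_peaks = int(rng.integers(6, 13))
        centres, widths, heights = random_peaks(n_peaks)
        if name == "glutamine":
            base_gln = (centres, widths, heights)
        profiles[name] = _peak_profile(axis, centres, widths, heights)
    # broad water/medium signature, constant over the batch
    bg_c = rng.uniform(axis_range[0], axis_range[1], 6)
    bg_w = rng.uniform(150.0, 450.0, 6)
    bg_h = rng.uniform(0.4, 1.0, 6)
    background = _peak_profile(axis, bg_c, bg_w, bg_h) + 0.2
    return ComponentLibrary(axis=axis, profiles=profiles, background=background)


def default_params() -> KineticParams:
    """The study conditions used by the generator (see docs/methods.md).

    Saturating uptake hooks keep nutrient draw physical as concentrations
    approach zero; they are the generator's choice of the model's unspecified
    modifier functions.
    """
    return KineticParams(
        f_upt=lambda gln_c: gln_c / (gln_c + 0.05),
        q_glc_factor=lambda glc_c, lac_c: glc_c / (glc_c + 0.1),
    )


def default_initial_state() -> KineticState:
    """10 L reactor seeded at 0.3e6 viable cells/mL, 8 g/L glucose, 4 g/L glutamine."""
    n0 = 0.3 * 1000.0 * 10.0  # 1e6-cell units: conc(1e6/mL) * 1000 mL/L * V(L)
    return KineticState(n_g1=0.55 * n0, n_s=0.25 * n0, n_g2m=0.12 * n0,
                        n_g0=0.08 * n0, v=10.0, a_gln=40.0, a_amn=2.0,
                        a_glc=80.0, a_lac=1.0, a_mab=0.0)


def make_batch(seed: int | None = 0, params: KineticParams | None = None,
               feeding: str = "daily-bolus", days: int = 14,
               state0: KineticState | None = None, refs_per_day: int = 2,
               meas_noise: float = 0.02, glc_setpoint: float = 8.0,
               gln_setpoint: float = 4.0, grid_h: float = 0.5,
               batch_id: str = "batch") -> tuple[Trajectory, ReferenceTable, FeedSchedule]:
    """One 14-day fed-batch with daily manual dosing and sparse references.

    ``feeding='daily-bolus'`` emulates the manual protocol: once a day the
    operator reads the current concentrations and doses glucose/glutamine
    stock back up to the setpoints, producing the sawtooth nutrient profile.
    ``feeding='continuous'`` applies constant feed rates instead.  Reference
    rows are sampled 1-2x/day with relative measurement noise ``meas_noise``;
    the underlying trajectory is deterministic given params/feeding, and the
    seed drives only measurement noise and sampling-time jitter.
    """
    params = params or default_params()
    state = state0 or default_initial_state()
    if feeding not in ("daily-bolus", "continuous"):
        raise ValueError("feeding must be 'daily-bolus' or 'continuous'")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    jitter_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    times_all: list[np.ndarray] = []
    states_all: list[np.ndarray] = []
    boluses: list[Bolus] = []
    if feeding == "continuous":
        # constant rates sized to replace roughly the mid-batch consumption
        rates = [(0.0, 2.5e-4, 2.0e-4, 0.0)]
        schedule = FeedSchedule(rate_segments=rates)
        traj = simulate(state, params, schedule, t_end=24.0 * days,
                        grid_h=grid_h, rtol=1e-7, atol=1e-9)
        times_all.append(traj.times)
        states_all.append(traj.states)
    else:
        schedule = FeedSchedule()
        vec_state = state
        for day in range(days):
            day_traj = simulate(vec_state, params, FeedSchedule(),
                                t_end=24.0, grid_h=grid_h, rtol=1e-7, atol=1e-9)
            offset = 24.0 * day
            sl = slice(1, None) if day > 0 else slice(None)
            times_all.append(day_traj.times[sl] + offset)
            states_all.append(day_traj.states[sl])
            end = day_traj.states[-1].copy()
            if day < days - 1:
                t_dose = offset + 24.0
                v = end[4]
                v_glc = max(0.0, (glc_setpoint - end[7] / v)) * v / params.glc_feed
                v_gln = max(0.0, (gln_setpoint - end[5] / v)) * v / params.gln_feed
                if v_glc > 0:
                    end[4] += v_glc
                    end[7] += v_glc * params.glc_feed
                    boluses.append(Bolus(t_dose, v_glc, "glc"))
                if v_gln > 0:
                    end[4] += v_gln
                    end[5] += v_gln * params.gln_feed
                    boluses.append(Bolus(t_dose, v_gln, "gln"))
            vec_state = KineticState.from_vector(end)
        schedule = FeedSchedule(boluses=boluses)

    traj = Trajectory(times=np.concatenate(times_all),
                      states=np.vstack(states_all), params=params)

    frame = concentration_frame(traj)
    ref_times = []
    for day in range(days):
        anchors = [10.0] if refs_per_day == 1 else list(
            np.linspace(9.0, 17.0, refs_per_day))
        for a in anchors:
            t = 24.0 * day + a + jitter_rng.uniform(-0.5, 0.5)
            ref_times.append(min(max(t, 0.0), 24.0 * days))
    ref_times = np.array(sorted(ref_times))
    values = {}
    for var in DEFAULT_ANALYTES:
        series = np.interp(ref_times, frame["time_h"].to_numpy(),
                           frame[var].to_numpy())
        scale = np.std(frame[var].to_numpy()) or 1.0
        values[var] = series + noise_rng.normal(0.0, meas_noise * scale,
                                                ref_times.size)
    refs = ReferenceTable(timestamps=ref_times * 3600.0,
                          values=pd.DataFrame(values), batch_id=batch_id)
    return traj, refs, schedule


def concentration_frame(traj: Trajectory) -> pd.DataFrame:
    """Per-grid-point concentrations of the seven soft-sensor variables.

    The kinetic model carries no glutamate state; its concentration is an
    auxiliary series tied to cumulative glutamine turnover (tracked by the
    ammonia pool), which keeps it deterministic and strongly collinear with
    the biology, as in real broth.
    """
    obs = traj.observables()
    frame = obs[["time_h", "glucose", "glutamine", "lactate", "ammonium",
                 "vcc", "tcc"]].copy()
    frame["glutamate"] = 0.15 + 0.045 * obs["ammonium"].to_numpy()
    return frame


def make_spectra(traj: Trajectory | pd.DataFrame, library: ComponentLibrary,
                 nuisance: NuisanceModel | None = None, every_s: float = 1800.0,
                 seed: int | None = 0, id_prefix: str = "s",
                 time_offset_s: float = 0.0) -> tuple[SpectraSet, list]:
    """Half-hourly linear-mixture spectra with nuisances and planted outliers.

    Returns the spectra plus the ground-truth list of outlier spectrum ids.
    Passing ``nuisance=None`` uses defaults; use
    ``NuisanceModel(outlier_rate=0, ...)`` etc. to switch effects off.
    """
    frame = concentration_frame(traj) if isinstance(traj, Trajectory) else traj
    nuisance = nuisance or NuisanceModel()
    rng = np.random.default_rng(seed)
    t_end_h = float(frame["time_h"].max())
    times_h = np.arange(0.0, t_end_h, every_s / 3600.0)
    axis = library.axis
    m = axis.size
    xi = np.linspace(-1.0, 1.0, m)

    rows = np.empty((times_h.size, m))
    outlier_ids: list[str] = []
    ids = [f"{id_prefix}{i:04d}" for i in range(times_h.size)]
    for i, t in enumerate(times_h):
        conc = {a: float(np.interp(t, frame["time_h"], frame[a]))
                for a in library.analytes if a in frame.columns}
        signal = library.mix(conc)
        coef = rng.normal(0.0, 1.0, nuisance.baseline_order + 1)
        baseline = nuisance.baseline_amplitude * np.polyval(coef, xi)
        baseline = baseline - baseline.min()  # fluorescence background is additive
        drift = nuisance.drift_amplitude * (t / max(t_end_h, 1e-9)) * (1.0 + xi)
        gain = float(np.exp(rng.normal(0.0, nuisance.gain_sigma)))
        noise = rng.normal(0.0, nuisance.noise_sigma, m)
        spec = gain * (signal + baseline + drift) + noise
        if nuisance.outlier_rate > 0 and rng.random() < nuisance.outlier_rate:
            spec = _corrupt(spec, axis, nuisance, rng)
            outlier_ids.append(ids[i])
        rows[i] = spec
    spectra = SpectraSet(axis=axis, intensities=rows,
                         timestamps=times_h * 3600.0 + time_offset_s, ids=ids,
                         provenance={"synthetic": True, "every_s": every_s})
    return spectra, outlier_ids


def _corrupt(spec: np.ndarray, axis: np.ndarray, nuisance: NuisanceModel,
             rng: np.random.Generator) -> np.ndarray:
    kind = nuisance.outlier_types[int(rng.integers(len(nuisance.outlier_types)))]
    mag = nuisance.outlier_magnitude
    scale = max(np.ptp(spec), 1e-9)
    if kind == "spike":
        centre = rng.uniform(axis[0], axis[-1])
        width = rng.uniform(5.0, 20.0)
        return spec + mag * scale * np.exp(-0.5 * ((axis - centre) / width) ** 2)
    if kind == "baseline-jump":
        cut = rng.integers(axis.size // 4, 3 * axis.size // 4)
        out = spec.copy()
        out[cut:] += mag * scale * 0.5
        return out
    # gain-burst: strong multiplicative excursion plus distortion so the
    # corruption survives SNV normalisation
    warp = 1.0 + 0.5 * np.sin(np.linspace(0, rng.uniform(2, 6) * np.pi, axis.size))
    return spec * (1.0 + mag * 0.3) * warp


@dataclass
class Benchmark:
    """The canonical multi-batch calibration fixture."""

    batches: list = field(default_factory=list)   # (SpectraSet, ReferenceTable)
    outlier_ids: list = field(default_factory=list)
    library: ComponentLibrary | None = None
    seed: int | None = None


def make_paired_benchmark(seed: int | None = 0, n_batches: int = 4,
                          days: int = 14, refs_per_day: int = 2,
                          n_channels: int = 3000,
                          nuisance: NuisanceModel | None = None,
                          meas_noise: float = 0.02) -> Benchmark:
    """Four 14-day batches of spectra + references with ~2% planted outliers.

    This emulates the scarcity of real calibration data: hundreds of spectra
    per batch but only 1-2 reference rows per day, i.e. on the order of 100
    usable training pairs in total.  Half of the planted outliers are forced
    onto spectra adjacent to reference times so they actually enter the
    calibration set.
    """
    nuisance = nuisance or NuisanceModel()
    root = np.random.SeedSequence(seed)
    lib_seed, *batch_seeds = root.spawn(n_batches + 1)
    library = make_component_library(lib_seed, n_channels=n_channels)
    bench = Benchmark(library=library, seed=seed)
    base = NuisanceModel(**{**nuisance.__dict__, "outlier_rate": 0.0})
    for b, bseed in enumerate(batch_seeds):
        s_traj, s_spec, s_force = bseed.spawn(3)
        traj, refs, _ = make_batch(s_traj, days=days, refs_per_day=refs_per_day,
                                   meas_noise=meas_noise, batch_id=f"b{b}")
        offset = b * days * 24.0 * 3600.0 * 10.0  # keep batch timelines disjoint
        spectra, _ = make_spectra(traj, library, base, seed=s_spec,
                                  id_prefix=f"b{b}s", time_offset_s=offset)
        refs = ReferenceTable(refs.timestamps + offset, refs.values,
                              batch_id=refs.batch_id)
        # plant outliers at the nuisance rate; force that same rate onto the
        # reference-adjacent spectra so some corrupted spectra always enter
        # the calibration pairs (as in real batches)
        rng = np.random.default_rng(s_force)
        n_out = max(1, int(round(nuisance.outlier_rate * spectra.n_spectra)))
        near_refs = np.unique([int(np.argmin(np.abs(spectra.timestamps - rt)))
                               for rt in refs.timestamps])
        n_force = min(max(1, int(round(nuisance.outlier_rate * near_refs.size))),
                      near_refs.size)
        picked = set(rng.choice(near_refs, size=n_force, replace=False).tolist())
        pool = np.setdiff1d(np.arange(spectra.n_spectra), np.array(sorted(picked)))
        extra = rng.choice(pool, size=max(0, n_out - len(picked)), replace=False)
        picked |= set(int(i) for i in extra)
        rows = spectra.intensities.copy()
        for i in sorted(picked):
            rows[i] = _corrupt(rows[i], library.axis, nuisance, rng)
            bench.outlier_ids.append(spectra.ids[i])
        spectra = spectra.replace_intensities(rows)
        bench.batches.append((spectra, refs))
    return bench


def benchmark_pairs(bench: Benchmark, variable: str, preprocess_fn=None,
                    max_lag_s: float = 1800.0):
    """Pool preprocessed spectrum/reference pairs across the benchmark batches.

    Returns ``(X, y, ids, is_outlier)`` where ``is_outlier`` marks pairs whose
    spectrum is a planted outlier.  ``preprocess_fn`` maps a SpectraSet to a
    SpectraSet (e.g. :func:`softsense.preprocess.preprocess_pipeline`).
    """
    from .io import pair_by_time

    xs, ys, ids = [], [], []
    for spectra, refs in bench.batches:
        if preprocess_fn is not None:
            spectra = preprocess_fn(spectra)
        ds = pair_by_time(spectra, refs, variable, max_lag_s=max_lag_s)
        xs.append(ds.X)
        ys.append(ds.y)
        ids.extend(ds.ids)
    X = np.vstack(xs)
    y = np.concatenate(ys)
    flagged = set(bench.outlier_ids)
    is_outlier = np.array([i in flagged for i in ids])
    return X, y, ids, is_outlier


def make_sparse_linear(seed: int | None = 0, n: int = 60, m: int = 50,
                       informative=(3, 7), coef: float = 4.0,
                       noise_sd: float = 0.3):
    """Regression benchmark: a few informative predictors among pure noise.

    Returns ``(X, y, informative_indices)``.  Used for the variable-selection
    recovery studies.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (n, m))
    informative = np.asarray(informative, dtype=int)
    y = X[:, informative] @ np.full(informative.size, coef) + rng.normal(0, noise_sd, n)
    return X, y, informative


def make_outlier_benchmark(seed: int | None = 0, n: int = 60, m: int = 20,
                           n_outliers: int = 2, shift_sigmas: float = 5.0,
                           noise_sd: float = 0.3):
    """Linear data with planted response outliers (reference-analysis errors).

    ``n_outliers`` rows get their y shifted by ``shift_sigmas`` response
    standard deviations.  Returns ``(X, y, outlier_indices)``.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (n, m))
    b = rng.normal(0.0, 1.0, m)
    y = X @ b + rng.normal(0.0, noise_sd, n)
    idx = rng.choice(n, size=n_outliers, replace=False)
    y = y.copy()
    y[idx] += shift_sigmas * y.std() * rng.choice([-1.0, 1.0], size=n_outliers)
    return X, y, np.sort(idx)
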