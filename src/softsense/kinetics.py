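"""Mechanistic fed-batch model of CHO cell-cycle kinetics.

The culture is described by four cell-cycle compartments (G0, G1, S, G2/M),
the reactor volume, and amount balances for glutamine, ammonia, glucose,
lactate and monoclonal antibody.  Mitosis returns two G1 cells per G2/M cell;
the G1 efflux splits between the S phase and the quiescent G0 pool according
to a metabolic-stress fraction.  Glutamine is consumed by viable cells and
degrades thermally to ammonia; glucose is consumed by cycling cells (plus a
maintenance draw by quiescent cells) and partially converted to lactate; the
per-phase specific productivities drive antibody formation at the cell-cycle
growth rate mu = ln 2 / (t_G1 + t_S + t_G2M).

States are integrated in *amount* form (concentration x volume), which is the
literal form of the balance equations and keeps feeding exact: continuous
feeds enter the right-hand side, while manual boluses and sample draws are
instantaneous events applied between integration segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import log

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParams",
    "KineticState",
    "FeedSchedule",
    "Bolus",
    "Sampling",
    "Trajectory",
    "growth_rate",
    "derivatives",
    "simulate",
    "observables",
]

#: state-vector layout (amounts; cells in 1e6-cell units, volume in L,
#: glutamine/glucose/lactate in g, ammonia in mmol, antibody in mg)
STATE_NAMES = ("n_g1", "n_s", "n_g2m", "n_g0", "v",
               "a_gln", "a_amn", "a_glc", "a_lac", "a_mab")


def growth_rate(t_g1: float, t_s: float, t_g2m: float) -> float:
    """Cell-cycle growth rate mu = ln(2) / (t_G1 + t_S + t_G2M), in 1/h."""
    if t_g1 <= 0 or t_s <= 0 or t_g2m <= 0:
        raise ValueError("phase durations must be positive")
    return log(2.0) / (t_g1 + t_s + t_g2m)


@dataclass
class KineticParams:
    """Rate/yield constants of the fed-batch CHO model.

    Units (see docs/methods.md): transition/death/degradation rates in 1/h;
    phase durations in h; specific uptakes Q/m in g per 1e6 cells per h;
    Y_lac in g lactate per g glucose; Y_amn in mmol ammonia per g glutamine;
    feed stocks in g/L; specific productivities q_* in mg per 1e6 cells per h.

    The optional hooks are multiplicative factors the printed model names but
    does not specify (temperature stress on the G1->G0 transition,
    temperature/lactate inhibition of glucose uptake, and the glutamine
    uptake-limiting function); each defaults to a constant 1.
    """

    # cell-cycle transitions (1/h) and death
    k_g1s: float = 0.054
    k_sg2m: float = 0.072
    k_g2mg1: float = 0.108
    k_g1g0: float = 0.002
    k_d: float = 0.005
    # phase durations (h) determine the cell-cycle growth rate mu
    t_g1: float = 20.0
    t_s: float = 15.0
    t_g2m: float = 10.0
    m_stress: float = 0.95
    # glutamine / ammonia
    q_gln: float = 2e-6
    k_deg: float = 0.004
    y_amn: float = 4.8
    gln_feed: float = 30.0
    # glucose / lactate
    q_glc: float = 1.8e-5
    m_glc: float = 4e-6
    y_lac: float = 0.5
    glc_feed: float = 400.0
    # product formation (per phase, scaled by mu in the balance)
    q_g1g0: float = 0.02
    q_s: float = 0.07
    q_g2m: float = 0.05
    # unspecified-modifier hooks (callables), constant 1 by default
    f_upt: object = None            # f(gln_conc) -> factor on Q_gln
    q_glc_factor: object = None     # f(glc_conc, lac_conc) -> factor on Q_glc
    k_g1g0_factor: object = None    # f(t) -> factor on k_g1g0
    mu_override: float | None = None

    def __post_init__(self):
        for name in ("k_g1s", "k_sg2m", "k_g2mg1", "k_g1g0", "k_d",
                     "t_g1", "t_s", "t_g2m", "q_gln", "k_deg", "y_amn",
                     "gln_feed", "q_glc", "m_glc", "y_lac", "glc_feed",
                     "q_g1g0", "q_s", "q_g2m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.m_stress <= 1.0:
            raise ValueError("m_stress must lie in [0, 1]")

    @property
    def mu(self) -> float:
        if self.mu_override is not None:
            return float(self.mu_override)
        return growth_rate(self.t_g1, self.t_s, self.t_g2m)

    @classmethod
    def from_durations(cls, t_g1: float = 20.0, t_s: float = 15.0,
                       t_g2m: float = 10.0, **kwargs) -> "KineticParams":
        """Convenience constructor deriving transition rates from phase durations.

        Uses k_phase = ln(2)/t_phase, the scaling consistent with the
        growth-rate definition; any rate given explicitly in ``kwargs`` wins.
        """
        derived = {"k_g1s": log(2.0) / t_g1, "k_sg2m": log(2.0) / t_s,
                   "k_g2mg1": log(2.0) / t_g2m}
        derived.update(kwargs)
        return cls(t_g1=t_g1, t_s=t_s, t_g2m=t_g2m, **derived)

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)


@dataclass
class KineticState:
    """Amount-form state: cell numbers per phase (1e6 cells), volume (L), analytes."""

    n_g1: float = 0.0
    n_s: float = 0.0
    n_g2m: float = 0.0
    n_g0: float = 0.0
    v: float = 1.0
    a_gln: float = 0.0
    a_amn: float = 0.0
    a_glc: float = 0.0
    a_lac: float = 0.0
    a_mab: float = 0.0

    def __post_init__(self):
        if self.v <= 0:
            raise ValueError("volume must be positive")
        for name in STATE_NAMES:
            if name != "v" and getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "KineticState":
        return cls(**dict(zip(STATE_NAMES, map(float, vec))))


@dataclass(frozen=True)
class Bolus:
    """Instantaneous feed addition: adds volume and stock-concentration x volume."""

    time_h: float
    volume_l: float
    feed: str  # "glc" or "gln"


@dataclass(frozen=True)
class Sampling:
    """Instantaneous sample draw: removes volume at current concentrations."""

    time_h: float
    volume_l: float


@dataclass
class FeedSchedule:
    """Piecewise-constant feed/outflow rates plus instantaneous events.

    ``rate_segments`` is a list of ``(t_start_h, f_glc, f_gln, f_out)`` in L/h,
    each valid from its start time until the next segment.
    """

    rate_segments: list = field(default_factory=lambda: [(0.0, 0.0, 0.0, 0.0)])
    boluses: list = field(default_factory=list)
    samplings: list = field(default_factory=list)

    def __post_init__(self):
        self.rate_segments = sorted(self.rate_segments, key=lambda s: s[0])
        for _, fg, fq, fo in self.rate_segments:
            if fg < 0 or fq < 0 or fo < 0:
                raise ValueError("feed rates must be >= 0")
        self.boluses = sorted(self.boluses, key=lambda b: b.time_h)
        self.samplings = sorted(self.samplings, key=lambda s: s.time_h)

    def rates_at(self, t: float) -> tuple[float, float, float]:
        f_glc = f_gln = f_out = 0.0
        for t0, fg, fq, fo in self.rate_segments:
            if t0 <= t:
                f_glc, f_gln, f_out = fg, fq, fo
            else:
                break
        return f_glc, f_gln, f_out

    def event_times(self, t_end: float) -> np.ndarray:
        times = {b.time_h for b in self.boluses if 0.0 < b.time_h < t_end}
        times |= {s.time_h for s in self.samplings if 0.0 < s.time_h < t_end}
        times |= {t0 for t0, *_ in self.rate_segments if 0.0 < t0 < t_end}
        return np.array(sorted(times))


def _hook(fn, *args) -> float:
    return 1.0 if fn is None else float(fn(*args))


def derivatives(state, params: KineticParams, feeds_at_t=(0.0, 0.0, 0.0),
                t: float = 0.0) -> np.ndarray:
    """Time derivative of the amount-form state vector.

    ``feeds_at_t`` is the tuple (F_glc, F_gln, F_out) of rates in L/h.  The
    outflow removes every species at its current concentration.
    """
    vec = state.to_vector() if isinstance(state, KineticState) else np.asarray(state, float)
    n_g1, n_s, n_g2m, n_g0, v, a_gln, a_amn, a_glc, a_lac, a_mab = vec
    if v <= 0:
        raise ValueError("volume must be positive")
    f_glc, f_gln, f_out = feeds_at_t
    out = f_out / v  # 1/h; removal at current concentration

    n_tot = n_g1 + n_s + n_g2m + n_g0
    gln_c, glc_c, lac_c = a_gln / v, a_glc / v, a_lac / v

    k_g1g0 = params.k_g1g0 * _hook(params.k_g1g0_factor, t)
    upt = params.q_gln * _hook(params.f_upt, gln_c)
    q_glc = params.q_glc * _hook(params.q_glc_factor, glc_c, lac_c)

    d = np.empty(10)
    # cell-cycle compartments: mitosis doubles G2/M into G1
    d[0] = (2.0 * params.k_g2mg1 * n_g2m - params.k_g1s * n_g1
            - k_g1g0 * n_g1 - params.k_d * n_g1 - out * n_g1)
    d[1] = (params.k_g1s * params.m_stress * n_g1 - params.k_sg2m * n_s
            - params.k_d * n_s - out * n_s)
    d[2] = (params.k_sg2m * n_s - params.k_g2mg1 * n_g2m
            - params.k_d * n_g2m - out * n_g2m)
    d[3] = (params.k_g1s * (1.0 - params.m_stress) * n_g1 + k_g1g0 * n_g1
            - params.k_d * n_g0 - out * n_g0)
    # volume
    d[4] = f_glc + f_gln - f_out
    # glutamine and ammonia (degradation feeds the ammonia pool)
    d[5] = -upt * n_tot - params.k_deg * a_gln + f_gln * params.gln_feed - out * a_gln
    d[6] = upt * params.y_amn * n_tot + params.k_deg * a_gln - out * a_amn
    # glucose and lactate; cycling cells consume Q_glc, quiescent cells m_glc
    cycling, quiescent = n_tot - n_g0, n_g0
    d[7] = (-q_glc * cycling - params.m_glc * quiescent
            + f_glc * params.glc_feed - out * a_glc)
    d[8] = (params.y_lac * q_glc * cycling - params.y_lac * params.m_glc * quiescent
            - out * a_lac)
    # product formation at the cell-cycle growth rate
    d[9] = (params.mu * (params.q_g1g0 * (n_g1 + n_g0) + params.q_s * n_s
                         + params.q_g2m * n_g2m) - out * a_mab)
    return d


def _apply_bolus(vec: np.ndarray, bolus: Bolus, params: KineticParams) -> np.ndarray:
    vec = vec.copy()
    vec[4] += bolus.volume_l
    if bolus.feed == "glc":
        vec[7] += bolus.volume_l * params.glc_feed
    elif bolus.feed == "gln":
        vec[5] += bolus.volume_l * params.gln_feed
    else:
        raise ValueError(f"unknown feed {bolus.feed!r}")
    return vec


def _apply_sampling(vec: np.ndarray, sampling: Sampling) -> np.ndarray:
    vec = vec.copy()
    v = vec[4]
    if sampling.volume_l >= v:
        raise ValueError("sample volume exceeds reactor volume")
    factor = (v - sampling.volume_l) / v
    vec[[0, 1, 2, 3, 5, 6, 7, 8, 9]] *= factor
    vec[4] = v - sampling.volume_l
    return vec


def _clamp_negatives(vec: np.ndarray, t: float) -> np.ndarray:
    scale = max(1.0, float(np.max(np.abs(vec))))
    worst = vec.min()
    if worst < -1e-9 * scale:
        raise RuntimeError(f"state went significantly negative at t={t:.3f} h "
                           f"(min {worst:.3e}); check parameters/schedule")
    if worst < 0:
        vec = np.maximum(vec, 0.0)
    return vec


@dataclass
class Trajectory:
    """Integrated fed-batch trajectory on a regular grid (amount-form states)."""

    times: np.ndarray           # h
    states: np.ndarray          # (len(times), 10), columns = STATE_NAMES
    params: KineticParams

    def state_at(self, idx: int) -> KineticState:
        return KineticState.from_vector(self.states[idx])

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def observables(self) -> pd.DataFrame:
        return observables(self)


def simulate(state0: KineticState, params: KineticParams,
             schedule: FeedSchedule | None = None, t_end: float = 336.0,
             grid_h: float = 0.5, rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate the fed-batch model with event handling.

    The horizon is split at bolus/sampling/rate-change times; each segment is
    integrated with an adaptive stiff-capable solver, then instantaneous
    events are applied as amount/volume jumps.  Output is evaluated on the
    requested regular grid (an event landing exactly on a grid point is
    reported pre-event; the jump shows at the next grid point).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    schedule = schedule or FeedSchedule()
    grid = np.round(np.arange(0.0, t_end + grid_h / 2, grid_h), 9)
    breaks = np.concatenate([[0.0], schedule.event_times(t_end), [t_end]])

    events_at: dict[float, list] = {}
    for b in schedule.boluses:
        events_at.setdefault(b.time_h, []).append(("bolus", b))
    for s in schedule.samplings:
        events_at.setdefault(s.time_h, []).append(("sampling", s))

    vec = state0.to_vector()
    out_times: list[float] = []
    out_states: list[np.ndarray] = []
    if grid[0] == 0.0:
        out_times.append(0.0)
        out_states.append(vec.copy())

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t1 > t0:
            feeds = schedule.rates_at((t0 + t1) / 2)
            t_eval = grid[(grid > t0) & (grid <= t1)]
            sol = solve_ivp(lambda t, s_: derivatives(s_, params, feeds, t),
                            (t0, t1), vec, method=method, rtol=rtol, atol=atol,
                            t_eval=t_eval if t_eval.size else None,
                            dense_output=False)
            if not sol.success:
                raise RuntimeError(f"ODE solver failed in [{t0}, {t1}] h: "
                                   f"{sol.message} (last good t={sol.t[-1] if sol.t.size else t0})")
            for ti, col in zip(sol.t, sol.y.T):
                if ti in t_eval:
                    out_times.append(float(ti))
                    out_states.append(_clamp_negatives(col, ti))
            vec = _clamp_negatives(sol.y[:, -1].copy(), t1)
            if sol.t[-1] < t1:  # t_eval may not include t1
                solb = solve_ivp(lambda t, s_: derivatives(s_, params, feeds, t),
                                 (sol.t[-1], t1), sol.y[:, -1], method=method,
                                 rtol=rtol, atol=atol)
                vec = _clamp_negatives(solb.y[:, -1].copy(), t1)
        for kind, ev in events_at.get(t1, []):
            vec = _apply_bolus(vec, ev, params) if kind == "bolus" else _apply_sampling(vec, ev)

    times = np.array(out_times)
    states = np.array(out_states)
    if times.size != grid.size:
        warnings.warn("trajectory grid incomplete; returning evaluated points only",
                      stacklevel=2)
    return Trajectory(times=times, states=states, params=params)


def observables(traj: Trajectory) -> pd.DataFrame:
    """Derived time series: concentrations, viable/total cell counts, G0 fraction.

    VCC/TCC are reported in 1e6 cells/mL; the total count is a bookkeeping
    proxy adding the cumulative death flux to the viable pool (dead cells are
    not a model state).  All quantities are recomputable bit-exactly from the
    stored states.
    """
    t = traj.times
    s = traj.states
    v = s[:, 4]
    n_tot = s[:, 0] + s[:, 1] + s[:, 2] + s[:, 3]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_g0 = np.where(n_tot > 0, s[:, 3] / np.where(n_tot > 0, n_tot, 1.0), 0.0)
    death_flux = traj.params.k_d * n_tot
    dead = np.concatenate([[0.0], np.cumsum(
        0.5 * (death_flux[1:] + death_flux[:-1]) * np.diff(t))]) if t.size > 1 else np.zeros_like(t)
    return pd.DataFrame({
        "time_h": t,
        "vcc": n_tot / v / 1000.0,
        "tcc": (n_tot + dead) / v / 1000.0,
        "f_g0": f_g0,
        "glucose": s[:, 7] / v,
        "glutamine": s[:, 5] / v,
        "lactate": s[:, 8] / v,
        "ammonium": s[:, 6] / v,
        "mab": s[:, 9] / v,
        "volume_l": v,
    })
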