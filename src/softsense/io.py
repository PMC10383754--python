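"""Spectra and reference-table containers, CSV round-trips, and time pairing.

The raw material of a Raman soft sensor is (a) a stack of spectra on a shared
Raman-shift axis, acquired every half hour or so, and (b) a sparse table of
offline reference measurements (glucose, glutamine, cell counts, ...) taken
once or twice a day with a bio analyzer.  Calibration needs the two paired by
acquisition time.

File dialect: comma-separated, decimal point, UTF-8.  Spectra CSV is
row-major with header ``id,time_s,<wavenumber>,...``; reference CSV has
header ``time_s,<variable>,...`` (units fixed per column, see README).
Timestamps may be numeric seconds since batch start or ISO-8601 strings;
they are normalised to seconds-since-start on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "PairedDataset",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "read_references",
    "write_references",
    "pair_by_time",
    "split_train_validation",
    "REFERENCE_VARIABLES",
]

#: canonical reference variables and their units
REFERENCE_VARIABLES = {
    "glucose": "g/L",
    "glutamine": "g/L",
    "glutamate": "g/L",
    "lactate": "g/L",
    "ammonium": "mmol/L",
    "vcc": "1e6 cells/mL",
    "tcc": "1e6 cells/mL",
}


class SpectraFormatError(ValueError):
    """Raised when a spectra file or container violates the format contract."""


def _normalise_times(values) -> np.ndarray:
    """Coerce numeric-seconds or ISO-8601 timestamps to float seconds since start."""
    arr = np.asarray(values)
    try:
        return arr.astype(float)
    except (TypeError, ValueError):
        ts = pd.to_datetime(arr)
        return (ts - ts.min()).total_seconds().to_numpy().astype(float)


@dataclass
class SpectraSet:
    """A stack of spectra on a common, strictly increasing Raman-shift axis.

    Parameters
    ----------
    axis : array, shape (m,)
        Raman-shift grid in cm^-1, strictly increasing.
    intensities : array, shape (n, m)
        One row per spectrum, arbitrary counts.
    timestamps : array, shape (n,)
        Acquisition time in seconds since batch start; rows are kept sorted.
    ids : list of str
        Unique spectrum labels.
    """

    axis: np.ndarray
    intensities: np.ndarray
    timestamps: np.ndarray
    ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.timestamps = _normalise_times(self.timestamps)
        self.ids = [str(i) for i in self.ids]
        if self.intensities.shape[1] != self.axis.size:
            raise SpectraFormatError(
                f"intensity rows have {self.intensities.shape[1]} channels, "
                f"axis has {self.axis.size}"
            )
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise SpectraFormatError("Raman-shift axis must be strictly increasing")
        if len(self.ids) != self.intensities.shape[0] or self.timestamps.size != len(self.ids):
            raise SpectraFormatError("ids, timestamps and intensity rows must align")
        seen: dict[str, int] = {}
        for sid in self.ids:
            if sid in seen:
                raise SpectraFormatError(f"duplicate spectrum id: {sid!r}")
            seen[sid] = 1
        order = np.argsort(self.timestamps, kind="stable")
        if not np.array_equal(order, np.arange(order.size)):
            self.intensities = self.intensities[order]
            self.timestamps = self.timestamps[order]
            self.ids = [self.ids[i] for i in order]

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def replace_intensities(self, intensities, provenance: dict | None = None) -> "SpectraSet":
        prov = dict(self.provenance)
        if provenance:
            prov.update(provenance)
        return SpectraSet(self.axis, intensities, self.timestamps.copy(),
                          list(self.ids), prov)


@dataclass
class ReferenceTable:
    """Timestamped offline reference measurements (the y-side raw material)."""

    timestamps: np.ndarray
    values: pd.DataFrame
    batch_id: str = ""

    def __post_init__(self):
        self.timestamps = _normalise_times(self.timestamps)
        self.values = pd.DataFrame(self.values).reset_index(drop=True)
        if len(self.values) != self.timestamps.size:
            raise ValueError("timestamps and value rows must align")
        if len(self.values) and self.values.isna().all(axis=1).any():
            raise ValueError("every reference row needs at least one non-missing value")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PairedDataset:
    """Spectra matrix aligned 1:1 with one reference variable."""

    X: np.ndarray
    y: np.ndarray
    pair_lags: np.ndarray
    axis: np.ndarray
    ids: list[str]
    variable: str = ""

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        self.pair_lags = np.asarray(self.pair_lags, dtype=float)
        if not (self.X.shape[0] == self.y.size == self.pair_lags.size == len(self.ids)):
            raise ValueError("X rows, y, pair_lags and ids must align 1:1")

    def __len__(self) -> int:
        return self.y.size

    def subset(self, indices) -> "PairedDataset":
        idx = np.asarray(indices, dtype=int)
        return PairedDataset(self.X[idx], self.y[idx], self.pair_lags[idx],
                             self.axis, [self.ids[i] for i in idx], self.variable)


def read_spectra(path) -> SpectraSet:
    """Read a spectra CSV (header ``id,time_s,<wavenumbers...>``)."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise SpectraFormatError("spectra file needs id, time_s and >=1 channel column")
    try:
        axis = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header: {exc}") from exc
    if df.iloc[:, 2:].isna().any().any():
        raise SpectraFormatError("ragged or missing intensity values")
    return SpectraSet(
        axis=axis,
        intensities=df.iloc[:, 2:].to_numpy(dtype=float),
        timestamps=df.iloc[:, 1].to_numpy(),
        ids=df.iloc[:, 0].astype(str).tolist(),
    )


def write_spectra(spectra: SpectraSet, path) -> None:
    df = pd.DataFrame(spectra.intensities,
                      columns=[repr(float(v)) for v in spectra.axis])
    df.insert(0, "time_s", spectra.timestamps)
    df.insert(0, "id", spectra.ids)
    df.to_csv(path, index=False)


def read_references(path, batch_id: str = "") -> ReferenceTable:
    """Read a reference CSV (header ``time_s,<variable>,...``)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("reference file needs a 'time_s' column")
    times = df["time_s"].to_numpy()
    return ReferenceTable(times, df.drop(columns=["time_s"]), batch_id=batch_id)


def write_references(refs: ReferenceTable, path) -> None:
    df = refs.values.copy()
    df.insert(0, "time_s", refs.timestamps)
    df.to_csv(path, index=False)


def pair_by_time(spectra: SpectraSet, refs: ReferenceTable, variable: str,
                 max_lag_s: float = 1800.0) -> PairedDataset:
    """Match each reference row to its nearest-in-time spectrum.

    Reference rows are the scarce resource (1-2 per day versus half-hourly
    spectra), so pairing iterates over them.  A spectrum may serve at most one
    reference row; conflicts are resolved in favour of the smaller lag, then
    the earlier spectrum.  References with no spectrum within ``max_lag_s``
    are dropped with a warning.
    """
    if spectra.n_spectra == 0 or len(refs) == 0:
        raise ValueError("pairing needs non-empty spectra and references")
    if max_lag_s <= 0:
        raise ValueError("max_lag_s must be positive")
    if variable not in refs.values.columns:
        raise KeyError(f"unknown reference variable {variable!r}; "
                       f"available: {list(refs.values.columns)}")

    yvals = refs.values[variable].to_numpy(dtype=float)
    ref_idx = np.flatnonzero(~np.isnan(yvals))
    if ref_idx.size == 0:
        raise ValueError(f"no non-missing values for variable {variable!r}")

    # lag matrix over candidate pairs; greedy global-minimum assignment
    lags = np.abs(refs.timestamps[ref_idx][:, None] - spectra.timestamps[None, :])
    lags = np.where(lags <= max_lag_s, lags, np.inf)
    assigned: dict[int, int] = {}  # ref position -> spectrum row
    free_refs = set(range(ref_idx.size))
    free_spec = np.ones(spectra.n_spectra, dtype=bool)
    work = lags.copy()
    while free_refs:
        flat = np.argmin(work)
        r, s = np.unravel_index(flat, work.shape)
        if not np.isfinite(work[r, s]):
            break
        assigned[r] = s
        free_refs.discard(int(r))
        free_spec[s] = False
        work[r, :] = np.inf
        work[:, s] = np.inf

    dropped = sorted(free_refs)
    if dropped:
        warnings.warn(f"{len(dropped)} reference row(s) had no spectrum within "
                      f"{max_lag_s} s and were dropped", stacklevel=2)
    if not assigned:
        raise ValueError("pairing produced zero pairs")

    order = sorted(assigned)  # keep reference chronological order
    rows = [assigned[r] for r in order]
    return PairedDataset(
        X=spectra.intensities[rows],
        y=yvals[ref_idx[order]],
        pair_lags=np.array([lags[r, assigned[r]] for r in order]),
        axis=spectra.axis,
        ids=[spectra.ids[s] for s in rows],
        variable=variable,
    )


def split_train_validation(ds: PairedDataset, fraction: float = 0.8,
                           seed: int | None = 0) -> tuple[PairedDataset, PairedDataset]:
    """Random, reproducible, disjoint and exhaustive train/validation split."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    n_train = int(np.floor(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return ds.subset(np.sort(perm[:n_train])), ds.subset(np.sort(perm[n_train:]))
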