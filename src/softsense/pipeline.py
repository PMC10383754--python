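"""End-to-end soft-sensor pipeline: generate/load -> preprocess -> pair ->
train (plain / VIP / CARS / CARS + outlier removal) -> validate -> report.

The report lists, per process variable and per method, the validation RMSEP
and R^2 — the summary a calibration scientist reads to pick the deployed
model.  Every artifact written to disk carries the configuration hash and the
master seed, and a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import PairedDataset, SpectraSet
from .outliers import flag_outliers, mc_error_profile, remove_and_refit
from .pls import fit_pls, predict, r2, rmse
from .preprocess import SavGolSpec, preprocess_pipeline
from .synth import (DEFAULT_ANALYTES, NuisanceModel, benchmark_pairs,
                    make_paired_benchmark)
from .varsel import cars_select, refit_with_mask, vip_scores

__all__ = ["RunConfig", "run_pipeline", "train_methods", "reconstruct_series",
           "METHODS"]

METHODS = ("pls", "vip", "cars", "cars_outliers")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (validated on construction)."""

    seed: int = 0
    out_dir: str = "softsense_run"
    variables: tuple = DEFAULT_ANALYTES
    methods: tuple = METHODS
    # synthetic-world size
    n_batches: int = 4
    days: int = 14
    refs_per_day: int = 2
    n_channels: int = 3000
    outlier_rate: float = 0.02
    meas_noise: float = 0.02
    # preprocessing
    sg_half_window: int = 7
    sg_poly_order: int = 2
    sg_target: str = "smooth"
    snv: bool = True
    max_lag_s: float = 1800.0
    # modelling
    validation_fraction: float = 0.2
    a_max: int = 10
    folds: int = 5
    cars_iterations: int = 100
    vip_threshold: float = 1.0
    outlier_repeats: int = 100

    def __post_init__(self):
        self.variables = tuple(self.variables)
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        SavGolSpec(self.sg_half_window, self.sg_poly_order, self.sg_target)

    @property
    def savgol(self) -> SavGolSpec:
        return SavGolSpec(self.sg_half_window, self.sg_poly_order, self.sg_target)

    def hash(self) -> str:
        # identifies the scientific configuration; artifact location excluded
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _child_seed(seed, *salt) -> int:
    h = hashlib.sha256(repr((seed,) + salt).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def train_methods(X, y, seed: int = 0, methods=METHODS, a_max: int = 10,
                  folds: int = 5, cars_iterations: int = 100,
                  vip_threshold: float = 1.0, outlier_repeats: int = 100,
                  validation_fraction: float = 0.2,
                  validation_exclude=None) -> dict:
    """Train and validate the method family on one paired dataset.

    Splits once into calibration/validation, then fits plain PLS, VIP-reduced,
    CARS-reduced, and CARS-reduced with Monte-Carlo outlier removal, all on
    the same split.  Returns ``{method: {rmsep, r2, model, ...}}``.

    ``validation_exclude`` (optional boolean mask) marks rows that must stay
    in the calibration set — e.g. spectra known to be corrupted.  Validation
    then measures recovery of trustworthy references, while the contaminated
    rows are left for the outlier-removal step to find, mirroring how outlier
    spectra enter a real calibration campaign.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(_child_seed(seed, "split"))
    n_val = min(max(int(round(validation_fraction * n)), 1), n - 2)
    if validation_exclude is None:
        perm = rng.permutation(n)
        val_idx, train_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])
    else:
        validation_exclude = np.asarray(validation_exclude, dtype=bool)
        eligible = rng.permutation(np.flatnonzero(~validation_exclude))
        n_val = min(n_val, eligible.size - 1)
        val_idx = np.sort(eligible[:n_val])
        train_idx = np.sort(np.setdiff1d(np.arange(n), val_idx))
    Xt, yt, Xv, yv = X[train_idx], y[train_idx], X[val_idx], y[val_idx]

    results: dict[str, dict] = {}

    def evaluate(model, extra=None):
        pred = predict(model, Xv)
        entry = {"rmsep": rmse(yv, pred), "r2": r2(yv, pred), "model": model}
        entry.update(extra or {})
        return entry

    plain = fit_pls(Xt, yt, a_max=a_max, folds=folds, scheme="random",
                    seed=_child_seed(seed, "pls"))
    if "pls" in methods:
        results["pls"] = evaluate(plain)

    if "vip" in methods:
        vip = vip_scores(plain, threshold=vip_threshold)
        mask = plain.variable_mask[vip.selected] if vip.selected.size else \
            plain.variable_mask[np.argsort(vip.scores)[::-1][:max(1, a_max)]]
        model = refit_with_mask(X[train_idx], yt, mask, a_max=a_max, folds=folds,
                                seed=_child_seed(seed, "vip"))
        results["vip"] = evaluate(model, {"n_selected": int(mask.size)})

    cars_mask = None
    if "cars" in methods or "cars_outliers" in methods:
        cars = cars_select(Xt, yt, n_iterations=cars_iterations, folds=folds,
                           seed=_child_seed(seed, "cars"), a_max=a_max)
        cars_mask = cars.winner
    if "cars" in methods:
        model = refit_with_mask(Xt, yt, cars_mask, a_max=a_max, folds=folds,
                                seed=_child_seed(seed, "cars-refit"))
        results["cars"] = evaluate(model, {"n_selected": int(cars_mask.size)})

    if "cars_outliers" in methods:
        Xm = Xt[:, cars_mask]
        report = flag_outliers(mc_error_profile(
            Xm, yt, n_repeats=outlier_repeats, a_max=a_max,
            seed=_child_seed(seed, "mc"), folds=folds))
        model, cum = remove_and_refit(Xm, yt, report, a_max=a_max,
                                      seed=_child_seed(seed, "refit"))
        model.variable_mask = cars_mask[model.variable_mask]
        model.n_original_columns = X.shape[1]
        results["cars_outliers"] = evaluate(
            model, {"n_selected": int(cars_mask.size),
                    "n_removed": int(cum.flagged.size)})
    return results


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full synthetic-benchmark pipeline and write artifacts.

    Writes ``report.csv``/``report.json`` (per-variable, per-method validation
    RMSEP and R^2) and one serialised model JSON per variable/method under
    ``out_dir``.  Returns the report frame.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}

    bench = make_paired_benchmark(
        seed=config.seed, n_batches=config.n_batches, days=config.days,
        refs_per_day=config.refs_per_day, n_channels=config.n_channels,
        nuisance=NuisanceModel(outlier_rate=config.outlier_rate),
        meas_noise=config.meas_noise)
    prep = lambda s: preprocess_pipeline(s, config.savgol, do_snv=config.snv)

    rows = []
    for variable in config.variables:
        X, y, _, is_outlier = benchmark_pairs(bench, variable, preprocess_fn=prep,
                                              max_lag_s=config.max_lag_s)
        res = train_methods(
            X, y, seed=_child_seed(config.seed, variable), methods=config.methods,
            validation_exclude=is_outlier,
            a_max=config.a_max, folds=config.folds,
            cars_iterations=config.cars_iterations,
            vip_threshold=config.vip_threshold,
            outlier_repeats=config.outlier_repeats,
            validation_fraction=config.validation_fraction)
        row = {"variable": variable}
        for method in config.methods:
            row[f"{method}_rmsep"] = res[method]["rmsep"]
            row[f"{method}_r2"] = res[method]["r2"]
            model = res[method]["model"]
            model.metadata.update(stamp)
            model.to_json(out / "models" / f"{variable}_{method}.json")
        rows.append(row)

    report = pd.DataFrame(rows).set_index("variable")
    with open(out / "report.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={stamp['config_hash']} seed={stamp['seed']}\n")
        fh.write(report.to_csv(float_format="%.6g"))
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump({**stamp, "report": report.round(10).to_dict(orient="index")},
                  fh, indent=1, sort_keys=True)
    return report


def reconstruct_series(model, spectra: SpectraSet, savgol: SavGolSpec | None = None,
                       do_snv: bool = True) -> pd.DataFrame:
    """Apply a trained soft sensor to *all* spectra of a batch.

    Calibration uses only the spectra paired with reference rows, but once the
    model exists every half-hourly spectrum yields a prediction, turning the
    sparse daily reference series into a dense reconstructed time series.
    """
    processed = preprocess_pipeline(spectra, savgol or SavGolSpec(), do_snv=do_snv)
    pred = predict(model, processed.intensities)
    return pd.DataFrame({"time_s": processed.timestamps, "prediction": pred,
                         "id": processed.ids})
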