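"""Monte-Carlo resampling outlier detection for calibration spectra.

Spectra corrupted by fluorescence, bubbles, or inhomogeneous mixing distort a
PLS calibration.  The detector repeatedly splits the paired data at random
(4:1 by default), fits the PLS pipeline on the training part, and records the
absolute prediction error of every test spectrum.  Each spectrum lands in
many different test sets, so a per-spectrum mean error and standard deviation
accumulate; spectra whose errors are consistently high relative to a robust
(median + MAD) threshold are flagged and can be removed before refitting.
Removal is capped at 20% of the rows so the model cannot be trimmed into
overfitting the "typical" spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .pls import PLSModel, cross_validate, fit_pls, nipals_fit, predict, standardize

__all__ = ["OutlierReport", "mc_error_profile", "flag_outliers", "remove_and_refit"]


@dataclass
class OutlierReport:
    """Per-spectrum Monte-Carlo prediction-error profile and flags."""

    mean_error: np.ndarray
    std_error: np.ndarray
    appearances: np.ndarray
    ids: list
    n_repeats: int
    seed: int | None
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    thresholds: dict = field(default_factory=dict)

    def flagged_ids(self) -> list:
        return [self.ids[i] for i in self.flagged]


def mc_error_profile(X, y, n_repeats: int = 200, train_fraction: float = 0.8,
                     a_max: int = 10, seed: int | None = 0,
                     ids=None, folds: int = 5) -> OutlierReport:
    """Per-spectrum mean/std absolute prediction error over random splits.

    The component count A is chosen once by cross-validation on the full data
    and reused in every repeat, so the profile reflects the influence of
    individual spectra rather than model-order jitter.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 spectra for a Monte-Carlo profile")
    if n_repeats < 20:
        raise ValueError("n_repeats must be >= 20")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if ids is None:
        ids = list(range(n))

    rng = np.random.default_rng(seed)
    a_cap = min(a_max, int(np.floor(train_fraction * n)) - 1, X.shape[1])
    curve = cross_validate(X, y, a_max=max(1, a_cap), folds=folds,
                           scheme="random", seed=int(rng.integers(2 ** 31)))
    A = curve.chosen

    n_train = min(max(int(round(train_fraction * n)), 2), n - 1)
    err_sum = np.zeros(n)
    err_sqsum = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        Xs, Ys, constants = standardize(X[train], y[train])
        model = nipals_fit(Xs, Ys, min(A, Xs.shape[0] - 1, Xs.shape[1]),
                           constants=constants, keep_scores=False)
        abs_err = np.abs(predict(model, X[test]) - y[test])
        err_sum[test] += abs_err
        err_sqsum[test] += abs_err ** 2
        counts[test] += 1

    if np.any(counts == 0):
        missing = [ids[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"spectra never appeared in a test set: {missing}; "
                         f"increase n_repeats")
    mean = err_sum / counts
    var = np.maximum(err_sqsum / counts - mean ** 2, 0.0)
    return OutlierReport(mean_error=mean, std_error=np.sqrt(var),
                         appearances=counts, ids=list(ids),
                         n_repeats=n_repeats, seed=seed)


def _robust_threshold(values: np.ndarray, c: float) -> float:
    # normal-consistent MAD (x1.4826), so c is in sigma-equivalents
    med = float(np.median(values))
    mad = 1.4826 * float(np.median(np.abs(values - med)))
    return med + c * mad


def flag_outliers(report: OutlierReport, c_mean: float = 3.5,
                  c_combined: float = 3.5) -> OutlierReport:
    """Flag spectra whose mean error (or mean + std) exceeds a median+MAD rule.

    Robust location/scale are used because the error population itself is
    contaminated by the very outliers being sought.
    """
    mean_thr = _robust_threshold(report.mean_error, c_mean)
    combined = report.mean_error + report.std_error
    comb_thr = _robust_threshold(combined, c_combined)
    flagged = np.flatnonzero((report.mean_error > mean_thr) | (combined > comb_thr))
    return replace(report, flagged=flagged,
                   thresholds={"mean": mean_thr, "combined": comb_thr,
                               "c_mean": c_mean, "c_combined": c_combined})


def remove_and_refit(X, y, report: OutlierReport, max_rounds: int = 1,
                     max_removal_fraction: float = 0.2, a_max: int = 10,
                     seed: int | None = 0, **profile_kwargs):
    """Drop flagged spectra, refit, and optionally re-profile.

    Repeats up to ``max_rounds`` times or until no new spectra are flagged.
    Never removes more than ``max_removal_fraction`` of the original rows in
    total; hitting the guard stops the loop with a warning.

    Returns ``(model, cumulative_report)`` where the report carries the flags
    (positions into the *original* row order) accumulated over all rounds.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    max_removed = int(np.floor(max_removal_fraction * n))

    removed: list[int] = []   # original-row positions
    keep = np.arange(n)
    current = report
    rounds = 0
    while rounds < max_rounds:
        if current.flagged.size == 0:
            current = flag_outliers(current,
                                    c_mean=report.thresholds.get("c_mean", 3.5),
                                    c_combined=report.thresholds.get("c_combined", 3.5))
        new_flags = current.flagged
        if new_flags.size == 0:
            break
        if len(removed) + new_flags.size > max_removed:
            budget = max_removed - len(removed)
            if budget <= 0:
                warnings.warn("outlier-removal guard reached "
                              f"({max_removal_fraction:.0%} of rows); stopping",
                              stacklevel=2)
                break
            order = np.argsort(current.mean_error[new_flags])[::-1]
            new_flags = new_flags[order[:budget]]
            warnings.warn("outlier-removal guard truncated this round's flags",
                          stacklevel=2)
        removed.extend(int(keep[i]) for i in new_flags)
        keep = np.setdiff1d(keep, np.array(removed, dtype=int))
        rounds += 1
        if rounds >= max_rounds or len(removed) >= max_removed:
            break
        current = flag_outliers(
            mc_error_profile(X[keep], y[keep], a_max=a_max, seed=seed,
                             ids=[report.ids[i] for i in keep], **profile_kwargs),
            c_mean=report.thresholds.get("c_mean", 3.5),
            c_combined=report.thresholds.get("c_combined", 3.5))

    model = fit_pls(X[keep], y[keep], a_max=a_max, seed=seed)
    cumulative = replace(report, flagged=np.array(sorted(removed), dtype=int))
    cumulative.thresholds = dict(report.thresholds)
    cumulative.thresholds["rows_removed"] = len(removed)
    return model, cumulative
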