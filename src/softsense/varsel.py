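"""Variable selection for PLS soft sensors: VIP scores and CARS.

Raman spectra carry thousands of wavenumber channels, of which only a small
subset is informative for a given analyte.  Two selectors are provided:

* VIP (variable importance in projection): per-channel influence score
  aggregating the squared PLS weights across components, weighted by the
  response variance each component explains.  Squared scores average to one,
  so ``score >= 1`` is the customary keep-rule.

* CARS (competitive adaptive reweighted sampling): a Monte-Carlo loop that
  repeatedly fits PLS on a row subsample, scores channels by the magnitude of
  their standardised regression coefficient, enforces an exponentially
  decreasing retained-channel count, resamples channels with probability
  proportional to their weight, and keeps the subset with the lowest RMSECV.
  It typically returns far fewer channels than VIP and handles collinearity
  better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import (PLSModel, RankExhaustedError, _coefficients, _nipals,
                  cross_validate, fit_pls, standardize)

__all__ = ["VIPResult", "CARSResult", "vip_scores", "cars_schedule",
           "cars_select", "refit_with_mask"]


@dataclass
class VIPResult:
    """VIP scores per predictor with the threshold-based selection mask."""

    scores: np.ndarray
    threshold: float
    selected: np.ndarray  # indices of predictors with score >= threshold


@dataclass
class CARSResult:
    """Per-iteration record of a CARS run and the winning channel subset."""

    masks: list = field(default_factory=list)      # per-iteration index arrays
    rmsecv: np.ndarray = None
    winner: np.ndarray = None
    n_iterations: int = 0
    seed: int | None = None

    @property
    def winning_rmsecv(self) -> float:
        return float(np.min(self.rmsecv))


def vip_scores(model: PLSModel, threshold: float = 1.0) -> VIPResult:
    """Wold VIP scores from a fitted model with retained scores.

    ``VIP_j = sqrt( m * sum_a SSY_a w_ja^2 / sum_a SSY_a )`` with
    ``SSY_a = q_a^2 t_a't_a`` the response sum of squares explained by
    component a and w the unit-norm weight vectors.  By construction
    ``mean(VIP^2) = 1`` over the predictors.
    """
    if model.A < 1:
        raise ValueError("model has no components")
    if model.T is None:
        raise ValueError("model must retain training scores T for VIP")
    m = model.W.shape[0]
    ssy = (model.Q ** 2).sum(axis=0) * np.einsum("ia,ia->a", model.T, model.T)
    total = ssy.sum()
    if total == 0:
        raise ValueError("model explains no response variance")
    scores = np.sqrt(m * (model.W ** 2) @ ssy / total)
    return VIPResult(scores=scores, threshold=threshold,
                     selected=np.flatnonzero(scores >= threshold))


def _cv_rmsecv_min(X, y, a_max, folds, scheme="random", seed=0):
    """Minimum RMSECV over component counts, tolerant of tiny subsets."""
    a_cap = min(a_max, X.shape[0] - 1 - int(np.ceil(X.shape[0] / folds)), X.shape[1])
    a_cap = max(a_cap, 1)
    try:
        curve = cross_validate(X, y, a_max=a_cap, folds=folds, scheme=scheme, seed=seed)
    except RankExhaustedError:
        return np.inf
    return float(curve.rmsecv.min())


def cars_schedule(m: int, n_iterations: int) -> np.ndarray:
    """Exponentially decreasing retained-variable counts r(i).

    Calibrated so r(1) = m and r(n_iterations) = 2; the returned sequence is
    integer, non-increasing.
    """
    if n_iterations < 2 or m < 2:
        raise ValueError("need n_iterations >= 2 and m >= 2")
    lam = np.log(m / 2.0) / (n_iterations - 1)
    schedule = np.maximum(2, np.round(m * np.exp(-lam * np.arange(n_iterations)))).astype(int)
    return np.minimum.accumulate(schedule)


def cars_select(X, y, n_iterations: int = 100, mc_fraction: float = 0.8,
                folds: int = 5, seed: int | None = 0, a_max: int = 10) -> CARSResult:
    """Competitive adaptive reweighted sampling over predictor columns.

    Each iteration is one Monte-Carlo run: fit PLS on a random
    ``mc_fraction`` row subsample using the currently retained channels,
    weight channels by |b| (standardised coefficients), shrink the retained
    count along the exponentially decreasing schedule r(i) calibrated so
    r(1) = m and r(n_iterations) = 2, resample channels proportionally to
    weight, and score the candidate subset by cross-validated RMSECV.  The
    winner is the subset with minimal RMSECV.  Fully reproducible per seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n_iterations < 2:
        raise ValueError("n_iterations must be >= 2")
    if m < 2:
        raise ValueError("CARS needs at least 2 predictors")
    rng = np.random.default_rng(seed)
    schedule = cars_schedule(m, n_iterations)

    current = np.arange(m)
    masks: list[np.ndarray] = []
    scores: list[float] = []
    n_sub = max(2, int(round(mc_fraction * n)))
    for i in range(n_iterations):
        if current.size < 2:
            warnings.warn("CARS subset collapsed below 2 variables; stopping early",
                          stacklevel=2)
            break
        rows = np.sort(rng.choice(n, size=n_sub, replace=False))
        try:
            Xs, Ys, _ = standardize(X[np.ix_(rows, current)], y[rows])
            req = max(1, min(a_max, Xs.shape[0] - 1, Xs.shape[1]))
            W, P, Q, _, achieved = _nipals(Xs, Ys, req)
            b = np.abs(_coefficients(W, P, Q)[:, 0]) if achieved else np.ones(current.size)
        except ValueError:
            b = np.ones(current.size)
        if b.sum() == 0:
            b = np.ones(current.size)

        r_i = min(schedule[i], current.size)
        # enforced decreasing count: keep the top-|b| channels
        keep = current[np.argsort(b)[::-1][:r_i]]
        keep_w = b[np.argsort(b)[::-1][:r_i]]
        # adaptive reweighted sampling: channels compete in proportion to weight
        if keep_w.sum() == 0:
            keep_w = np.ones(keep.size)
        drawn = rng.choice(keep, size=r_i, replace=True, p=keep_w / keep_w.sum())
        subset = np.unique(drawn)
        if subset.size < 1:
            subset = keep[:1]
        masks.append(subset)
        scores.append(_cv_rmsecv_min(X[:, subset], y, a_max, folds,
                                     scheme="random", seed=int(rng.integers(2 ** 31))))
        current = subset

    if not masks:
        raise ValueError("CARS produced no candidate subsets")
    scores_arr = np.asarray(scores)
    best = int(np.argmin(scores_arr))
    return CARSResult(masks=masks, rmsecv=scores_arr, winner=masks[best],
                      n_iterations=len(masks), seed=seed)


def refit_with_mask(X, y, mask, a_max: int = 10, folds: int = 5,
                    scheme: str = "random", seed: int | None = 0) -> PLSModel:
    """Full pipeline (standardise -> CV-select A -> fit) on the masked channels.

    The returned model's ``variable_mask`` indexes the *original* columns, so
    :func:`softsense.pls.predict` accepts full-width spectra directly.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ValueError("mask must be non-empty")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if mask.max() >= X.shape[1]:
        raise IndexError("mask references columns beyond the data")
    model = fit_pls(X[:, mask], y, a_max=a_max, folds=folds, scheme=scheme, seed=seed)
    model.variable_mask = mask[model.variable_mask]
    model.n_original_columns = X.shape[1]
    model.metadata["selection_mask"] = mask.tolist()
    return model
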