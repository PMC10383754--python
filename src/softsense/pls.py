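"""NIPALS partial least squares: fitting, prediction, cross-validation.

PLS extracts latent variables that maximise predictor-response covariance.
The NIPALS algorithm builds them one at a time: for each component, iterate

    w = X'u / u'u,   w <- w/||w||,   t = Xw,   u = Y't / t't

until the score vector t stabilises, then deflate

    p = X't / t't,   q = Y't / t't,   X <- X - tp',   Y <- Y - tq'.

After A components the regression coefficients on the standardised scale are
B = W (P'W)^-1 Q'.  For a single response the inner loop converges in one
pass, which makes PLS1 fast enough to sit inside Monte-Carlo loops.

Model-order selection uses RMSECV from K-fold cross-validation with
standardisation re-done inside each fold (no leakage), and a parsimony rule:
the smallest component count whose RMSECV is within a relative tolerance of
the curve minimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CVCurve",
    "RankExhaustedError",
    "standardize",
    "nipals_fit",
    "fit_pls",
    "predict",
    "rmse",
    "r2",
    "cross_validate",
    "select_components",
]


class RankExhaustedError(RuntimeError):
    """Requested more latent variables than the data support.

    Carries ``achieved``, the number of components extracted before the score
    vector vanished.
    """

    def __init__(self, requested: int, achieved: int):
        super().__init__(f"rank exhausted after {achieved} of {requested} components")
        self.requested = requested
        self.achieved = achieved


@dataclass
class PLSModel:
    """A fitted PLS model plus the standardisation constants needed to use it.

    ``W``, ``P``, ``Q`` are the weight and loading matrices (columns = latent
    variables); ``B`` is the regression coefficient matrix on the
    *standardised* scale, reproducible as ``W (P'W)^-1 Q'``.
    ``variable_mask`` holds the original predictor column indices the model
    was trained on (zero-variance columns are dropped at standardisation).
    """

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    W: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    A: int
    variable_mask: np.ndarray
    n_original_columns: int
    T: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "x_mean": self.x_mean.tolist(), "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean.tolist(), "y_scale": self.y_scale.tolist(),
            "W": self.W.tolist(), "P": self.P.tolist(), "Q": self.Q.tolist(),
            "B": self.B.tolist(), "A": int(self.A),
            "variable_mask": self.variable_mask.tolist(),
            "n_original_columns": int(self.n_original_columns),
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
        return cls(
            x_mean=np.array(payload["x_mean"]), x_scale=np.array(payload["x_scale"]),
            y_mean=np.array(payload["y_mean"]), y_scale=np.array(payload["y_scale"]),
            W=np.array(payload["W"]), P=np.array(payload["P"]), Q=np.array(payload["Q"]),
            B=np.array(payload["B"]), A=int(payload["A"]),
            variable_mask=np.array(payload["variable_mask"], dtype=int),
            n_original_columns=int(payload["n_original_columns"]),
            metadata=payload.get("metadata", {}),
        )


@dataclass
class CVCurve:
    """RMSECV per candidate component count 1..a_max, plus the chosen count."""

    rmsecv: np.ndarray
    scheme: str
    chosen: int

    @property
    def a_max(self) -> int:
        return self.rmsecv.size


def standardize(X, Y):
    """Column-wise standardisation (sample std, divisor n-1) of X and Y.

    Zero-variance predictor columns are dropped and recorded in the returned
    mask; a zero-variance response is an error.

    Returns ``(Xs, Ys, constants)`` where constants holds the centring/scaling
    vectors and the retained-column mask.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("standardisation needs at least 2 rows")
    x_std = X.std(axis=0, ddof=1)
    mask = np.flatnonzero(x_std > 0)
    if mask.size == 0:
        raise ValueError("all predictor columns have zero variance")
    y_std = Y.std(axis=0, ddof=1)
    if np.any(y_std == 0):
        raise ValueError("zero-variance response column")
    x_mean = X[:, mask].mean(axis=0)
    x_scale = x_std[mask]
    y_mean = Y.mean(axis=0)
    constants = {
        "x_mean": x_mean, "x_scale": x_scale,
        "y_mean": y_mean, "y_scale": y_std,
        "mask": mask, "n_original_columns": X.shape[1],
    }
    return (X[:, mask] - x_mean) / x_scale, (Y - y_mean) / y_std, constants


def _nipals(Xs, Ys, a_max, tol=1e-10, max_iter=500):
    """Core NIPALS loop on standardised matrices.

    Returns (W, P, Q, T, achieved).  Stops early if a score vector vanishes
    (rank exhausted).
    """
    X = np.array(Xs, dtype=float)
    Y = np.array(Ys, dtype=float)
    n, m = X.shape
    p = Y.shape[1]
    W = np.zeros((m, a_max))
    P = np.zeros((m, a_max))
    Q = np.zeros((p, a_max))
    T = np.zeros((n, a_max))
    x_norm0 = np.linalg.norm(X) or 1.0
    achieved = 0
    tt_first = None
    for a in range(a_max):
        u = Y[:, 0].copy()  # initial u: first response column
        if np.linalg.norm(u) == 0 or np.linalg.norm(X) < 1e-12 * x_norm0:
            break
        t_old = None
        w = t = None
        for _ in range(max_iter):
            w = X.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                t = None
                break
            w /= nw
            t = X @ w
            tt = t @ t
            if tt == 0:
                t = None
                break
            if t_old is not None and np.linalg.norm(t - t_old) / np.linalg.norm(t_old) < tol:
                break
            t_old = t
            # u-update: Y-loading direction q = Y't/t't, then u = Yq/q'q;
            # for a single response this is u = y, so one pass converges
            q_dir = Y.T @ t / tt
            qq = q_dir @ q_dir
            if qq == 0:
                t = None
                break
            u = Y @ q_dir / qq
        else:
            warnings.warn(f"NIPALS did not converge within {max_iter} iterations "
                          f"for component {a + 1}; accepting current vectors",
                          stacklevel=2)
        if t is None:
            break
        tt = t @ t
        # rank guard: relative to the first component, further score vectors
        # of negligible variance are numerical residue, not structure
        if tt < 1e-12 * n or (tt_first is not None and tt < 1e-9 * tt_first):
            break
        if tt_first is None:
            tt_first = tt
        p_vec = X.T @ t / tt
        q_vec = Y.T @ t / tt
        X = X - np.outer(t, p_vec)
        Y = Y - np.outer(t, q_vec)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q_vec, t
        achieved = a + 1
    return W[:, :achieved], P[:, :achieved], Q[:, :achieved], T[:, :achieved], achieved


def _coefficients(W, P, Q, a=None):
    """B = W (P'W)^-1 Q' from the first ``a`` components (standardised scale)."""
    if a is None:
        a = W.shape[1]
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def nipals_fit(Xs, Ys, A, tol=1e-10, max_iter=500, constants=None,
               keep_scores: bool = True) -> PLSModel:
    """Fit A latent variables by NIPALS on standardised matrices.

    ``constants`` (from :func:`standardize`) attaches the centring/scaling
    info to the model; without it the model assumes identity scaling.
    Raises :class:`RankExhaustedError` if fewer than A components exist.
    """
    if A < 1:
        raise ValueError("A must be >= 1")
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    Ys = np.asarray(Ys, dtype=float)
    if Ys.ndim == 1:
        Ys = Ys[:, None]
    W, P, Q, T, achieved = _nipals(Xs, Ys, A, tol=tol, max_iter=max_iter)
    if achieved < A:
        raise RankExhaustedError(A, achieved)
    B = _coefficients(W, P, Q)
    m = Xs.shape[1]
    if constants is None:
        constants = {"x_mean": np.zeros(m), "x_scale": np.ones(m),
                     "y_mean": np.zeros(Ys.shape[1]), "y_scale": np.ones(Ys.shape[1]),
                     "mask": np.arange(m), "n_original_columns": m}
    return PLSModel(
        x_mean=np.asarray(constants["x_mean"], dtype=float),
        x_scale=np.asarray(constants["x_scale"], dtype=float),
        y_mean=np.asarray(constants["y_mean"], dtype=float),
        y_scale=np.asarray(constants["y_scale"], dtype=float),
        W=W, P=P, Q=Q, B=B, A=achieved,
        variable_mask=np.asarray(constants["mask"], dtype=int),
        n_original_columns=int(constants["n_original_columns"]),
        T=T if keep_scores else None,
    )


def fit_pls(X, y, A: int | None = None, a_max: int = 10, folds: int = 5,
            scheme: str = "blocks", seed: int | None = 0, rel_tol: float = 0.05,
            tol: float = 1e-10, max_iter: int = 500) -> PLSModel:
    """Standardise, pick the component count by cross-validation, and fit.

    If ``A`` is given the cross-validation step is skipped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    Xs, Ys, constants = standardize(X, y)
    cap = min(Xs.shape[0] - 1, Xs.shape[1])
    if A is None:
        curve = cross_validate(X, y, a_max=min(a_max, cap), folds=folds,
                               scheme=scheme, seed=seed, rel_tol=rel_tol)
        A = curve.chosen
        meta = {"cv_rmsecv": curve.rmsecv.tolist(), "cv_scheme": curve.scheme}
    else:
        meta = {}
    model = nipals_fit(Xs, Ys, min(A, cap), tol=tol, max_iter=max_iter,
                       constants=constants)
    model.metadata.update(meta)
    return model


def predict(model: PLSModel, Xnew) -> np.ndarray:
    """Predict responses for new spectra (un-standardised scale).

    Accepts matrices with either the full original column count (the stored
    variable mask is applied) or exactly the masked column count.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] == model.n_original_columns:
        Xnew = Xnew[:, model.variable_mask]
    elif Xnew.shape[1] != model.variable_mask.size:
        raise ValueError(
            f"expected {model.n_original_columns} or {model.variable_mask.size} "
            f"columns, got {Xnew.shape[1]}")
    Xs = (Xnew - model.x_mean) / model.x_scale
    Ys = Xs @ model.B
    Y = Ys * model.y_scale + model.y_mean
    return Y[:, 0] if Y.shape[1] == 1 else Y


def rmse(y, y_hat) -> float:
    """Root mean square error sqrt(mean((y - y_hat)^2))."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r2(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 values")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance y: R2 undefined")
    return float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)


def _fold_indices(n: int, folds: int, scheme: str, seed) -> list[np.ndarray]:
    idx = np.arange(n)
    if scheme == "random":
        idx = np.random.default_rng(seed).permutation(n)
    elif scheme != "blocks":
        raise ValueError("scheme must be 'blocks' or 'random'")
    return [np.sort(part) for part in np.array_split(idx, folds)]


def cross_validate(X, y, a_max: int = 10, folds: int = 5, scheme: str = "blocks",
                   seed: int | None = 0, rel_tol: float = 0.05) -> CVCurve:
    """RMSECV per component count 1..a_max with in-fold standardisation.

    Spectra are a time series, so the default fold scheme is contiguous
    blocks, which reduces train/test leakage between neighbouring spectra;
    ``scheme='random'`` gives the classic shuffled K-fold.  If some training
    fold exhausts its rank below ``a_max``, the curve is truncated with a
    warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least as many rows as folds")
    parts = _fold_indices(n, folds, scheme, seed)
    a_cap = a_max
    sq_err = np.zeros((a_max, n))
    for test_idx in parts:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        Xs, Ys, constants = standardize(X[train_idx], y[train_idx])
        req = min(a_max, Xs.shape[0] - 1, Xs.shape[1])
        W, P, Q, _, achieved = _nipals(Xs, Ys, req)
        if achieved < a_cap:
            a_cap = achieved
        Xt = (X[test_idx][:, constants["mask"]] - constants["x_mean"]) / constants["x_scale"]
        for a in range(1, achieved + 1):
            B = _coefficients(W, P, Q, a)
            pred = (Xt @ B) * constants["y_scale"] + constants["y_mean"]
            sq_err[a - 1, test_idx] = (pred[:, 0] - y[test_idx]) ** 2
    if a_cap < 1:
        raise RankExhaustedError(a_max, 0)
    if a_cap < a_max:
        warnings.warn(f"RMSECV curve truncated to {a_cap} components "
                      f"(rank limit in a training fold)", stacklevel=2)
    curve = np.sqrt(sq_err[:a_cap].mean(axis=1))
    chosen = select_components(curve, rel_tol=rel_tol)
    return CVCurve(rmsecv=curve, scheme=f"{scheme}-{folds}fold", chosen=chosen)


def select_components(curve, rel_tol: float = 0.05) -> int:
    """Parsimonious elbow rule: smallest count within ``rel_tol`` of the minimum."""
    values = curve.rmsecv if isinstance(curve, CVCurve) else np.asarray(curve, dtype=float)
    if values.size == 0:
        raise ValueError("empty RMSECV curve")
    threshold = (1.0 + rel_tol) * values.min()
    return int(np.flatnonzero(values <= threshold)[0]) + 1
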