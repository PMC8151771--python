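"""PLS1 regression by NIPALS, with venetian-blind cross-validated choice of
the number of latent variables and the standard chemometric figures of merit
(R2, RMSEC/RMSECV/RMSEP, SEP, bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ConfigurationError, DataValidationError
from .partition import CVSegments


def r2_corr(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared Pearson correlation between measured and predicted values.

    This is the conventional chemometric 'determination coefficient'; the
    alternative 1 - SSE/SST is available as :func:`r2_sse`.
    """
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    sy, syh = y.std(), yhat.std()
    if sy == 0 or syh == 0:
        return np.nan
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def r2_sse(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return np.nan
    return float(1.0 - np.sum((y - yhat) ** 2) / sst)


@dataclass
class FitMetrics:
    """Figures of merit of one calibrated model (NaN where not computed)."""

    response: str = ""
    lvs: int = 0
    n_cal: int = 0
    n_pred: int = 0
    r2_cal: float = np.nan
    rmsec: float = np.nan
    r2_cv: float = np.nan
    rmsecv: float = np.nan
    r2_pred: float = np.nan
    rmsep: float = np.nan
    sep: float = np.nan
    bias: float = np.nan


@dataclass
class PLSModel:
    """Fitted PLS1 state for 1..max_lvs latent variables.

    ``B`` stacks the regression vectors column-wise (one column per LV
    count) on the centered/scaled X scale, so predictions for any LV count
    are a single matrix product.
    """

    response: str
    recipe_label: str
    x_mean: np.ndarray
    x_scale: np.ndarray | None
    y_mean: float
    W: np.ndarray  # (p, A) unit-norm weight vectors
    P: np.ndarray  # (p, A) X loadings
    T: np.ndarray  # (n, A) scores
    q: np.ndarray  # (A,) y loadings
    B: np.ndarray  # (p, A) regression vectors per LV count
    chosen_lvs: int = 0
    rmsecv_curve: np.ndarray | None = None
    r2cv_curve: np.ndarray | None = None

    @property
    def max_lvs(self) -> int:
        return self.W.shape[1]

    def regression_vector(self, n_lvs: int | None = None) -> np.ndarray:
        """Regression vector on the original X scale."""
        a = self._lv(n_lvs)
        b = self.B[:, a - 1]
        return b if self.x_scale is None else b / self.x_scale

    def _lv(self, n_lvs: int | None) -> int:
        a = n_lvs if n_lvs is not None else (self.chosen_lvs or self.max_lvs)
        if not 1 <= a <= self.max_lvs:
            raise ConfigurationError(f"n_lvs must be in [1, {self.max_lvs}], got {a}")
        return a

    def predict(self, X: np.ndarray, n_lvs: int | None = None) -> np.ndarray:
        a = self._lv(n_lvs)
        Xc = np.asarray(X, float) - self.x_mean
        if self.x_scale is not None:
            Xc = Xc / self.x_scale
        return Xc @ self.B[:, a - 1] + self.y_mean

    # --- serialization (JSON-safe: floats round-trip exactly) ----------
    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "recipe_label": self.recipe_label,
            "x_mean": self.x_mean.tolist(),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "y_mean": float(self.y_mean),
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "T": self.T.tolist(),
            "q": self.q.tolist(),
            "B": self.B.tolist(),
            "chosen_lvs": int(self.chosen_lvs),
            "rmsecv_curve": None
            if self.rmsecv_curve is None
            else self.rmsecv_curve.tolist(),
            "r2cv_curve": None if self.r2cv_curve is None else self.r2cv_curve.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            response=d["response"],
            recipe_label=d["recipe_label"],
            x_mean=arr(d["x_mean"]),
            x_scale=arr(d["x_scale"]),
            y_mean=float(d["y_mean"]),
            W=arr(d["W"]),
            P=arr(d["P"]),
            T=arr(d["T"]),
            q=arr(d["q"]),
            B=arr(d["B"]),
            chosen_lvs=int(d["chosen_lvs"]),
            rmsecv_curve=arr(d["rmsecv_curve"]),
            r2cv_curve=arr(d["r2cv_curve"]),
        )


def fit_nipals(
    X: np.ndarray,
    y: np.ndarray,
    max_lvs: int,
    response: str = "",
    recipe_label: str = "",
    scale: bool = False,
) -> PLSModel:
    """PLS1 by the classic NIPALS sequence with X and y deflation.

    Per component: w = X'y/||X'y||, t = Xw, p = X't/(t't), q = y't/(t't),
    then X <- X - t p' and y <- y - q t.  X is mean-centered internally
    (and unit-variance scaled when ``scale``); regression vectors are
    assembled for every LV count from 1 to ``max_lvs``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DataValidationError("X and y row counts differ")
    if y.std() == 0:
        raise DataValidationError("response has zero variance")
    max_lvs = int(max_lvs)
    if not 1 <= max_lvs <= min(n - 1, p):
        raise ConfigurationError(
            f"max_lvs must be in [1, {min(n - 1, p)}], got {max_lvs}"
        )

    x_mean = X.mean(axis=0)
    x_scale = None
    Xc = X - x_mean
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        if np.any(x_scale == 0):
            raise DataValidationError("constant X columns cannot be scaled")
        Xc = Xc / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((p, max_lvs))
    P = np.zeros((p, max_lvs))
    T = np.zeros((n, max_lvs))
    q = np.zeros(max_lvs)
    a_eff = 0
    norm0 = None
    for a in range(max_lvs):
        xty = Xc.T @ yc
        norm = np.linalg.norm(xty)
        if norm0 is None:
            norm0 = norm
        # stop once the deflated covariance is numerically exhausted
        if norm <= max(1e-14 * max(1.0, np.abs(y).max()), 1e-12 * norm0):
            warnings.warn(
                f"NIPALS stopped early at {a} latent variables (X'y vanished)",
                stacklevel=2,
            )
            break
        w = xty / norm
        t = Xc @ w
        tt = float(t @ t)
        W[:, a], T[:, a] = w, t
        P[:, a] = Xc.T @ t / tt
        q[a] = float(yc @ t) / tt
        Xc = Xc - np.outer(t, P[:, a])
        yc = yc - q[a] * t
        a_eff = a + 1
    if a_eff == 0:
        raise DataValidationError("no latent variable could be extracted")
    W, P, T, q = W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff]

    # b_a = W_a (P_a' W_a)^-1 q_a for each LV count a
    B = np.zeros((p, a_eff))
    PtW = P.T @ W
    for a in range(1, a_eff + 1):
        coef = np.linalg.solve(PtW[:a, :a], q[:a])
        B[:, a - 1] = W[:, :a] @ coef

    return PLSModel(
        response=response,
        recipe_label=recipe_label,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        W=W,
        P=P,
        T=T,
        q=q,
        B=B,
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    segments: CVSegments,
    unit_ids: np.ndarray,
    max_lvs: int,
    scale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Segmented cross-validation of the LV count.

    For every fold the model (including centering/scaling) is refit on the
    remaining segments and the held-out units are predicted for every LV
    count; errors are pooled across folds.  Returns (rmsecv, r2_cv) arrays
    indexed by LV count - 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    unit_ids = np.asarray(unit_ids)
    masks = segments.fold_masks(unit_ids)
    if any(m.sum() < 1 for m in masks):
        raise DataValidationError("every cross-validation segment needs >= 1 unit")
    preds = np.full((y.size, max_lvs), np.nan)
    for mask in masks:
        model = fit_nipals(X[~mask], y[~mask], max_lvs, scale=scale)
        for a in range(1, model.max_lvs + 1):
            preds[mask, a - 1] = model.predict(X[mask], n_lvs=a)
        # folds too small for the full LV range reuse their largest model
        for a in range(model.max_lvs + 1, max_lvs + 1):
            preds[mask, a - 1] = preds[mask, model.max_lvs - 1]
    errors = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(errors**2, axis=0))
    r2_cv = np.array([r2_corr(y, preds[:, a]) for a in range(max_lvs)])
    return rmsecv, r2_cv


def select_lvs(rmsecv_curve: np.ndarray) -> int:
    """LV count minimizing RMSECV; ties break toward fewer LVs."""
    curve = np.asarray(rmsecv_curve, dtype=float)
    if curve.size == 0:
        raise ConfigurationError("empty RMSECV curve")
    best = int(np.argmin(curve)) + 1
    if best == curve.size and curve.size > 1:
        warnings.warn(
            "RMSECV is minimized at the largest LV count tried; the model "
            "space may be under-explored",
            stacklevel=2,
        )
    return best


def fit_with_cv(
    X: np.ndarray,
    y: np.ndarray,
    segments: CVSegments,
    unit_ids: np.ndarray,
    max_lvs: int,
    response: str = "",
    recipe_label: str = "",
    scale: bool = False,
) -> PLSModel:
    """Cross-validate the LV count, then refit on all calibration units."""
    cap = min(max_lvs, min(int((~m).sum()) for m in segments.fold_masks(unit_ids)) - 1)
    cap = min(cap, X.shape[1])
    rmsecv, r2cv = cross_validate(X, y, segments, unit_ids, cap, scale=scale)
    model = fit_nipals(
        X, y, cap, response=response, recipe_label=recipe_label, scale=scale
    )
    model.chosen_lvs = min(select_lvs(rmsecv), model.max_lvs)
    model.rmsecv_curve = rmsecv
    model.r2cv_curve = r2cv
    return model


def prediction_metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    """(rmsep, bias, sep) of a prediction-error vector; SEP uses n-1."""
    y, yhat = np.asarray(y, float).ravel(), np.asarray(yhat, float).ravel()
    if y.size < 3:
        raise DataValidationError("need >= 3 samples to estimate SEP")
    e = yhat - y
    rmsep = float(np.sqrt(np.mean(e**2)))
    bias = float(e.mean())
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (e.size - 1)))
    return rmsep, bias, sep


def evaluate(
    model: PLSModel,
    X_new: np.ndarray,
    y_new: np.ndarray,
    n_lvs: int | None = None,
) -> FitMetrics:
    """External validation on an independent prediction set.

    Metrics are computed on the model's working scale (i.e. the transformed
    response where one is used), matching how calibration tables report
    1/TPC and log10 DPPH.
    """
    yhat = model.predict(X_new, n_lvs=n_lvs)
    y_new = np.asarray(y_new, dtype=float).ravel()
    rmsep, bias, sep = prediction_metrics(y_new, yhat)
    return FitMetrics(
        response=model.response,
        lvs=model._lv(n_lvs),
        n_pred=y_new.size,
        r2_pred=r2_corr(y_new, yhat),
        rmsep=rmsep,
        sep=sep,
        bias=bias,
    )
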