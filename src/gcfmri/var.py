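"""Least-squares vector autoregressive (VAR) modelling with BIC order selection.

The zero-mean VAR(p) model of a d-variate series ``x(t)`` is

    x(t) = sum_{k=1..p} A_k x(t-k) + eps(t),

fitted by ordinary least squares over rows ``p+1..n`` with no intercept
(series are expected to be detrended).  Multiple runs contribute their
own rows and are never lagged across a run boundary.  Model order is
chosen by the Bayesian information criterion (BIC) over 1..20 (or the
largest order the sample size allows), with ties broken toward the
smaller, more parsimonious order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .timeseries import InvalidInputError, RoiTimeSeries

DEFAULT_MAX_ORDER = 20


def _as_run_matrices(series_set: Sequence[RoiTimeSeries] | Sequence[Sequence[RoiTimeSeries]],
                     center: bool = True) -> list[np.ndarray]:
    """Normalise input to a list of (n_r, d) run matrices.

    Accepts either one run (a sequence of d RoiTimeSeries with equal n, dt)
    or several runs (a sequence of such sequences, one per run).  Runs are
    mean-centred per column by default (the zero-mean AR convention is
    re-enforced internally; the models carry no intercept).
    """
    if len(series_set) == 0:
        raise InvalidInputError("empty series set")
    first = series_set[0]
    runs = [series_set] if isinstance(first, RoiTimeSeries) else list(series_set)
    mats = []
    d = None
    dt = None
    for run in runs:
        run = list(run)
        if not run:
            raise InvalidInputError("empty run")
        n = run[0].n
        for s in run:
            if s.n != n:
                raise InvalidInputError("series within a run must have equal length")
            if dt is None:
                dt = s.dt
            elif not np.isclose(s.dt, dt):
                raise InvalidInputError("all series must share the sampling interval")
        if d is None:
            d = len(run)
        elif len(run) != d:
            raise InvalidInputError("all runs must contain the same series")
        X = np.column_stack([s.values for s in run])
        if center:
            X = X - X.mean(axis=0)
        mats.append(X)
    return mats


def lag_embed(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design for one run: returns (future, design).

    ``future`` is ``X[p:]`` (rows p+1..n); ``design`` has, for each lag
    k = 1..p, the d columns ``X[t-k]``, ordered lag-major.
    """
    n, d = X.shape
    if n - p < 1:
        raise InvalidInputError(f"run too short (n={n}) for order {p}")
    blocks = [X[p - k: n - k, :] for k in range(1, p + 1)]
    return X[p:, :], np.concatenate(blocks, axis=1)


def _stacked_design(run_mats: Sequence[np.ndarray], p: int) -> tuple[np.ndarray, np.ndarray]:
    futs, dess = [], []
    for X in run_mats:
        f, D = lag_embed(X, p)
        futs.append(f)
        dess.append(D)
    return np.vstack(futs), np.vstack(dess)


@dataclass
class VarModel:
    """A fitted zero-mean VAR(p) model.

    Attributes
    ----------
    order_p : int
        Model order.
    coefficients : list of (d, d) ndarray
        ``A_k`` for k = 1..p; scalars are stored as 1x1 matrices.
    residual_cov : (d, d) ndarray
        Residual covariance, sum of squared residuals / n_effective.
    n_samples : int
        Total number of samples across runs.
    n_effective : int
        Number of regressed rows, sum over runs of (n_run - p).
    rank_deficient : bool
        True if the design was collinear and a minimum-norm solution
        was used.
    """

    order_p: int
    coefficients: list[np.ndarray]
    residual_cov: np.ndarray
    n_samples: int
    n_effective: int
    rank_deficient: bool = False

    @property
    def d(self) -> int:
        return self.residual_cov.shape[0]

    def companion_spectral_radius(self) -> float:
        """Spectral radius of the companion matrix (< 1 for a stable model)."""
        p, d = self.order_p, self.d
        C = np.zeros((d * p, d * p))
        for k, A in enumerate(self.coefficients):
            C[:d, k * d:(k + 1) * d] = A
        if p > 1:
            C[d:, :-d] = np.eye(d * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(C))))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "order_p": int(self.order_p),
            "coefficients": [np.asarray(A).tolist() for A in self.coefficients],
            "residual_cov": np.asarray(self.residual_cov).tolist(),
            "n_samples": int(self.n_samples),
            "n_effective": int(self.n_effective),
            "rank_deficient": bool(self.rank_deficient),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "VarModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            order_p=payload["order_p"],
            coefficients=[np.asarray(A, float) for A in payload["coefficients"]],
            residual_cov=np.asarray(payload["residual_cov"], float),
            n_samples=payload["n_samples"],
            n_effective=payload["n_effective"],
            rank_deficient=payload["rank_deficient"],
        )


@dataclass
class OrderSelection:
    """Result of BIC order selection over a 1..max_order search range."""

    chosen_order: int
    criterion_values: dict[int, float]
    search_range: tuple[int, int]


def _fit_ls(run_mats: Sequence[np.ndarray], p: int) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """OLS fit on stacked lagged rows.

    Returns (B, residual_cov, n_eff, rank_deficient) with B of shape
    (d*p, d) mapping design rows to one-step predictions.
    """
    fut, des = _stacked_design(run_mats, p)
    n_eff, c = des.shape
    if n_eff < c + 1:
        raise InvalidInputError(
            f"insufficient samples: {n_eff} effective rows for {c} coefficients"
        )
    B, _, rank, _ = np.linalg.lstsq(des, fut, rcond=None)
    resid = fut - des @ B
    sigma = resid.T @ resid / n_eff
    return B, sigma, n_eff, rank < c


def fit_var(
    series_set: Sequence[RoiTimeSeries] | Sequence[Sequence[RoiTimeSeries]],
    order_p: int,
) -> VarModel:
    """Fit a zero-mean VAR(order_p) by least squares.

    ``series_set`` is one run (list of RoiTimeSeries) or several runs
    (list of lists); runs are regressed block-wise so no lag crosses a
    run boundary.  Collinear designs are resolved by the minimum-norm
    least-squares solution and flagged via ``rank_deficient``.
    """
    if order_p < 1:
        raise InvalidInputError("order_p must be >= 1")
    run_mats = _as_run_matrices(series_set)
    d = run_mats[0].shape[1]
    B, sigma, n_eff, deficient = _fit_ls(run_mats, order_p)
    if deficient:
        warnings.warn("collinear VAR design; minimum-norm solution used",
                      RuntimeWarning, stacklevel=2)
    coeffs = [B[k * d:(k + 1) * d, :].T for k in range(order_p)]
    return VarModel(
        order_p=order_p,
        coefficients=coeffs,
        residual_cov=sigma,
        n_samples=sum(X.shape[0] for X in run_mats),
        n_effective=n_eff,
        rank_deficient=deficient,
    )


def bic(residual_cov: np.ndarray, n_effective: int, n_free_coeffs: int) -> float:
    """Multivariate BIC: n_eff * ln det(Sigma) + k * ln(n_eff)."""
    sigma = np.atleast_2d(residual_cov)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.isfinite(logdet):
        return float("inf")
    return float(n_effective * logdet + n_free_coeffs * np.log(n_effective))


def max_feasible_order(run_mats: Sequence[np.ndarray], max_order: int) -> int:
    """Largest order allowed by the sample size: every run must retain at
    least one regressed row and the total must leave the least squares
    determined (n_effective >= d*p + 1)."""
    d = run_mats[0].shape[1]
    n_min = min(X.shape[0] for X in run_mats)
    n_tot = sum(X.shape[0] for X in run_mats)
    n_runs = len(run_mats)
    p_hi = 0
    for p in range(1, max_order + 1):
        if n_min - p < 1:
            break
        if n_tot - n_runs * p < d * p + 1:
            break
        p_hi = p
    return p_hi


def _fit_ls_common(run_mats: Sequence[np.ndarray], p: int,
                   p_start: int) -> tuple[np.ndarray, int]:
    """OLS residual covariance for order ``p`` regressed only on rows
    ``p_start+1..n`` of each run, so competing orders share the sample."""
    futs, dess = [], []
    for X in run_mats:
        f, D = lag_embed(X, p)
        skip = p_start - p
        futs.append(f[skip:])
        dess.append(D[skip:])
    fut = np.vstack(futs)
    des = np.vstack(dess)
    B, _, _, _ = np.linalg.lstsq(des, fut, rcond=None)
    resid = fut - des @ B
    n_eff = fut.shape[0]
    return resid.T @ resid / n_eff, n_eff


def select_order(
    series_set: Sequence[RoiTimeSeries] | Sequence[Sequence[RoiTimeSeries]],
    max_order: int = DEFAULT_MAX_ORDER,
) -> OrderSelection:
    """Choose the VAR order in 1..max_order minimising the BIC.

    The search is capped at the largest order the sample size allows;
    all candidate orders are scored on the common sample (rows
    ``p_max+1..n`` of each run) so their criteria are comparable — this
    also makes the selection invariant to rescaling the series.  Ties
    break toward the smaller order.
    """
    run_mats = _as_run_matrices(series_set)
    d = run_mats[0].shape[1]
    p_hi = max_feasible_order(run_mats, max_order)
    if p_hi < 1:
        raise InvalidInputError("series too short for even a first-order model")
    scores: dict[int, float] = {}
    for p in range(1, p_hi + 1):
        sigma, n_eff = _fit_ls_common(run_mats, p, p_hi)
        scores[p] = bic(sigma, n_eff, d * d * p)
    best = min(scores, key=lambda p: (scores[p], p))
    return OrderSelection(chosen_order=best, criterion_values=scores,
                          search_range=(1, p_hi))


def joint_order(p_x: int, p_y: int) -> int:
    """Common order for a pair analysis: the minimum of the two univariate
    orders, favouring model simplicity."""
    if p_x < 1 or p_y < 1:
        raise InvalidInputError("orders must be >= 1")
    return min(p_x, p_y)


class VectorAutoregression:
    """Scikit-learn style estimator wrapping :func:`fit_var` / :func:`select_order`.

    Parameters
    ----------
    order : int or None
        VAR order; if None the order is selected by BIC up to ``max_order``.
    max_order : int
        Upper bound of the BIC search when ``order`` is None.
    dt : float
        Sampling interval attached to the input columns (seconds).

    Attributes (after ``fit``)
    --------------------------
    order_ : int
    coef_ : ndarray of shape (order, d, d)
    resid_cov_ : ndarray of shape (d, d)
    bic_ : dict mapping order -> BIC (only when order was selected)
    model_ : VarModel
    """

    def __init__(self, order: int | None = None,
                 max_order: int = DEFAULT_MAX_ORDER, dt: float = 1.0):
        self.order = order
        self.max_order = max_order
        self.dt = dt

    def get_params(self, deep: bool = True) -> dict:
        return {"order": self.order, "max_order": self.max_order, "dt": self.dt}

    def set_params(self, **params) -> "VectorAutoregression":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _series(self, X: np.ndarray) -> list[RoiTimeSeries]:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2:
            raise InvalidInputError("X must be (n_samples, n_series)")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("X must be finite")
        return [RoiTimeSeries(values=X[:, j], dt=self.dt, roi=str(j))
                for j in range(X.shape[1])]

    def fit(self, X: np.ndarray, y: None = None) -> "VectorAutoregression":
        series = self._series(X)
        if self.order is None:
            sel = select_order(series, self.max_order)
            self.bic_ = sel.criterion_values
            self.order_ = sel.chosen_order
        else:
            self.order_ = int(self.order)
        self.model_ = fit_var(series, self.order_)
        self.coef_ = np.stack(self.model_.coefficients)
        self.resid_cov_ = self.model_.residual_cov
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """One-step-ahead predictions for rows order_..n-1 of ``X``."""
        if not hasattr(self, "model_"):
            raise InvalidInputError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        p, d = self.order_, self.model_.d
        _, D = lag_embed(X, p)
        B = np.concatenate([A.T for A in self.model_.coefficients], axis=0)
        return D @ B

    def score(self, X: np.ndarray, y: None = None) -> float:
        """Mean across series of one-step R^2 (1 - residual/total variance)."""
        X2 = np.asarray(X, dtype=float)
        if X2.ndim == 1:
            X2 = X2[:, None]
        pred = self.predict(X2)
        fut = X2[self.order_:, :]
        ss_res = ((fut - pred) ** 2).sum(axis=0)
        ss_tot = ((fut - fut.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - ss_res / ss_tot
        return float(np.mean(r2))
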