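"""Granger causality (GC), conditional GC, influence differences, and the
parametric F inference.

For a zero-mean target series y and source x, both modelled at order p,

    G_{x->y} = ln( var(eps_y) / var(eps_{y,x}) )

where ``eps_y`` is the residual of the univariate AR(p) fit of y and
``eps_{y,x}`` the y-component residual of the bivariate VAR(p) fit of
[y, x].  Because the bivariate model nests the univariate one, the ratio
is >= 1 and G >= 0.  The conditional variant adds a set of conditioning
series z to both the restricted and the full model, removing influence
mediated through (or shared with) z.  The dominant direction of
information flow between a pair is summarised by the influence
difference dG = G_{x->y} - G_{y->x}.

"Residual variance" here is the sum of squared residuals divided by the
number of regressed rows; GC is invariant to this shared normaliser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .timeseries import InvalidInputError, RoiTimeSeries
from .var import _as_run_matrices, _fit_ls

#: tolerance below which a numerically negative GC is floored at zero
_NEG_TOL = 1e-10

RunsLike = Sequence[RoiTimeSeries] | RoiTimeSeries


class InternalConsistencyError(RuntimeError):
    """A nested model fit produced an impossible (negative beyond
    tolerance) causality value."""


@dataclass
class CausalityResult:
    """One directed pair's (conditional) Granger causality value."""

    source: str
    target: str
    order_p: int
    n: int
    g_value: float
    restricted_resvar: float
    full_resvar: float
    parametric_p: float | None = None
    surrogate_p: float | None = None
    conditional_on: tuple[str, ...] = ()


@dataclass
class InfluenceResult:
    """Influence difference dG = G_{x->y} - G_{y->x} for one ROI pair."""

    x: str
    y: str
    delta_g: float
    g_xy: float
    g_yx: float
    order_p: int
    surrogate_p: float | None = None

    @property
    def dominant_direction(self) -> tuple[str, str]:
        return (self.x, self.y) if self.delta_g > 0 else (self.y, self.x)


def _runs(series: RunsLike) -> list[RoiTimeSeries]:
    if isinstance(series, RoiTimeSeries):
        return [series]
    out = list(series)
    if not out or not all(isinstance(s, RoiTimeSeries) for s in out):
        raise InvalidInputError("expected a RoiTimeSeries or a sequence of runs")
    return out


def _check_pairable(*series_runs: list[RoiTimeSeries]) -> None:
    n_runs = len(series_runs[0])
    for runs in series_runs[1:]:
        if len(runs) != n_runs:
            raise InvalidInputError("all series must have the same number of runs")
    for i in range(n_runs):
        n = series_runs[0][i].n
        dt = series_runs[0][i].dt
        for runs in series_runs:
            if runs[i].n != n:
                raise InvalidInputError("length mismatch between series")
            if not np.isclose(runs[i].dt, dt):
                raise InvalidInputError("sampling-interval mismatch between series")
    for runs in series_runs:
        v = np.concatenate([r.values for r in runs])
        if np.std(v) == 0:
            raise InvalidInputError("degenerate (zero-variance) series")


def _run_matrix_sets(*series_runs: list[RoiTimeSeries]) -> list[np.ndarray]:
    """Stack per-run (n_r, d) matrices, one column per series, centring each
    run (zero-mean convention of the AR model)."""
    n_runs = len(series_runs[0])
    mats = []
    for i in range(n_runs):
        X = np.column_stack([runs[i].values for runs in series_runs])
        mats.append(X - X.mean(axis=0))
    return mats


def _component_resvar(run_mats: list[np.ndarray], p: int, component: int) -> tuple[float, bool]:
    _, sigma, _, deficient = _fit_ls(run_mats, p)
    return float(sigma[component, component]), deficient


def _floor_g(g: float, deficient: bool = False) -> float:
    """Negative values are floating-point noise (the models are nested) and
    are floored at zero.  Beyond tolerance they can only arise from the
    rank-truncated minimum-norm solution of a collinear design, where "no
    further reduction" (g = 0) is the meaningful reading; for
    well-conditioned fits such a value indicates a bug and raises."""
    if g < -_NEG_TOL and not deficient:
        raise InternalConsistencyError(
            f"negative Granger causality beyond tolerance: {g!r}"
        )
    return max(g, 0.0)


def granger_causality(x: RunsLike, y: RunsLike, order_p: int,
                      compute_parametric: bool = True) -> CausalityResult:
    """Bivariate Granger causality of x onto y at order ``order_p``.

    ``x`` and ``y`` are single series or per-run lists (runs are regressed
    block-wise).  The restricted model is the univariate AR(p) of y; the
    full model is the bivariate VAR(p) of [y, x].
    """
    if order_p < 1:
        raise InvalidInputError("order_p must be >= 1")
    xr, yr = _runs(x), _runs(y)
    _check_pairable(xr, yr)
    y_only = _run_matrix_sets(yr)
    joint = _run_matrix_sets(yr, xr)
    restricted, def_r = _component_resvar(y_only, order_p, 0)
    full, def_f = _component_resvar(joint, order_p, 0)
    if full <= 0:
        g = 0.0
    else:
        g = _floor_g(float(np.log(restricted / full)), def_r or def_f)
    n = sum(r.n for r in yr)
    res = CausalityResult(
        source=xr[0].roi, target=yr[0].roi, order_p=order_p, n=n,
        g_value=g, restricted_resvar=restricted, full_resvar=full,
    )
    if compute_parametric and n > 2 * order_p:
        res.parametric_p = parametric_p(res)
    return res


def parametric_p(result: CausalityResult) -> float:
    """Parametric p-value of a GC value: the upper-tail probability of

        ((n-p)/p) * (exp(G) - (n-2p)/(n-p))

    under an F distribution with (p, n-2p) degrees of freedom.
    """
    n, p, g = result.n, result.order_p, result.g_value
    return parametric_p_value(g, n, p)


def parametric_p_value(g: float, n: int, p: int) -> float:
    if n <= 2 * p:
        raise InvalidInputError("parametric inference needs n > 2p")
    stat = ((n - p) / p) * (np.exp(g) - (n - 2 * p) / (n - p))
    return float(stats.f.sf(stat, p, n - 2 * p))


def influence_difference(x: RunsLike, y: RunsLike, order_p: int) -> InfluenceResult:
    """Influence difference dG = G_{x->y} - G_{y->x}; antisymmetric in its
    arguments by construction."""
    fwd = granger_causality(x, y, order_p, compute_parametric=False)
    rev = granger_causality(y, x, order_p, compute_parametric=False)
    xr, yr = _runs(x), _runs(y)
    return InfluenceResult(
        x=xr[0].roi, y=yr[0].roi,
        delta_g=fwd.g_value - rev.g_value,
        g_xy=fwd.g_value, g_yx=rev.g_value, order_p=order_p,
    )


def conditional_gc(x: RunsLike, y: RunsLike, z_set: Sequence[RunsLike],
                   order_p: int, compute_parametric: bool = True) -> CausalityResult:
    """Conditional Granger causality of x onto y given the series in z_set.

    Restricted model: VAR(p) on [y, z...]; full model: VAR(p) on
    [y, x, z...]; both compared on the y-component residual variance.
    With an empty conditioning set this equals :func:`granger_causality`.
    """
    if order_p < 1:
        raise InvalidInputError("order_p must be >= 1")
    xr, yr = _runs(x), _runs(y)
    zrs = [_runs(z) for z in z_set]
    _check_pairable(xr, yr, *zrs)
    restricted_m = _run_matrix_sets(yr, *zrs)
    full_m = _run_matrix_sets(yr, xr, *zrs)
    restricted, def_r = _component_resvar(restricted_m, order_p, 0)
    full, def_f = _component_resvar(full_m, order_p, 0)
    g = 0.0 if full <= 0 else _floor_g(float(np.log(restricted / full)),
                                       def_r or def_f)
    n = sum(r.n for r in yr)
    res = CausalityResult(
        source=xr[0].roi, target=yr[0].roi, order_p=order_p, n=n,
        g_value=g, restricted_resvar=restricted, full_resvar=full,
        conditional_on=tuple(z[0].roi for z in zrs),
    )
    if compute_parametric and n > 2 * order_p:
        res.parametric_p = parametric_p(res)
    return res


def results_to_frame(results: Sequence[CausalityResult]) -> pd.DataFrame:
    """Tidy table of causality results (one row per directed pair)."""
    return pd.DataFrame(
        {
            "source": [r.source for r in results],
            "target": [r.target for r in results],
            "conditional_on": ["|".join(r.conditional_on) for r in results],
            "order": [r.order_p for r in results],
            "g": [r.g_value for r in results],
            "parametric_p": [r.parametric_p for r in results],
            "surrogate_p": [r.surrogate_p for r in results],
        }
    )


def results_to_csv(results: Sequence[CausalityResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False)


class GrangerCausalityAnalyzer:
    """Scikit-learn style pairwise (conditional) Granger causality analyser.

    ``fit`` takes an (n_samples, n_series) array, selects a univariate AR
    order per column by BIC (unless ``order`` is given), uses the pairwise
    minimum order per pair, and computes the directed GC matrix.

    Parameters
    ----------
    order : int or None
        Common model order; None selects per-series orders by BIC and
        combines them with the pairwise minimum rule.
    max_order : int
        BIC search cap.
    conditional : bool
        If True, condition every pair on all remaining columns.
    dt : float
        Sampling interval attached to the columns (seconds).

    Attributes (after ``fit``)
    --------------------------
    labels_ : list of str
    orders_ : ndarray of per-series selected orders
    gc_matrix_ : (d, d) ndarray, entry [i, j] = G_{j -> i} (column causes row)
    p_matrix_ : (d, d) ndarray of parametric p-values
    results_ : pandas.DataFrame (tidy, one row per directed pair)
    """

    def __init__(self, order: int | None = None, max_order: int = 20,
                 conditional: bool = False, dt: float = 1.0):
        self.order = order
        self.max_order = max_order
        self.conditional = conditional
        self.dt = dt

    def get_params(self, deep: bool = True) -> dict:
        return {"order": self.order, "max_order": self.max_order,
                "conditional": self.conditional, "dt": self.dt}

    def set_params(self, **params) -> "GrangerCausalityAnalyzer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y: None = None,
            labels: Sequence[str] | None = None) -> "GrangerCausalityAnalyzer":
        from .var import joint_order, select_order

        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise InvalidInputError("X must be (n_samples, n_series >= 2)")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("X must be finite")
        d = X.shape[1]
        self.labels_ = (list(labels) if labels is not None
                        else [str(j) for j in range(d)])
        series = [RoiTimeSeries(values=X[:, j] - X[:, j].mean(), dt=self.dt,
                                roi=self.labels_[j]) for j in range(d)]
        if self.order is None:
            self.orders_ = np.array(
                [select_order([s], self.max_order).chosen_order for s in series]
            )
        else:
            self.orders_ = np.full(d, int(self.order))
        self.gc_matrix_ = np.full((d, d), np.nan)
        self.p_matrix_ = np.full((d, d), np.nan)
        rows = []
        for i in range(d):          # target
            for j in range(d):      # source
                if i == j:
                    continue
                p = joint_order(self.orders_[i], self.orders_[j])
                if self.conditional:
                    z = [series[k] for k in range(d) if k not in (i, j)]
                    res = conditional_gc(series[j], series[i], z, p)
                else:
                    res = granger_causality(series[j], series[i], p)
                self.gc_matrix_[i, j] = res.g_value
                self.p_matrix_[i, j] = res.parametric_p
                rows.append(res)
        self.results_ = results_to_frame(rows)
        return self
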