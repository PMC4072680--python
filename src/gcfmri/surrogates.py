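"""AAFT surrogate data and non-parametric causality inference.

The amplitude-adjusted Fourier transform (AAFT) builds a surrogate
series that keeps the marginal value distribution of the original
exactly (the surrogate is a permutation of the observed samples) and
its linear autocorrelation approximately, while destroying any
phase/lag relationship with other series.  Construction (Theiler's):

1. rank-remap the input onto a sorted Gaussian reference series;
2. randomise the Fourier phases of that Gaussianised series (conjugate
   symmetry preserved; DC and Nyquist bins untouched so the result is
   real);
3. rank-remap back onto the original amplitudes.

Significance of a causality value G_{x->y} is the fraction of
surrogates for which recomputing the statistic with an AAFT copy of the
*source* series exceeds the observed value (strict ``>``; ties do not
count).  Influence differences dG use the same scheme with the putative
source surrogate-replaced in both directed terms.  Group inference
pools exceedance counts over subjects and divides by the total number
of permutations — a fixed-effect analysis.

Ensemble statistics are computed by batched normal-equation solves
assembled from Gram blocks accumulated run by run (lags never cross a
run boundary), so a 1000-surrogate ensemble costs a handful of batched
matrix products rather than thousands of independent model fits.
Equivalence with the plain per-model path is covered by tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .timeseries import InvalidInputError, RoiTimeSeries
from .causality import (
    RunsLike,
    _check_pairable,
    _runs,
    conditional_gc,
    granger_causality,
)

_MIN_AAFT_N = 16


@dataclass
class SurrogateEnsemble:
    """Null-distribution sample for one statistic on one subject's data."""

    n_surrogates: int
    seed: int
    statistic_values: np.ndarray
    observed: float

    def __post_init__(self) -> None:
        self.statistic_values = np.asarray(self.statistic_values, dtype=float)
        if self.statistic_values.size != self.n_surrogates:
            raise InvalidInputError("ensemble size mismatch")

    @property
    def exceedances(self) -> int:
        return int(np.sum(self.statistic_values > self.observed))

    @property
    def p_value(self) -> float:
        return self.exceedances / self.n_surrogates

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"statistic": self.statistic_values}).to_csv(path, index=False)


def format_p(p: float, n_surrogates: int) -> str:
    """Render a permutation p-value; exact zero becomes '< 1/N'."""
    if p == 0:
        return f"<{1.0 / n_surrogates:g}"
    return f"{p:g}"


def _aaft_batch(values: np.ndarray, n_surrogates: int,
                rng: np.random.Generator) -> np.ndarray:
    """Generate ``n_surrogates`` AAFT surrogates of ``values`` as rows."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < _MIN_AAFT_N:
        raise InvalidInputError(f"AAFT needs at least {_MIN_AAFT_N} samples")
    order_x = np.argsort(x, kind="stable")
    rank_x = np.empty(n, dtype=int)
    rank_x[order_x] = np.arange(n)
    sorted_x = x[order_x]

    # 1. Gaussianise: reference noise re-ordered to follow x's ranks.
    gauss = np.sort(rng.standard_normal((n_surrogates, n)), axis=1)
    g = gauss[:, rank_x]

    # 2. Phase randomisation with conjugate symmetry.
    spec = np.fft.rfft(g, axis=1)
    nf = spec.shape[1]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, nf))
    phases[:, 0] = 0.0
    if n % 2 == 0:
        phases[:, -1] = 0.0
    spec *= np.exp(1j * phases)
    g2 = np.fft.irfft(spec, n, axis=1)

    # 3. Amplitude adjustment: original values in the shuffled rank order.
    out = np.empty((n_surrogates, n))
    out[np.arange(n_surrogates)[:, None], np.argsort(g2, axis=1, kind="stable")] = sorted_x
    return out


def aaft(x: RoiTimeSeries, seed: int) -> RoiTimeSeries:
    """One AAFT surrogate of ``x`` (deterministic given ``seed``)."""
    rng = np.random.default_rng(seed)
    values = _aaft_batch(x.values, 1, rng)[0]
    return replace(x, values=values)


# ---------------------------------------------------------------------------
# Batched nested-regression machinery.
#
# Residual sums of squares of all nested models are assembled from Gram
# blocks accumulated run by run:
#
#   W   = fixed lagged predictors [y-lags | z-lags]   (cw columns)
#   X_s = lagged surrogate source, one block per surrogate s
#
# A model's SSR is  t't - b' M^{-1} b  with M the Gram matrix of its
# design and b the design/target cross products, solved batched over
# surrogates.  Within-window lag order is immaterial (SSR is invariant
# to column permutation), which lets the lagged blocks stay strided
# views of the surrogate matrix.
# ---------------------------------------------------------------------------

def _lag_fixed(v: np.ndarray, p: int) -> np.ndarray:
    """(n,) -> (n-p, p) lagged design (strided view)."""
    return np.lib.stride_tricks.sliding_window_view(v, p)[: v.size - p, :]

def _lag_view(v: np.ndarray, p: int) -> np.ndarray:
    """(S, n) -> (S, n-p, p) lagged designs (strided view)."""
    return np.lib.stride_tricks.sliding_window_view(v, p, axis=1)[:, : v.shape[1] - p, :]


def _solve_ssr(M: np.ndarray, b: np.ndarray, tt: np.ndarray) -> np.ndarray:
    """Batched SSR = tt - b' M^{-1} b with a pseudo-inverse fallback for
    singular (collinear) Gram matrices."""
    try:
        theta = np.linalg.solve(M, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        theta = np.empty_like(b)
        for s in range(M.shape[0]):
            theta[s] = np.linalg.pinv(M[s], hermitian=True) @ b[s]
    ssr = tt - np.einsum("...i,...i->...", b, theta)
    return np.maximum(ssr, 0.0)


def _solve_ssr_fixed(M: np.ndarray, b: np.ndarray, tt: float) -> float:
    try:
        theta = np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        theta = np.linalg.pinv(M, hermitian=True) @ b
    return max(tt - float(b @ theta), 0.0)


def _safe_log_ratio(restricted, full) -> np.ndarray:
    restricted = np.asarray(restricted, dtype=float)
    full = np.asarray(full, dtype=float)
    tiny = np.finfo(float).tiny
    g = np.log(np.maximum(restricted, tiny) / np.maximum(full, tiny))
    return np.maximum(g, 0.0)


def _ensemble_stats(xr: list[RoiTimeSeries], yr: list[RoiTimeSeries],
                    zrs: list[list[RoiTimeSeries]], p: int, n_surrogates: int,
                    rng: np.random.Generator, reverse: bool) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-surrogate G(x*->y) and (optionally) G(y->x*), conditioning on z.

    Returns (g_fwd, g_rev); ``g_rev`` is None unless ``reverse``.
    """
    S = n_surrogates
    cw = p * (1 + len(zrs))

    WW = np.zeros((cw, cw))
    Wy = np.zeros(cw)
    yy = 0.0
    WX = np.zeros((S, cw, p))
    XX = np.zeros((S, p, p))
    Xy = np.zeros((S, p))
    if reverse:
        Wx = np.zeros((S, cw))
        Xx = np.zeros((S, p))
        xx = np.zeros(S)

    for i in range(len(yr)):
        yv = yr[i].values - yr[i].values.mean()
        zvs = [z[i].values - z[i].values.mean() for z in zrs]
        xs = _aaft_batch(xr[i].values, S, rng)
        xs -= xs.mean(axis=1, keepdims=True)

        W = np.hstack([_lag_fixed(yv, p)] + [_lag_fixed(z, p) for z in zvs])
        yf = yv[p:]
        Xl = _lag_view(xs, p)
        Xlt = np.swapaxes(Xl, 1, 2)
        xf = xs[:, p:]

        WW += W.T @ W
        Wy += W.T @ yf
        yy += float(yf @ yf)
        WX += np.matmul(W.T, Xl)
        XX += np.matmul(Xlt, Xl)
        Xy += np.matmul(Xlt, yf)
        if reverse:
            Wx += np.matmul(xf, W)
            Xx += np.matmul(Xlt, xf[:, :, None])[:, :, 0]
            xx += np.einsum("sr,sr->s", xf, xf)

    WXt = np.swapaxes(WX, 1, 2)

    def joint(M11, M12, M22):
        c1 = M11.shape[-1]
        c2 = M22.shape[-1]
        M = np.empty((S, c1 + c2, c1 + c2))
        M[:, :c1, :c1] = M11
        M[:, :c1, c1:] = M12
        M[:, c1:, :c1] = np.swapaxes(M12, 1, 2)
        M[:, c1:, c1:] = M22
        return M

    # forward: y on W (restricted) vs on [W, X_s] (full)
    ssr0_y = _solve_ssr_fixed(WW, Wy, yy)
    M_full = joint(np.broadcast_to(WW, (S, cw, cw)), WX, XX)
    b_full = np.concatenate([np.broadcast_to(Wy, (S, cw)), Xy], axis=1)
    ssr1_y = _solve_ssr(M_full, b_full, np.full(S, yy))
    g_fwd = _safe_log_ratio(ssr0_y, ssr1_y)

    if not reverse:
        return g_fwd, None

    # reverse: x* on [X_s | z-lags] (restricted) vs on [X_s | W] (full);
    # the z block sits at columns p.. of W.
    ZZ = WW[p:, p:]
    ZX = WX[:, p:, :]
    Zx = Wx[:, p:]
    cz = cw - p
    M_r = joint(XX, np.swapaxes(ZX, 1, 2), np.broadcast_to(ZZ, (S, cz, cz)))
    b_r = np.concatenate([Xx, Zx], axis=1)
    ssr0_x = _solve_ssr(M_r, b_r, xx)
    M_f = joint(XX, WXt, np.broadcast_to(WW, (S, cw, cw)))
    b_f = np.concatenate([Xx, Wx], axis=1)
    ssr1_x = _solve_ssr(M_f, b_f, xx)
    g_rev = _safe_log_ratio(ssr0_x, ssr1_x)
    return g_fwd, g_rev


def _prepare_pair(x: RunsLike, y: RunsLike,
                  z_set: Sequence[RunsLike] = ()) -> tuple:
    xr, yr = _runs(x), _runs(y)
    zrs = [_runs(z) for z in z_set]
    _check_pairable(xr, yr, *zrs)
    return xr, yr, zrs


def surrogate_gc_ensemble(x: RunsLike, y: RunsLike, order_p: int,
                          n_surrogates: int = 1000, seed: int = 0,
                          z_set: Sequence[RunsLike] = ()) -> SurrogateEnsemble:
    """Null ensemble of (conditional) G_{x->y} with AAFT-replaced source."""
    xr, yr, zrs = _prepare_pair(x, y, z_set)
    if zrs:
        observed = conditional_gc(xr, yr, zrs, order_p,
                                  compute_parametric=False).g_value
    else:
        observed = granger_causality(xr, yr, order_p,
                                     compute_parametric=False).g_value
    rng = np.random.default_rng(seed)
    g_fwd, _ = _ensemble_stats(xr, yr, zrs, order_p, n_surrogates, rng,
                               reverse=False)
    return SurrogateEnsemble(n_surrogates=n_surrogates, seed=seed,
                             statistic_values=g_fwd, observed=observed)


def surrogate_influence_ensemble(x: RunsLike, y: RunsLike, order_p: int,
                                 n_surrogates: int = 1000, seed: int = 0,
                                 z_set: Sequence[RunsLike] = ()) -> SurrogateEnsemble:
    """Null ensemble of the influence difference dG = G_{x->y} - G_{y->x}
    (conditional when ``z_set`` is non-empty); the putative source x is
    surrogate-replaced in both directed terms."""
    xr, yr, zrs = _prepare_pair(x, y, z_set)
    p = order_p
    if zrs:
        fwd = conditional_gc(xr, yr, zrs, p, compute_parametric=False).g_value
        rev = conditional_gc(yr, xr, zrs, p, compute_parametric=False).g_value
    else:
        fwd = granger_causality(xr, yr, p, compute_parametric=False).g_value
        rev = granger_causality(yr, xr, p, compute_parametric=False).g_value
    rng = np.random.default_rng(seed)
    g_fwd, g_rev = _ensemble_stats(xr, yr, zrs, p, n_surrogates, rng,
                                   reverse=True)
    return SurrogateEnsemble(n_surrogates=n_surrogates, seed=seed,
                             statistic_values=g_fwd - g_rev,
                             observed=fwd - rev)


def surrogate_p_gc(x: RunsLike, y: RunsLike, order_p: int,
                   n_surrogates: int = 1000, seed: int = 0,
                   z_set: Sequence[RunsLike] = ()) -> float:
    """Surrogate p-value of (conditional) G_{x->y}: the fraction of AAFT
    source replacements whose statistic strictly exceeds the observed."""
    ens = surrogate_gc_ensemble(x, y, order_p, n_surrogates, seed, z_set)
    return ens.p_value


def surrogate_p_influence(x: RunsLike, y: RunsLike, order_p: int,
                          n_surrogates: int = 1000, seed: int = 0,
                          z_set: Sequence[RunsLike] = ()) -> float:
    """Surrogate p-value of the influence difference dG for one subject."""
    ens = surrogate_influence_ensemble(x, y, order_p, n_surrogates, seed, z_set)
    return ens.p_value


def group_influence_p(observed: Sequence[float],
                      ensembles: Sequence[SurrogateEnsemble]) -> float:
    """Fixed-effect group p: pooled exceedance count over subjects divided
    by the total number of permutations across subjects."""
    observed = list(observed)
    ensembles = list(ensembles)
    if not observed or len(observed) != len(ensembles):
        raise InvalidInputError("need one ensemble per observed value")
    exceed = 0
    total = 0
    for obs, ens in zip(observed, ensembles):
        exceed += int(np.sum(ens.statistic_values > obs))
        total += ens.n_surrogates
    return exceed / total


def subject_seed(master_seed: int, *labels) -> int:
    """Deterministic sub-seed for a (subject, pair, ...) context; stable
    across processes (label hashing does not use Python's salted hash)."""
    crcs = [zlib.crc32(str(l).encode()) for l in labels]
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF] + crcs)
    return int(ss.generate_state(1)[0] % (2 ** 31))
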