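"""FIR-basis GLM estimation of hemodynamic responses and timing indices.

The hemodynamic response function (HRF) at each ROI is estimated without
a fixed functional form: the design matrix contains one regressor per
peristimulus lag (a finite-impulse-response, FIR, basis) spanning a 6-s
pre-stimulus baseline and a 24-s post-stimulus window, plus DC and
linear-drift nuisance columns.  Baseline noise is the standard deviation
of the series over the pre-stimulus intervals; dividing the estimated
response by it gives a dSPM-style statistic that is t-like under the
null of no response.  The response shape is summarised by four timing
indices: onset, time-to-half (TTH), time-to-peak (TTP), and the
full width at half maximum (FWHM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .timeseries import EventDesign, InvalidInputError, RoiTimeSeries


@dataclass
class FirDesign:
    """FIR design matrix with per-column bookkeeping."""

    matrix: np.ndarray
    lags_s: np.ndarray           # one peristimulus lag grid (shared by conditions)
    conditions: tuple[str, ...]
    dt: float
    pre_s: float
    post_s: float
    events: EventDesign

    @property
    def n_fir_columns(self) -> int:
        return self.lags_s.size * len(self.conditions)


@dataclass
class HrfEstimate:
    """FIR-GLM estimate of the hemodynamic response per condition."""

    lags_s: np.ndarray
    betas: dict[str, np.ndarray]      # condition -> response per lag
    baseline_sd: float
    dt: float


@dataclass
class TimingIndices:
    """Summary timing of a hemodynamic response, all in seconds."""

    onset_s: float
    time_to_half_s: float
    time_to_peak_s: float
    fwhm_s: float

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.time_to_half_s <= self.time_to_peak_s):
            raise InvalidInputError("timing indices must be ordered")
        if not self.fwhm_s > 0:
            raise InvalidInputError("FWHM must be positive")


def build_fir_design(events: EventDesign, dt: float,
                     pre_s: float = 6.0, post_s: float = 24.0) -> FirDesign:
    """Design matrix of shifted event impulse trains plus DC and drift.

    One column per peristimulus lag per condition; the lag grid runs from
    ``-pre_s`` to ``post_s - dt`` in steps of ``dt``.  Event onsets are
    snapped to the nearest sample.
    """
    n_pre = pre_s / dt
    n_post = post_s / dt
    if abs(n_pre - round(n_pre)) > 1e-6 or abs(n_post - round(n_post)) > 1e-6:
        raise InvalidInputError("dt must divide the pre/post window lengths")
    n_pre, n_post = int(round(n_pre)), int(round(n_post))
    n_rows = int(round(events.run_length / dt))
    if any(t < 0 or t > events.run_length for t in events.onsets):
        raise InvalidInputError("event outside the run")
    lag_idx = np.arange(-n_pre, n_post)
    conditions = tuple(sorted(set(events.conditions)))
    cols = []
    for cond in conditions:
        onset_rows = [int(round(t / dt)) for t, c in
                      zip(events.onsets, events.conditions) if c == cond]
        block = np.zeros((n_rows, lag_idx.size))
        for r in onset_rows:
            rows = r + lag_idx
            ok = (rows >= 0) & (rows < n_rows)
            block[rows[ok], np.nonzero(ok)[0]] += 1.0
        cols.append(block)
    dc = np.ones((n_rows, 1))
    drift = np.linspace(-1.0, 1.0, n_rows)[:, None]
    matrix = np.hstack(cols + [dc, drift])
    return FirDesign(matrix=matrix, lags_s=lag_idx * dt, conditions=conditions,
                     dt=dt, pre_s=pre_s, post_s=post_s, events=events)


def _baseline_indices(design: FirDesign) -> np.ndarray:
    """Sample indices inside any pre-stimulus baseline interval."""
    n_rows = design.matrix.shape[0]
    idx: set[int] = set()
    for t in design.events.onsets:
        a = int(round((t - design.pre_s) / design.dt))
        b = int(round(t / design.dt))
        idx.update(range(max(a, 0), min(b, n_rows)))
    return np.array(sorted(idx), dtype=int)


def fit_glm(ts: RoiTimeSeries, design: FirDesign) -> HrfEstimate:
    """Least-squares FIR-GLM fit of one ROI series.

    ``baseline_sd`` is the standard deviation of the raw series over the
    pre-stimulus intervals.  Rank-deficient designs are resolved by the
    minimum-norm solution with a warning.
    """
    X = design.matrix
    if X.shape[0] != ts.n:
        raise InvalidInputError("design rows must match the series length")
    beta, _, rank, _ = np.linalg.lstsq(X, ts.values, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient FIR design; minimum-norm solution used",
                      RuntimeWarning, stacklevel=2)
    nlag = design.lags_s.size
    betas = {cond: beta[i * nlag:(i + 1) * nlag]
             for i, cond in enumerate(design.conditions)}
    base_idx = _baseline_indices(design)
    if base_idx.size < 2:
        raise InvalidInputError("no pre-stimulus baseline samples in the run")
    baseline_sd = float(np.std(ts.values[base_idx], ddof=1))
    return HrfEstimate(lags_s=design.lags_s, betas=betas,
                       baseline_sd=baseline_sd, dt=design.dt)


def dspm(hrf: HrfEstimate, condition: str | None = None) -> np.ndarray:
    """dSPM-style statistic per lag: estimate / baseline noise SD."""
    if not hrf.baseline_sd > 0:
        raise InvalidInputError("baseline SD must be positive")
    if condition is None:
        condition = next(iter(hrf.betas))
    return hrf.betas[condition] / hrf.baseline_sd


def select_rois(statistic_map: np.ndarray, lags_s: np.ndarray,
                threshold: float = 4.0,
                window: tuple[float, float] = (4.0, 7.0)) -> np.ndarray:
    """Select responding locations: mean statistic over the post-stimulus
    window strictly above the threshold.

    ``statistic_map`` is (n_locations, n_lags); returns a boolean mask.
    """
    lo, hi = window
    if not lo < hi:
        raise InvalidInputError("empty selection window")
    sel = (lags_s >= lo) & (lags_s <= hi)
    if not np.any(sel):
        raise InvalidInputError("window outside the lag grid")
    stat = np.atleast_2d(np.asarray(statistic_map, dtype=float))
    return stat[:, sel].mean(axis=1) > threshold


def _cross_time(lags: np.ndarray, resp: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time at which resp crosses ``level`` between
    grid points i and i+1."""
    y0, y1 = resp[i], resp[i + 1]
    if y1 == y0:
        return float(lags[i])
    frac = (level - y0) / (y1 - y0)
    return float(lags[i] + frac * (lags[i + 1] - lags[i]))


def timing_indices_from_curve(lags_s: np.ndarray, response: np.ndarray) -> TimingIndices:
    """Timing indices of a sampled response curve (post-stimulus part).

    TTP is the lag of the maximum; TTH the first upward crossing of half
    the peak; FWHM the width between the two half-peak crossings around
    the peak; onset the first time the response exceeds 10% of the peak
    and stays above it until the peak (a convention — onset has no
    universal definition).
    """
    lags_s = np.asarray(lags_s, dtype=float)
    response = np.asarray(response, dtype=float)
    post = lags_s >= 0
    lags = lags_s[post]
    resp = response[post]
    if resp.size < 3 or np.max(resp) <= 0:
        raise InvalidInputError("response must have a positive peak")
    ipk = int(np.argmax(resp))
    peak = resp[ipk]
    ttp = float(lags[ipk])

    half = 0.5 * peak
    rise_i = None
    for i in range(ipk):
        if resp[i] < half <= resp[i + 1]:
            rise_i = i
    if rise_i is None:
        tth = float(lags[0])
    else:
        tth = _cross_time(lags, resp, rise_i, half)

    fall_t = None
    for i in range(ipk, resp.size - 1):
        if resp[i] >= half > resp[i + 1]:
            fall_t = _cross_time(lags, resp, i, half)
            break
    if fall_t is None:
        raise InvalidInputError("falling half-maximum crossing not found; "
                                "FWHM undefined on this window")
    fwhm = fall_t - tth

    tenth = 0.1 * peak
    onset = float(lags[0])
    below = np.nonzero(resp[:ipk + 1] < tenth)[0]
    if below.size:
        j = int(below[-1])
        onset = _cross_time(lags, resp, j, tenth) if j < ipk else float(lags[j])
    return TimingIndices(onset_s=onset, time_to_half_s=tth,
                         time_to_peak_s=ttp, fwhm_s=fwhm)


def timing_indices(hrf: HrfEstimate, condition: str | None = None) -> TimingIndices:
    """Timing indices of a fitted hemodynamic response."""
    if condition is None:
        condition = next(iter(hrf.betas))
    return timing_indices_from_curve(hrf.lags_s, hrf.betas[condition])


def hrf_to_csv(hrf: HrfEstimate, path: str | Path) -> None:
    """Export the estimate as tidy CSV (lag_s, condition, beta, dspm)."""
    rows = []
    for cond, b in hrf.betas.items():
        stat = b / hrf.baseline_sd
        for lag, beta, s in zip(hrf.lags_s, b, stat):
            rows.append({"lag_s": lag, "condition": cond, "beta": beta, "dspm": s})
    pd.DataFrame(rows).to_csv(path, index=False)
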