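"""Containers and preprocessing for ROI-averaged fMRI time series.

A :class:`RoiTimeSeries` is a uniformly sampled scalar series for one
region of interest (ROI) of one subject/run, carrying its sampling
interval ``dt`` in seconds.  Preparation of the series for causality
analysis follows the usual BOLD pipeline: average voxels within the ROI,
remove the DC offset and any linear scanner drift, and — for
sampling-rate experiments — resample by plain decimation (sample
discarding, no anti-alias filter) or band-limited SINC interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """Uniformly sampled scalar series for one ROI / subject / run.

    Parameters
    ----------
    values : array-like of float
        The samples.  Sample ``k`` is at time ``k * dt`` from run start.
    dt : float
        Sampling interval in seconds (> 0).
    roi, subject : str
        Labels identifying the region and subject.
    run : str or None
        Run label, if the series belongs to a single run.
    """

    values: np.ndarray
    dt: float
    roi: str = ""
    subject: str = ""
    run: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InvalidInputError("values must be one-dimensional")
        if v.size < 2:
            raise InvalidInputError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("all samples must be finite")
        if not (self.dt > 0):
            raise InvalidInputError("dt must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from run start (0-based convention)."""
        return np.arange(self.n) * self.dt


@dataclass(frozen=True)
class EventDesign:
    """Event-related stimulus design for one run.

    ``onsets`` are stimulus onset times in seconds, strictly increasing;
    ``conditions`` is a parallel list of condition labels.
    """

    onsets: tuple[float, ...]
    conditions: tuple[str, ...]
    run_length: float
    stimulus_duration: float

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.onsets)
        conditions = tuple(str(c) for c in self.conditions)
        if len(onsets) != len(conditions):
            raise InvalidInputError("onsets and conditions must be parallel")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InvalidInputError("onsets must be strictly increasing")
        if onsets and onsets[-1] + self.stimulus_duration > self.run_length:
            raise InvalidInputError("events must end inside the run")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "conditions", conditions)

    @property
    def n_events(self) -> int:
        return len(self.onsets)


def detrend(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the DC value and the linear drift by OLS regression on time.

    Returns a new series equal to the residuals of the least-squares fit
    of the samples on an intercept and the time index.  The output has
    zero mean and zero linear trend; ``dt`` and labels are unchanged.
    """
    if ts.n < 3:
        raise InvalidInputError("detrend needs at least 3 samples")
    t = np.arange(ts.n, dtype=float)
    X = np.column_stack([np.ones(ts.n), t])
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    return replace(ts, values=ts.values - X @ beta)


def decimate(ts: RoiTimeSeries, factor: int, offset: int = 0) -> RoiTimeSeries:
    """Downsample by discarding samples: keep indices ``offset, offset+factor, ...``.

    No anti-alias filtering is applied — this mirrors reducing an fMRI
    sampling rate by dropping acquisitions.  Output ``dt`` is
    ``factor * dt``.  ``offset`` selects the sampling phase.
    """
    factor = int(factor)
    offset = int(offset)
    if factor < 1:
        raise InvalidInputError("factor must be a positive integer")
    if offset < 0 or offset >= factor:
        raise InvalidInputError("offset must satisfy 0 <= offset < factor")
    return replace(ts, values=ts.values[offset::factor], dt=ts.dt * factor)


def sinc_interpolate(ts: RoiTimeSeries, factor: int) -> RoiTimeSeries:
    """Band-limited (SINC) upsampling by an integer factor.

    Implemented as zero-padding of the discrete Fourier spectrum under a
    periodic-boundary assumption, with the Nyquist bin split evenly for
    even input length.  Values at the original grid points are preserved
    exactly (up to floating point); output ``dt`` is ``dt / factor`` and
    output length is ``factor * n``.  Edge ringing from the periodicity
    assumption is expected on non-periodic data.
    """
    factor = int(factor)
    if factor < 1:
        raise InvalidInputError("factor must be a positive integer")
    if ts.n < 8:
        raise InvalidInputError("sinc interpolation needs at least 8 samples")
    if factor == 1:
        return ts
    n = ts.n
    m = n * factor
    spec = np.fft.rfft(ts.values)
    out_spec = np.zeros(m // 2 + 1, dtype=complex)
    out_spec[: spec.size] = spec
    if n % 2 == 0:
        # Nyquist bin of the input is shared between +/- frequencies;
        # splitting keeps the interpolant real and grid-preserving.
        out_spec[n // 2] = spec[-1] / 2.0
    out = np.fft.irfft(out_spec, m) * factor
    return replace(ts, values=out, dt=ts.dt / factor)


# ---------------------------------------------------------------------------
# I/O: delimited ROI tables with a JSON sidecar, event tables, NIfTI means.
# ---------------------------------------------------------------------------

def write_roi_table(
    path: str | Path,
    series: Sequence[RoiTimeSeries],
    sep: str = ",",
) -> None:
    """Write ROI series (equal length/dt, one subject/run) to a delimited
    table with one column per ROI plus a ``<path>.json`` metadata sidecar."""
    series = list(series)
    if not series:
        raise InvalidInputError("no series to write")
    n = series[0].n
    dt = series[0].dt
    for s in series:
        if s.n != n or s.dt != dt:
            raise InvalidInputError("all series must share n and dt")
    df = pd.DataFrame({s.roi: s.values for s in series})
    path = Path(path)
    df.to_csv(path, sep=sep, index=False)
    meta = {"dt": dt, "subject": series[0].subject, "run": series[0].run}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_roi_table(
    path: str | Path,
    dt: float | None = None,
    sep: str = ",",
) -> list[RoiTimeSeries]:
    """Read a delimited ROI table (header row of ROI labels).

    ``dt`` may be supplied directly or found in a ``<path>.json`` sidecar
    written by :func:`write_roi_table`.
    """
    path = Path(path)
    meta: dict = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if dt is None:
        dt = meta.get("dt")
    if dt is None:
        raise InvalidInputError("sampling interval dt not provided and no sidecar found")
    df = pd.read_csv(path, sep=sep)
    return [
        RoiTimeSeries(
            values=df[c].to_numpy(float),
            dt=float(dt),
            roi=str(c),
            subject=str(meta.get("subject", "")),
            run=meta.get("run"),
        )
        for c in df.columns
    ]


def read_event_table(path: str | Path, run_length: float,
                     stimulus_duration: float = 0.5) -> EventDesign:
    """Read an event table CSV with columns ``onset_s`` and ``condition``."""
    df = pd.read_csv(path)
    if "onset_s" not in df.columns or "condition" not in df.columns:
        raise InvalidInputError("event table needs onset_s and condition columns")
    order = np.argsort(df["onset_s"].to_numpy(float), kind="stable")
    return EventDesign(
        onsets=tuple(df["onset_s"].to_numpy(float)[order]),
        conditions=tuple(df["condition"].astype(str).to_numpy()[order]),
        run_length=float(run_length),
        stimulus_duration=float(stimulus_duration),
    )


def roi_series_from_nifti(
    image_path: str | Path,
    mask_path: str | Path,
    dt: float,
    subject: str = "",
    run: str | None = None,
) -> list[RoiTimeSeries]:
    """Extract mean ROI series from a 4-D NIfTI volume and an integer-labelled
    3-D ROI mask: the voxel mean within each nonzero label at each time point."""
    import nibabel as nib

    img = nib.load(str(image_path))
    mask = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(mask.dataobj)
    if data.ndim != 4:
        raise InvalidInputError("image must be 4-D")
    if labels.shape != data.shape[:3]:
        raise InvalidInputError("mask shape must match the image's spatial grid")
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = labels == lab
        out.append(
            RoiTimeSeries(
                values=data[sel, :].mean(axis=0),
                dt=dt,
                roi=str(int(lab)),
                subject=subject,
                run=run,
            )
        )
    return out
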