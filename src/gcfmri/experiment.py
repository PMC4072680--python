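"""End-to-end sampling-rate (TR) experiments on a cohort of ROI series.

The central question: how does the fMRI sampling interval affect the
detectability of directed (Granger-causal) influence?  Starting from a
cohort sampled at 0.1 s, each target TR is produced either by plain
decimation (``mode="decimate"``) or by decimation followed by SINC
re-interpolation back to the original length (``mode="sinc_control"``,
which controls for the number of observations).  Per subject the
pipeline is: resample -> detrend per run -> univariate BIC order
selection per ROI (capped by the sample count) -> pairwise influence
differences with AAFT surrogate null -> fixed-effect group pooling.

Group significance uses inclusive thresholds: p <= 0.05 is a
significant ("strong") causal modulation, 0.05 < p <= 0.1 a trend.  For
an unordered pair analysed as (x, y), p close to 1 is evidence for the
reverse direction (the reverse-direction p-value is 1 - p).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .causality import (
    CausalityResult,
    InfluenceResult,
    conditional_gc,
    granger_causality,
)
from .surrogates import (
    SurrogateEnsemble,
    group_influence_p,
    subject_seed,
    surrogate_gc_ensemble,
    surrogate_influence_ensemble,
)
from .synthetic import Cohort, CohortSpec
from .timeseries import InvalidInputError, RoiTimeSeries, decimate, detrend, sinc_interpolate
from .var import joint_order, max_feasible_order, select_order

logger = logging.getLogger("gcfmri")

STRONG_P = 0.05
TREND_P = 0.1


@dataclass
class ConnectivityTable:
    """All pairwise results for one ROI set at one TR/mode.

    ``influences`` holds one group-level entry per unordered pair
    (delta_g = across-subject mean, surrogate_p = fixed-effect pooled p);
    ``directed`` one entry per ordered pair (g_value = across-subject
    geometric-mean ratio).  ``per_subject`` is the tidy subject-level
    table behind the summaries.
    """

    tr_s: float
    mode: str
    roi_labels: tuple[str, ...]
    influences: list[InfluenceResult]
    directed: list[CausalityResult]
    per_subject: pd.DataFrame
    thresholds: tuple[float, float] = (STRONG_P, TREND_P)

    def influence_p(self, x: str, y: str) -> float:
        """Group p for the pair as analysed in orientation (x, y); the
        orientation (y, x) returns 1 - p."""
        for r in self.influences:
            if (r.x, r.y) == (x, y):
                return r.surrogate_p
            if (r.x, r.y) == (y, x):
                return 1.0 - r.surrogate_p
        raise KeyError(f"pair ({x}, {y}) not in table")

    def significant_edges(self, alpha: float = STRONG_P) -> list[tuple[str, str]]:
        """Directed edges whose influence-difference group p <= alpha
        (for the analysed orientation) or >= 1 - alpha (reverse)."""
        edges = []
        for r in self.influences:
            if r.surrogate_p is not None and r.surrogate_p <= alpha:
                edges.append((r.x, r.y))
            elif r.surrogate_p is not None and r.surrogate_p >= 1.0 - alpha:
                edges.append((r.y, r.x))
        return edges

    def trend_edges(self) -> list[tuple[str, str]]:
        strong, trend = self.thresholds
        edges = []
        for r in self.influences:
            if r.surrogate_p is None:
                continue
            if strong < r.surrogate_p <= trend:
                edges.append((r.x, r.y))
            elif 1.0 - trend <= r.surrogate_p < 1.0 - strong:
                edges.append((r.y, r.x))
        return edges


def _resample_subject(subject, factor: int, mode: str) -> dict[str, list[RoiTimeSeries]]:
    """Per-ROI lists of per-run series at the target TR, detrended."""
    out: dict[str, list[RoiTimeSeries]] = {}
    for roi in subject.runs[0].keys():
        runs = []
        for run in subject.runs:
            s = decimate(run[roi], factor)
            if mode == "sinc_control" and factor > 1:
                s = sinc_interpolate(s, factor)
            runs.append(detrend(s))
        out[roi] = runs
    return out


def _pairs(labels: Sequence[str]) -> list[tuple[str, str]]:
    return [(labels[i], labels[j]) for i in range(len(labels))
            for j in range(i + 1, len(labels))]


def analyze_cohort(
    cohort: Cohort,
    tr_s: float,
    mode: str = "decimate",
    n_perm: int = 1000,
    master_seed: int = 0,
    conditional: bool = False,
    max_order: int = 20,
    directed_surrogates: bool = False,
) -> ConnectivityTable:
    """One TR condition: resample, detrend, order-select, and test every
    ROI pair's influence difference with AAFT surrogates, pooling the
    permutation counts across subjects (fixed effect)."""
    if mode not in ("decimate", "sinc_control"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    dt0 = cohort.config.dt
    ratio = tr_s / dt0
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise InvalidInputError(f"TR {tr_s} is not an integer multiple of dt {dt0}")

    labels = list(cohort.roi_labels)
    pair_obs: dict[tuple[str, str], list[float]] = {p: [] for p in _pairs(labels)}
    pair_ens: dict[tuple[str, str], list[SurrogateEnsemble]] = {p: [] for p in _pairs(labels)}
    dir_ens: dict[tuple[str, str], list[SurrogateEnsemble]] = {}
    rows = []

    t0 = time.perf_counter()
    for subject in cohort.subjects:
        series = _resample_subject(subject, factor, mode)
        # univariate order per ROI; each run is its own regression block
        orders = {roi: select_order([[r] for r in series[roi]],
                                    max_order).chosen_order
                  for roi in labels}
        for x_lab, y_lab in _pairs(labels):
            p = joint_order(orders[x_lab], orders[y_lab])
            xr, yr = series[x_lab], series[y_lab]
            z_set = ([series[z] for z in labels if z not in (x_lab, y_lab)]
                     if conditional else [])
            if conditional:
                fwd = conditional_gc(xr, yr, z_set, p, compute_parametric=False)
                rev = conditional_gc(yr, xr, z_set, p, compute_parametric=False)
            else:
                fwd = granger_causality(xr, yr, p, compute_parametric=False)
                rev = granger_causality(yr, xr, p, compute_parametric=False)
            seed = subject_seed(master_seed, subject.subject, x_lab, y_lab,
                                f"{tr_s}:{mode}:{conditional}")
            ens = surrogate_influence_ensemble(xr, yr, p, n_perm, seed, z_set)
            pair_obs[(x_lab, y_lab)].append(ens.observed)
            pair_ens[(x_lab, y_lab)].append(ens)
            if directed_surrogates:
                for (src, dst), (sr, dr) in ((( x_lab, y_lab), (xr, yr)),
                                             ((y_lab, x_lab), (yr, xr))):
                    dseed = subject_seed(master_seed, subject.subject, src, dst,
                                         f"gc:{tr_s}:{mode}:{conditional}")
                    de = surrogate_gc_ensemble(sr, dr, p, n_perm, dseed, z_set)
                    dir_ens.setdefault((src, dst), []).append(de)
            rows.append({
                "subject": subject.subject, "x": x_lab, "y": y_lab,
                "order": p, "g_xy": fwd.g_value, "g_yx": rev.g_value,
                "delta_g": fwd.g_value - rev.g_value,
                "resvar_restricted_xy": fwd.restricted_resvar,
                "resvar_full_xy": fwd.full_resvar,
                "subject_p": ens.p_value,
            })
    logger.info("analyze tr=%gs mode=%s conditional=%s: %.1fs",
                tr_s, mode, conditional, time.perf_counter() - t0)

    per_subject = pd.DataFrame(rows)
    influences = []
    directed = []
    for x_lab, y_lab in _pairs(labels):
        obs = pair_obs[(x_lab, y_lab)]
        group_p = group_influence_p(obs, pair_ens[(x_lab, y_lab)])
        sub = per_subject[(per_subject.x == x_lab) & (per_subject.y == y_lab)]
        order_med = int(np.median(sub["order"]))
        influences.append(InfluenceResult(
            x=x_lab, y=y_lab, delta_g=float(np.mean(obs)),
            g_xy=float(np.mean(sub["g_xy"])), g_yx=float(np.mean(sub["g_yx"])),
            order_p=order_med, surrogate_p=group_p))
        for src, dst, col in ((x_lab, y_lab, "g_xy"), (y_lab, x_lab, "g_yx")):
            g_mean = float(np.mean(sub[col]))
            sp = None
            if (src, dst) in dir_ens:
                ens_list = dir_ens[(src, dst)]
                sp = group_influence_p([e.observed for e in ens_list], ens_list)
            directed.append(CausalityResult(
                source=src, target=dst, order_p=order_med,
                n=int(sub.shape[0]),
                g_value=g_mean,
                restricted_resvar=float(np.exp(g_mean)),
                full_resvar=1.0,
                parametric_p=None, surrogate_p=sp,
                conditional_on=tuple(z for z in labels if z not in (src, dst))
                if conditional else ()))
    return ConnectivityTable(tr_s=tr_s, mode=mode, roi_labels=tuple(labels),
                             influences=influences, directed=directed,
                             per_subject=per_subject)


def run_tr_sweep(cohort: Cohort, trs: Sequence[float] = (0.1, 0.5, 1.0, 2.0),
                 mode: str = "decimate", n_perm: int = 1000,
                 master_seed: int = 0) -> list[ConnectivityTable]:
    """The sampling-rate sweep: one ConnectivityTable per requested TR."""
    return [analyze_cohort(cohort, tr, mode, n_perm, master_seed) for tr in trs]


def run_conditional_pass(cohort: Cohort, trs: Sequence[float] = (0.1, 0.5, 1.0, 2.0),
                         n_perm: int = 100, master_seed: int = 0,
                         mode: str = "decimate") -> list[ConnectivityTable]:
    """Conditional-GC pass: each pair conditioned on all remaining ROIs.

    The permutation count defaults to 100 (conditional models are an
    order of magnitude more expensive), so the p-resolution is 1/100.
    """
    return [analyze_cohort(cohort, tr, mode, n_perm, master_seed,
                           conditional=True) for tr in trs]


@dataclass
class ResidualReduction:
    """Worked residual-power comparison for one directed pair."""

    restricted_power: float
    full_power: float

    @property
    def percent_reduction(self) -> float:
        return 100.0 * (self.restricted_power - self.full_power) / self.restricted_power

    def formatted(self) -> str:
        return (f"{self.restricted_power:g}→{self.full_power:g}; "
                f"{self.percent_reduction:.1f}% reduction")


def residual_reduction_from_powers(restricted: float, full: float) -> ResidualReduction:
    """Report how much the residual power of the restricted (target-only)
    model drops when the source series is added to the model."""
    if restricted <= 0:
        raise InvalidInputError("restricted power must be positive")
    return ResidualReduction(restricted_power=restricted, full_power=full)


def residual_reduction_report(x, y, order_p: int) -> ResidualReduction:
    """Residual powers of the restricted and full fits for y given source x
    and the percent reduction (the exp(-G) identity links the two)."""
    res = granger_causality(x, y, order_p, compute_parametric=False)
    return ResidualReduction(restricted_power=res.restricted_resvar,
                             full_power=res.full_resvar)


def table_to_frame(table: ConnectivityTable) -> pd.DataFrame:
    rows = []
    for r in table.influences:
        rows.append({
            "tr_s": table.tr_s, "mode": table.mode, "kind": "influence",
            "source": r.x, "target": r.y, "order": r.order_p,
            "value": r.delta_g, "group_p": r.surrogate_p,
        })
    for r in table.directed:
        rows.append({
            "tr_s": table.tr_s, "mode": table.mode,
            "kind": "conditional_gc" if r.conditional_on else "gc",
            "source": r.source, "target": r.target, "order": r.order_p,
            "value": r.g_value, "group_p": r.surrogate_p,
        })
    return pd.DataFrame(rows)


def render_report(tables: Sequence[ConnectivityTable]) -> str:
    """Human-readable per-TR adjacency summary (deterministic ordering)."""
    tables = list(tables)
    if not tables:
        raise InvalidInputError("no tables to report")
    lines = []
    for t in tables:
        lines.append(f"TR = {t.tr_s:g} s ({t.mode})")
        strong = sorted(t.significant_edges())
        trend = sorted(t.trend_edges())
        lines.append(f"  strong edges (p <= {t.thresholds[0]:g}): {len(strong)}")
        for a, b in strong:
            lines.append(f"    {a} -> {b}  (p = {t.influence_p(a, b):g})")
        lines.append(f"  trend edges ({t.thresholds[0]:g} < p <= {t.thresholds[1]:g}): {len(trend)}")
        for a, b in trend:
            lines.append(f"    {a} -> {b}  (p = {t.influence_p(a, b):g})")
    return "\n".join(lines) + "\n"


def write_outputs(tables: Sequence[ConnectivityTable], directory: str | Path,
                  config_manifest: dict | None = None) -> None:
    """Write tidy CSVs per table plus a JSON manifest for provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in tables:
        name = f"connectivity_tr{t.tr_s:g}_{t.mode}"
        table_to_frame(t).to_csv(directory / f"{name}.csv", index=False)
        t.per_subject.to_csv(directory / f"{name}_subjects.csv", index=False)
    (directory / "report.txt").write_text(render_report(tables))
    if config_manifest is not None:
        (directory / "manifest.json").write_text(json.dumps(config_manifest, indent=2))


def scaled_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """A reduced cohort (8 subjects, 2 runs) whose full sweep completes in
    minutes while keeping per-run design and sampling identical."""
    return CohortSpec(n_subjects=8, n_runs=2, master_seed=master_seed)
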