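import numpy as np
import pytest

import gcfmri as g
from gcfmri import EventDesign, InvalidInputError

from conftest import series


def design_with(onsets, dt, run_length=240.0, conditions=None):
    ev = EventDesign(onsets=tuple(onsets),
                     conditions=tuple(conditions or ["stim"] * len(onsets)),
                     run_length=run_length, stimulus_duration=0.5)
    return g.build_fir_design(ev, dt)


class TestFirDesign:
    def test_column_count_fine_sampling(self):
        d = design_with([30.0, 60.0], dt=0.1)
        assert d.n_fir_columns == 300          # (6 + 24) / 0.1
        assert d.matrix.shape[1] == 302        # + DC + drift

    def test_column_count_epi_sampling(self):
        d = design_with([30.0, 60.0], dt=2.0)
        assert d.n_fir_columns == 15
        assert d.matrix.shape[1] == 17

    def test_two_conditions_double_columns(self):
        d = design_with([30.0, 60.0], dt=2.0, conditions=["L", "R"])
        assert d.n_fir_columns == 30
        assert d.conditions == ("L", "R")

    def test_impulse_identity(self):
        # one event: the lag-0 column has its single 1 exactly at the event row
        d = design_with([10.0], dt=1.0, run_length=60.0)
        lag0 = np.where(d.lags_s == 0.0)[0][0]
        col = d.matrix[:, lag0]
        assert col[10] == 1.0 and col.sum() == 1.0

    def test_rejects_event_outside_run(self):
        ev = EventDesign(onsets=(10.0,), conditions=("a",), run_length=240.0,
                         stimulus_duration=0.5)
        bad = EventDesign.__new__(EventDesign)
        object.__setattr__(bad, "onsets", (-5.0,))
        object.__setattr__(bad, "conditions", ("a",))
        object.__setattr__(bad, "run_length", 240.0)
        object.__setattr__(bad, "stimulus_duration", 0.5)
        with pytest.raises(InvalidInputError):
            g.build_fir_design(bad, 1.0)
        assert g.build_fir_design(ev, 1.0).matrix.shape[0] == 240

    def test_dt_must_divide_window(self):
        ev = EventDesign(onsets=(10.0,), conditions=("a",), run_length=240.0,
                         stimulus_duration=0.5)
        with pytest.raises(InvalidInputError):
            g.build_fir_design(ev, dt=0.7)


class TestFitGlm:
    def test_noiseless_recovery_exact(self, rng):
        d = design_with([20.0, 50.0, 90.0, 130.0, 170.0], dt=0.5)
        beta_true = rng.standard_normal(d.matrix.shape[1])
        ts = series(d.matrix @ beta_true, dt=0.5)
        hrf = g.fit_glm(ts, d)
        assert np.allclose(hrf.betas["stim"], beta_true[:d.lags_s.size],
                           atol=1e-8)

    def test_noisy_recovery_rmse(self):
        # 96 events (4 runs) at 0.1-s sampling with unit white noise: the
        # run-averaged per-lag beta error stays well below the response scale
        rng = np.random.default_rng(2)
        spec = g.CohortSpec(master_seed=9)
        beta_runs = []
        for r in range(4):
            fir = g.build_fir_design(g.make_design(spec, r, 0), 0.1)
            lag_resp = np.exp(-0.5 * ((fir.lags_s - 5.0) / 2.0) ** 2)
            lag_resp[fir.lags_s < 0] = 0.0
            beta_true = np.concatenate([lag_resp, [0.0, 0.0]])
            ts = series(fir.matrix @ beta_true
                        + rng.standard_normal(fir.matrix.shape[0]), dt=0.1)
            beta_runs.append(g.fit_glm(ts, fir).betas["stim"])
        est = np.mean(beta_runs, axis=0)
        assert np.sqrt(np.mean((est - lag_resp) ** 2)) < 0.5

    def test_permuted_onsets_give_near_zero_betas(self):
        rng = np.random.default_rng(3)
        onsets = list(np.arange(12.0, 230.0, 9.0))
        d = design_with(onsets, dt=0.5)
        lag_resp = np.exp(-0.5 * ((d.lags_s - 5.0) / 1.5) ** 2)
        lag_resp[d.lags_s < 0] = 0.0
        beta_true = np.concatenate([lag_resp, [0.0, 0.0]])
        signal = d.matrix @ beta_true
        wrong = design_with(list(np.sort(rng.uniform(8, 230, len(onsets)))),
                            dt=0.5)
        means = []
        for _ in range(5):
            ts = series(signal + 0.5 * rng.standard_normal(480), dt=0.5)
            hrf = g.fit_glm(ts, wrong)
            means.append(hrf.betas["stim"].mean())
        assert abs(np.mean(means)) < 0.1

    def test_baseline_sd_from_prestimulus_interval(self):
        d = design_with([30.0], dt=1.0, run_length=60.0)
        vals = np.zeros(60)
        vals[24:30] = [1, -1, 1, -1, 1, -1]  # the 6-s pre-stimulus window
        hrf = g.fit_glm(series(vals, dt=1.0), d)
        assert hrf.baseline_sd == pytest.approx(np.std(vals[24:30], ddof=1))

    def test_design_length_mismatch(self):
        d = design_with([30.0], dt=1.0)
        with pytest.raises(InvalidInputError):
            g.fit_glm(series(np.zeros(100), dt=1.0), d)


class TestDspm:
    def test_ratio(self):
        hrf = g.HrfEstimate(lags_s=np.arange(5.0), betas={"a": np.full(5, 2.0)},
                            baseline_sd=1.0, dt=1.0)
        assert np.allclose(g.dspm(hrf), 2.0)

    def test_null_betas(self):
        hrf = g.HrfEstimate(lags_s=np.arange(5.0), betas={"a": np.zeros(5)},
                            baseline_sd=2.0, dt=1.0)
        assert np.allclose(g.dspm(hrf), 0.0)

    def test_scale_invariance(self, rng):
        d = design_with([30.0, 70.0, 110.0], dt=1.0)
        vals = rng.standard_normal(240)
        a = g.dspm(g.fit_glm(series(vals, dt=1.0), d))
        b = g.dspm(g.fit_glm(series(vals * 13.0, dt=1.0), d))
        assert np.allclose(a, b, atol=1e-8)

    def test_zero_baseline_rejected(self):
        hrf = g.HrfEstimate(lags_s=np.arange(5.0), betas={"a": np.ones(5)},
                            baseline_sd=0.0, dt=1.0)
        with pytest.raises(InvalidInputError):
            g.dspm(hrf)

    def test_noise_calibration_sd_near_one(self):
        # baseline SD estimated on one noise realisation should normalise an
        # independent realisation of the same process to unit SD
        rng = np.random.default_rng(5)
        d = design_with([30.0, 90.0, 150.0], dt=1.0)
        sds = []
        for _ in range(500):
            est = g.fit_glm(series(rng.standard_normal(240), dt=1.0), d)
            fresh = rng.standard_normal(100)
            sds.append(np.std(fresh / est.baseline_sd))
        assert 0.8 < np.mean(sds) < 1.2


class TestSelectRois:
    def test_constant_above_threshold(self):
        lags = np.arange(0.0, 10.0, 0.5)
        stat = np.vstack([np.full(lags.size, 5.0), np.full(lags.size, 3.9)])
        mask = g.select_rois(stat, lags)
        assert mask.tolist() == [True, False]

    def test_planted_responders_recovered(self):
        hits = 0
        lags = np.arange(-2.0, 12.0, 0.5)
        sel = (lags >= 4.0) & (lags <= 7.0)
        for i in range(40):
            rng = np.random.default_rng(200 + i)
            stat = rng.standard_normal((10, lags.size))
            planted = [0, 2, 4, 6, 8]
            for loc in planted:
                stat[loc, sel] += 6.0
            mask = g.select_rois(stat, lags)
            hits += set(np.where(mask)[0]) == set(planted)
        assert hits >= 38

    def test_empty_window_rejected(self):
        with pytest.raises(InvalidInputError):
            g.select_rois(np.zeros((2, 10)), np.arange(10.0), window=(7.0, 4.0))


class TestTimingIndices:
    def test_triangular_geometry(self):
        lags = np.arange(0.0, 12.1, 0.1)
        resp = np.interp(lags, [0, 4, 8, 12], [0, 1, 0, 0])
        ti = g.timing_indices_from_curve(lags, resp)
        assert ti.time_to_peak_s == pytest.approx(4.0, abs=1e-9)
        assert ti.time_to_half_s == pytest.approx(2.0, abs=1e-6)
        assert ti.fwhm_s == pytest.approx(4.0, abs=1e-6)
        assert ti.onset_s == pytest.approx(0.4, abs=1e-6)

    def test_amplitude_invariance(self):
        lags = np.arange(0.0, 20.0, 0.1)
        resp = np.exp(-0.5 * ((lags - 5.0) / 1.5) ** 2)
        a = g.timing_indices_from_curve(lags, resp)
        b = g.timing_indices_from_curve(lags, 42.0 * resp)
        for f in ("onset_s", "time_to_half_s", "time_to_peak_s", "fwhm_s"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-9)

    def test_ordering_invariant(self):
        lags = np.arange(0.0, 25.0, 0.1)
        for ttp, width in [(3.6, 1.2), (4.5, 2.0), (6.0, 2.5)]:
            resp = np.exp(-0.5 * ((lags - ttp) / width) ** 2)
            ti = g.timing_indices_from_curve(lags, resp)
            assert ti.onset_s <= ti.time_to_half_s <= ti.time_to_peak_s
            assert ti.fwhm_s > 0

    def test_missing_falling_crossing_raises(self):
        lags = np.arange(0.0, 5.0, 0.1)
        resp = lags.copy()  # monotone rise, never falls below half max
        with pytest.raises(InvalidInputError):
            g.timing_indices_from_curve(lags, resp)

    def test_nonpositive_peak_rejected(self):
        lags = np.arange(0.0, 5.0, 0.1)
        with pytest.raises(InvalidInputError):
            g.timing_indices_from_curve(lags, -np.ones(lags.size))

    def test_from_fitted_estimate(self):
        lags = np.arange(-6.0, 24.0, 0.5)
        resp = np.exp(-0.5 * ((lags - 5.0) / 1.8) ** 2)
        resp[lags < 0] = 0.0
        hrf = g.HrfEstimate(lags_s=lags, betas={"stim": resp},
                            baseline_sd=1.0, dt=0.5)
        ti = g.timing_indices(hrf)
        assert ti.time_to_peak_s == pytest.approx(5.0, abs=0.25)
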