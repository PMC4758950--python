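"""Trace segmentation, per-condition estimation, and curve fits."""

import math

import numpy as np
import pandas as pd
import pytest

import kip2mt
from kip2mt import (
    AssayConfig,
    CouplingParams,
    DynamicsParams,
    MicrotubuleDynamics,
    MotorParams,
    DEFAULT_LENGTH_BINS,
    PhaseSegment,
    UNBOUNDED,
    binned_growth_vs_length,
    catastrophe_length_statistic,
    estimate_dynamics,
    fit_exponential,
    fit_length_law,
    fit_saturation,
    force_displacement,
    generate_assay,
    relative_se,
    segment_trace,
    segments_from_trajectory,
    simulate_coupled,
    substreams,
    tables,
    tubulin_kinetics_regression,
)
from kip2mt.simulate import EventRecord
from kip2mt.synthetic import SampledTrace


def synthetic_trace(path_vertices, frame_s=2.0, noise=0.0, seed=0,
                    mt_id="mt0"):
    """Sample a hand-specified piecewise-linear path (time min, length um)."""
    tv = np.array([p[0] for p in path_vertices])
    lv = np.array([p[1] for p in path_vertices])
    t_s = np.arange(0.0, tv[-1] * 60.0 + 1e-9, frame_s)
    pos = np.interp(t_s / 60.0, tv, lv)
    if noise:
        pos = pos + np.random.default_rng(seed).normal(0, noise, pos.shape)
    return SampledTrace(mt_id, t_s, pos)


class TestSegmentation:
    def test_noiseless_two_phase_trace_exact(self):
        # grow at 0.32 for 5 min, then shrink at 27.6
        peak = 0.32 * 5
        trace = synthetic_trace([(0, 0), (5, peak),
                                 (5 + peak / 27.6, 0.0)], frame_s=1.0)
        segs, events = segment_trace(trace)
        cats = [e for e in events if e.kind == "catastrophe"]
        assert len(cats) == 1
        assert cats[0].time == pytest.approx(5.0, abs=2 / 60)
        growth = [s for s in segs if s.kind == "growth"]
        shrink = [s for s in segs if s.kind == "shrink"]
        assert len(growth) == 1
        assert growth[0].slope == pytest.approx(0.32, rel=1e-6)
        assert len(shrink) == 1
        assert shrink[0].slope == pytest.approx(-27.6, rel=0.05)

    def test_monotone_growth_has_one_segment_no_events(self):
        trace = synthetic_trace([(0, 0), (10, 3.2)])
        segs, events = segment_trace(trace)
        assert len(segs) == 1
        assert segs[0].kind == "growth"
        assert events == []

    def test_rescue_versus_reset_distinction(self):
        # one excursion reversing at 1.5 um (rescue), one reaching the seed
        trace = synthetic_trace([
            (0, 0), (5, 3.0), (5.05, 1.5), (8, 2.5), (8.04, 0.0), (10, 0.6)],
            frame_s=1.0)
        _, events = segment_trace(trace)
        kinds = [e.kind for e in events]
        assert kinds.count("catastrophe") == 2
        assert kinds.count("rescue") == 1
        assert kinds.count("reset_to_seed") == 1
        rescue = next(e for e in events if e.kind == "rescue")
        assert rescue.length_at_event == pytest.approx(1.5, abs=0.1)

    def test_event_recovery_on_noisy_fixture(self, noisy_0nM_assay):
        # the generating event log is the oracle; match within +/-2 frames
        cfg, traces, truths = noisy_0nM_assay
        dt = cfg.frame_interval / 60.0
        n_true = n_match = 0
        for tr, truth in zip(traces, truths):
            _, evs = segment_trace(tr)
            det = [e.time for e in evs if e.kind == "catastrophe"]
            for e in truth.events:
                if e.kind != "catastrophe":
                    continue
                if not 2 * dt < e.time < tr.frame_times[-1] / 60 - 2 * dt:
                    continue
                n_true += 1
                n_match += any(abs(t - e.time) <= 2 * dt + 1e-9 for t in det)
        assert n_true > 80
        # catastrophes shallower than ~2x the localization noise are
        # undetectable in principle; the detector recovers the rest
        assert n_match / n_true >= 0.85

    def test_all_noise_trace_flagged_empty(self):
        rng = np.random.default_rng(0)
        trace = SampledTrace("mt0", np.arange(0, 40.0, 2.0),
                             rng.normal(0, 0.05, 20))
        segs, events = segment_trace(trace)
        # a flat noise trace yields at most a single near-zero-slope phase
        assert len(segs) <= 1
        assert not [e for e in events if e.kind == "catastrophe"]

    def test_too_short_trace_rejected(self):
        trace = SampledTrace("mt0", np.arange(0, 8.0, 2.0), np.zeros(4))
        with pytest.raises(ValueError):
            segment_trace(trace)


class TestEstimateDynamics:
    def test_single_noiseless_phase_slope_exact(self):
        trace = synthetic_trace([(0, 0), (10, 5.0)])
        segs, events = segment_trace(trace)
        est = estimate_dynamics(segs, events, total_time=10.0)
        assert est.growth_rate == pytest.approx(0.5, rel=1e-9)
        assert est.n_growth == 1
        assert est.catastrophe_freq == 0.0
        assert "no_catastrophes" in est.flags

    def test_ratio_identities_to_machine_precision(self, noisy_0nM_assay):
        _, traces, _ = noisy_0nM_assay
        res = MicrotubuleDynamics(traces).fit()
        e = res.estimate
        assert e.catastrophe_distance == pytest.approx(
            e.growth_rate / e.catastrophe_freq, rel=1e-12)
        assert e.rescue_distance == pytest.approx(
            e.shrink_rate / e.rescue_freq, rel=1e-12)

    def test_full_fixture_parameter_recovery(self, noisy_0nM_assay,
                                             porcine_0nM):
        _, traces, _ = noisy_0nM_assay
        e = MicrotubuleDynamics(traces).fit().estimate
        assert abs(e.growth_rate - 0.32) < 3 * e.growth_rate_se
        assert abs(e.catastrophe_freq - 0.166) < 3 * e.catastrophe_freq_se
        assert abs(e.shrink_rate - 27.6) < 3 * e.shrink_rate_se

    def test_denominator_modes_differ_consistently(self, noisy_0nM_assay):
        _, traces, _ = noisy_0nM_assay
        model = MicrotubuleDynamics(traces)
        growth = model.fit(freq_denominator="growth_time").estimate
        total = model.fit(freq_denominator="total_time").estimate
        # growth time <= total observation time, so the frequency is larger
        assert growth.catastrophe_freq >= total.catastrophe_freq
        assert growth.n_catastrophes == total.n_catastrophes

    def test_monotone_pipeline_in_catastrophe_rate(self):
        # raising only the generating catastrophe rate can only shorten
        # the estimated catastrophe distance (5-point ladder)
        dists = []
        for i, f in enumerate((0.05, 0.1, 0.2, 0.4, 0.8)):
            d = DynamicsParams(0.5, f, 27.6, 0.0)
            cfg = AssayConfig(n_microtubules=40, seed=50 + i)
            traces = generate_assay(cfg, d)
            e = MicrotubuleDynamics(traces).fit().estimate
            dists.append(float(e.catastrophe_distance))
        assert all(a > b for a, b in zip(dists, dists[1:]))

    def test_summary_renders(self, noisy_0nM_assay):
        _, traces, _ = noisy_0nM_assay
        text = MicrotubuleDynamics(traces).fit().summary()
        assert "growth rate" in text and "catastrophe freq" in text


class TestBinnedGrowth:
    def test_flat_profile_for_length_independent_growth(self, noisy_0nM_assay):
        _, traces, _ = noisy_0nM_assay
        res = MicrotubuleDynamics(traces).fit()
        prof = binned_growth_vs_length(res.segments).dropna(subset=["mean_rate"])
        centers = 0.5 * (prof["bin_left"] + prof["bin_right"])
        slope = np.polyfit(centers, prof["mean_rate"], 1,
                           w=1 / prof["se"].clip(lower=1e-3))[0]
        # regression of bin means on length: consistent with zero
        assert abs(slope) < 0.02

    def test_single_segment_single_bin(self):
        seg = PhaseSegment("m", 0.0, 1.0, 4.2, 4.8, "growth", 0.6)
        prof = binned_growth_vs_length([seg])
        row = prof[(prof.bin_left == 4.0)].iloc[0]
        assert row.mean_rate == pytest.approx(0.6)
        assert prof.dropna(subset=["mean_rate"]).shape[0] == 1

    def test_coupled_fixture_profile_tracks_generating_law(self):
        d0 = DynamicsParams(0.32, 0.166, 27.6, 0.88)
        m, p = MotorParams(), CouplingParams()
        segs = []
        for rng in substreams(60, 60):
            segs.extend(segments_from_trajectory(
                simulate_coupled(d0, m, p, 5.0, 10.0, rng)))
        prof = binned_growth_vs_length(segs).dropna(subset=["mean_rate"])
        prof = prof[prof.n_segments >= 10]
        assert len(prof) >= 2
        means = prof["mean_rate"].to_numpy()
        assert (np.diff(means) > -0.02).all()  # increasing with length
        assert means.min() >= p.v0 - 1e-9 and means.max() <= p.vmax + 1e-9

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            binned_growth_vs_length([], bin_edges=(0, 2, 1))


class TestCatastropheLengthStatistic:
    def test_hand_countable_single_trajectory(self):
        # grow 0 -> 6 um, one catastrophe at 6: no short-side events,
        # 4 um of short-side distance still logged; long side = 2/1
        segs = [PhaseSegment("m", 0.0, 10.0, 0.0, 6.0, "growth", 0.6)]
        events = [EventRecord(10.0, "catastrophe", 6.0)]
        out = catastrophe_length_statistic(segs, events, cutoff=4.0)
        assert math.isnan(out["short"])
        assert "no_short_catastrophes" in out["flags"]
        assert out["dist_short"] == pytest.approx(4.0)
        assert out["long"] == pytest.approx(2.0)
        assert out["n_long"] == 1

    def test_homogeneous_catastrophe_gives_equal_sides(self):
        # length-independent f: mean catastrophe length equal below and
        # above the cutoff (3 SE)
        d = DynamicsParams(0.6, 0.15, 27.6, 0.0)
        segs, events = [], []
        for rng in substreams(61, 300):
            tr = kip2mt.simulate_dynamic_instability(d, 10.0, rng)
            segs.extend(segments_from_trajectory(tr))
            events.extend(tr.events)
        out = catastrophe_length_statistic(segs, events, cutoff=4.0)
        se = math.hypot(out["short_se"], out["long_se"])
        assert abs(out["short"] - out["long"]) < 3 * se

    def test_coupled_model_protects_long_microtubules(self):
        # with motors, catastrophe distance above the cutoff exceeds the
        # one below it (length-dependent stabilization)
        # 30-min windows: the long side needs time above the cutoff to
        # accumulate events (endpoint-calibrated feedback grows slowly
        # through the mid-concentration range)
        d0 = DynamicsParams(0.32, 0.166, 27.6, 0.88)
        m, p = MotorParams(), CouplingParams()
        segs, events = [], []
        for rng in substreams(62, 120):
            tr = simulate_coupled(d0, m, p, 5.0, 30.0, rng)
            segs.extend(segments_from_trajectory(tr))
            events.extend(tr.events)
        out = catastrophe_length_statistic(segs, events, cutoff=4.0)
        assert out["n_long"] >= 20
        se = math.hypot(out["short_se"], out["long_se"])
        assert out["long"] - out["short"] > 3 * se


class TestFitExponential:
    def test_mle_equals_sample_mean(self):
        rng = np.random.default_rng(70)
        x = rng.exponential(3.6, 10_000)
        fit = fit_exponential(x)
        assert fit["x0"] == pytest.approx(x.mean(), rel=1e-12)
        assert abs(fit["x0"] - 3.6) < 3 * 3.6 / 100.0

    def test_single_sample(self):
        fit = fit_exponential([2.5])
        assert fit["x0"] == 2.5
        assert "single_sample" in fit.flags

    def test_censoring_mle(self):
        # right-censored MLE: total time over uncensored count
        x = np.array([1.0, 2.0, 3.0, 4.0])
        cens = np.array([False, False, True, True])
        fit = fit_exponential(x, cens)
        assert fit["x0"] == pytest.approx(10.0 / 2)

    def test_censoring_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(71)
        x = rng.exponential(4.1, 2000)
        c = rng.exponential(6.0, 2000)
        obs = np.minimum(x, c)
        cens = c < x
        ours = fit_exponential(obs, cens)["x0"]
        ef = lifelines.ExponentialFitter().fit(obs, ~cens)
        assert ours == pytest.approx(ef.lambda_, rel=1e-6)

    def test_all_censored_raises(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, 2.0], [True, True])

    def test_histogram_mode_with_first_bin_exclusion(self):
        rng = np.random.default_rng(72)
        x = rng.exponential(4.1, 20_000)
        # emulate under-detection of short runs, then exclude that bin
        keep = (x > 0.5) | (rng.uniform(size=x.size) > 0.7)
        fit = fit_exponential(x[keep], method="histogram", bins=24,
                              exclude_first_bin=True)
        assert abs(fit["x0"] - 4.1) < 0.4

    def test_recovers_run_length_and_dwell_scales(self):
        rng = np.random.default_rng(73)
        runs = rng.exponential(3.6, 10_000)
        dwells = rng.exponential(44.1, 10_000)
        assert abs(fit_exponential(runs)["x0"] - 3.6) < 3 * 3.6 / 100
        assert abs(fit_exponential(dwells)["x0"] - 44.1) < 3 * 44.1 / 100


class TestFitSaturation:
    def test_exact_model_recovered(self):
        c = np.array([0, 1, 2, 5, 10, 20, 40.0])
        y = 0.3 + (1.0 - 0.3) * c / (7.0 + c)
        fit = fit_saturation(c, y)
        assert fit["half_max_conc"] == pytest.approx(7.0, abs=1e-6)
        assert fit["base"] == pytest.approx(0.3, abs=1e-8)
        assert fit["plateau"] == pytest.approx(1.0, abs=1e-6)

    def test_reference_growth_column_half_max(self):
        tbl = tables.load_table("porcine")
        fit = fit_saturation(tbl["kip2_nM"], tbl["growth_rate"])
        assert 4.0 <= fit["half_max_conc"] <= 10.0

    def test_yeast_column_weakly_identified_but_consistent(self):
        tbl = tables.load_table("yeast")
        fit = fit_saturation(tbl["kip2_nM"], tbl["growth_rate"])
        assert abs(fit["half_max_conc"] - 12.0) <= fit.bse["half_max_conc"]
        assert "weakly_identified" in fit.flags

    def test_needs_baseline_point(self):
        with pytest.raises(ValueError):
            fit_saturation([1, 2, 5, 10], [1, 2, 3, 4])


class TestFitLengthLaw:
    @staticmethod
    def make_bins(v0=0.294, vmax=1.03, A=39.8, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        centers = [1, 2.5, 3.5, 5, 7, 10, 14, 20.0]
        for c in (1, 2, 5, 10, 20, 40.0):
            for L in centers:
                v = v0 + (vmax - v0) * c * L / (A + c * L)
                se = 0.01
                rows.append({"conc": c, "length": L,
                             "rate": v + noise * rng.normal(0, se), "se": se})
        return pd.DataFrame(rows)

    def test_noiseless_bins_exact(self):
        fit = fit_length_law(self.make_bins())
        assert fit["v0"] == pytest.approx(0.294, abs=1e-6)
        assert fit["vmax"] == pytest.approx(1.03, abs=1e-6)
        assert fit["A"] == pytest.approx(39.8, rel=1e-4)
        df = self.make_bins()
        resid = df["rate"] - (fit["v0"] + (fit["vmax"] - fit["v0"])
                              * df.conc * df.length
                              / (fit["A"] + df.conc * df.length))
        assert (resid ** 2).sum() < 1e-16

    def test_noisy_bins_recover_within_3se(self):
        fit = fit_length_law(self.make_bins(noise=1.0, seed=1))
        assert abs(fit["v0"] - 0.294) < 3 * fit.bse["v0"]
        assert abs(fit["vmax"] - 1.03) < 3 * fit.bse["vmax"]
        assert abs(fit["A"] - 39.8) < 3 * fit.bse["A"]

    def test_motor_free_data_flagged_unidentifiable(self):
        df = pd.DataFrame({"conc": 0.0, "length": [1, 2, 3.0],
                           "rate": [0.3, 0.31, 0.29], "se": 0.01})
        fit = fit_length_law(df)
        assert "unidentifiable_no_motor_data" in fit.flags
        assert fit["v0"] == pytest.approx(0.3, abs=0.01)
        assert math.isnan(fit["vmax"])


class TestTubulinKinetics:
    def test_exact_line(self):
        c = np.array([4, 8, 12, 16.0])
        slope_um = kip2mt.slope_from_kon(0.70)
        v = -0.05 + slope_um * c
        tk = tubulin_kinetics_regression(c, v, np.full(4, 0.01))
        assert tk.kon == pytest.approx(0.70, rel=1e-12)
        assert tk.intercept == pytest.approx(-0.05 * 1625 / 60, rel=1e-9)

    def test_noisy_recovery_and_zero_intercept_flag(self):
        rng = np.random.default_rng(80)
        c = np.array([4, 6, 8, 10, 12, 14.0])
        se = np.full(6, 0.02)
        v = kip2mt.slope_from_kon(0.70) * c + rng.normal(0, se)
        tk = tubulin_kinetics_regression(c, v, se)
        assert abs(tk.kon - 0.70) < 3 * tk.kon_se
        assert tk.intercept_consistent_with_zero

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            tubulin_kinetics_regression([1, 2], [0.1, 0.2], [0.01, 0.01])


class TestScalarHelpers:
    @pytest.mark.parametrize("est,n,expect", [
        (0.166, 126, 0.0148), (0.103, 116, 0.0096), (7.0, 1, 7.0)])
    def test_relative_se(self, est, n, expect):
        assert relative_se(est, n) == pytest.approx(expect, abs=5e-4)

    @pytest.mark.parametrize("f,k,expect", [
        (0.5, 0.03, 16.7), (0.0, 0.03, 0.0), (0.81, 0.03, 27.0)])
    def test_force_displacement(self, f, k, expect):
        assert force_displacement(f, k) == pytest.approx(expect, abs=0.05)

    def test_bad_stiffness(self):
        with pytest.raises(ValueError):
            force_displacement(1.0, 0.0)
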