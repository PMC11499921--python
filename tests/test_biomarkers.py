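"""Restitution fitting (Smax), dominant frequency, regional aggregation."""

import numpy as np
import pytest

from latwin.biomarkers import (RegionalSummary, dominant_frequency,
                               df_map, extract_apd_di, fit_restitution,
                               restitution_slope, smax_map)
from latwin.myocyte import ModelError
from latwin.substrate import REGION_NAMES, SheetMesh, segment_regions
from latwin.tissue import SimulationTrace


def square_ap_train(act_times, apd_ms, t_end_ms, dt_ms=1.0,
                    v_rest=-80.0, v_peak=20.0):
    """Rectangular-AP membrane trace with given activations and APDs."""
    t = np.arange(0.0, t_end_ms, dt_ms)
    v = np.full_like(t, v_rest)
    apds = np.broadcast_to(np.asarray(apd_ms, dtype=float),
                           (len(act_times),))
    for a, apd in zip(act_times, apds):
        v[(t >= a) & (t < a + apd)] = v_peak
    return t, v


class TestExtractApdDi:
    def test_constant_train_di_equals_cl_minus_apd(self):
        acts = np.arange(100.0, 4100.0, 500.0)
        t, v = square_ap_train(acts, 200.0, 4500.0)
        pairs, dropped = extract_apd_di(t, v)
        assert dropped == 0
        assert len(pairs) == len(acts) - 1
        # square pulse: APD90 ~ pulse width, DI = CL - APD
        assert np.allclose(pairs[:, 0], 300.0, atol=3.0)
        assert np.allclose(pairs[:, 1], 200.0, atol=3.0)

    def test_missed_beat_doubles_di(self):
        acts = [100.0, 600.0, 1600.0]  # 2:1 block on the second interval
        t, v = square_ap_train(acts, 200.0, 2200.0)
        pairs, _ = extract_apd_di(t, v)
        assert pairs[0, 0] == pytest.approx(300.0, abs=3.0)
        assert pairs[1, 0] == pytest.approx(800.0, abs=3.0)

    def test_ramp_gives_nonincreasing_di(self):
        acts, t0 = [], 100.0
        for cl in (400, 350, 300, 250, 200):
            acts.append(t0)
            t0 += cl
        t, v = square_ap_train(acts, 150.0, 2200.0)
        pairs, _ = extract_apd_di(t, v)
        assert np.all(np.diff(pairs[:, 0]) <= 1e-9)

    def test_fewer_than_two_beats_gives_empty(self):
        t, v = square_ap_train([100.0], 200.0, 600.0)
        pairs, dropped = extract_apd_di(t, v)
        assert pairs.shape == (0, 2)


class TestFitRestitution:
    y0, a1, tau1 = 100.0, 150.0, 60.0

    def model(self, di):
        return self.y0 + self.a1 * (1 - np.exp(-di / self.tau1))

    def test_noise_free_recovery(self):
        di = np.arange(20.0, 401.0, 20.0)
        fit = fit_restitution(np.column_stack([di, self.model(di)]))
        assert fit.fitted
        assert fit.tau1_ms == pytest.approx(self.tau1, rel=0.01)
        assert fit.y0_ms == pytest.approx(self.y0, rel=0.01)
        # closed-form slope at DI_min = 20:
        # (150/60) * exp(-20/60) = 1.791...
        expected = (150.0 / 60.0) * np.exp(-20.0 / 60.0)
        assert expected == pytest.approx(1.791, abs=5e-4)
        assert fit.smax == pytest.approx(expected, rel=0.01)
        assert fit.smax == pytest.approx(
            restitution_slope(fit.a1_ms, fit.tau1_ms, fit.di_min_ms), rel=1e-12)

    def test_flat_pairs_give_zero_slope(self):
        di = np.array([50.0, 120.0, 200.0, 320.0])
        fit = fit_restitution(np.column_stack([di, np.full(4, 180.0)]))
        assert fit.fitted
        assert fit.smax == 0.0

    def test_too_few_or_degenerate_reported_not_zeroed(self):
        fit = fit_restitution(np.array([[100.0, 200.0], [150.0, 210.0]]))
        assert not fit.fitted and fit.reason
        same_di = np.column_stack([np.full(5, 100.0), np.arange(5) + 200.0])
        fit2 = fit_restitution(same_di)
        assert not fit2.fitted and "degenerate" in fit2.reason

    def test_noisy_recovery_median_within_10pct(self, rng):
        di = np.arange(20.0, 401.0, 5.0)
        truth = (self.a1 / self.tau1) * np.exp(-di.min() / self.tau1)
        errs = []
        for _ in range(50):
            apd = self.model(di) * rng.normal(1.0, 0.05, di.size)
            fit = fit_restitution(np.column_stack([di, apd]))
            if fit.fitted:
                errs.append(abs(fit.smax - truth) / truth)
        assert np.median(errs) < 0.10


class TestDominantFrequency:
    @pytest.mark.parametrize("f0", [1.5, 6.0, 13.0, 19.5])
    def test_pure_tone_recovered_within_one_bin(self, f0):
        t = np.arange(0.0, 6000.0, 1.0)  # 6 s at 1 kHz
        v = np.sin(2 * np.pi * f0 * t / 1000.0)
        dfv = dominant_frequency(t, v, window_s=(0, 6))
        assert dfv.found
        assert abs(dfv.df_hz - f0) <= 1.0 / 6.0  # one natural bin

    def test_dominant_component_wins(self):
        t = np.arange(0.0, 6000.0, 1.0)
        v = np.sin(2 * np.pi * 4 * t / 1000) + 0.3 * np.sin(2 * np.pi * 8 * t / 1000)
        dfv = dominant_frequency(t, v, window_s=(0, 6))
        assert dfv.df_hz == pytest.approx(4.0, abs=1 / 6)

    def test_constant_signal_flagged(self):
        t = np.arange(0.0, 6000.0, 1.0)
        dfv = dominant_frequency(t, np.full_like(t, -80.0), window_s=(0, 6))
        assert not dfv.found

    def test_uncovered_window_rejected(self):
        t = np.arange(0.0, 3000.0, 1.0)
        with pytest.raises(ModelError, match="does not cover"):
            dominant_frequency(t, np.sin(t), window_s=(17, 23))


def periodic_trace(mesh, cl_by_node_ms, t_end_ms, record_dt_ms=2.0):
    """Trace whose node k shows square APs at cycle length cl_by_node[k]."""
    times = np.arange(0.0, t_end_ms, record_dt_ms)
    frames = np.full((times.size, mesh.n_nodes), -80.0, dtype=np.float32)
    act = np.full((mesh.n_nodes, 256), np.nan)
    counts = np.zeros(mesh.n_nodes, dtype=np.int64)
    for k, cl in enumerate(cl_by_node_ms):
        starts = np.arange(10.0, t_end_ms, cl)
        for s in starts:
            frames[(times >= s) & (times < s + 0.4 * cl), k] = 20.0
        counts[k] = min(len(starts), 256)
        act[k, :counts[k]] = starts[:counts[k]]
    return SimulationTrace(frame_times_ms=times, frames=frames,
                           act_times=act, act_counts=counts,
                           dt_ms=0.1, t_end_ms=t_end_ms)


class TestMaps:
    mesh = SheetMesh(6, 4, 1.0)

    def test_df_map_reciprocal_of_cl_and_uniform_delta(self):
        labels = segment_regions(self.mesh)
        cls = np.full(self.mesh.n_nodes, 250.0)
        trace = periodic_trace(self.mesh, cls, 7000.0)
        df, summ = df_map(trace, labels, window_s=(1.0, 7.0))
        assert np.nanmedian(df) == pytest.approx(4.0, abs=0.2)
        assert summ.delta_regional == pytest.approx(0.0, abs=0.2)

    def test_regional_means_match_brute_force(self):
        labels = segment_regions(self.mesh)
        rng = np.random.default_rng(3)
        values = rng.uniform(0.5, 2.5, self.mesh.n_nodes)
        summ = RegionalSummary.from_values(values, labels)
        for r, name in enumerate(REGION_NAMES):
            assert summ.region_means[name] == pytest.approx(
                values[labels == r].mean(), rel=1e-12)
        assert summ.highest >= summ.mean >= summ.lowest
        assert summ.delta_regional == pytest.approx(
            summ.highest - summ.lowest, rel=1e-12)

    def test_count_weighted_region_mean_equals_global_mean(self):
        labels = segment_regions(self.mesh)
        values = np.random.default_rng(4).uniform(0, 3, self.mesh.n_nodes)
        summ = RegionalSummary.from_values(values, labels)
        weighted = sum(summ.region_means[n] * summ.region_counts[n]
                       for n in REGION_NAMES) / sum(summ.region_counts.values())
        assert weighted == pytest.approx(values.mean(), rel=1e-12)

    def test_smax_map_on_synthetic_ramp(self):
        labels = segment_regions(self.mesh)
        times = np.arange(0.0, 3000.0, 1.0)
        frames = np.full((times.size, self.mesh.n_nodes), -80.0,
                         dtype=np.float32)
        # restitution-shaped APDs: APD = 80 + 120 (1 - exp(-DI/80))
        acts, t0 = [], 50.0
        apd_prev = 200.0
        for cl in (400, 350, 300, 260, 230, 200, 180, 160):
            acts.append((t0, apd_prev))
            di = cl - apd_prev
            apd_prev = 80.0 + 120.0 * (1 - np.exp(-max(di, 1) / 80.0))
            t0 += cl
        for k in range(self.mesh.n_nodes):
            for a, apd in acts:
                frames[(times >= a) & (times < a + apd), k] = 20.0
        trace = SimulationTrace(frame_times_ms=times, frames=frames,
                                act_times=np.full((self.mesh.n_nodes, 8), np.nan),
                                act_counts=np.zeros(self.mesh.n_nodes, dtype=np.int64),
                                dt_ms=0.1, t_end_ms=3000.0)
        smax, summ = smax_map(trace, labels)
        assert summ.n_valid == self.mesh.n_nodes
        # homogeneous tissue: negligible inter-node dispersion
        assert np.nanstd(smax) / np.nanmean(smax) < 0.2
        assert summ.delta_regional >= 0
        assert summ.delta_regional == pytest.approx(0.0, abs=1e-6)

    def test_unfittable_nodes_flag_low_confidence(self):
        labels = segment_regions(self.mesh)
        times = np.arange(0.0, 1000.0, 1.0)
        frames = np.full((times.size, self.mesh.n_nodes), -80.0,
                         dtype=np.float32)  # no beats anywhere
        trace = SimulationTrace(frame_times_ms=times, frames=frames,
                                act_times=np.full((self.mesh.n_nodes, 4), np.nan),
                                act_counts=np.zeros(self.mesh.n_nodes, dtype=np.int64),
                                dt_ms=0.1, t_end_ms=1000.0)
        smax, summ = smax_map(trace, labels)
        assert np.all(np.isnan(smax))
        assert summ.low_confidence
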