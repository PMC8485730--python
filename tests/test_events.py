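"""Tests of event detection, velocity-binned rates, activation counting and
the nonparametric statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from stimscope.events import (
    DEFAULT_VELOCITY_EDGES,
    EventRaster,
    bin_rates_by_velocity,
    count_activated_cells,
    detect_events,
    dunn_posthoc,
    event_rate_timeseries,
    fit_velocity_gain,
    kruskal_wallis,
    normalize_to_rest,
    rest_mean_rate,
    suppression_ratio,
)
from stimscope.sim import (
    BehaviorTrace,
    SimConfig,
    StimEpoch,
    StimSchedule,
    build_stim_schedule,
    convolve_calcium,
    generate_footprints,
    generate_spike_trains,
    generate_velocity_trace,
    simulate_session,
)


class TestDetectEvents:
    def test_zero_traces_no_events(self):
        raster = detect_events(np.zeros((3, 100)), 20.0)
        assert raster.events.sum() == 0

    def test_single_transient_gives_one_event_at_peak(self):
        cfg = SimConfig(fov_px=(16, 16), n_cells=0)
        ev = np.zeros((1, 400))
        ev[0, 100] = 1
        traces = convolve_calcium(ev, cfg)
        raster = detect_events(traces, cfg.frame_rate_hz)
        hits = np.flatnonzero(raster.events[0])
        assert len(hits) == 1
        assert abs(hits[0] - (100 + np.argmax(traces[0, 100:120]))) <= 1

    def test_constant_trace_yields_nothing(self):
        raster = detect_events(np.full((1, 50), 3.3), 20.0)
        assert raster.events.sum() == 0

    def test_recovers_most_simulated_events(self):
        cfg = SimConfig(fov_px=(32, 32), n_cells=5, cell_radius_px=(2, 3),
                        baseline_rate_hz=0.15, seed=2)
        fp = generate_footprints(cfg)
        beh = generate_velocity_trace(6000, cfg)
        ev = generate_spike_trains(beh, None, fp, cfg)
        traces = convolve_calcium(ev, cfg)
        raster = detect_events(traces, cfg.frame_rate_hz)
        # events are marked at the transient peak, which lags the spike by
        # the kernel rise time
        from stimscope.sim import calcium_kernel
        delay = int(np.argmax(calcium_kernel(cfg)))
        hit = 0
        total = 0
        for i in range(5):
            true_frames = np.flatnonzero(ev[i])
            det = np.flatnonzero(raster.events[i])
            total += len(true_frames)
            for t in true_frames:
                if det.size and np.abs(det - (t + delay)).min() <= 2:
                    hit += 1
        # refractoriness merges near-coincident events, so recovery is
        # checked against isolated-event expectations
        assert hit / total >= 0.8


class TestRateSeries:
    def test_empty_raster(self):
        rate = event_rate_timeseries(EventRaster(np.zeros((0, 30)), 20.0))
        np.testing.assert_array_equal(rate, 0)

    def test_sum_across_cells(self):
        ev = np.zeros((3, 10), dtype=int)
        ev[:, 7] = 1
        rate = event_rate_timeseries(EventRaster(ev, 20.0))
        assert rate[7] == 3 and rate.sum() == 3

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(0)
        ev = rng.poisson(0.2, size=(6, 50))
        r1 = event_rate_timeseries(EventRaster(ev, 20.0))
        r2 = event_rate_timeseries(EventRaster(ev[::-1], 20.0))
        np.testing.assert_array_equal(r1, r2)


class TestVelocityBinning:
    def test_all_rest(self):
        beh = BehaviorTrace(np.zeros(50), 20.0)
        binned = bin_rates_by_velocity(np.ones(50), beh)
        assert binned.n_frames[0] == 50
        assert binned.n_frames[1:].sum() == 0

    def test_half_open_convention_at_rest_boundary(self):
        beh = BehaviorTrace(np.array([0.5]), 20.0)
        binned = bin_rates_by_velocity(np.ones(1), beh)
        assert binned.n_frames[0] == 0
        assert binned.n_frames[1] == 1

    def test_brute_force_oracle_on_hand_built_series(self):
        v = np.array([0.0, 0.4, 0.6, 1.2, 2.0, 2.4, 3.0, 6.0, 11.0, 0.1])
        r = np.arange(10.0)
        beh = BehaviorTrace(v, 20.0)
        binned = bin_rates_by_velocity(r, beh, edges=(0.5, 2.5, 10.0))
        # brute force: rest [0,.5): frames 0,1,9 ; [.5,2.5): 2,3,4,5 ;
        # [2.5,10): 6,7 ; overflow: 8
        expect = [np.mean([0, 1, 9]), np.mean([2, 3, 4, 5]),
                  np.mean([6, 7]), 8.0]
        np.testing.assert_allclose(binned.rate, expect)
        np.testing.assert_array_equal(binned.n_frames, [3, 4, 2, 1])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bin_rates_by_velocity(np.ones(5), BehaviorTrace(np.zeros(4), 20.0))


class TestNormalization:
    def test_rest_only_data_normalizes_to_exactly_one(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 0.49, size=200)
        rate = rng.poisson(2.0, size=200).astype(float)
        beh = BehaviorTrace(v, 20.0)
        rest = rest_mean_rate(rate, beh)
        binned = normalize_to_rest(bin_rates_by_velocity(rate, beh), rest)
        assert binned.rate[0] == 1.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 8, size=500)
        rate = rng.poisson(1.0, size=500).astype(float)
        beh = BehaviorTrace(v, 20.0)
        b1 = normalize_to_rest(bin_rates_by_velocity(rate, beh),
                               rest_mean_rate(rate, beh))
        b2 = normalize_to_rest(bin_rates_by_velocity(2 * rate, beh),
                               rest_mean_rate(2 * rate, beh))
        np.testing.assert_allclose(b1.rate, b2.rate)

    def test_nonpositive_rest_mean_rejected(self):
        binned = bin_rates_by_velocity(np.ones(5),
                                       BehaviorTrace(np.zeros(5), 20.0))
        with pytest.raises(ValueError):
            normalize_to_rest(binned, 0.0)

    def test_velocity_gain_recovery_from_rate_law(self):
        # lambda(v) = lambda0 (1 + beta v): the normalized binned curve must
        # recover beta via slope/intercept within 20%
        beta = 0.5
        cfg = SimConfig(fov_px=(64, 64), n_cells=50, cell_radius_px=(2, 3),
                        baseline_rate_hz=0.2, velocity_gain=beta, seed=6)
        T = 30000
        fp = generate_footprints(cfg)
        beh = generate_velocity_trace(T, cfg)
        ev = generate_spike_trains(beh, None, fp, cfg)
        rate = ev.sum(axis=0).astype(float)
        binned = normalize_to_rest(bin_rates_by_velocity(rate, beh),
                                   rest_mean_rate(rate, beh))
        est = fit_velocity_gain(binned)
        assert abs(est - beta) / beta <= 0.2


class TestActivation:
    def _schedule(self, n_epochs=3, length=100, gap=200):
        eps = []
        start = gap
        freqs = [30.0, 80.0, 130.0]
        for k in range(n_epochs):
            eps.append(StimEpoch(start, start + length, freqs[k % 3], 30, 140))
            start += length + gap
        return StimSchedule(eps, "anesthetized")

    def test_zero_traces_zero_counts(self):
        sched = self._schedule()
        counts = count_activated_cells(np.zeros((4, 1200)), sched)
        assert (counts["n_activated"] == 0).all()

    def test_single_injected_transient_detected_once(self):
        sched = self._schedule()
        traces = np.random.default_rng(3).normal(0, 0.01, size=(2, 1200))
        ep = sched.epochs[1]
        traces[0, ep.start:ep.stop] += 1.0
        counts = count_activated_cells(traces, sched)
        assert counts.loc[1, "n_activated"] == 1
        assert counts.loc[0, "n_activated"] == 0
        assert counts.loc[2, "n_activated"] == 0

    def test_epoch_without_baseline_window_is_skipped(self):
        sched = StimSchedule([StimEpoch(10, 60, 130.0, 30, 140)], "anesthetized")
        with pytest.warns(UserWarning, match="baseline"):
            counts = count_activated_cells(np.zeros((1, 100)), sched)
        assert counts.empty

    def test_frequency_ordering_of_mean_counts(self):
        # recruit_prob {30: .1, 80: .4, 130: .5} with 50 cells: activated-cell
        # counts must order 30 < 80 and 30 < 130 on average
        per_freq = {30.0: [], 80.0: [], 130.0: []}
        for seed in range(8):
            cfg = SimConfig(fov_px=(80, 80), n_cells=50, cell_radius_px=(2, 3),
                            baseline_rate_hz=0.0, seed=seed)
            T = 3000
            sched = build_stim_schedule("anesthetized", T, 20.0, gap_s=5.0)
            fp = generate_footprints(cfg)
            beh = generate_velocity_trace(T, cfg)
            ev = generate_spike_trains(beh, sched, fp, cfg)
            traces = convolve_calcium(ev, cfg)
            counts = count_activated_cells(traces, sched)
            for _, row in counts.iterrows():
                per_freq[row.frequency_hz].append(row.n_activated)
        m = {f: np.mean(c) for f, c in per_freq.items()}
        assert m[30.0] < m[80.0]
        assert m[30.0] < m[130.0]


def _dunn_oracle(groups, adjust="holm"):
    """Naive reference implementation of Dunn's test, written directly from
    the rank-sum formula with explicit loops."""
    pooled = []
    for gi, g in enumerate(groups):
        pooled.extend((float(x), gi) for x in g)
    values = sorted(x for x, _ in pooled)
    # mid-ranks with ties
    rank_of = {}
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        for k in range(i, j):
            rank_of.setdefault(values[i], (i + j + 1) / 2.0)
        i = j
    N = len(values)
    tie = 0.0
    for val in set(values):
        t = values.count(val)
        tie += t**3 - t
    var = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    mean_ranks = []
    for g in groups:
        mean_ranks.append(sum(rank_of[float(x)] for x in g) / len(g))
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = (var * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))) ** 0.5
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * sps.norm.sf(abs(z))
            out.append([i, j, z, p])
    # Holm adjustment
    order = sorted(range(len(out)), key=lambda k: out[k][3])
    running = 0.0
    m = len(out)
    for rank, k in enumerate(order):
        running = max(running, (m - rank) * out[k][3])
        out[k].append(min(1.0, running))
    return out


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_ranked_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_within_group_permutation_invariance(self):
        a, b = [3.0, 1.0, 7.0], [2.0, 9.0, 4.0, 5.0]
        r1 = kruskal_wallis([a, b])
        r2 = kruskal_wallis([a[::-1], b[::-1]])
        assert r1.statistic == r2.statistic

    def test_matches_scipy_on_random_datasets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 5)
            groups = [rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
                      for _ in range(k)]
            if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                continue
            res = kruskal_wallis(groups)
            H_ref, p_ref = sps.kruskal(*groups)
            assert abs(res.statistic - H_ref) <= 1e-8
            assert abs(res.p_value - p_ref) <= 1e-8

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])


class TestDunn:
    def test_identical_groups_z_zero(self):
        res = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res[0]["z"] == pytest.approx(0.0, abs=1e-12)
        assert res[0]["p_adjusted"] == pytest.approx(1.0)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(size=8), rng.normal(size=6), rng.normal(1, size=7)]
        for row in dunn_posthoc(groups):
            assert row["p_adjusted"] >= row["p_raw"] - 1e-15

    def test_large_shift_detected_only_for_shifted_pair(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        c = rng.normal(10, 1, 20)
        res = {(r["group_a"], r["group_b"]): r for r in dunn_posthoc([a, b, c])}
        assert res[(0, 2)]["p_adjusted"] < 0.05
        assert res[(1, 2)]["p_adjusted"] < 0.05
        assert res[(0, 1)]["p_adjusted"] >= 0.05

    def test_matches_naive_oracle_on_random_datasets(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 6, size=int(rng.integers(3, 10))).astype(float)
                      for _ in range(k)]
            res = dunn_posthoc(groups)
            ref = _dunn_oracle(groups)
            for row, (i, j, z, p, p_adj) in zip(res, ref):
                assert (row["group_a"], row["group_b"]) == (i, j)
                assert abs(row["z"] - z) <= 1e-8
                assert abs(row["p_raw"] - p) <= 1e-8
                assert abs(row["p_adjusted"] - p_adj) <= 1e-8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([[1.0], []])


class TestSuppressionRatio:
    def test_recovers_simulated_suppression_factor(self):
        cfg = SimConfig(fov_px=(64, 64), n_cells=80, cell_radius_px=(2, 3),
                        baseline_rate_hz=0.3, velocity_gain=0.5,
                        suppression_factor=0.6, seed=17)
        T = 30000
        sched = build_stim_schedule("awake", T, cfg.frame_rate_hz,
                                    block_s=150.0)
        fp = generate_footprints(cfg)
        beh = generate_velocity_trace(T, cfg)
        ev = generate_spike_trains(beh, sched, fp, cfg)
        rate = ev.sum(axis=0).astype(float)
        ratio = suppression_ratio(rate, beh, sched)
        assert abs(ratio - 0.6) / 0.6 <= 0.2
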