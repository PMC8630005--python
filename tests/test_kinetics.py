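"""Synchronicity pairing, dwell extraction, exponential fits, rate constants."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

import smpet
from smpet.config import AnalysisConfig, SimulationConfig
from smpet.kinetics import (BLEACH_CANDIDATE, NON_SYNCHRONOUS, SYNCHRONOUS,
                            synchronicity_counts)
from smpet.simulate import CLOSED, OPEN
from smpet.stepdetect import FLUORESCENT, QUENCHED, IdealizedTrace, Step


def step(frame, direction, amplitude=None):
    if amplitude is None:
        amplitude = -100.0 if direction == "down" else 100.0
    return Step(frame=frame, direction=direction, amplitude=amplitude)


def ideal_from_steps(steps, n_frames, start="fluorescent"):
    labels = np.empty(n_frames, dtype=object)
    level = start
    last = 0
    for s in steps:
        labels[last:s.frame] = level
        level = QUENCHED if s.direction == "down" else FLUORESCENT
        last = s.frame
    labels[last:] = level
    return IdealizedTrace(labels=labels, steps=list(steps), single_level=False)


class TestPairSynchronous:
    def test_within_window_is_synchronous(self):
        # extra recovery steps keep the quenches non-terminal
        g = [step(100, "down"), step(150, "up")]
        r = [step(104, "down"), step(152, "up")]
        events = smpet.pair_synchronous(g, r, AnalysisConfig(sync_window_frames=6))
        n_s, n_ns = synchronicity_counts(events)
        assert (n_s, n_ns) == (2, 0)
        quench = [e for e in events if e.direction == "quench"]
        assert {e.partner_frame for e in quench} == {100, 104}

    def test_beyond_window_is_non_synchronous(self):
        g = [step(100, "down"), step(150, "up")]
        r = [step(110, "down"), step(160, "up")]
        events = smpet.pair_synchronous(g, r, AnalysisConfig(sync_window_frames=6))
        quench = [e for e in events if e.direction == "quench"]
        assert all(e.klass == NON_SYNCHRONOUS for e in quench)

    def test_direction_mismatch_not_paired(self):
        g = [step(100, "down"), step(130, "up")]
        r = [step(102, "up"), step(131, "down"), step(160, "up")]
        events = smpet.pair_synchronous(g, r, AnalysisConfig(sync_window_frames=6))
        down_g = [e for e in events if e.channel == "green" and e.direction == "quench"]
        assert down_g[0].klass == NON_SYNCHRONOUS

    def test_terminal_quench_is_bleach_candidate(self):
        g = [step(60, "down"), step(90, "up"), step(200, "down")]
        r = [step(60, "down"), step(90, "up")]
        events = smpet.pair_synchronous(g, r, AnalysisConfig())
        last = [e for e in events if e.frame == 200]
        assert last[0].klass == BLEACH_CANDIDATE

    def test_simultaneous_terminal_quench_pair_is_bleach(self):
        g = [step(60, "down"), step(90, "up"), step(200, "down")]
        r = [step(61, "down"), step(91, "up"), step(202, "down")]
        events = smpet.pair_synchronous(g, r, AnalysisConfig())
        n_s, n_ns = synchronicity_counts(events)
        assert n_s == 2 and n_ns == 0
        assert sum(e.klass == BLEACH_CANDIDATE for e in events) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_min_delta_assignment(self, seed):
        # greedy matching equals the optimal assignment on tiny instances
        rng = np.random.default_rng(seed)
        n_g, n_r = rng.integers(1, 5), rng.integers(1, 5)
        gf = np.sort(rng.choice(np.arange(20, 400, 4), n_g, replace=False))
        rf = np.sort(rng.choice(np.arange(20, 400, 4), n_r, replace=False))
        g = [step(int(f), "down") for f in gf] + [step(500, "up")]
        r = [step(int(f), "down") for f in rf] + [step(500, "up")]
        window = 6
        events = smpet.pair_synchronous(g, r, AnalysisConfig(sync_window_frames=window))
        n_s, _ = synchronicity_counts(events)
        # brute force over one-to-one assignments of the quench steps
        best = 0
        for k in range(min(n_g, n_r), 0, -1):
            ok = False
            for rows in itertools.combinations(range(n_g), k):
                for cols in itertools.permutations(range(n_r), k):
                    if all(abs(int(gf[i]) - int(rf[j])) <= window
                           for i, j in zip(rows, cols)):
                        ok = True
                        break
                if ok:
                    break
            if ok:
                best = k
                break
        assert n_s - 1 == best  # minus the paired trailing recoveries


class TestExtractDwells:
    def test_closed_dwell_arithmetic(self):
        steps = [step(100, "down"), step(140, "up")]
        ideal = {"green": ideal_from_steps(steps, 300)}
        events = [smpet.TransitionEvent(0, "green", 100, "quench", SYNCHRONOUS),
                  smpet.TransitionEvent(0, "green", 140, "recovery", SYNCHRONOUS)]
        cfg = AnalysisConfig(frame_interval_s=0.3)
        dwells = smpet.extract_dwells(ideal, events, cfg, molecule_id=0)
        closed = [d for d in dwells if d.state == "closed" and not d.censored]
        assert len(closed) == 1
        assert closed[0].duration_s == pytest.approx(12.0)
        assert closed[0].provenance == SYNCHRONOUS

    def test_single_step_gives_no_uncensored_dwells(self):
        ideal = {"green": ideal_from_steps([step(100, "down")], 300)}
        dwells = smpet.extract_dwells(ideal, [], AnalysisConfig())
        assert all(d.censored for d in dwells)

    def test_bleach_tail_censored(self):
        steps = [step(50, "down"), step(80, "up"), step(200, "down")]
        ideal = {"green": ideal_from_steps(steps, 300)}
        events = [smpet.TransitionEvent(0, "green", 200, "quench", BLEACH_CANDIDATE)]
        dwells = smpet.extract_dwells(ideal, events, AnalysisConfig(), 0)
        open_after = [d for d in dwells if d.state == "open" and d.duration_s == pytest.approx(0.3 * 120)]
        assert open_after and open_after[0].right_censored

    def test_overlapping_steps_rejected(self):
        bad = IdealizedTrace(labels=np.full(100, FLUORESCENT, dtype=object),
                             steps=[step(50, "down"), step(50, "up")],
                             single_level=False)
        with pytest.raises(ValueError, match="overlapping"):
            smpet.extract_dwells({"green": bad}, [], AnalysisConfig())

    def test_simulated_closed_dwell_mean(self):
        # ground-truth trajectories -> idealizations without detection noise
        cfg = SimulationConfig(n_molecules=120, duration_s=540.0,
                               frame_interval_s=0.3, k_close=2.0, k_open=5.0,
                               p_uncoupled=0.0, seed=13)
        trajs = smpet.simulate_clamp_trajectory(cfg)
        acfg = AnalysisConfig(frame_interval_s=0.3)
        durations = []
        for traj in trajs:
            ideal = {}
            for ch, s in traj.states.items():
                changes = (np.nonzero(np.diff(s))[0] + 1).tolist()
                steps = [step(f, "down" if s[f] == CLOSED else "up") for f in changes]
                ideal[ch] = ideal_from_steps(steps, s.size,
                                             start="fluorescent" if s[0] == OPEN else "quenched")
            for d in smpet.extract_dwells(ideal, [], acfg, traj.molecule_id):
                if d.state == "closed" and not d.censored:
                    durations.append(d.duration_s)
        assert len(durations) >= 800
        assert abs(np.mean(durations) - 12.0) < 1.2


class TestCumulativeSum:
    def test_basic_curve(self):
        x, y = smpet.cumulative_sum([3.0, 1.0, 2.0])
        np.testing.assert_array_equal(x, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(y, [1, 2, 3])

    def test_identical_durations_single_riser(self):
        x, y = smpet.cumulative_sum([5.0] * 7)
        assert np.all(x == 5.0) and y[-1] == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            smpet.cumulative_sum([])

    def test_converges_to_exponential_cdf(self):
        # Dvoretzky-Kiefer-Wolfowitz band at alpha = 0.01
        rng = np.random.default_rng(5)
        tau, n = 10.0, 2000
        x, y = smpet.cumulative_sum(rng.exponential(tau, n))
        sup = np.max(np.abs(y / n - (1.0 - np.exp(-x / tau))))
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))
        assert sup <= eps


class TestExponentialFit:
    def test_exact_mono_cdf_recovered(self):
        tau = 10.0
        # curve sampled deep into the tail so the final count is the true total
        t = np.linspace(0.05, 250, 400)
        n_tot = 500.0
        y = n_tot * (1 - np.exp(-t / tau))
        fit = smpet.fit_exponential_cdf(t, y, model_selection="bic")
        assert fit.n_components == 1
        assert fit.taus[0] == pytest.approx(tau, rel=1e-6)

    def test_mono_sample_recovery(self):
        rng = np.random.default_rng(7)
        fit = smpet.fit_exponential_cdf(rng.exponential(12.0, 1000))
        assert fit.n_components == 1
        assert 11.0 <= fit.taus[0] <= 13.0

    def test_mixture_recovery_selects_bi(self):
        rng = np.random.default_rng(9)
        d = np.concatenate([rng.exponential(5.0, 1000), rng.exponential(60.0, 1000)])
        fit = smpet.fit_exponential_cdf(d)
        assert fit.n_components == 2
        assert abs(fit.amplitudes[0] - 0.5) <= 0.1
        assert abs(fit.taus[0] - 5.0) / 5.0 <= 0.25
        assert abs(fit.taus[1] - 60.0) / 60.0 <= 0.25

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            smpet.fit_exponential_cdf([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 25"):
            smpet.fit_exponential_cdf(list(range(1, 13)), model_selection="fixed_bi")

    def test_degenerate_durations_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            smpet.fit_exponential_cdf([4.0] * 50)


class TestMeanRate:
    def mono(self, tau, unit="min"):
        return smpet.ExponentialFit(components=[(1.0, tau)], n_components=1,
                                    rss=0.0, bic=0.0, n_points=100, time_unit=unit)

    def test_mono_formula(self):
        assert smpet.mean_rate(self.mono(0.2)) == pytest.approx(5.0)

    def test_weighted_formula(self):
        fit = smpet.ExponentialFit(components=[(0.6, 0.5), (0.4, 2.0)],
                                   n_components=2, rss=0.0, bic=0.0,
                                   n_points=100, time_unit="min")
        assert smpet.mean_rate(fit) == pytest.approx(1.0 / 1.1, rel=1e-6)

    def test_reorder_invariance(self):
        a = smpet.ExponentialFit([(0.6, 0.5), (0.4, 2.0)], 2, 0.0, 0.0, 100, "min")
        b = smpet.ExponentialFit([(0.4, 2.0), (0.6, 0.5)], 2, 0.0, 0.0, 100, "min")
        assert smpet.mean_rate(a) == pytest.approx(smpet.mean_rate(b))

    def test_unit_conversion_consistency(self):
        # 12 s dwells: 5 /min either way
        assert smpet.mean_rate(self.mono(12.0, unit="s")) == pytest.approx(5.0)
        assert smpet.mean_rate(self.mono(0.2, unit="min")) == pytest.approx(5.0)

    def test_unnormalized_amplitudes_rejected(self):
        bad = smpet.ExponentialFit([(0.5, 1.0), (0.3, 2.0)], 2, 0.0, 0.0, 100, "min")
        with pytest.raises(ValueError, match="normalized"):
            smpet.mean_rate(bad)


class TestSynchronicityCounts:
    @pytest.mark.parametrize("n_s,n_ns,ratio,of_total", [
        (322, 57, 17.7, 15.0),
        (422, 62, 14.7, 12.8),
        (516, 55, 10.7, 9.6),
        (100, 0, 0.0, 0.0),
    ])
    def test_both_conventions(self, n_s, n_ns, ratio, of_total):
        pct = smpet.percent_non_synchronous(n_s, n_ns)
        assert pct["ratio_to_synchronous"] == pytest.approx(ratio, abs=0.05)
        assert pct["fraction_of_total"] == pytest.approx(of_total, abs=0.05)


class TestIdentifyPetEvents:
    def one_colour(self, steps, n_frames=900):
        return {0: ideal_from_steps(steps, n_frames)}

    def test_quench_with_post_o2_recovery_confirmed(self):
        ideal = self.one_colour([step(300, "down"), step(650, "up")])
        df = smpet.identify_pet_events(ideal, 600.0, 1.0)
        quench = df[df.direction == "quench"].iloc[0]
        assert quench.status == "pet_confirmed"

    def test_quench_without_recovery_unconfirmed(self):
        ideal = self.one_colour([step(300, "down")])
        df = smpet.identify_pet_events(ideal, 600.0, 1.0)
        assert df[df.direction == "quench"].iloc[0].status == "unconfirmed"

    def test_pre_o2_recovery_flagged_anomalous(self):
        ideal = self.one_colour([step(300, "down"), step(500, "up")])
        df = smpet.identify_pet_events(ideal, 600.0, 1.0)
        assert df[df.direction == "recovery"].iloc[0].status == "anomalous_recovery"
        assert df[df.direction == "quench"].iloc[0].status == "unconfirmed"

    def test_o2_outside_span_rejected(self):
        ideal = self.one_colour([step(300, "down")], n_frames=500)
        with pytest.raises(ValueError, match="outside"):
            smpet.identify_pet_events(ideal, 600.0, 1.0)


class TestBulkDecay:
    def biexp(self, t, a=(0.7, 0.3), tau=(2.0, 15.0), i_inf=100.0, amp=900.0):
        return i_inf + amp * (a[0] * np.exp(-t / tau[0]) + a[1] * np.exp(-t / tau[1]))

    def test_noiseless_parameters_recovered(self):
        t = np.linspace(0, 60, 400)
        fit, rate = smpet.fit_bulk_decay(t, self.biexp(t), time_unit="min")
        np.testing.assert_allclose(fit.amplitudes, [0.7, 0.3], rtol=1e-4)
        np.testing.assert_allclose(fit.taus, [2.0, 15.0], rtol=1e-4)
        assert rate == pytest.approx(1.0 / (0.7 * 2 + 0.3 * 15), rel=1e-4)

    def test_noisy_mean_rate_within_5_percent(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 60, 400)
        y = self.biexp(t)
        y = y + rng.normal(0, 0.01 * y[0], t.size)
        _, rate = smpet.fit_bulk_decay(t, y, time_unit="min")
        assert abs(rate - 0.169) / 0.169 <= 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="decay"):
            smpet.fit_bulk_decay(np.linspace(0, 10, 50), np.full(50, 3.0))

    def test_rising_series_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(ValueError, match="decay"):
            smpet.fit_bulk_decay(t, 100.0 + 10.0 * t)


class TestDeltaDeltaG:
    def test_twofold_at_298K(self):
        assert smpet.delta_delta_g(2.0, 298.15) == pytest.approx(0.41, abs=0.005)

    def test_unit_ratio_is_zero(self):
        assert smpet.delta_delta_g(1.0) == 0.0

    def test_ratio_e_gives_rt(self):
        assert smpet.delta_delta_g(np.e, 298.15) == pytest.approx(0.593, abs=0.001)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            smpet.delta_delta_g(0.0)
        with pytest.raises(ValueError):
            smpet.delta_delta_g(2.0, temperature_K=-1.0)
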