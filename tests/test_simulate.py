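"""Synthetic cohort generator: determinism, degenerate strategies, analytic
expectations, and loss-driven QC removal."""

import filecmp

import numpy as np
import pytest

import speechgaze.simulate as S
from speechgaze.gaze_io import TrialEvents, segment_windows
from speechgaze.metrics import Segment, social_tuning_ratio, trial_dwell_profile
from speechgaze.qc import onscreen_fraction

EV = S.DEFAULT_EVENTS[1]
TRACK = S.default_tracks()[1]


def noiseless(p_social, **kw):
    base = dict(jitter_sd_px=0.0, shift_latency_mean_ms=0.0,
                shift_latency_sd_ms=0.0, loss_rate=0.0, offscreen_rate=0.0)
    base.update(kw)
    return S.StrategyParams(p_social=p_social, **base)


class TestSimulateTrial:
    def test_noiseless_strategist_gives_perfect_pattern(self):
        trial, truth = S.simulate_trial(noiseless(1.0), EV, TRACK,
                                        np.random.default_rng(0))
        assert truth["behaviour"] == "social"
        prof = trial_dwell_profile(trial, EV, TRACK)
        assert prof.cell("eyes", Segment.PRE) == pytest.approx(100.0, abs=1.0)
        assert prof.cell("mouth", Segment.SPEECH) == pytest.approx(100.0, abs=1.0)
        assert prof.cell("eyes", Segment.POST) == pytest.approx(100.0, abs=1.0)
        assert social_tuning_ratio(prof) > 0.99

    def test_mouth_only_degenerate_strategy(self):
        params = noiseless(0.0, w_mouth=1.0, w_eyes=0.0, w_roam=0.0)
        trial, truth = S.simulate_trial(params, EV, TRACK, np.random.default_rng(1))
        assert truth["behaviour"] == "mouth"
        prof = trial_dwell_profile(trial, EV, TRACK)
        assert prof.cell("mouth", Segment.SPEECH) == pytest.approx(100.0, abs=1.0)
        # all dwell mass in mouth cells: the pattern score collapses to 1/3
        assert social_tuning_ratio(prof) == pytest.approx(1 / 3, abs=0.01)

    def test_latency_delays_mouth_arrival(self):
        params = noiseless(1.0, shift_latency_mean_ms=400.0)
        trial, _ = S.simulate_trial(params, EV, TRACK, np.random.default_rng(2))
        prof = trial_dwell_profile(trial, EV, TRACK)
        w = EV.speech_offset_ms - EV.speech_onset_ms
        assert prof.cell("mouth", Segment.SPEECH) == pytest.approx(
            100.0 * (1 - 400.0 / w), abs=1.0)

    def test_forced_behaviour_override(self):
        trial, truth = S.simulate_trial(noiseless(1.0), EV, TRACK,
                                        np.random.default_rng(3), behaviour="eyes")
        assert truth["behaviour"] == "eyes"
        prof = trial_dwell_profile(trial, EV, TRACK)
        assert prof.cell("eyes", Segment.SPEECH) == pytest.approx(100.0, abs=1.0)

    def test_heavy_loss_fails_qc(self):
        """Valid coverage tracks the analytic run-length expectation, and a
        strategy with expected validity far below 0.5 loses its trials."""
        params = noiseless(0.0, w_mouth=1.0, w_eyes=0.0, w_roam=0.0,
                           loss_rate=0.04, loss_run_mean=100.0)
        expected_v = S.expected_valid_fraction(params)
        assert expected_v == pytest.approx(0.2, abs=1e-9)
        rng = np.random.default_rng(4)
        fracs = []
        for _ in range(60):
            trial, _ = S.simulate_trial(params, EV, TRACK, rng)
            fracs.append(onscreen_fraction(trial, segment_windows(EV)))
        assert np.mean(fracs) == pytest.approx(expected_v, abs=0.06)
        assert np.mean([f <= 0.5 for f in fracs]) > 0.9


class TestExpectedMetrics:
    def test_zero_latency_pure_pattern_is_perfect(self):
        prof = S.expected_metrics(noiseless(1.0), {1: EV})
        assert prof.pct_eyes[Segment.PRE] == pytest.approx(100.0)
        assert prof.pct_mouth[Segment.SPEECH] == pytest.approx(100.0)
        assert prof.pct_eyes[Segment.POST] == pytest.approx(100.0)

    def test_small_latency_geometry(self):
        """Deterministic latency L into a window of length W costs L/W of
        the mouth dwell."""
        params = noiseless(1.0, shift_latency_mean_ms=200.0)
        ev = TrialEvents(1, 5000, 1000, 4500)  # W = 3500 >> L
        prof = S.expected_metrics(params, {1: ev})
        assert prof.pct_mouth[Segment.SPEECH] == pytest.approx(
            100.0 * (1 - 200.0 / 3500.0), rel=1e-6)

    def test_mixture_linearity(self):
        """A 50/50 social / mouth-only mixture has the average profile of
        the two pure strategies."""
        pure_social = S.expected_metrics(noiseless(1.0), {1: EV})
        pure_mouth = S.expected_metrics(
            noiseless(0.0, w_mouth=1.0, w_eyes=0.0, w_roam=0.0), {1: EV})
        mix = S.expected_metrics(
            noiseless(0.5, w_mouth=1.0, w_eyes=0.0, w_roam=0.0), {1: EV})
        for seg in Segment:
            assert mix.pct_mouth[seg] == pytest.approx(
                (pure_social.pct_mouth[seg] + pure_mouth.pct_mouth[seg]) / 2)

    def test_expected_str_increases_with_p_social(self):
        last = -1.0
        for p in np.linspace(0.0, 1.0, 11):
            params = S.StrategyParams(p_social=float(p), w_mouth=0.7,
                                      w_eyes=0.1, w_roam=0.2,
                                      jitter_sd_px=10.0, loss_rate=0.001)
            ratio = social_tuning_ratio(S.expected_metrics(params))
            assert ratio > last
            last = ratio

    def test_empirical_profile_converges_to_expectation(self):
        """Monte-Carlo dwell cells approach the analytic expectation."""
        params = S.StrategyParams(p_social=0.4, w_mouth=0.6, w_eyes=0.2,
                                  w_roam=0.2, jitter_sd_px=5.0,
                                  shift_latency_mean_ms=300.0,
                                  shift_latency_sd_ms=100.0,
                                  loss_rate=0.0, offscreen_rate=0.0)
        rng = np.random.default_rng(6)
        cells = []
        for _ in range(800):
            trial, _ = S.simulate_trial(params, EV, TRACK, rng)
            prof = trial_dwell_profile(trial, EV, TRACK)
            cells.append(np.concatenate([prof.pct_eyes, prof.pct_mouth]))
        got = np.mean(cells, axis=0)
        exp = S.expected_metrics(params, {1: EV})
        want = np.concatenate([exp.pct_eyes, exp.pct_mouth])
        assert np.allclose(got, want, atol=4.0)


class TestSimulateCohort:
    def small_config(self, seed=9, **kw):
        return S.CohortConfig(cells=[
            S.CellConfig("deaf", "speechreading", 2,
                         S.DEFAULT_CELLS[("deaf", "speechreading")]),
            S.CellConfig("hearing", "none", 3,
                         S.DEFAULT_CELLS[("hearing", "none")]),
        ], seed=seed, **kw)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        S.simulate_cohort(self.small_config(), out_dir=a)
        S.simulate_cohort(self.small_config(), out_dir=b)
        for name in ("gaze.tsv", "events.csv", "landmarks.csv",
                     "participants.csv", "ground_truth.json"):
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_different_seeds_differ(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        S.simulate_cohort(self.small_config(seed=1), out_dir=a)
        S.simulate_cohort(self.small_config(seed=2), out_dir=b)
        assert not filecmp.cmp(a / "gaze.tsv", b / "gaze.tsv", shallow=False)

    def test_single_cell_dataset(self):
        cfg = S.CohortConfig(cells=[
            S.CellConfig("hearing", "none", 4,
                         S.DEFAULT_CELLS[("hearing", "none")])], seed=3)
        data = S.simulate_cohort(cfg)
        assert set(data.participants.group) == {"hearing"}
        assert len(data.participants) == 4
        assert len(data.trials) == 4 * 12

    def test_scores_within_bounds_and_ground_truth_complete(self):
        data = S.simulate_cohort(self.small_config())
        assert data.participants.tocs_questions_score.between(0, 62).all()
        gt = data.ground_truth
        assert set(gt["realized"]) == set(data.participants.participant_id)
        assert "beta_str" in gt["outcome_model"]

    def test_metric_resolution_matches_sample_resolution_in_mean(self):
        cells = [S.CellConfig("hearing", "none", 40,
                              S.DEFAULT_CELLS[("hearing", "none")])]
        cfg = S.CohortConfig(cells=cells, seed=21)
        ds = S.simulate_cohort(cfg, resolution="samples")
        dm = S.simulate_cohort(cfg, resolution="metrics")

        def means(d):
            r = d.ground_truth["realized"]
            return (np.mean([v["mouth_ndt"] for v in r.values()]),
                    np.mean([v["str"] for v in r.values()]))

        ms, mm = means(ds), means(dm)
        assert ms[0] == pytest.approx(mm[0], abs=5.0)
        assert ms[1] == pytest.approx(mm[1], abs=0.04)
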