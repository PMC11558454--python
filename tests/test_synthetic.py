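"""Synthetic duets, waveforms and choices: determinism, calibration, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from chorusnet import (
    ConfigError,
    SimConfig,
    collate,
    gen_call_timeline,
    gen_choices,
    gen_waveform,
    mean_preference,
    measure_call,
    segment_interactions,
    timeline_to_events,
)


class TestConfig:
    def test_invalid_fields_named_in_error(self):
        with pytest.raises(ConfigError, match="mean_interval_s"):
            SimConfig(mean_interval_s=-1)
        with pytest.raises(ConfigError, match="chuck_probs"):
            SimConfig(chuck_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ConfigError, match="condition"):
            SimConfig(condition="city")
        with pytest.raises(ConfigError, match="choice_slope"):
            SimConfig(choice_slope=float("inf"))


class TestTimeline:
    def test_same_seed_bit_identical(self):
        a1, b1 = gen_call_timeline(SimConfig(seed=11))
        a2, b2 = gen_call_timeline(SimConfig(seed=11))
        assert a1 == a2 and b1 == b2
        a3, _ = gen_call_timeline(SimConfig(seed=12))
        assert a1 != a3

    def test_zero_duration_empty(self):
        a, b = gen_call_timeline(SimConfig(session_duration=0.0))
        assert a == [] and b == []

    def test_events_sorted_bounded_nonoverlapping(self):
        cfg = SimConfig(seed=5, session_duration=300.0)
        for tl in gen_call_timeline(cfg):
            onsets = [c.onset for c in tl]
            assert onsets == sorted(onsets)
            assert all(c.offset > c.onset for c in tl)
            assert tl[0].onset >= 0 and tl[-1].offset <= cfg.session_duration
            for prev, cur in zip(tl, tl[1:]):
                assert cur.onset >= prev.offset

    def test_call_count_matches_renewal_expectation(self):
        """Mean call count over 200 seeded replicates within 3 SD of the
        analytic gamma-renewal rate (no rests: one uninterrupted bout)."""
        duration, mean_int, shape = 120.0, 2.0, 4.0
        counts = []
        for seed in range(200):
            cfg = SimConfig(
                seed=seed, session_duration=duration, mean_interval_s=mean_int,
                interval_shape=shape, mean_bout_s=1e9,  # no rests
            )
            a, _ = gen_call_timeline(cfg)
            counts.append(len(a))
        expected = duration / mean_int
        # renewal CLT: per-replicate variance ~ T * sigma^2 / mu^3
        var = duration * (mean_int**2 / shape) / mean_int**3
        sem = math.sqrt(var / 200)
        assert abs(np.mean(counts) - expected) < 3 * sem + 1  # +1: edge effects

    def test_contains_dyad_breaking_silences(self):
        # default pause model produces > 10 s joint rests: segmentation must
        # find more than one interaction in a long session (smoke, 50 seeds)
        n_multi = 0
        for seed in range(50):
            a, b = gen_call_timeline(SimConfig(seed=seed))
            inters = segment_interactions(timeline_to_events(a), timeline_to_events(b))
            assert len(inters) >= 1
            n_multi += len(inters) > 1
        assert n_multi > 25


class TestWaveform:
    def test_single_whine_p2p_is_twice_amplitude(self):
        from chorusnet.synthetic import TimelineCall

        call = TimelineCall("A", 0.5, 0.85, 0, peak_amplitude=0.3)
        wav, truth = gen_waveform([call], sample_rate=44100, background_rms=0.0)
        assert truth.loc[0, "true_p2p"] == pytest.approx(0.6, rel=0.02)
        m = measure_call(wav, 44100, 0.5, 0.85)
        assert m.corrected_p2p == pytest.approx(truth.loc[0, "true_p2p"], abs=1e-9)

    def test_zero_events_pure_background(self):
        wav, truth = gen_waveform([], sample_rate=22050, background_rms=0.05,
                                  duration=2.0, seed=1)
        assert truth.empty
        assert np.sqrt(np.mean(wav**2)) == pytest.approx(0.05, rel=0.05)
        assert wav.size == math.ceil(2.0 * 22050)

    def test_events_beyond_duration_rejected(self):
        from chorusnet.synthetic import TimelineCall

        with pytest.raises(ValueError):
            gen_waveform([TimelineCall("A", 0.0, 3.0, 0, 0.1)], duration=1.0)

    def test_round_trip_recovers_ground_truth(self):
        """measure_call on a clean synthesized call train reproduces the
        ground-truth RMS within 5% (spacing leaves clean background flanks)."""
        cfg = SimConfig(seed=21, session_duration=30.0, mean_bout_s=1e9)
        a, _ = gen_call_timeline(cfg)
        wav, truth = gen_waveform(a, sample_rate=22050, background_rms=0.0)
        checked = 0
        for i, r in enumerate(truth.itertuples()):
            # measure only calls whose 0.1 s background flanks are clean
            prev_clear = i == 0 or r.onset_s - truth.offset_s.iloc[i - 1] >= 0.15
            next_clear = (
                i == len(truth) - 1 or truth.onset_s.iloc[i + 1] - r.offset_s >= 0.15
            )
            if r.onset_s < 0.2 or not (prev_clear and next_clear):
                continue
            m = measure_call(wav, 22050, r.onset_s, r.offset_s)
            assert m.corrected_rms == pytest.approx(r.true_rms, rel=0.05)
            checked += 1
        assert checked >= 5


def _stimuli(prop_diff, n=1):
    return pd.DataFrame(
        {
            "stimulus_id": [f"s{i}" for i in range(n)],
            "rival_pair_id": [f"p{i}" for i in range(n)],
            "prop_diff_call_rate": prop_diff,
            "faster": "A",
        }
    )


class TestChoices:
    def test_slope_zero_is_a_fair_coin(self):
        cfg = SimConfig(seed=2, choice_slope=0.0, trials_per_stimulus=10_000)
        df = gen_choices(_stimuli(0.8), cfg)
        share = (df["chosen"] == "A").mean()
        assert share == pytest.approx(0.5, abs=0.01)

    def test_saturating_slope_always_picks_faster(self):
        cfg = SimConfig(seed=3, choice_slope=500.0, trials_per_stimulus=200)
        df = gen_choices(_stimuli(0.5), cfg)
        assert (df["chosen"] == "A").all()

    def test_logistic_probability_recovered(self):
        # slope 2, proportional difference 0.5 -> P(faster) = logistic(1)
        cfg = SimConfig(seed=4, choice_slope=2.0, trials_per_stimulus=100_000)
        df = gen_choices(_stimuli(0.5), cfg)
        expected = 1 / (1 + math.exp(-1.0))
        assert (df["chosen"] == "A").mean() == pytest.approx(expected, abs=0.005)

    def test_determinism_and_required_columns(self):
        cfg = SimConfig(seed=9, trials_per_stimulus=20)
        d1 = gen_choices(_stimuli(0.3, n=3), cfg)
        d2 = gen_choices(_stimuli(0.3, n=3), cfg)
        pd.testing.assert_frame_equal(d1, d2)
        assert {"female_id", "chosen", "latency_s", "stimulus_id"} <= set(d1.columns)
        with pytest.raises(ConfigError, match="stimuli"):
            gen_choices(pd.DataFrame({"stimulus_id": ["s0"]}), cfg)


class TestParameterRecovery:
    def test_mean_ps_increases_with_choice_slope(self):
        """Preference pipeline recovers a monotone PS-vs-slope relationship
        over the slope grid (500 trials per condition, common random numbers
        across arms via the shared seed)."""
        grid = [0.0, 0.5, 1.0, 2.0, 4.0]
        means = []
        for slope in grid:
            cfg = SimConfig(seed=77, choice_slope=slope, trials_per_stimulus=10)
            trials = gen_choices(_stimuli([1.0] * 50, n=50), cfg)
            cells = collate(trials, "per_stimulus").cells
            assert sum(c.n for c in cells) == 500
            means.append(mean_preference(cells, "unweighted"))
        rho = spearmanr(grid, means).statistic
        assert rho > 0.9
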