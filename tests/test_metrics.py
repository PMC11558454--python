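"""Pair metrics: overlap, per-male traits, Weber-scaled rival differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chorusnet import (
    AmplitudeMeasurement,
    CallEvent,
    Interaction,
    MaleMetrics,
    male_metrics,
    overlap_rate,
    pair_metrics,
    select_amplitude_calls,
)
from chorusnet.metrics import pair_metrics_frame

from conftest import alternating_duet, oracle_overlap, random_toy_events


def _measured(male_id, onset, offset, n_chucks=0, p2p=0.5):
    amp = AmplitudeMeasurement(
        raw_rms=p2p / (2 * np.sqrt(2)), raw_p2p=p2p,
        background_rms=0.0, background_p2p=0.0,
    )
    return CallEvent(male_id, onset, offset, n_chucks, amp)


class TestOverlapRate:
    def test_alternating_disjoint_calls_never_overlap(self):
        a, b = alternating_duet(n_calls=10)
        inter = Interaction("p", tuple(sorted(a + b, key=lambda e: e.onset)))
        assert overlap_rate(inter) == (0, 10)

    def test_identical_call_times_always_overlap(self):
        a = [CallEvent("A", i * 2.0, i * 2.0 + 0.5) for i in range(5)]
        b = [CallEvent("B", i * 2.0, i * 2.0 + 0.5) for i in range(5)]
        inter = Interaction("p", tuple(sorted(a + b, key=lambda e: (e.onset, e.male_id))))
        assert overlap_rate(inter) == (10, 10)

    def test_toy_configuration_with_two_crossing_pairs(self):
        # A: [0,1], [4,5], [8,9]; B: [0.5,1.5], [4.2,4.8], [20,21]
        # -> the first two calls of each male overlap, the last of each does not
        ev = [
            CallEvent("A", 0, 1), CallEvent("B", 0.5, 1.5),
            CallEvent("A", 4, 5), CallEvent("B", 4.2, 4.8),
            CallEvent("A", 8, 9), CallEvent("B", 20, 21),
        ]
        inter = Interaction("p", tuple(ev))
        assert overlap_rate(inter) == (4, 6)
        assert overlap_rate(inter) == oracle_overlap(inter)

    def test_touching_endpoints_do_not_overlap(self):
        ev = (CallEvent("A", 0, 1), CallEvent("B", 1, 2))
        assert overlap_rate(Interaction("p", ev)) == (0, 2)

    def test_matches_pairwise_oracle_on_random_inputs(self, rng):
        for _ in range(100):
            a, b = random_toy_events(rng, max_events=20)
            if not a or not b:
                continue
            inter = Interaction("p", tuple(sorted(a + b, key=lambda e: e.onset)))
            assert overlap_rate(inter) == oracle_overlap(inter)


class TestMaleMetrics:
    def test_call_rate_and_complexity_identities(self):
        # 30 A-calls over a 60 s interaction -> 30 calls/min;
        # chuck counts cycling 0,1,2 -> mean complexity 1.0
        ev = []
        for i in range(30):
            ev.append(_measured("A", i * 2.0, i * 2.0 + 0.3, n_chucks=i % 3))
        ev.append(_measured("B", 59.4, 59.7))
        inter = Interaction("p", tuple(sorted(ev, key=lambda e: e.onset)))
        assert inter.length == pytest.approx(59.7)
        m = male_metrics(inter, "A")
        assert m.call_rate == pytest.approx(60 * 30 / 59.7)
        assert m.complexity == pytest.approx(1.0)

    def test_amplitude_call_selection_matches_exhaustive_oracle(self):
        # 10 A-calls with known loudness; one overlaps B, one lacks flanking
        # silence; first/last 3 are barred -> eligible interior calls only
        p2ps = [0.9, 0.2, 0.3, 0.95, 0.6, 0.7, 0.4, 0.85, 0.1, 0.05]
        a = [_measured("A", i * 4.0, i * 4.0 + 0.4, p2p=p2ps[i]) for i in range(10)]
        b = [
            _measured("B", 12.2, 12.5),        # overlaps A's call 3 (the loudest)
            _measured("B", 16.45, 16.8),       # within 0.1 s of A's call 4 offset
            _measured("B", 30.0, 30.3),
        ]
        inter = Interaction("p", tuple(sorted(a + b, key=lambda e: e.onset)))
        chosen = select_amplitude_calls(inter, "A")

        def eligible(idx):
            e = a[idx]
            if idx < 3 or idx >= 7:
                return False
            for o in b:
                if e.onset < o.offset and o.onset < e.offset:
                    return False
                if o.onset < e.offset + 0.1 and e.onset - 0.1 < o.offset:
                    return False
            return True

        want = sorted(
            (i for i in range(10) if eligible(i)), key=lambda i: -p2ps[i]
        )[:3]
        assert [c.onset for c in chosen] == [a[i].onset for i in want]
        m = male_metrics(inter, "A")
        assert m.whine_p2p == pytest.approx(np.mean([p2ps[i] for i in want]))

    def test_no_eligible_call_flags_absent_amplitude(self):
        # every call is in the first/last 3 -> amplitude fields absent
        a = [_measured("A", i * 3.0, i * 3.0 + 0.3) for i in range(5)]
        b = [_measured("B", 1.5, 1.8), _measured("B", 13.0, 13.3)]
        inter = Interaction("p", tuple(sorted(a + b, key=lambda e: e.onset)))
        m = male_metrics(inter, "A")
        assert not m.has_amplitude
        assert m.whine_rms is None


class TestPairMetrics:
    def _inter(self):
        a, b = alternating_duet(n_calls=20)
        return Interaction("p", tuple(sorted(a + b, key=lambda e: e.onset)))

    def _mm(self, male_id, call_rate, complexity, rms=None, p2p=None):
        return MaleMetrics(
            male_id=male_id, n_calls=10, call_rate=call_rate, complexity=complexity,
            whine_rms=rms, whine_p2p=p2p, n_amplitude_calls=3 if rms else 0,
        )

    def test_hand_computed_differences(self):
        pm = pair_metrics(
            self._inter(),
            self._mm("A", 10.0, 2.0, rms=0.4, p2p=1.0),
            self._mm("B", 5.0, 2.0, rms=0.1, p2p=0.5),
        )
        assert pm.mean["call_rate"] == pytest.approx(7.5)
        assert pm.abs_diff["call_rate"] == pytest.approx(5.0)
        assert pm.prop_diff["call_rate"] == pytest.approx(0.5)
        assert pm.abs_diff["complexity"] == 0.0
        assert pm.prop_diff["complexity"] == 0.0
        assert pm.prop_diff["whine_rms"] == pytest.approx(0.75)

    def test_zero_vs_positive_gives_prop_one(self):
        pm = pair_metrics(
            self._inter(), self._mm("A", 8.0, 1.5), self._mm("B", 0.0001, 0.0)
        )
        # complexity: a > 0, b = 0 -> proportional difference 1
        assert pm.prop_diff["complexity"] == pytest.approx(1.0)

    def test_both_zero_flagged(self):
        pm = pair_metrics(self._inter(), self._mm("A", 8.0, 0.0), self._mm("B", 6.0, 0.0))
        assert pm.prop_diff["complexity"] == 0.0
        assert "complexity" in pm.zero_pair_traits

    @given(
        st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.01, 10)
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetry_and_rescaling_invariance(self, a, b, gain):
        inter = self._inter()
        pm_ab = pair_metrics(inter, self._mm("A", a, 1.0), self._mm("B", b, 1.0))
        pm_ba = pair_metrics(inter, self._mm("B", b, 1.0), self._mm("A", a, 1.0))
        assert pm_ab.mean["call_rate"] == pytest.approx(pm_ba.mean["call_rate"])
        assert pm_ab.abs_diff["call_rate"] == pytest.approx(pm_ba.abs_diff["call_rate"])
        # proportional difference survives a common rescaling; absolute does not
        pm_scaled = pair_metrics(
            inter, self._mm("A", a * gain, 1.0), self._mm("B", b * gain, 1.0)
        )
        assert pm_scaled.prop_diff["call_rate"] == pytest.approx(
            pm_ab.prop_diff["call_rate"], rel=1e-9
        )
        if a != b and abs(gain - 1) > 1e-9:
            assert pm_scaled.abs_diff["call_rate"] != pytest.approx(
                pm_ab.abs_diff["call_rate"], rel=1e-12
            )

    def test_transform_export_adds_columns_without_mutation(self):
        pm = pair_metrics(
            self._inter(),
            self._mm("A", 10.0, 2.0, rms=0.4, p2p=1.0),
            self._mm("B", 5.0, 1.0, rms=0.1, p2p=0.5),
        )
        plain = pair_metrics_frame([pm])
        rich = pair_metrics_frame([pm], transformed=True)
        assert "sqrt_abs_diff_call_rate" not in plain.columns
        assert rich.loc[0, "sqrt_abs_diff_call_rate"] == pytest.approx(np.sqrt(5.0))
        assert rich.loc[0, "log_interaction_length"] == pytest.approx(
            np.log(pm.interaction_length)
        )
        # untransformed columns identical in both exports
        assert plain.loc[0, "abs_diff_call_rate"] == rich.loc[0, "abs_diff_call_rate"]
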