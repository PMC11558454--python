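"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by different routes than the
implementation (O(n^2) window scans, pairwise enumeration, closed forms) so
that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from chorusnet import CallEvent, Interaction


def make_events(specs, male_id="A", chucks=0):
    """[(onset, offset), ...] -> list of CallEvent."""
    return [CallEvent(male_id, on, off, chucks) for on, off in specs]


def alternating_duet(n_calls=12, period=5.0, call_dur=0.4, start=0.0):
    """A and B alternate every period/2 seconds; returns (events_a, events_b)."""
    a, b = [], []
    for i in range(n_calls):
        t = start + i * period / 2
        ev = CallEvent("A" if i % 2 == 0 else "B", t, t + call_dur)
        (a if i % 2 == 0 else b).append(ev)
    return a, b


def random_toy_events(rng, max_events=30):
    """Random two-male event set for oracle comparison: short calls, gaps
    spanning the 10 s pause threshold, occasional exact-boundary gaps."""
    n = int(rng.integers(1, max_events + 1))
    events_a, events_b = [], []
    t_a = t_b = 0.0
    for _ in range(n):
        male = rng.random() < 0.5
        dur = float(rng.uniform(0.2, 0.6))
        # gaps drawn to straddle the max_pause boundary, sometimes exactly 10
        gap = float(rng.choice([rng.uniform(0.1, 9.0), 10.0, rng.uniform(10.1, 15.0)],
                               p=[0.7, 0.1, 0.2]))
        if male:
            t_a = max(t_a, t_b - float(rng.uniform(0, 5))) + gap
            events_a.append(CallEvent("A", t_a, t_a + dur))
            t_a += dur
        else:
            t_b = max(t_b, t_a - float(rng.uniform(0, 5))) + gap
            events_b.append(CallEvent("B", t_b, t_b + dur))
            t_b += dur
    return events_a, events_b


def oracle_segment(events_a, events_b, max_pause=10.0, min_length=20.0):
    """Brute-force bout finder: enumerate every contiguous window of the
    pooled sequence, mark it valid when all internal dyad gaps are
    <= max_pause, keep windows not strictly contained in a larger valid
    window, then apply the both-males and minimum-span rules."""
    pooled = sorted(events_a + events_b, key=lambda e: (e.onset, e.offset))
    n = len(pooled)

    def window_valid(i, j):
        cover = pooled[i].offset
        for m in range(i + 1, j + 1):
            if pooled[m].onset - cover > max_pause:
                return False
            cover = max(cover, pooled[m].offset)
        return True

    valid = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i, n):
            valid[i, j] = window_valid(i, j)

    bouts = []
    for i in range(n):
        for j in range(i, n):
            if not valid[i, j]:
                continue
            # maximal iff no strictly larger valid window contains (i..j)
            containing = valid[: i + 1, j:].sum() - 1
            if containing > 0:
                continue
            window = pooled[i : j + 1]
            span = max(e.offset for e in window) - window[0].onset
            if len({e.male_id for e in window}) >= 2 and span >= min_length:
                bouts.append(window)
    return bouts


def oracle_overlap(interaction: Interaction):
    """Pairwise interval-intersection count (half-open intervals)."""
    ev = interaction.events
    n_overlap = 0
    for i, e in enumerate(ev):
        hit = False
        for j, o in enumerate(ev):
            if i == j or o.male_id == e.male_id:
                continue
            if e.onset < o.offset and o.onset < e.offset:
                hit = True
        n_overlap += hit
    return n_overlap, len(ev)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
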