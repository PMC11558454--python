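"""Rival-interaction segmentation.

An interaction is a maximal bout of joint calling by a dyad: a run of pooled
calls of both males in which no dyad silence (gap from the end of acoustic
coverage to the next call onset) exceeds 10 s, spanning at least 20 s from the
onset of the first call to the offset of the last, and containing at least one
call of each male. Per recording session the longest such interaction is
selected, ignoring interactions starting in the first 2 min the pair could
interact. Pairs whose selected interaction has too few calls (< 8) or too
quiet whines (< 60 dB mean whine RMS) in either sensory condition are
excluded.

"Pause" is interpreted as silence of the dyad — the pooled call sequence of
both males — not per-male gaps, and the both-males requirement filters whole
bouts rather than trimming them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .audio import AmplitudeMeasurement

__all__ = [
    "CallEvent",
    "Interaction",
    "SegmentationError",
    "segment_interactions",
    "select_longest",
    "exclude_pair",
    "events_from_frame",
    "interactions_to_frame",
]

MAX_PAUSE_S = 10.0
MIN_LENGTH_S = 20.0
EXCLUSION_WINDOW_S = 120.0
MIN_CALLS = 8
MIN_WHINE_RMS_DB = 60.0


class SegmentationError(ValueError):
    """Invalid event input (unsorted, overlapping within a male, ...)."""


@dataclass(frozen=True)
class CallEvent:
    """One vocalization of one male: a whine, optionally with chucks."""

    male_id: str
    onset: float
    offset: float
    n_chucks: int = 0
    amplitude: AmplitudeMeasurement | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise SegmentationError(
                f"call offset must exceed onset ({self.male_id}: "
                f"[{self.onset}, {self.offset}])"
            )
        if self.n_chucks < 0:
            raise SegmentationError("n_chucks must be >= 0")


@dataclass(frozen=True)
class Interaction:
    """A maximal qualifying bout of joint calling by one rival pair."""

    pair_id: str
    events: tuple[CallEvent, ...]
    condition: str | None = None
    start: float = field(init=False)
    end: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.events:
            raise SegmentationError("an interaction needs at least one call")
        object.__setattr__(self, "start", self.events[0].onset)
        object.__setattr__(self, "end", max(e.offset for e in self.events))

    @property
    def length(self) -> float:
        """Onset of the first call to offset of the last call, seconds."""
        return self.end - self.start

    @property
    def male_ids(self) -> tuple[str, ...]:
        return tuple(sorted({e.male_id for e in self.events}))

    @property
    def n_calls(self) -> int:
        return len(self.events)

    def calls_of(self, male_id: str) -> tuple[CallEvent, ...]:
        return tuple(e for e in self.events if e.male_id == male_id)

    def silences(self, min_gap: float = 0.0) -> list[tuple[float, float]]:
        """Maximal dyad-silence gaps longer than ``min_gap`` inside the bout."""
        gaps = []
        cover_end = self.events[0].offset
        for e in self.events[1:]:
            if e.onset - cover_end > min_gap:
                gaps.append((cover_end, e.onset))
            cover_end = max(cover_end, e.offset)
        return gaps


def _validate_sorted(events: Sequence[CallEvent], label: str) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.onset < prev.onset:
            raise SegmentationError(f"{label}: events not sorted by onset")
        if cur.onset < prev.offset and cur.male_id == prev.male_id:
            raise SegmentationError(
                f"{label}: overlapping calls within male {cur.male_id}"
            )


def segment_interactions(
    events_a: Sequence[CallEvent],
    events_b: Sequence[CallEvent],
    max_pause: float = MAX_PAUSE_S,
    min_length: float = MIN_LENGTH_S,
    pair_id: str = "pair",
    condition: str | None = None,
) -> list[Interaction]:
    """All maximal qualifying interactions of a dyad, in temporal order.

    Pools both males' calls, splits the pooled sequence wherever dyad silence
    exceeds ``max_pause``, then keeps runs in which both males call and whose
    first-onset-to-last-offset span is at least ``min_length``.
    """
    _validate_sorted(events_a, "male A")
    _validate_sorted(events_b, "male B")
    pooled = sorted(list(events_a) + list(events_b), key=lambda e: (e.onset, e.offset))
    if not pooled:
        return []

    runs: list[list[CallEvent]] = [[pooled[0]]]
    cover_end = pooled[0].offset
    for e in pooled[1:]:
        if e.onset - cover_end > max_pause:
            runs.append([e])
            cover_end = e.offset
        else:
            runs[-1].append(e)
            cover_end = max(cover_end, e.offset)

    out = []
    for run in runs:
        males = {e.male_id for e in run}
        span = max(e.offset for e in run) - run[0].onset
        if len(males) >= 2 and span >= min_length:
            out.append(Interaction(pair_id=pair_id, events=tuple(run), condition=condition))
    return out


def select_longest(
    interactions: Iterable[Interaction],
    session_interaction_start: float = 0.0,
    exclusion: float = EXCLUSION_WINDOW_S,
) -> Interaction | None:
    """Longest interaction starting after the carry-over exclusion window.

    Only interactions starting at or after ``session_interaction_start +
    exclusion`` qualify; ties on length break toward the earlier start.
    """
    cutoff = session_interaction_start + exclusion
    eligible = [i for i in interactions if i.start >= cutoff]
    if not eligible:
        return None
    return max(eligible, key=lambda i: (i.length, -i.start))


def _mean_whine_rms_db(interaction: Interaction) -> float:
    vals = [
        e.amplitude.rms_db
        for e in interaction.events
        if e.amplitude is not None and e.amplitude.rms_db is not None
    ]
    if not vals:
        raise SegmentationError(
            f"{interaction.pair_id}: no calibrated whine RMS available for exclusion rule"
        )
    return float(np.mean(vals))


def exclude_pair(
    interaction_forest: Interaction,
    interaction_urban: Interaction,
    min_calls: int = MIN_CALLS,
    min_rms_db: float = MIN_WHINE_RMS_DB,
) -> tuple[bool, list[str]]:
    """Keep/drop decision for a rival pair from its two condition interactions.

    Drops the pair when either interaction has fewer than ``min_calls`` calls
    (pair total) or a mean measured whine RMS below ``min_rms_db``; boundary
    values (exactly 8 calls, exactly 60.0 dB) are kept. Returns
    ``(keep, reasons)`` with machine-readable reason codes.
    """
    reasons = []
    for inter in (interaction_forest, interaction_urban):
        if inter.n_calls < min_calls and "min_calls" not in reasons:
            reasons.append("min_calls")
        if _mean_whine_rms_db(inter) < min_rms_db and "min_rms" not in reasons:
            reasons.append("min_rms")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# Tabular interchange

def events_from_frame(df: pd.DataFrame) -> dict[str, list[CallEvent]]:
    """Events CSV rows (male_id, onset_s, offset_s, n_chucks, [amplitudes]) → per-male lists."""
    has_amp = {"corrected_rms", "corrected_p2p"}.issubset(df.columns)
    by_male: dict[str, list[CallEvent]] = {}
    for r in df.sort_values("onset_s").itertuples():
        amp = None
        if has_amp and not pd.isna(r.corrected_rms):
            amp = AmplitudeMeasurement(
                raw_rms=float(getattr(r, "raw_rms", r.corrected_rms)),
                raw_p2p=float(getattr(r, "raw_p2p", r.corrected_p2p)),
                background_rms=float(getattr(r, "background_rms", 0.0)),
                background_p2p=float(getattr(r, "background_p2p", 0.0)),
            )
            rms_db = getattr(r, "rms_db", None)
            p2p_db = getattr(r, "p2p_db", None)
            amp.rms_db = None if rms_db is None or pd.isna(rms_db) else float(rms_db)
            amp.p2p_db = None if p2p_db is None or pd.isna(p2p_db) else float(p2p_db)
        by_male.setdefault(str(r.male_id), []).append(
            CallEvent(
                male_id=str(r.male_id),
                onset=float(r.onset_s),
                offset=float(r.offset_s),
                n_chucks=int(getattr(r, "n_chucks", 0)),
                amplitude=amp,
            )
        )
    return by_male


def interactions_to_frame(interactions: Sequence[Interaction]) -> pd.DataFrame:
    """Interactions → summary table (pair_id, condition, start_s, end_s, ...)."""
    rows = []
    for k, inter in enumerate(interactions):
        males = inter.male_ids
        rows.append(
            {
                "interaction_id": k,
                "pair_id": inter.pair_id,
                "condition": inter.condition,
                "start_s": inter.start,
                "end_s": inter.end,
                "length_s": inter.length,
                "n_calls_A": len(inter.calls_of(males[0])) if males else 0,
                "n_calls_B": len(inter.calls_of(males[1])) if len(males) > 1 else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "interaction_id", "pair_id", "condition", "start_s", "end_s",
            "length_s", "n_calls_A", "n_calls_B",
        ],
    )
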