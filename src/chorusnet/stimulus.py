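"""Phonotaxis-stimulus eligibility rules.

A rival pair's recorded interaction qualifies as a playback stimulus when it
is long enough for a female to sample both males (>= 30 s), short enough that
she is unlikely to decide before hearing a full interaction (<= 150 s), and
has no distracting dyad silences: no silence of more than 5 s intersecting
the first or last 30 s of the interaction, and no two such silences within
any 30 s window. A pair enters the stimulus set only if the interactions from
BOTH sensory conditions (forest and urban) pass.

Rule identifiers: ``min_length``, ``max_length``, ``silence_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .segmentation import Interaction

__all__ = [
    "StimulusDecision",
    "check_stimulus",
    "filter_pairs",
    "export_stimulus",
]

MIN_STIMULUS_LENGTH_S = 30.0
MAX_STIMULUS_LENGTH_S = 150.0
MAX_SILENCE_S = 5.0
EDGE_WINDOW_S = 30.0
DOUBLE_SILENCE_WINDOW_S = 30.0
APPENDED_SILENCE_S = 10.0


@dataclass(frozen=True)
class StimulusDecision:
    """Eligibility verdict for one pair (both condition interactions)."""

    pair_id: str
    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        assert self.eligible == (len(self.reasons) == 0)


def check_stimulus(
    interaction: Interaction,
    min_length: float = MIN_STIMULUS_LENGTH_S,
    max_length: float = MAX_STIMULUS_LENGTH_S,
    max_silence: float = MAX_SILENCE_S,
    edge_window: float = EDGE_WINDOW_S,
    double_window: float = DOUBLE_SILENCE_WINDOW_S,
    edge_mode: str = "intersect",
) -> list[str]:
    """Violated stimulus rules for one interaction (empty list = eligible).

    Long silences are the maximal dyad-silence gaps > ``max_silence``.
    ``edge_mode='intersect'`` (default) rejects a long silence that intersects
    the first or last ``edge_window`` seconds; ``'within'`` requires the
    silence to start (resp. end) inside the window. The "twice within 30 s"
    rule slides a window anchored at each long silence's onset.
    """
    violations = []
    if interaction.length < min_length:
        violations.append("min_length")
    if interaction.length > max_length:
        violations.append("max_length")

    long_silences = interaction.silences(min_gap=max_silence)
    head_end = interaction.start + edge_window
    tail_start = interaction.end - edge_window
    silence_bad = False
    for s0, s1 in long_silences:
        if edge_mode == "intersect":
            in_head = s0 < head_end and s1 > interaction.start
            in_tail = s1 > tail_start and s0 < interaction.end
        else:  # 'within'
            in_head = interaction.start <= s0 <= head_end
            in_tail = tail_start <= s1 <= interaction.end
        if in_head or in_tail:
            silence_bad = True
            break
    if not silence_bad:
        onsets = [s0 for s0, _ in long_silences]
        silence_bad = any(
            later - first <= double_window
            for first, later in zip(onsets, onsets[1:])
        )
    if silence_bad:
        violations.append("silence_rule")
    return violations


def filter_pairs(
    decisions_by_condition: dict[str, dict[str, list[str]]],
) -> list[StimulusDecision]:
    """Combine per-condition rule checks into per-pair decisions.

    ``decisions_by_condition`` maps pair_id -> {condition: violated rules};
    every pair must carry both a 'forest' and an 'urban' entry. A pair is
    eligible iff neither condition's interaction violates any rule.
    """
    out = []
    for pair_id, conds in sorted(decisions_by_condition.items()):
        missing = {"forest", "urban"} - set(conds)
        if missing:
            raise ValueError(f"pair {pair_id}: missing condition(s) {sorted(missing)}")
        reasons = sorted({r for rules in conds.values() for r in rules})
        out.append(
            StimulusDecision(
                pair_id=pair_id, eligible=not reasons, reasons=tuple(reasons)
            )
        )
    return out


def export_stimulus(
    interaction: Interaction,
    tone_rms: float = 1.0,
    appended_silence: float = APPENDED_SILENCE_S,
) -> pd.DataFrame:
    """Deterministic stimulus-timeline export.

    Re-times the interaction's events to start at 0 (the editing steps that
    were done by hand on audio: background removed between calls, amplitudes
    normalized by the calibration-tone RMS, 10 s of silence appended). The
    returned table carries per-call times, the amplitude scale factor
    1/tone_rms, and a final ``total_duration_s`` attribute in ``df.attrs``.
    """
    if tone_rms <= 0:
        raise ValueError("tone_rms must be positive")
    rows = [
        {
            "male_id": e.male_id,
            "onset_s": e.onset - interaction.start,
            "offset_s": e.offset - interaction.start,
            "n_chucks": e.n_chucks,
            "gain": 1.0 / tone_rms,
        }
        for e in interaction.events
    ]
    df = pd.DataFrame(rows)
    df.attrs["total_duration_s"] = interaction.length + appended_silence
    df.attrs["stimulus_id"] = f"{interaction.pair_id}_{interaction.condition or 'na'}"
    return df
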