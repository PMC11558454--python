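"""Per-interaction calling metrics and rival differences.

For the selected interaction of a rival pair this module computes, per male,
call rate (calls/min), call complexity (mean chucks/call) and whine amplitude
(RMS and P2P, averaged over up to 3 selected loud calls), and at the pair
level the temporal overlap rate, the two-male trait means, absolute rival
differences |a - b|, and proportional rival differences |a - b| / max(a, b) —
the Weber-scaled difference presumed relevant to perceptual discrimination.

Amplitude calls are selected by ranking a male's calls by raw P2P (loudest
first) and keeping up to 3 that do not overlap the rival, have at least 0.1 s
of dyad silence on both flanks, and are not among that male's first or last
3 calls of the interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CallEvent, Interaction

__all__ = [
    "MaleMetrics",
    "PairMetrics",
    "overlap_rate",
    "select_amplitude_calls",
    "male_metrics",
    "pair_metrics",
    "pair_metrics_frame",
    "TRAITS",
]

AMPLITUDE_FLANK_S = 0.1
MAX_AMPLITUDE_CALLS = 3
EDGE_CALLS_SKIPPED = 3

TRAITS = ("call_rate", "complexity", "whine_rms", "whine_p2p")


@dataclass(frozen=True)
class MaleMetrics:
    """One male's calling metrics within one interaction."""

    male_id: str
    n_calls: int
    call_rate: float  # calls/min
    complexity: float  # chucks/call
    whine_rms: float | None = None  # linear, background-corrected
    whine_p2p: float | None = None
    whine_rms_db: float | None = None
    whine_p2p_db: float | None = None
    n_amplitude_calls: int = 0

    @property
    def has_amplitude(self) -> bool:
        return self.n_amplitude_calls > 0


@dataclass(frozen=True)
class PairMetrics:
    """Pair-level summary of one interaction: means and rival differences."""

    pair_id: str
    condition: str | None
    interaction_length: float
    overlap_count: int
    call_count: int
    mean: dict[str, float | None]
    abs_diff: dict[str, float | None]
    prop_diff: dict[str, float | None]
    zero_pair_traits: tuple[str, ...] = ()


def _intervals_overlap(a: CallEvent, b: CallEvent) -> bool:
    # half-open [onset, offset): touching endpoints do not overlap
    return a.onset < b.offset and b.onset < a.offset


def overlap_rate(interaction: Interaction) -> tuple[int, int]:
    """(number of calls overlapping a rival call, total calls of both males).

    A call overlaps iff its half-open [onset, offset) interval intersects any
    call interval of the other male; the count is symmetric in the two males.
    """
    events = interaction.events
    n_overlap = 0
    for e in events:
        if any(
            _intervals_overlap(e, o) for o in events if o.male_id != e.male_id
        ):
            n_overlap += 1
    return n_overlap, len(events)


def select_amplitude_calls(
    interaction: Interaction,
    male_id: str,
    max_calls: int = MAX_AMPLITUDE_CALLS,
    flank_s: float = AMPLITUDE_FLANK_S,
    edge_calls: int = EDGE_CALLS_SKIPPED,
) -> list[CallEvent]:
    """Up to ``max_calls`` loudest eligible calls of one male.

    Eligible: measured amplitude present, no overlap with the rival, at least
    ``flank_s`` of dyad silence before and after, and not among the male's
    first or last ``edge_calls`` calls of the interaction. Ranked by raw P2P
    descending (ties to the earlier call).
    """
    own = interaction.calls_of(male_id)
    others = [e for e in interaction.events if e.male_id != male_id]
    interior = list(own[edge_calls : len(own) - edge_calls if edge_calls else None])

    def flanked(e: CallEvent) -> bool:
        for o in interaction.events:
            if o is e:
                continue
            if o.onset < e.offset + flank_s and e.onset - flank_s < o.offset:
                return False
        return True

    eligible = [
        e
        for e in own
        if any(e is x for x in interior)
        and e.amplitude is not None
        and not any(_intervals_overlap(e, o) for o in others)
        and flanked(e)
    ]
    eligible.sort(key=lambda e: (-e.amplitude.raw_p2p, e.onset))
    return eligible[:max_calls]


def male_metrics(
    interaction: Interaction,
    male_id: str,
    amplitude_calls: list[CallEvent] | None = None,
) -> MaleMetrics:
    """Call rate, complexity and (when measurable) whine amplitude of one male."""
    own = interaction.calls_of(male_id)
    if not own:
        raise ValueError(f"male {male_id} has no calls in interaction")
    if interaction.length <= 0:
        raise ValueError("interaction length must be positive")
    if amplitude_calls is None:
        amplitude_calls = select_amplitude_calls(interaction, male_id)

    call_rate = 60.0 * len(own) / interaction.length
    complexity = float(np.mean([e.n_chucks for e in own]))

    amps = [e.amplitude for e in amplitude_calls if e.amplitude is not None]
    kw: dict[str, float | None] = {}
    if amps:
        kw["whine_rms"] = float(np.mean([a.corrected_rms for a in amps]))
        kw["whine_p2p"] = float(np.mean([a.corrected_p2p for a in amps]))
        rms_db = [a.rms_db for a in amps if a.rms_db is not None]
        p2p_db = [a.p2p_db for a in amps if a.p2p_db is not None]
        kw["whine_rms_db"] = float(np.mean(rms_db)) if rms_db else None
        kw["whine_p2p_db"] = float(np.mean(p2p_db)) if p2p_db else None
    return MaleMetrics(
        male_id=male_id,
        n_calls=len(own),
        call_rate=call_rate,
        complexity=complexity,
        n_amplitude_calls=len(amps),
        **kw,
    )


def _prop(a: float, b: float) -> float:
    hi = max(a, b)
    return abs(a - b) / hi if hi > 0 else 0.0


def pair_metrics(
    interaction: Interaction,
    metrics_a: MaleMetrics,
    metrics_b: MaleMetrics,
) -> PairMetrics:
    """Pair means and absolute/proportional rival differences per trait.

    ``prop_diff = |a - b| / max(a, b)``; a trait with both values zero gets
    proportional difference 0 and is flagged in ``zero_pair_traits``. Traits
    missing on either male (no eligible amplitude call) get None.
    """
    n_overlap, n_total = overlap_rate(interaction)
    mean: dict[str, float | None] = {}
    abs_diff: dict[str, float | None] = {}
    prop_diff: dict[str, float | None] = {}
    zero_traits = []
    for trait in TRAITS:
        a = getattr(metrics_a, trait)
        b = getattr(metrics_b, trait)
        if a is None or b is None:
            mean[trait] = abs_diff[trait] = prop_diff[trait] = None
            continue
        mean[trait] = (a + b) / 2.0
        abs_diff[trait] = abs(a - b)
        prop_diff[trait] = _prop(a, b)
        if a == 0 and b == 0:
            zero_traits.append(trait)
    return PairMetrics(
        pair_id=interaction.pair_id,
        condition=interaction.condition,
        interaction_length=interaction.length,
        overlap_count=n_overlap,
        call_count=n_total,
        mean=mean,
        abs_diff=abs_diff,
        prop_diff=prop_diff,
        zero_pair_traits=tuple(zero_traits),
    )


def pair_metrics_frame(
    pairs: list[PairMetrics], transformed: bool = False
) -> pd.DataFrame:
    """Wide table of pair metrics, one row per interaction.

    With ``transformed=True`` adds the downstream modeling transforms as extra
    columns (log interaction length; sqrt of the absolute differences in
    whine RMS, call rate and complexity and of the proportional differences
    in call rate and complexity) — originals are never modified in place.
    """
    rows = []
    for p in pairs:
        row: dict[str, object] = {
            "pair_id": p.pair_id,
            "condition": p.condition,
            "interaction_length_s": p.interaction_length,
            "overlap_count": p.overlap_count,
            "call_count": p.call_count,
            "overlap_rate": p.overlap_count / p.call_count if p.call_count else np.nan,
        }
        for trait in TRAITS:
            row[f"mean_{trait}"] = p.mean[trait]
            row[f"abs_diff_{trait}"] = p.abs_diff[trait]
            row[f"prop_diff_{trait}"] = p.prop_diff[trait]
        if transformed:
            row["log_interaction_length"] = math.log(p.interaction_length)
            for trait in ("whine_rms", "call_rate", "complexity"):
                v = p.abs_diff[trait]
                row[f"sqrt_abs_diff_{trait}"] = math.sqrt(v) if v is not None else None
            for trait in ("call_rate", "complexity"):
                v = p.prop_diff[trait]
                row[f"sqrt_prop_diff_{trait}"] = math.sqrt(v) if v is not None else None
        rows.append(row)
    return pd.DataFrame(rows)
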