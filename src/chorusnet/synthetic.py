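"""Synthetic duets, waveforms and choice data.

Everything downstream of raw field recordings can be exercised without any
field data: this module generates (1) two-male antiphonal call timelines as
independent gamma renewal processes with occasional long pauses, (2) optional
mono waveforms per male — whines as downward 900→400 Hz sweeps, chucks as
short high-frequency bursts — over white background noise, with a ground-truth
amplitude table, and (3) Bernoulli female choice trials whose bias toward the
faster-calling male is a logistic function of the proportional call-rate
difference between the rivals.

Both males share a bout/rest schedule — joint calling bouts separated by
joint rests longer than the 10 s segmentation pause threshold — because only
simultaneous silence of the dyad breaks an interaction; independent per-male
pauses would never do so while the rival keeps calling.

All randomness flows from a single seed. Stream order (documented contract):
stream 0 drives the shared bout/rest schedule, stream 1 male A's timeline,
stream 2 male B's, stream 3 waveform background noise, stream 4 choice
trials. The timing model is a stated world,
not an estimate of the study system: no quantitative call-timing
distributions are published for these frogs, so defaults were chosen once as
field-plausible (whines ≈ 0.35 s, onset-to-onset intervals ≈ 2 s, moderately
regular) and are documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import CallEvent

__all__ = [
    "SimConfig",
    "ConfigError",
    "TimelineCall",
    "gen_call_timeline",
    "gen_waveform",
    "gen_choices",
    "timeline_to_frame",
    "timeline_to_events",
]

CHUCK_DURATION_S = 0.05


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Stated world for the simulator; defaults are desk-scale plausible.

    The ``condition`` covariate nudges behavior the way urban sensory
    pollution plausibly would (more interruptions, louder calling) so that
    condition contrasts are non-trivial downstream; effect sizes are design
    choices, not estimates.
    """

    seed: int = 0
    session_duration: float = 600.0
    condition: str = "forest"
    origin: str = "forest"
    # per-male calling parameters
    mean_interval_s: float = 2.0       # onset-to-onset, gamma renewal
    interval_shape: float = 4.0        # gamma shape; 1 = Poisson-like, large = metronomic
    whine_duration_s: float = 0.35
    chuck_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)  # P(0..3 chucks)
    mean_amplitude: float = 0.1        # linear full-scale
    amplitude_cv: float = 0.2
    alternation_offset_s: float = 0.5  # male B's start lag (crude antiphony)
    # pause model: shared calling bouts separated by dyad-breaking rests
    mean_bout_s: float = 60.0
    pause_min_s: float = 12.0
    pause_max_s: float = 25.0
    # condition covariates (urban sensory pollution shortens joint bouts and
    # elicits slightly louder calling)
    urban_bout_factor: float = 0.5
    urban_amplitude_factor: float = 1.1
    # choice model
    baseline_choice_prob: float = 0.5
    choice_slope: float = 2.0
    trials_per_stimulus: int = 10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "mean_interval_s", "interval_shape", "whine_duration_s",
            "mean_amplitude", "mean_bout_s", "pause_min_s", "pause_max_s",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.session_duration < 0:
            raise ConfigError(f"session_duration must be >= 0, got {self.session_duration}")
        if not 0 <= self.baseline_choice_prob <= 1:
            raise ConfigError(
                f"baseline_choice_prob must be in [0, 1], got {self.baseline_choice_prob}"
            )
        if self.condition not in ("forest", "urban"):
            raise ConfigError(f"condition must be 'forest' or 'urban', got {self.condition!r}")
        if self.origin not in ("forest", "urban"):
            raise ConfigError(f"origin must be 'forest' or 'urban', got {self.origin!r}")
        if abs(sum(self.chuck_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.chuck_probs):
            raise ConfigError("chuck_probs must be nonnegative and sum to 1")
        if self.pause_max_s < self.pause_min_s:
            raise ConfigError("pause_max_s must be >= pause_min_s")
        if not math.isfinite(self.choice_slope):
            raise ConfigError("choice_slope must be finite")
        if self.amplitude_cv < 0:
            raise ConfigError(f"amplitude_cv must be >= 0, got {self.amplitude_cv}")
        if self.trials_per_stimulus < 0:
            raise ConfigError("trials_per_stimulus must be >= 0")


@dataclass(frozen=True)
class TimelineCall:
    """A generated call with its true (noise-free) peak amplitude."""

    male_id: str
    onset: float
    offset: float
    n_chucks: int
    peak_amplitude: float

    def to_event(self) -> CallEvent:
        return CallEvent(
            male_id=self.male_id, onset=self.onset,
            offset=self.offset, n_chucks=self.n_chucks,
        )


def _streams(config: SimConfig) -> list[np.random.Generator]:
    # documented stream order: bout schedule, male A, male B, waveform noise, choices
    return np.random.default_rng(config.seed).spawn(5)


def _rest_schedule(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Shared dyad rests: bouts ~ gamma(2) with the configured mean, rests
    uniform on [pause_min_s, pause_max_s] (both > the 10 s pause threshold)."""
    mean_bout = config.mean_bout_s * (
        config.urban_bout_factor if config.condition == "urban" else 1.0
    )
    rests = []
    t = float(rng.gamma(2.0, mean_bout / 2.0))
    while t < config.session_duration:
        rest = float(rng.uniform(config.pause_min_s, config.pause_max_s))
        rests.append((t, t + rest))
        t += rest + float(rng.gamma(2.0, mean_bout / 2.0))
    return rests


def _male_timeline(
    config: SimConfig,
    male_id: str,
    rng: np.random.Generator,
    start: float,
    rests: list[tuple[float, float]],
) -> list[TimelineCall]:
    amp_mean = config.mean_amplitude * (
        config.urban_amplitude_factor if config.condition == "urban" else 1.0
    )
    # lognormal with the requested mean and CV
    if config.amplitude_cv > 0:
        sigma2 = math.log(1.0 + config.amplitude_cv**2)
        mu = math.log(amp_mean) - sigma2 / 2.0
    scale = config.mean_interval_s / config.interval_shape

    calls: list[TimelineCall] = []
    t = start
    while True:
        for r0, r1 in rests:  # no calling during a shared rest
            if r0 <= t < r1:
                t = r1 + start
        n_chucks = int(rng.choice(len(config.chuck_probs), p=config.chuck_probs))
        duration = config.whine_duration_s + CHUCK_DURATION_S * n_chucks
        if t + duration > config.session_duration:
            break
        amp = (
            float(rng.lognormal(mu, math.sqrt(sigma2)))
            if config.amplitude_cv > 0
            else amp_mean
        )
        calls.append(
            TimelineCall(
                male_id=male_id, onset=t, offset=t + duration,
                n_chucks=n_chucks, peak_amplitude=amp,
            )
        )
        interval = max(float(rng.gamma(config.interval_shape, scale)), duration + 0.05)
        t += interval
    return calls


def gen_call_timeline(
    config: SimConfig,
) -> tuple[list[TimelineCall], list[TimelineCall]]:
    """Two males' call timelines for one session.

    Each male is a gamma renewal process of call onsets (mean
    ``mean_interval_s``, shape ``interval_shape``), male B lagged by the
    alternation offset. Both males observe a shared bout/rest schedule whose
    rests exceed the 10 s dyad-pause threshold, so sessions contain several
    separate interactions. Events are sorted, non-overlapping within a male,
    and lie in [0, session_duration]. Fixed seed ⇒ bit-identical output.
    """
    config.validate()
    rng_sched, rng_a, rng_b, _, _ = _streams(config)
    rests = _rest_schedule(config, rng_sched)
    a = _male_timeline(config, "A", rng_a, start=0.0, rests=rests)
    b = _male_timeline(config, "B", rng_b, start=config.alternation_offset_s, rests=rests)
    return a, b


def timeline_to_events(calls: Sequence[TimelineCall]) -> list[CallEvent]:
    return [c.to_event() for c in calls]


def timeline_to_frame(
    calls: Sequence[TimelineCall], truth: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Events table (male_id, onset_s, offset_s, n_chucks [, true_rms, true_p2p])."""
    df = pd.DataFrame(
        [
            {
                "male_id": c.male_id, "onset_s": c.onset, "offset_s": c.offset,
                "n_chucks": c.n_chucks, "peak_amplitude": c.peak_amplitude,
            }
            for c in calls
        ],
        columns=["male_id", "onset_s", "offset_s", "n_chucks", "peak_amplitude"],
    )
    if truth is not None:
        df = df.join(truth[["true_rms", "true_p2p"]])
    return df


# ---------------------------------------------------------------------------
# Waveform synthesis

WHINE_F_HIGH = 900.0  # downward sweep within the ~0.4–1 kHz whine band
WHINE_F_LOW = 400.0
CHUCK_FREQ = 2500.0   # chuck energy concentrated above 2 kHz
CHUCK_GAIN = 1.2


def _whine(duration: float, amplitude: float, sample_rate: float) -> np.ndarray:
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    # linear downward sweep; instantaneous phase = 2π∫f dt
    freq_slope = (WHINE_F_LOW - WHINE_F_HIGH) / duration
    phase = 2 * np.pi * (WHINE_F_HIGH * t + 0.5 * freq_slope * t**2)
    # Tukey envelope: flat center, 10% cosine ramps to avoid clicks
    env = np.ones(n)
    ramp = max(int(0.1 * n), 1)
    ramp_shape = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[:ramp] = ramp_shape
    env[-ramp:] = ramp_shape[::-1]
    return amplitude * env * np.sin(phase)


def _chuck(amplitude: float, sample_rate: float) -> np.ndarray:
    n = int(round(CHUCK_DURATION_S * sample_rate))
    t = np.arange(n) / sample_rate
    env = np.sin(np.pi * np.arange(n) / n) ** 2
    return CHUCK_GAIN * amplitude * env * np.sin(2 * np.pi * CHUCK_FREQ * t)


def gen_waveform(
    calls: Sequence[TimelineCall],
    sample_rate: int = 22050,
    background_rms: float = 0.0,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Mono waveform for one male's channel plus a ground-truth table.

    Each call is a whine sweep followed by its chucks; white Gaussian noise of
    RMS ``background_rms`` is added afterwards. The ground-truth table holds
    each call's RMS and P2P measured on the clean signal over [onset, offset],
    before noise — the oracle for round-trip amplitude tests.
    """
    if sample_rate < 8000:
        raise ConfigError(f"sample_rate must be >= 8000 Hz, got {sample_rate}")
    if duration is None:
        duration = (max(c.offset for c in calls) + 0.5) if calls else 1.0
    if calls and max(c.offset for c in calls) > duration:
        raise ValueError("events exceed the requested waveform duration")
    n = math.ceil(duration * sample_rate)
    clean = np.zeros(n)
    rows = []
    for c in calls:
        i0 = int(round(c.onset * sample_rate))
        whine = _whine(
            c.offset - c.onset - CHUCK_DURATION_S * c.n_chucks,
            c.peak_amplitude,
            sample_rate,
        )
        parts = [whine] + [_chuck(c.peak_amplitude, sample_rate)] * c.n_chucks
        call_sig = np.concatenate(parts)
        i1 = min(i0 + call_sig.size, n)
        clean[i0:i1] += call_sig[: i1 - i0]
        span = clean[i0:i1]
        rows.append(
            {
                "male_id": c.male_id,
                "onset_s": c.onset,
                "offset_s": c.offset,
                "true_rms": float(np.sqrt(np.mean(span**2))),
                "true_p2p": float(span.max() - span.min()),
            }
        )
    if background_rms > 0:
        if rng is None:
            rng = np.random.default_rng(seed).spawn(5)[3]
        clean = clean + rng.normal(0.0, background_rms, size=n)
    return clean, pd.DataFrame(
        rows, columns=["male_id", "onset_s", "offset_s", "true_rms", "true_p2p"]
    )


# ---------------------------------------------------------------------------
# Choice trials

def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def gen_choices(
    stimuli: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bernoulli choice trials for each stimulus.

    ``stimuli`` needs columns ``stimulus_id``, ``prop_diff_call_rate`` and
    ``faster`` ('A' or 'B'); optional ``rival_pair_id``, ``male_origin``,
    ``male_treatment`` are carried through. Per trial the probability of
    choosing the faster-calling male is
    ``logistic(choice_slope × proportional call-rate difference)`` —
    slope 0 is a fair coin; the slope sign sets the association direction
    (positive: larger rate contrast, stronger bias). Latencies are lognormal.
    """
    config.validate()
    required = {"stimulus_id", "prop_diff_call_rate", "faster"}
    if not required.issubset(stimuli.columns):
        raise ConfigError(f"stimuli table missing columns {required - set(stimuli.columns)}")
    if rng is None:
        rng = _streams(config)[4]
    rows = []
    fid = 0
    for s in stimuli.itertuples():
        faster = str(s.faster)
        slower = "B" if faster == "A" else "A"
        p = _logistic(config.choice_slope * float(s.prop_diff_call_rate))
        for _ in range(config.trials_per_stimulus):
            pick_faster = bool(rng.random() < p)
            rows.append(
                {
                    "female_id": f"F{fid:04d}",
                    "female_origin": config.origin,
                    "female_treatment": config.condition,
                    "stimulus_id": s.stimulus_id,
                    "rival_pair_id": getattr(s, "rival_pair_id", s.stimulus_id),
                    "male_origin": getattr(s, "male_origin", config.origin),
                    "male_treatment": getattr(s, "male_treatment", config.condition),
                    "chosen": faster if pick_faster else slower,
                    "latency_s": float(rng.lognormal(math.log(60.0), 0.5)),
                }
            )
            fid += 1
    return pd.DataFrame(rows)
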