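"""Synthetic observer: generative model for button presses and 4AFC memory.

Detection presses are generated per sequence: with a condition-dependent hit
probability the observer emits exactly one press at the second-presentation
onset plus a shifted-lognormal reaction time, occasionally a second in-window
press, and false alarms arrive as a homogeneous Poisson process over the
whole stream (plus the trailing response window).  Memory responses pick the
target with a condition-dependent probability (else one of the three foils,
uniformly), with confidence drawn from separate discrete distributions for
correct and incorrect choices.

Default parameters are calibrated to two documented anchors of the behavioural
data: ~13.4 presses per 20-sequence block and ~2% of trials containing more
than one in-window response, with hit probability decreasing in the number
of distractors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .schedule import (N_SEQUENCES_PER_BLOCK, SessionDesign, StreamSchedule)

# the scoring rule's response window, also used generatively for "in-window"
# extra presses (ms after second-presentation onset)
WINDOW_START_MS = 200.0
WINDOW_END_MS = 2500.0

CONDITION_GROUPS = [f"R{d}" for d in range(1, 6)] + \
    [f"I{d}" for d in range(1, 6)]

PRESS_COLUMNS = ["participant", "block", "time_ms"]
MEMORY_COLUMNS = ["participant", "block", "probe_pos", "stream_pos",
                  "sequence_id", "target_id", "foil1", "foil2", "foil3",
                  "choice_id", "rt_ms", "confidence"]


class ObserverError(ValueError):
    """Invalid observer parameters or simulation inputs."""


def _check_prob_map(name: str, mapping: Mapping[str, float],
                    low: float = 0.0) -> dict[str, float]:
    out = {}
    for group in CONDITION_GROUPS:
        if group not in mapping:
            raise ObserverError(f"{name} must define group {group}")
        p = float(mapping[group])
        if not (low <= p <= 1.0):
            raise ObserverError(f"{name}[{group}]={p} outside [{low}, 1]")
        out[group] = p
    return out


def _check_conf_dist(name: str, dist: Sequence[float]) -> tuple[float, ...]:
    dist = tuple(float(p) for p in dist)
    if len(dist) != 5 or any(p < 0 for p in dist) or abs(sum(dist) - 1) > 1e-9:
        raise ObserverError(
            f"{name} must be a probability distribution over ratings 0..4")
    return dist


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic observer.

    ``hit_prob`` and ``mem_acc`` map condition groups (``R1``..``R5``,
    ``I1``..``I5``) to the probability of a detection press / correct 4AFC
    choice.  Reaction times are shift + lognormal(log(scale), sigma),
    truncated to the response window for presses.  ``fa_rate_hz`` is the
    false-alarm Poisson rate in presses per second.  ``mem_recency_slope``
    tilts memory accuracy with the target's stream position (logit scale,
    zero by default); it exists to let analyses inject a known recency
    effect.
    """

    hit_prob: Mapping[str, float]
    mem_acc: Mapping[str, float]
    conf_given_correct: tuple[float, ...]
    conf_given_error: tuple[float, ...]
    rt_shift_ms: float = 200.0
    rt_scale_ms: float = 600.0
    rt_sigma: float = 0.5
    extra_press_prob: float = 0.015
    fa_rate_hz: float = 0.01
    mem_rt_shift_ms: float = 300.0
    mem_rt_scale_ms: float = 1200.0
    mem_rt_sigma: float = 0.4
    mem_recency_slope: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "hit_prob",
                           _check_prob_map("hit_prob", self.hit_prob))
        # raw 4AFC accuracy cannot fall below the 0.25 chance floor
        object.__setattr__(self, "mem_acc",
                           _check_prob_map("mem_acc", self.mem_acc, low=0.25))
        object.__setattr__(self, "conf_given_correct",
                           _check_conf_dist("conf_given_correct",
                                            self.conf_given_correct))
        object.__setattr__(self, "conf_given_error",
                           _check_conf_dist("conf_given_error",
                                            self.conf_given_error))
        if not (0 <= self.extra_press_prob <= 1):
            raise ObserverError("extra_press_prob must be a probability")
        if self.fa_rate_hz < 0:
            raise ObserverError("fa_rate_hz must be non-negative")
        for name in ("rt_shift_ms", "rt_scale_ms", "rt_sigma",
                     "mem_rt_shift_ms", "mem_rt_scale_ms", "mem_rt_sigma"):
            if getattr(self, name) <= 0:
                raise ObserverError(f"{name} must be positive")

    def with_(self, **kwargs) -> "ObserverParams":
        """Copy with some fields replaced."""
        return replace(self, **kwargs)


def default_params(seed: int | None = None) -> ObserverParams:
    """Calibrated defaults for a plausible human-like observer.

    Hit probability falls with the distractor count (steeply for regular,
    shallowly for irregular-by-first-interval groups); the overall mean of
    0.615 together with a 1.5% double-press probability and a 0.01/s
    false-alarm rate reproduces ~13.4 presses per block and ~2% multi-press
    trials.  Memory accuracy sits between 4AFC chance (0.25) and ceiling and
    confidence is stochastically larger on correct trials.
    """
    return ObserverParams(
        hit_prob={"R1": 0.79, "R2": 0.69, "R3": 0.61, "R4": 0.53, "R5": 0.45,
                  "I1": 0.67, "I2": 0.64, "I3": 0.61, "I4": 0.59, "I5": 0.57},
        mem_acc={"R1": 0.80, "R2": 0.72, "R3": 0.65, "R4": 0.58, "R5": 0.52,
                 "I1": 0.70, "I2": 0.67, "I3": 0.65, "I4": 0.63, "I5": 0.61},
        conf_given_correct=(0.05, 0.10, 0.20, 0.30, 0.35),
        conf_given_error=(0.30, 0.30, 0.20, 0.12, 0.08),
        seed=seed,
    )


@dataclass
class ButtonPressLog:
    """Detection presses for one participant x block, ms from stream onset."""

    participant_id: int
    block_id: int
    press_times: np.ndarray

    def __post_init__(self):
        self.press_times = np.asarray(self.press_times, dtype=float)
        if self.press_times.ndim != 1:
            raise ObserverError("press_times must be one-dimensional")
        if len(self.press_times) and self.press_times.min() < 0:
            raise ObserverError("press times must be non-negative")
        if np.any(np.diff(self.press_times) < 0):
            raise ObserverError("press times must be sorted")

    def __len__(self) -> int:
        return len(self.press_times)


@dataclass(frozen=True)
class MemoryTrial:
    """One 4AFC probe: target among three foils, with RT and confidence."""

    probe_pos: int        # 1..20, order in the memory task
    stream_pos: int       # 1..20, order of the sequence in the stream
    sequence_id: int
    target_id: int
    foils: tuple[int, int, int]
    choice_id: int
    rt_ms: float
    confidence: int

    def __post_init__(self):
        if self.choice_id not in (self.target_id, *self.foils):
            raise ObserverError("choice must be one of the four options")
        if not (0 <= self.confidence <= 4):
            raise ObserverError("confidence must be on the 0..4 scale")

    @property
    def correct(self) -> bool:
        return self.choice_id == self.target_id


@dataclass
class MemoryResponseSet:
    """The 20 memory probes following one block."""

    participant_id: int
    block_id: int
    trials: list[MemoryTrial]

    def __post_init__(self):
        if len(self.trials) != N_SEQUENCES_PER_BLOCK:
            raise ObserverError("expected 20 memory trials per block")
        probes = sorted(t.probe_pos for t in self.trials)
        streams = sorted(t.stream_pos for t in self.trials)
        if probes != list(range(1, 21)) or streams != list(range(1, 21)):
            raise ObserverError(
                "probe and stream positions must each be a permutation of 1..20")
        foils = [f for t in self.trials for f in t.foils]
        if len(set(foils)) != len(foils):
            raise ObserverError("each foil may be used in at most one probe")


def _trunc_shifted_lognormal(rng: np.random.Generator, n: int, shift: float,
                             scale: float, sigma: float,
                             lo: float, hi: float) -> np.ndarray:
    """Draw shift + LogNormal(log scale, sigma), rejection-truncated to (lo, hi)."""
    out = shift + rng.lognormal(np.log(scale), sigma, size=n)
    for _ in range(200):
        bad = (out <= lo) | (out >= hi)
        if not bad.any():
            break
        out[bad] = shift + rng.lognormal(np.log(scale), sigma, size=bad.sum())
    else:  # pathological parameters: fall back to uniform in the window
        bad = (out <= lo) | (out >= hi)
        out[bad] = rng.uniform(lo, hi, size=bad.sum())
    return out


def simulate_presses(schedule: StreamSchedule, params: ObserverParams,
                     seed: int | None = None,
                     participant_id: int = 0) -> ButtonPressLog:
    """Simulate one block's detection presses.

    Each sequence is detected with its group's hit probability, producing a
    press at the second-presentation onset plus a truncated reaction time;
    a detected sequence may receive one extra in-window press.  False alarms
    are Poisson over the stream duration plus the final response window.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    t2 = np.array([seq.second_onset_ms for seq in schedule.sequences])
    hit_p = np.array([params.hit_prob[seq.condition.group]
                      for seq in schedule.sequences])
    hits = rng.random(len(t2)) < hit_p
    times = []
    if hits.any():
        rts = _trunc_shifted_lognormal(
            rng, int(hits.sum()), params.rt_shift_ms, params.rt_scale_ms,
            params.rt_sigma, WINDOW_START_MS, WINDOW_END_MS)
        times.append(t2[hits] + rts)
        extra = rng.random(int(hits.sum())) < params.extra_press_prob
        if extra.any():
            lo = t2[hits][extra] + WINDOW_START_MS
            hi = t2[hits][extra] + WINDOW_END_MS
            times.append(rng.uniform(lo, hi))
    horizon_ms = schedule.total_duration_ms + WINDOW_END_MS
    n_fa = rng.poisson(params.fa_rate_hz * horizon_ms / 1000.0)
    if n_fa:
        times.append(rng.uniform(0.0, horizon_ms, size=n_fa))
    all_times = np.sort(np.concatenate(times)) if times else np.empty(0)
    return ButtonPressLog(participant_id=participant_id,
                          block_id=schedule.block_id, press_times=all_times)


def simulate_memory(schedule: StreamSchedule,
                    detected_flags: Sequence[bool],
                    params: ObserverParams,
                    seed: int | None = None,
                    participant_id: int = 0) -> MemoryResponseSet:
    """Simulate the 4AFC memory responses following one block.

    Probe order is a fresh uniform permutation of the stream order; the three
    foils of each probe are distinct single-presentation images from the same
    stream, disjoint across probes.  ``detected_flags`` (one per sequence) is
    accepted for interface symmetry with the scoring pipeline; the generative
    model draws accuracy from the condition group alone.
    """
    if len(detected_flags) != len(schedule.sequences):
        raise ObserverError("need one detected flag per sequence")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = len(schedule.sequences)
    pool = schedule.image_ids[~schedule.is_target]
    foils = rng.choice(pool, size=(n, 3), replace=False)
    probe_of_stream = np.argsort(rng.permutation(n))  # stream idx -> probe idx
    rts = _trunc_shifted_lognormal(
        rng, n, params.mem_rt_shift_ms, params.mem_rt_scale_ms,
        params.mem_rt_sigma, 200.0, 10000.0)

    trials: list[MemoryTrial] = []
    for s, seq in enumerate(schedule.sequences):
        acc = params.mem_acc[seq.condition.group]
        if params.mem_recency_slope:
            stream_pos = s + 1
            acc = float(expit(logit(np.clip(acc, 1e-6, 1 - 1e-6))
                              + params.mem_recency_slope * (stream_pos - 10.5)))
        correct = rng.random() < acc
        choice = seq.target_image if correct else int(
            foils[s, rng.integers(3)])
        dist = params.conf_given_correct if correct else params.conf_given_error
        confidence = int(rng.choice(5, p=dist))
        trials.append(MemoryTrial(
            probe_pos=int(probe_of_stream[s]) + 1, stream_pos=s + 1,
            sequence_id=seq.sequence_id, target_id=seq.target_image,
            foils=tuple(int(f) for f in foils[s]), choice_id=int(choice),
            rt_ms=float(rts[s]), confidence=confidence))
    trials.sort(key=lambda t: t.probe_pos)
    return MemoryResponseSet(participant_id=participant_id,
                             block_id=schedule.block_id, trials=trials)


def simulate_session(design: SessionDesign, params: ObserverParams,
                     seed: int | None = None
                     ) -> tuple[list[ButtonPressLog], list[MemoryResponseSet]]:
    """Simulate presses and memory responses for a whole session."""
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    children = root.spawn(2 * len(design.blocks))
    logs, responses = [], []
    for i, block in enumerate(design.blocks):
        press_seed = int(children[2 * i].generate_state(1)[0] % (2 ** 31))
        mem_seed = int(children[2 * i + 1].generate_state(1)[0] % (2 ** 31))
        log = simulate_presses(block, params, seed=press_seed,
                               participant_id=design.participant_id)
        logs.append(log)
        flags = [False] * len(block.sequences)  # generative accuracy is
        responses.append(simulate_memory(      # condition-driven, see docstring
            block, flags, params, seed=mem_seed,
            participant_id=design.participant_id))
    return logs, responses


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_press_logs(logs: Sequence[ButtonPressLog], path) -> None:
    rows = [(log.participant_id, log.block_id, t)
            for log in logs for t in log.press_times]
    pd.DataFrame(rows, columns=PRESS_COLUMNS).to_csv(
        Path(path), index=False, float_format="%.17g")


def read_press_logs(path) -> list[ButtonPressLog]:
    frame = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in PRESS_COLUMNS if c not in frame.columns]
    if missing:
        raise ObserverError(f"press log missing column(s): {missing}")
    logs = []
    for (pid, block), sub in frame.groupby(["participant", "block"],
                                           sort=True):
        logs.append(ButtonPressLog(int(pid), int(block),
                                   np.sort(sub["time_ms"].to_numpy())))
    return logs


def write_memory_responses(responses: Sequence[MemoryResponseSet],
                           path) -> None:
    rows = []
    for rs in responses:
        for t in rs.trials:
            rows.append((rs.participant_id, rs.block_id, t.probe_pos,
                         t.stream_pos, t.sequence_id, t.target_id,
                         *t.foils, t.choice_id, t.rt_ms, t.confidence))
    pd.DataFrame(rows, columns=MEMORY_COLUMNS).to_csv(
        Path(path), index=False, float_format="%.17g")


def read_memory_responses(path) -> list[MemoryResponseSet]:
    frame = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in MEMORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ObserverError(f"memory table missing column(s): {missing}")
    out = []
    for (pid, block), sub in frame.groupby(["participant", "block"],
                                           sort=True):
        trials = [MemoryTrial(
            probe_pos=int(r.probe_pos), stream_pos=int(r.stream_pos),
            sequence_id=int(r.sequence_id), target_id=int(r.target_id),
            foils=(int(r.foil1), int(r.foil2), int(r.foil3)),
            choice_id=int(r.choice_id), rt_ms=float(r.rt_ms),
            confidence=int(r.confidence)) for r in sub.itertuples()]
        trials.sort(key=lambda t: t.probe_pos)
        out.append(MemoryResponseSet(int(pid), int(block), trials))
    return out
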