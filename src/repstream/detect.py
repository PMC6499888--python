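"""Detection scoring: window rule, scrambled-timestamp chance level, contrasts.

A repetition sequence counts as *detected* when exactly one button press
falls strictly inside the window 200-2500 ms after the onset of the target's
second presentation (the first repetition), which is also the reaction-time
origin.  Chance level is estimated by rescoring the same press counts after
replacing all timestamps with uniform random ones; the difference between
real and scrambled detection rates (in percentage points) is the
chance-corrected performance measure.

Irregular trials are grouped by the number of distractors before the first
repetition (``I1``..``I5``) for per-condition summaries, but pooled for the
two regular-vs-irregular contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schedule import RepetitionSequence, SessionDesign, StreamSchedule

SCORE_COLUMNS = ["participant", "block", "sequence_id", "cond_group",
                 "detected", "rt_ms", "n_in_window"]


class ScoringError(ValueError):
    """Invalid input to a scoring operation."""


@dataclass(frozen=True)
class DetectionWindow:
    """Response window in ms after the second-presentation onset."""

    start_offset_ms: float = 200.0
    end_offset_ms: float = 2500.0

    def __post_init__(self):
        if not (0 < self.start_offset_ms < self.end_offset_ms):
            raise ScoringError("need 0 < start_offset < end_offset")

    @property
    def width_ms(self) -> float:
        return self.end_offset_ms - self.start_offset_ms


@dataclass(frozen=True)
class SequenceScore:
    """Outcome of the window rule for one sequence."""

    participant_id: int
    block_id: int
    sequence_id: int
    cond_group: str
    detected: bool
    rt_ms: float | None
    n_presses_in_window: int

    def __post_init__(self):
        if self.detected != (self.n_presses_in_window == 1):
            raise ScoringError("detected must mean exactly one in-window press")
        if (self.rt_ms is None) == self.detected:
            raise ScoringError("rt_ms must be present iff detected")


@dataclass(frozen=True)
class ConditionSummary:
    """Aggregate detection outcome for one condition group."""

    cond_group: str
    detection_rate: float
    mean_rt_ms: float
    n_trials: int
    chance_rate: float | None = None

    @property
    def pp_difference(self) -> float | None:
        """Real minus scrambled detection rate, in percentage points."""
        if self.chance_rate is None:
            return None
        return 100.0 * (self.detection_rate - self.chance_rate)


def group_condition(sequence: RepetitionSequence) -> str:
    """Condition group of a sequence: ``R{d}`` or ``I{first interval}``."""
    return sequence.condition.group


def _press_array(presses) -> np.ndarray:
    times = presses.press_times if hasattr(presses, "press_times") \
        else np.asarray(presses, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ScoringError("press times must be sorted")
    return times


def _sequences_of(schedule) -> list[RepetitionSequence]:
    if isinstance(schedule, StreamSchedule):
        return schedule.sequences
    return list(schedule)


def score_block(schedule, presses, window: DetectionWindow | None = None,
                *, participant_id: int | None = None) -> list[SequenceScore]:
    """Apply the one-and-only-one-press window rule to one block.

    ``schedule`` may be a :class:`StreamSchedule` or a plain sequence list.
    Should two windows overlap, a press is assigned to the earlier sequence
    only, so it can never be counted twice.
    """
    window = window or DetectionWindow()
    sequences = _sequences_of(schedule)
    times = _press_array(presses)
    if participant_id is None:
        participant_id = getattr(presses, "participant_id", 0)
    block_id = getattr(presses, "block_id",
                       getattr(schedule, "block_id", 0))
    order = np.argsort([seq.second_onset_ms for seq in sequences],
                       kind="stable")
    assigned = np.zeros(len(times), dtype=bool)
    counts = np.zeros(len(sequences), dtype=int)
    rt: dict[int, float] = {}
    for i in order:
        t2 = sequences[i].second_onset_ms
        in_window = ((times > t2 + window.start_offset_ms)
                     & (times < t2 + window.end_offset_ms) & ~assigned)
        counts[i] = int(in_window.sum())
        if counts[i] == 1:
            rt[i] = float(times[in_window][0] - t2)
        assigned |= in_window
    return [SequenceScore(
        participant_id=participant_id, block_id=block_id,
        sequence_id=seq.sequence_id, cond_group=seq.condition.group,
        detected=counts[i] == 1, rt_ms=rt.get(i),
        n_presses_in_window=int(counts[i]))
        for i, seq in enumerate(sequences)]


def score_session(design: SessionDesign, logs, window=None
                  ) -> list[SequenceScore]:
    """Score every block of a session against its press log."""
    by_block = {log.block_id: log for log in logs}
    scores: list[SequenceScore] = []
    for block in design.blocks:
        scores.extend(score_block(block, by_block[block.block_id], window))
    return scores


def scores_frame(scores: Iterable[SequenceScore]) -> pd.DataFrame:
    """Sequence scores as a tidy table."""
    return pd.DataFrame(
        [(s.participant_id, s.block_id, s.sequence_id, s.cond_group,
          s.detected, np.nan if s.rt_ms is None else s.rt_ms,
          s.n_presses_in_window) for s in scores],
        columns=SCORE_COLUMNS)


def write_scores(scores, path) -> None:
    frame = scores if isinstance(scores, pd.DataFrame) else scores_frame(scores)
    frame.to_csv(Path(path), index=False)


def read_scores(path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path))
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ScoringError(f"scores file missing column(s): {missing}")
    return frame


# ---------------------------------------------------------------------------
# scrambled-timestamp chance level
# ---------------------------------------------------------------------------

def scramble_log(presses, t_max: float, seed: int | None = None):
    """Replace press timestamps with sorted i.i.d. uniforms on [0, t_max]."""
    if t_max <= 0:
        raise ScoringError("t_max must be positive")
    times = _press_array(presses)
    rng = np.random.default_rng(seed)
    scrambled = np.sort(rng.uniform(0.0, t_max, size=len(times)))
    if hasattr(presses, "press_times"):
        from .observer import ButtonPressLog
        return ButtonPressLog(presses.participant_id, presses.block_id,
                              scrambled)
    return scrambled


def scramble_horizon_ms(schedule: StreamSchedule,
                        window: DetectionWindow | None = None) -> float:
    """Scramble domain: last image offset plus the response window."""
    window = window or DetectionWindow()
    return (float(schedule.onsets_ms[-1])
            + schedule.timing.image_duration_ms + window.end_offset_ms)


def chance_level(schedule: StreamSchedule, presses,
                 window: DetectionWindow | None = None,
                 n_scrambles: int = 1,
                 seed: int | None = None) -> dict[str, float]:
    """Mean scrambled detection rate per condition group for one block.

    ``n_scrambles=1`` mirrors the original single-scramble procedure; larger
    values average over scrambles to reduce Monte-Carlo noise.  When no
    window overlaps another (true of all generated designs) the scrambles are
    scored vectorised; otherwise each scramble goes through
    :func:`score_block`.
    """
    if n_scrambles < 1:
        raise ScoringError("n_scrambles must be at least 1")
    window = window or DetectionWindow()
    times = _press_array(presses)
    k = len(times)
    t_max = scramble_horizon_ms(schedule, window)
    groups = [seq.condition.group for seq in schedule.sequences]
    if k == 0:
        return {g: 0.0 for g in sorted(set(groups))}
    starts = np.array([seq.second_onset_ms + window.start_offset_ms
                       for seq in schedule.sequences])
    ends = starts + window.width_ms
    rng = np.random.default_rng(seed)
    no_overlap = np.all(ends[np.argsort(starts)][:-1]
                        <= starts[np.argsort(starts)][1:])
    hits = np.zeros(len(groups))
    if no_overlap:
        draws = rng.uniform(0.0, t_max, size=(n_scrambles, k))
        for i in range(len(groups)):
            inside = (draws > starts[i]) & (draws < ends[i])
            hits[i] = np.mean(inside.sum(axis=1) == 1)
    else:  # rare overlapping-window case: fall back to the exact rule
        for _ in range(n_scrambles):
            scrambled = np.sort(rng.uniform(0.0, t_max, size=k))
            for i, score in enumerate(score_block(schedule, scrambled, window)):
                hits[i] += score.detected / n_scrambles
    out: dict[str, list[float]] = {}
    for g, h in zip(groups, hits):
        out.setdefault(g, []).append(h)
    return {g: float(np.mean(v)) for g, v in sorted(out.items())}


def chance_level_session(design: SessionDesign, logs,
                         window: DetectionWindow | None = None,
                         n_scrambles: int = 1,
                         seed: int | None = None) -> dict[str, float]:
    """Trial-weighted scrambled detection rate per group over a session."""
    by_block = {log.block_id: log for log in logs}
    seeds = np.random.SeedSequence(seed).spawn(len(design.blocks))
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for block, child in zip(design.blocks, seeds):
        block_groups = [seq.condition.group for seq in block.sequences]
        rates = chance_level(block, by_block[block.block_id], window,
                             n_scrambles,
                             seed=int(child.generate_state(1)[0] % (2 ** 31)))
        for g in block_groups:
            sums[g] = sums.get(g, 0.0) + rates[g]
            counts[g] = counts.get(g, 0) + 1
    return {g: sums[g] / counts[g] for g in sorted(sums)}


def summarize_conditions(scores,
                         chance_rates: Mapping[str, float] | None = None
                         ) -> list[ConditionSummary]:
    """Per-group detection rate and mean RT, optionally with chance rates."""
    frame = scores if isinstance(scores, pd.DataFrame) else scores_frame(scores)
    out = []
    for group, sub in frame.groupby("cond_group", sort=True):
        detected = sub["detected"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_rt = float(np.nanmean(sub["rt_ms"])) if detected.any() \
                else float("nan")
        out.append(ConditionSummary(
            cond_group=str(group), detection_rate=float(detected.mean()),
            mean_rt_ms=mean_rt, n_trials=int(len(sub)),
            chance_rate=None if chance_rates is None
            else float(chance_rates.get(str(group), 0.0))))
    return out


# ---------------------------------------------------------------------------
# regular-vs-irregular contrasts (paired, per participant)
# ---------------------------------------------------------------------------

def _as_frame(scores) -> pd.DataFrame:
    return scores if isinstance(scores, pd.DataFrame) else scores_frame(scores)


def _participant_diff(reg: pd.DataFrame, irr: pd.DataFrame
                      ) -> tuple[float, float]:
    """Irregular minus regular (detection rate, mean detected RT)."""
    rate = irr["detected"].mean() - reg["detected"].mean()
    rt_irr = irr.loc[irr["detected"], "rt_ms"].mean()
    rt_reg = reg.loc[reg["detected"], "rt_ms"].mean()
    return float(rate), float(rt_irr - rt_reg)


def contrast_r3_vs_irregular(scores, seed: int | None = None) -> pd.DataFrame:
    """Regular-3 trials against an equal-size random irregular subsample.

    The two groups share the sequence length (21 images) and mean spacing by
    design.  Returns per-participant Irregular - Regular differences in
    detection rate and mean RT.
    """
    frame = _as_frame(scores)
    rng = np.random.default_rng(seed)
    rows = {}
    for pid, sub in frame.groupby("participant", sort=True):
        reg = sub[sub["cond_group"] == "R3"]
        irr = sub[sub["cond_group"].str.startswith("I")]
        if len(irr) < len(reg):
            raise ScoringError(
                f"participant {pid}: fewer irregular ({len(irr)}) than "
                f"regular-3 ({len(reg)}) trials")
        take = irr.iloc[rng.choice(len(irr), size=len(reg), replace=False)]
        rows[pid] = _participant_diff(reg, take)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["detection_diff", "rt_diff_ms"]
    ).rename_axis("participant")


def contrast_all_regular_vs_all_irregular(scores) -> pd.DataFrame:
    """All 120 regular against all 120 irregular trials per participant.

    Both pools contain every inter-repetition interval equally often, so the
    contrast equalises the spacing distribution rather than the sequence
    length.
    """
    frame = _as_frame(scores)
    rows = {}
    for pid, sub in frame.groupby("participant", sort=True):
        reg = sub[sub["cond_group"].str.startswith("R")]
        irr = sub[sub["cond_group"].str.startswith("I")]
        rows[pid] = _participant_diff(reg, irr)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["detection_diff", "rt_diff_ms"]
    ).rename_axis("participant")
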