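"""Scoring of the 4AFC memory task and the stream-to-probe delay analysis.

Accuracy, reaction time and confidence are aggregated per condition group —
first within participant, then across participants.  The delay between a
target's appearance in the stream and its probe in the memory task is the
number of intervening targets in the stream plus those in the memory task,
plus one; with stream position ``i`` and probe position ``j`` (both 1..20)
this is ``20 - i + j``.  Delays 3-20 count as short and 21-37 as long; the
rare extremes are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .observer import MemoryResponseSet, MemoryTrial
from .schedule import SessionDesign
from .stats import BootstrapCI, bca_bootstrap

MEMORY_SCORE_COLUMNS = ["participant", "cond_group", "accuracy",
                        "mean_rt_ms", "mean_conf", "n"]

SHORT_DELAY = (3, 20)
LONG_DELAY = (21, 37)


class MemoryScoringError(ValueError):
    """Invalid input to a memory scoring operation."""


@dataclass(frozen=True)
class MemoryScore:
    """Aggregate 4AFC outcome for one condition group (chance = 0.25)."""

    cond_group: str
    accuracy: float
    mean_rt_ms: float
    mean_confidence: float
    n_trials: int

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0):
            raise MemoryScoringError("accuracy must lie in [0, 1]")
        if not (0.0 <= self.mean_confidence <= 4.0):
            raise MemoryScoringError("confidence is on the 0..4 scale")


@dataclass(frozen=True)
class DelayRecord:
    """Delay between stream appearance and memory probe, with its bin."""

    stream_pos: int
    probe_pos: int
    delay: int
    bin: str  # "short", "long" or "excluded"


def compute_delay(trial_or_stream_pos, probe_pos: int | None = None
                  ) -> DelayRecord:
    """Delay of one memory trial: ``20 - stream_pos + probe_pos``.

    Accepts a :class:`~repstream.observer.MemoryTrial` or the two 1-based
    positions directly.
    """
    if isinstance(trial_or_stream_pos, MemoryTrial):
        i, j = trial_or_stream_pos.stream_pos, trial_or_stream_pos.probe_pos
    else:
        i, j = int(trial_or_stream_pos), int(probe_pos)
    if not (1 <= i <= 20 and 1 <= j <= 20):
        raise MemoryScoringError("positions must lie in 1..20")
    delay = 20 - i + j
    if SHORT_DELAY[0] <= delay <= SHORT_DELAY[1]:
        which = "short"
    elif LONG_DELAY[0] <= delay <= LONG_DELAY[1]:
        which = "long"
    else:
        which = "excluded"
    return DelayRecord(stream_pos=i, probe_pos=j, delay=delay, bin=which)


def _design_map(designs) -> Mapping[int, SessionDesign]:
    if isinstance(designs, SessionDesign):
        return {designs.participant_id: designs}
    if isinstance(designs, Mapping):
        return designs
    return {d.participant_id: d for d in designs}


def memory_frame(responses: Sequence[MemoryResponseSet],
                 designs) -> pd.DataFrame:
    """Memory trials as a tidy table with condition group and correctness.

    Validates each trial against its design: the probed target must be the
    sequence's target and the choice one of the four options (the latter is
    already enforced by :class:`MemoryTrial`).
    """
    by_pid = _design_map(designs)
    rows = []
    for rs in responses:
        design = by_pid[rs.participant_id]
        block = design.blocks[rs.block_id]
        for t in rs.trials:
            seq = block.sequences[t.sequence_id]
            if t.target_id != seq.target_image:
                raise MemoryScoringError(
                    f"participant {rs.participant_id} block {rs.block_id}: "
                    f"probe target {t.target_id} does not match the design")
            delay = compute_delay(t)
            rows.append((rs.participant_id, rs.block_id, t.probe_pos,
                         t.stream_pos, seq.condition.group, t.correct,
                         t.rt_ms, t.confidence, delay.delay, delay.bin))
    return pd.DataFrame(rows, columns=[
        "participant", "block", "probe_pos", "stream_pos", "cond_group",
        "correct", "rt_ms", "confidence", "delay", "delay_bin"])


def score_memory(responses: Sequence[MemoryResponseSet],
                 designs) -> list[MemoryScore]:
    """Per-condition-group memory scores, averaged within then across
    participants."""
    frame = memory_frame(responses, designs)
    per_participant = frame.groupby(["cond_group", "participant"]).agg(
        accuracy=("correct", "mean"), rt=("rt_ms", "mean"),
        conf=("confidence", "mean"), n=("correct", "size"))
    out = []
    for group, sub in per_participant.groupby(level="cond_group", sort=True):
        out.append(MemoryScore(
            cond_group=str(group), accuracy=float(sub["accuracy"].mean()),
            mean_rt_ms=float(sub["rt"].mean()),
            mean_confidence=float(sub["conf"].mean()),
            n_trials=int(sub["n"].sum())))
    return out


def memory_scores_frame(scores: Sequence[MemoryScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.cond_group, s.accuracy, s.mean_rt_ms, s.mean_confidence,
          s.n_trials) for s in scores],
        columns=["cond_group", "accuracy", "mean_rt_ms", "mean_conf", "n"])


def write_memory_scores(responses, designs, path) -> None:
    """Per-participant, per-group memory score CSV."""
    frame = memory_frame(responses, designs)
    table = frame.groupby(["participant", "cond_group"]).agg(
        accuracy=("correct", "mean"), mean_rt_ms=("rt_ms", "mean"),
        mean_conf=("confidence", "mean"), n=("correct", "size")).reset_index()
    table.to_csv(Path(path), index=False, columns=MEMORY_SCORE_COLUMNS)


# ---------------------------------------------------------------------------
# delay split
# ---------------------------------------------------------------------------

def delay_split(responses: Sequence[MemoryResponseSet], designs,
                n_boot: int = 2000, seed: int | None = None) -> dict:
    """Short- versus long-delay comparison of accuracy, RT and confidence.

    Computes per-participant means within each delay bin, then the
    across-participant short-minus-long difference with a 95% BCa bootstrap
    CI.  Participants missing one of the bins are dropped with a warning.
    The pooling is condition-unbalanced by construction.
    """
    frame = memory_frame(responses, designs)
    frame = frame[frame["delay_bin"] != "excluded"]
    per = frame.pivot_table(index="participant", columns="delay_bin",
                            values=["correct", "rt_ms", "confidence"],
                            aggfunc="mean")
    complete = per.dropna()
    dropped = sorted(set(per.index) - set(complete.index))
    if dropped:
        warnings.warn(f"dropping participants without both delay bins: "
                      f"{dropped}", stacklevel=2)
    if complete.empty:
        raise MemoryScoringError("no participant has trials in both bins")
    out: dict[str, dict] = {"n_participants": int(len(complete))}
    seeds = np.random.SeedSequence(seed).spawn(3)
    for child, (measure, column) in zip(
            seeds, [("accuracy", "correct"), ("rt_ms", "rt_ms"),
                    ("confidence", "confidence")]):
        diffs = (complete[(column, "short")]
                 - complete[(column, "long")]).to_numpy()
        ci: BootstrapCI | None = None
        if len(diffs) >= 2:
            ci = bca_bootstrap(diffs, n_boot=n_boot,
                               seed=int(child.generate_state(1)[0] % (2 ** 31)))
        out[measure] = {
            "short_mean": float(complete[(column, "short")].mean()),
            "long_mean": float(complete[(column, "long")].mean()),
            "difference": float(np.mean(diffs)),
            "ci": ci,
        }
    return out


# ---------------------------------------------------------------------------
# regular-vs-irregular contrasts on memory measures
# ---------------------------------------------------------------------------

def _memory_diff(reg: pd.DataFrame, irr: pd.DataFrame
                 ) -> tuple[float, float, float]:
    return (float(irr["correct"].mean() - reg["correct"].mean()),
            float(irr["rt_ms"].mean() - reg["rt_ms"].mean()),
            float(irr["confidence"].mean() - reg["confidence"].mean()))


def memory_contrast_r3_vs_irregular(responses, designs,
                                    seed: int | None = None) -> pd.DataFrame:
    """Regular-3 against an equal-size irregular subsample, per participant.

    Returns Irregular - Regular differences in accuracy, RT and confidence.
    """
    frame = memory_frame(responses, designs)
    rng = np.random.default_rng(seed)
    rows = {}
    for pid, sub in frame.groupby("participant", sort=True):
        reg = sub[sub["cond_group"] == "R3"]
        irr = sub[sub["cond_group"].str.startswith("I")]
        if len(irr) < len(reg):
            raise MemoryScoringError(
                f"participant {pid}: fewer irregular than regular-3 trials")
        take = irr.iloc[rng.choice(len(irr), size=len(reg), replace=False)]
        rows[pid] = _memory_diff(reg, take)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["accuracy_diff", "rt_diff_ms", "confidence_diff"]
    ).rename_axis("participant")


def memory_contrast_all_regular_vs_all_irregular(responses, designs
                                                 ) -> pd.DataFrame:
    """All regular against all irregular memory trials, per participant."""
    frame = memory_frame(responses, designs)
    rows = {}
    for pid, sub in frame.groupby("participant", sort=True):
        reg = sub[sub["cond_group"].str.startswith("R")]
        irr = sub[sub["cond_group"].str.startswith("I")]
        rows[pid] = _memory_diff(reg, irr)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["accuracy_diff", "rt_diff_ms", "confidence_diff"]
    ).rename_axis("participant")


def memory_contrasts(responses, designs, seed: int | None = None) -> dict:
    """Both regular-vs-irregular contrasts on the memory measures."""
    return {
        "r3_vs_irregular_subsample":
            memory_contrast_r3_vs_irregular(responses, designs, seed=seed),
        "all_regular_vs_all_irregular":
            memory_contrast_all_regular_vs_all_irregular(responses, designs),
    }
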