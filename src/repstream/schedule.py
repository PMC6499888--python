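"""Construction of RSVP session designs and per-block stream schedules.

A *block* is one continuous rapid-serial-visual-presentation (RSVP) stream of
abstract images (integer ids) shown at 15 Hz.  Twenty *repetition sequences*
are embedded in each stream: a target image shown six times with 1-5
never-repeated distractors between consecutive presentations.  Spacing is
either *regular* (the same distractor count d in every gap) or *irregular*
(the gaps are a permutation of 1..5).  A *session* is 12 blocks covering 120
regular sequences (24 per d) and all 120 irregular permutations exactly once,
shuffled over the whole session rather than balanced per block.

Timing is expressed in exact multiples of the 120 Hz screen refresh: each
image occupies 7 refreshes (58.33 ms) followed by a 1-refresh blank
(8.33 ms), giving a stimulus-onset asynchrony (SOA) of 1000/15 ms.  Event
onsets are computed as ``index * SOA`` from a zero origin so no cumulative
rounding can accumulate.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

REFRESH_HZ = 120.0
IMAGE_FRAMES = 7
BLANK_FRAMES = 1
IMAGE_MS = 1000.0 * IMAGE_FRAMES / REFRESH_HZ   # 58.333... ms (rounded: 58.3)
BLANK_MS = 1000.0 * BLANK_FRAMES / REFRESH_HZ   # 8.333... ms (rounded: 8.3)
SOA_MS = IMAGE_MS + BLANK_MS                    # 66.667 ms -> 15 Hz

N_PRESENTATIONS = 6          # times a target is shown within its sequence
N_SEQUENCES_PER_BLOCK = 20
N_BLOCKS = 12
N_REGULAR_PER_D = 24         # 24 x 5 = 120 regular sequences per session
TAIL_IMAGES = 22             # fixed distractor tail after the last sequence

SCHEDULE_COLUMNS = [
    "block", "index", "onset_ms", "duration_ms", "image_id",
    "role", "sequence_id", "cond_kind", "cond_spec",
]


class ScheduleError(ValueError):
    """A schedule violates the design invariants."""


class ParseError(ScheduleError):
    """A schedule file could not be parsed.

    Attributes
    ----------
    line : int or None
        1-based line number at which parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# configuration and condition types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingConfig:
    """Stream timing and gap parameters.

    Durations default to exact 120 Hz refresh multiples; ``gap_min_images`` /
    ``gap_max_images`` bound the uniformly drawn distractor count separating
    consecutive sequences (and preceding the first one when ``lead_in_gap``).
    ``tail_images`` distractors are appended after the final sequence.
    """

    image_duration_ms: float = IMAGE_MS
    blank_duration_ms: float = BLANK_MS
    presentation_rate_hz: float = 15.0
    gap_min_images: int = 37
    gap_max_images: int = 52
    lead_in_gap: bool = True
    tail_images: int = TAIL_IMAGES

    def __post_init__(self):
        if self.image_duration_ms <= 0 or self.blank_duration_ms <= 0:
            raise ScheduleError("durations must be positive")
        if self.presentation_rate_hz <= 0:
            raise ScheduleError("presentation rate must be positive")
        period = 1000.0 / self.presentation_rate_hz
        if abs(self.image_duration_ms + self.blank_duration_ms - period) > 0.1:
            raise ScheduleError(
                "image + blank duration must equal 1000/rate within 0.1 ms")
        if not (0 < self.gap_min_images <= self.gap_max_images):
            raise ScheduleError("need 0 < gap_min_images <= gap_max_images")
        if self.tail_images < 0:
            raise ScheduleError("tail_images must be non-negative")

    @property
    def soa_ms(self) -> float:
        """Stimulus-onset asynchrony: image duration plus blank."""
        return self.image_duration_ms + self.blank_duration_ms

    def to_dict(self) -> dict:
        return {
            "image_duration_ms": self.image_duration_ms,
            "blank_duration_ms": self.blank_duration_ms,
            "presentation_rate_hz": self.presentation_rate_hz,
            "gap_min_images": self.gap_min_images,
            "gap_max_images": self.gap_max_images,
            "lead_in_gap": self.lead_in_gap,
            "tail_images": self.tail_images,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TimingConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class SpacingCondition:
    """Spacing of one repetition sequence.

    ``regular`` conditions set ``regular_d`` (the constant distractor count in
    all five inter-target gaps); ``irregular`` conditions set ``order``, a
    permutation of (1, 2, 3, 4, 5) giving each gap's distractor count.
    """

    kind: str
    regular_d: int | None = None
    order: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.kind == "regular":
            if self.regular_d not in (1, 2, 3, 4, 5) or self.order is not None:
                raise ScheduleError(
                    "regular condition needs regular_d in 1..5 and no order")
        elif self.kind == "irregular":
            if self.regular_d is not None or self.order is None:
                raise ScheduleError(
                    "irregular condition needs an order and no regular_d")
            object.__setattr__(self, "order", tuple(int(x) for x in self.order))
            if sorted(self.order) != [1, 2, 3, 4, 5]:
                raise ScheduleError(
                    "irregular order must be a permutation of (1,2,3,4,5)")
        else:
            raise ScheduleError(f"unknown condition kind {self.kind!r}")

    @classmethod
    def regular(cls, d: int) -> "SpacingCondition":
        return cls(kind="regular", regular_d=int(d))

    @classmethod
    def irregular(cls, order: Sequence[int]) -> "SpacingCondition":
        return cls(kind="irregular", order=tuple(int(x) for x in order))

    @property
    def intervals(self) -> tuple[int, ...]:
        """Distractor counts in the five inter-target gaps."""
        if self.kind == "regular":
            return (self.regular_d,) * (N_PRESENTATIONS - 1)
        return self.order

    @property
    def n_distractors(self) -> int:
        return sum(self.intervals)

    @property
    def length(self) -> int:
        """Total sequence length in images (targets plus distractors)."""
        return N_PRESENTATIONS + self.n_distractors

    @property
    def group(self) -> str:
        """Analysis bin: ``R{d}`` or ``I{first interval}``."""
        if self.kind == "regular":
            return f"R{self.regular_d}"
        return f"I{self.order[0]}"

    @property
    def spec_string(self) -> str:
        if self.kind == "regular":
            return f"d={self.regular_d}"
        return "order=" + "-".join(str(x) for x in self.order)

    @classmethod
    def from_spec_string(cls, kind: str, spec: str) -> "SpacingCondition":
        try:
            key, value = spec.split("=", 1)
        except ValueError:
            raise ScheduleError(f"malformed condition spec {spec!r}") from None
        if kind == "regular" and key == "d":
            return cls.regular(int(value))
        if kind == "irregular" and key == "order":
            return cls.irregular([int(x) for x in value.split("-")])
        raise ScheduleError(f"malformed condition spec {kind!r}/{spec!r}")


@dataclass(frozen=True)
class RepetitionSequence:
    """One embedded repetition sequence: a target shown six times."""

    sequence_id: int
    target_image: int
    condition: SpacingCondition
    event_indices: tuple[int, ...]   # stream indices of the 6 presentations
    onset_times: tuple[float, ...]   # onsets (ms) of the 6 presentations

    def __post_init__(self):
        if len(self.event_indices) != N_PRESENTATIONS:
            raise ScheduleError("a sequence has exactly 6 target presentations")
        if len(self.onset_times) != N_PRESENTATIONS:
            raise ScheduleError("need one onset per presentation")
        gaps = np.diff(self.event_indices) - 1
        if tuple(int(g) for g in gaps) != self.condition.intervals:
            raise ScheduleError(
                "inter-presentation distractor counts do not match condition")

    @property
    def second_onset_ms(self) -> float:
        """Onset of the second presentation — the reaction-time origin."""
        return self.onset_times[1]


# ---------------------------------------------------------------------------
# stream and session containers
# ---------------------------------------------------------------------------

@dataclass
class StreamSchedule:
    """One block's RSVP stream: ordered timed image events plus sequences.

    Events are stored column-wise (image id, target flag, owning sequence or
    -1) with onsets derived as ``index * soa`` from the timing config.
    """

    block_id: int
    image_ids: np.ndarray            # int array, one entry per event
    is_target: np.ndarray            # bool array
    sequence_ids: np.ndarray         # int array, -1 for gap/tail distractors
    sequences: list[RepetitionSequence]
    timing: TimingConfig = field(default_factory=TimingConfig)
    rng_seed: int | None = None

    def __post_init__(self):
        self.image_ids = np.asarray(self.image_ids, dtype=np.int64)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        self.sequence_ids = np.asarray(self.sequence_ids, dtype=np.int64)
        if not (len(self.image_ids) == len(self.is_target)
                == len(self.sequence_ids)):
            raise ScheduleError("event columns must have equal length")

    @property
    def n_events(self) -> int:
        return len(self.image_ids)

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.arange(self.n_events) * self.timing.soa_ms

    @property
    def total_duration_ms(self) -> float:
        return self.n_events * self.timing.soa_ms

    def validate(self) -> None:
        """Check all design invariants; raise :class:`ScheduleError` if broken."""
        if self.n_events == 0:
            raise ScheduleError("schedule has no events")
        if len(self.sequences) != N_SEQUENCES_PER_BLOCK:
            raise ScheduleError(
                f"expected {N_SEQUENCES_PER_BLOCK} sequences, "
                f"got {len(self.sequences)}")
        target_ids = {seq.target_image for seq in self.sequences}
        ids, counts = np.unique(self.image_ids, return_counts=True)
        for img, count in zip(ids.tolist(), counts.tolist()):
            expected = N_PRESENTATIONS if img in target_ids else 1
            if count != expected:
                raise ScheduleError(
                    f"image {img} occurs {count} times, expected {expected}")
        for seq in self.sequences:
            idx = np.asarray(seq.event_indices)
            if not np.all(self.image_ids[idx] == seq.target_image):
                raise ScheduleError(
                    f"sequence {seq.sequence_id}: indices do not hold target")
            span = self.sequence_ids[idx[0]:idx[-1] + 1]
            if not np.all(span == seq.sequence_id):
                raise ScheduleError(
                    f"sequence {seq.sequence_id}: span not tagged consistently")
        # gaps: lead-in (if configured) and the 19 inter-sequence intervals
        starts = [seq.event_indices[0] for seq in self.sequences]
        ends = [seq.event_indices[-1] for seq in self.sequences]
        gaps = [starts[0]] if self.timing.lead_in_gap else []
        gaps += [starts[i + 1] - ends[i] - 1 for i in range(len(starts) - 1)]
        for g in gaps:
            if not (self.timing.gap_min_images <= g
                    <= self.timing.gap_max_images):
                raise ScheduleError(
                    f"gap of {g} images outside "
                    f"[{self.timing.gap_min_images}, "
                    f"{self.timing.gap_max_images}]")
        tail = self.n_events - 1 - ends[-1]
        if tail != self.timing.tail_images:
            raise ScheduleError(
                f"tail of {tail} images, expected {self.timing.tail_images}")

    def events_frame(self) -> pd.DataFrame:
        """Events as a tidy table (one row per presented image)."""
        n = self.n_events
        cond_kind = np.full(n, "", dtype=object)
        cond_spec = np.full(n, "", dtype=object)
        for seq in self.sequences:
            mask = self.sequence_ids == seq.sequence_id
            cond_kind[mask] = seq.condition.kind
            cond_spec[mask] = seq.condition.spec_string
        return pd.DataFrame({
            "block": self.block_id,
            "index": np.arange(n),
            "onset_ms": self.onsets_ms,
            "duration_ms": self.timing.image_duration_ms,
            "image_id": self.image_ids,
            "role": np.where(self.is_target, "target", "distractor"),
            "sequence_id": self.sequence_ids,
            "cond_kind": cond_kind,
            "cond_spec": cond_spec,
        })

    def __eq__(self, other) -> bool:
        if not isinstance(other, StreamSchedule):
            return NotImplemented
        return (self.block_id == other.block_id
                and self.rng_seed == other.rng_seed
                and self.timing == other.timing
                and np.array_equal(self.image_ids, other.image_ids)
                and np.array_equal(self.is_target, other.is_target)
                and np.array_equal(self.sequence_ids, other.sequence_ids)
                and self.sequences == other.sequences)


@dataclass
class SessionDesign:
    """One participant's full session: 12 blocks, 240 spacing conditions."""

    participant_id: int
    blocks: list[StreamSchedule]
    condition_ledger: list[SpacingCondition]
    timing: TimingConfig = field(default_factory=TimingConfig)
    rng_seed: int | None = None

    def validate(self) -> None:
        if len(self.blocks) != N_BLOCKS:
            raise ScheduleError(f"expected {N_BLOCKS} blocks")
        if len(self.condition_ledger) != N_BLOCKS * N_SEQUENCES_PER_BLOCK:
            raise ScheduleError("expected 240 conditions in the ledger")
        regular = [c for c in self.condition_ledger if c.kind == "regular"]
        irregular = [c for c in self.condition_ledger if c.kind == "irregular"]
        if len(regular) != len(irregular):
            raise ScheduleError("need equally many regular and irregular")
        for d in range(1, 6):
            if sum(c.regular_d == d for c in regular) != N_REGULAR_PER_D:
                raise ScheduleError(f"regular d={d} must occur 24 times")
        orders = {c.order for c in irregular}
        if len(orders) != 120:
            raise ScheduleError("each irregular permutation must occur once")
        for b, block in enumerate(self.blocks):
            block.validate()
            chunk = self.condition_ledger[
                b * N_SEQUENCES_PER_BLOCK:(b + 1) * N_SEQUENCES_PER_BLOCK]
            if [s.condition for s in block.sequences] != chunk:
                raise ScheduleError(f"block {b} does not match the ledger")

    def iter_sequences(self):
        """Yield ``(block, sequence)`` pairs in presentation order."""
        for block in self.blocks:
            for seq in block.sequences:
                yield block, seq

    def distinct_image_count(self, include_practice: bool = False,
                             practice: "PracticeConfig | None" = None) -> int:
        """Number of different images a participant would see.

        With ``include_practice`` the deterministic expected count of the
        practice blocks (which are not simulated in detail) is added.
        """
        distinct = len(np.unique(np.concatenate(
            [b.image_ids for b in self.blocks])))
        if include_practice:
            distinct += expected_practice_image_count(practice)
        return int(distinct)


@dataclass(frozen=True)
class PracticeConfig:
    """Coarse description of the warm-up blocks, kept only as an image count.

    Six short blocks of five or six sequences at increasing presentation
    rates; inter-sequence gaps keep their 2.5-3.5 s duration so their image
    count scales with the rate.
    """

    rates_hz: tuple[float, ...] = (2.0, 2.0, 8.0, 8.0, 15.0, 15.0)
    sequences_per_block: tuple[int, ...] = (5, 6, 5, 6, 5, 6)
    gap_seconds: float = 3.0             # expected gap duration
    tail_seconds: float = TAIL_IMAGES / 15.0


def expected_practice_image_count(practice: PracticeConfig | None = None) -> int:
    """Expected number of distinct images shown across the practice blocks.

    Each sequence contributes 16 distinct images on average (one target plus
    the mean 15 distractors of the condition mix); each block has one gap per
    sequence (lead-in plus the in-between gaps) and a short tail.
    """
    practice = practice or PracticeConfig()
    mean_seq_distinct = 1 + 15  # target + mean distractor count over conditions
    total = 0
    for rate, n_seq in zip(practice.rates_hz, practice.sequences_per_block):
        gap_images = round(practice.gap_seconds * rate)
        tail = round(practice.tail_seconds * rate)
        total += n_seq * mean_seq_distinct + n_seq * gap_images + tail
    return int(total)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def enumerate_irregular_orders() -> list[SpacingCondition]:
    """All 120 irregular spacing conditions in lexicographic order."""
    return [SpacingCondition.irregular(p)
            for p in itertools.permutations((1, 2, 3, 4, 5))]


def regular_conditions(copies: int = 1) -> list[SpacingCondition]:
    """The five regular conditions, each repeated ``copies`` times."""
    return [SpacingCondition.regular(d)
            for d in range(1, 6) for _ in range(copies)]


def make_sequence(condition: SpacingCondition, target: int,
                  distractors: Sequence[int]) -> list[int]:
    """Lay out one repetition sequence as an ordered list of image ids.

    The list starts and ends with the target; gap ``i`` holds the condition's
    i-th distractor count.
    """
    needed = condition.n_distractors
    distractors = list(distractors)
    if len(distractors) != needed:
        raise ScheduleError(
            f"condition {condition.spec_string} needs {needed} distractors, "
            f"got {len(distractors)}")
    if target in distractors:
        raise ScheduleError("target id must not appear among the distractors")
    if len(set(distractors)) != len(distractors):
        raise ScheduleError("distractor ids must be distinct")
    out = [target]
    pos = 0
    for gap in condition.intervals:
        out.extend(distractors[pos:pos + gap])
        pos += gap
        out.append(target)
    return out


def build_stream(block_conditions: Sequence[SpacingCondition],
                 timing: TimingConfig | None = None,
                 seed: int | None = None,
                 *,
                 block_id: int = 0,
                 id_start: int = 0,
                 rng: np.random.Generator | None = None) -> StreamSchedule:
    """Assemble one block's stream from its 20 spacing conditions.

    Inter-sequence gaps (and the lead-in) are drawn uniformly from the integer
    range ``[gap_min_images, gap_max_images]``; a fixed distractor tail closes
    the stream.  Image ids are allocated sequentially from ``id_start`` so a
    session-level caller can keep every distractor globally unique.
    """
    timing = timing or TimingConfig()
    conditions = list(block_conditions)
    if len(conditions) != N_SEQUENCES_PER_BLOCK:
        raise ScheduleError(
            f"expected {N_SEQUENCES_PER_BLOCK} conditions, "
            f"got {len(conditions)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_gaps = len(conditions) if timing.lead_in_gap else len(conditions) - 1
    gaps = rng.integers(timing.gap_min_images, timing.gap_max_images + 1,
                        size=n_gaps).tolist()
    if not timing.lead_in_gap:
        gaps = [0] + gaps

    soa = timing.soa_ms
    image_ids: list[int] = []
    is_target: list[bool] = []
    seq_col: list[int] = []
    sequences: list[RepetitionSequence] = []
    next_id = id_start
    for k, cond in enumerate(conditions):
        gap = gaps[k]
        image_ids.extend(range(next_id, next_id + gap))
        next_id += gap
        is_target.extend([False] * gap)
        seq_col.extend([-1] * gap)

        target = next_id
        next_id += 1
        distractors = list(range(next_id, next_id + cond.n_distractors))
        next_id += cond.n_distractors
        layout = make_sequence(cond, target, distractors)
        start = len(image_ids)
        indices = tuple(start + i for i, img in enumerate(layout)
                        if img == target)
        onsets = tuple(i * soa for i in indices)
        sequences.append(RepetitionSequence(
            sequence_id=k, target_image=target, condition=cond,
            event_indices=indices, onset_times=onsets))
        image_ids.extend(layout)
        is_target.extend([img == target for img in layout])
        seq_col.extend([k] * len(layout))

    image_ids.extend(range(next_id, next_id + timing.tail_images))
    is_target.extend([False] * timing.tail_images)
    seq_col.extend([-1] * timing.tail_images)

    schedule = StreamSchedule(
        block_id=block_id, image_ids=np.array(image_ids),
        is_target=np.array(is_target), sequence_ids=np.array(seq_col),
        sequences=sequences, timing=timing,
        rng_seed=None if seed is None else int(seed))
    return schedule


def build_session(participant_id: int, seed: int,
                  timing: TimingConfig | None = None) -> SessionDesign:
    """Build one participant's 12-block session.

    The 240-condition ledger (24 copies of each regular d plus every irregular
    permutation once) is globally shuffled and chunked into blocks, so
    conditions are not balanced per block.  The same seed reproduces the
    design bit-for-bit.
    """
    timing = timing or TimingConfig()
    rng = np.random.default_rng(seed)
    pool = regular_conditions(copies=N_REGULAR_PER_D) + \
        enumerate_irregular_orders()
    order = rng.permutation(len(pool))
    ledger = [pool[i] for i in order]

    blocks: list[StreamSchedule] = []
    next_id = 0
    for b in range(N_BLOCKS):
        chunk = ledger[b * N_SEQUENCES_PER_BLOCK:(b + 1) *
                       N_SEQUENCES_PER_BLOCK]
        block_seed = int(rng.integers(2 ** 31))
        block = build_stream(chunk, timing, block_seed,
                             block_id=b, id_start=next_id)
        next_id = int(block.image_ids.max()) + 1
        blocks.append(block)
    design = SessionDesign(participant_id=participant_id, blocks=blocks,
                           condition_ledger=ledger, timing=timing,
                           rng_seed=int(seed))
    return design


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_schedule(schedule: StreamSchedule, path) -> None:
    """Write one block's schedule as a commented CSV (UTF-8, header row)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# repstream schedule v1\n")
        fh.write(f"# rng_seed={'' if schedule.rng_seed is None else schedule.rng_seed}\n")
        frame = schedule.events_frame()
        frame["sequence_id"] = [
            "" if s < 0 else str(s) for s in frame["sequence_id"]]
        frame.to_csv(fh, index=False, columns=SCHEDULE_COLUMNS)


def read_schedule(path, timing: TimingConfig | None = None) -> StreamSchedule:
    """Read a schedule CSV back into a validated :class:`StreamSchedule`."""
    timing = timing or TimingConfig()
    path = Path(path)
    rng_seed: int | None = None
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []   # (line number, fields)
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, record in enumerate(csv.reader(fh), start=1):
            if not record:
                continue
            if record[0].startswith("#"):
                text = ",".join(record).lstrip("#").strip()
                if text.startswith("rng_seed="):
                    value = text.split("=", 1)[1]
                    rng_seed = int(value) if value else None
                continue
            if header is None:
                header = [h.strip() for h in record]
                missing = [c for c in SCHEDULE_COLUMNS if c not in header]
                if missing:
                    raise ParseError(
                        f"missing column(s): {', '.join(missing)}",
                        line=lineno)
                continue
            rows.append((lineno, record))
    if header is None:
        raise ParseError("no header row found")

    col = {name: header.index(name) for name in SCHEDULE_COLUMNS}
    image_ids, is_target, seq_col = [], [], []
    block_id = 0
    seq_rows: dict[int, list[tuple[int, str, str, int]]] = {}
    for lineno, record in rows:
        if len(record) < len(header):
            raise ParseError("row has too few fields", line=lineno)
        try:
            block_id = int(record[col["block"]])
            index = int(record[col["index"]])
            image = int(record[col["image_id"]])
            role = record[col["role"]]
            raw_seq = record[col["sequence_id"]].strip()
            seq_id = int(raw_seq) if raw_seq else -1
            float(record[col["onset_ms"]])
            float(record[col["duration_ms"]])
        except ValueError as exc:
            raise ParseError(str(exc), line=lineno) from None
        if role not in ("target", "distractor"):
            raise ParseError(f"unknown role {role!r}", line=lineno)
        if index != len(image_ids):
            raise ParseError(
                f"event index {index} out of order", line=lineno)
        image_ids.append(image)
        is_target.append(role == "target")
        seq_col.append(seq_id)
        if seq_id >= 0 and role == "target":
            seq_rows.setdefault(seq_id, []).append(
                (index, record[col["cond_kind"]],
                 record[col["cond_spec"]], image))

    soa = timing.soa_ms
    sequences = []
    for seq_id in sorted(seq_rows):
        entries = sorted(seq_rows[seq_id])
        indices = tuple(e[0] for e in entries)
        targets = {e[3] for e in entries}
        if len(targets) != 1:
            raise ParseError(
                f"sequence {seq_id} mixes target ids {sorted(targets)}")
        condition = SpacingCondition.from_spec_string(
            entries[0][1], entries[0][2])
        sequences.append(RepetitionSequence(
            sequence_id=seq_id, target_image=targets.pop(),
            condition=condition, event_indices=indices,
            onset_times=tuple(i * soa for i in indices)))

    schedule = StreamSchedule(
        block_id=block_id, image_ids=np.array(image_ids, dtype=np.int64),
        is_target=np.array(is_target, dtype=bool),
        sequence_ids=np.array(seq_col, dtype=np.int64),
        sequences=sequences, timing=timing, rng_seed=rng_seed)
    schedule.validate()
    return schedule


def write_session(design: SessionDesign, out_dir) -> None:
    """Write a session as one schedule CSV per block plus a YAML config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for block in design.blocks:
        write_schedule(block, out_dir / f"schedule_block{block.block_id:02d}.csv")
    config = {
        "participant_id": design.participant_id,
        "rng_seed": design.rng_seed,
        "n_blocks": len(design.blocks),
        "timing": design.timing.to_dict(),
    }
    with open(out_dir / "session.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def read_session(session_dir) -> SessionDesign:
    """Read a session written by :func:`write_session`."""
    session_dir = Path(session_dir)
    with open(session_dir / "session.yaml", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    timing = TimingConfig.from_dict(config["timing"])
    blocks = []
    for b in range(int(config["n_blocks"])):
        blocks.append(read_schedule(
            session_dir / f"schedule_block{b:02d}.csv", timing=timing))
    ledger = [seq.condition for block in blocks for seq in block.sequences]
    design = SessionDesign(
        participant_id=int(config["participant_id"]), blocks=blocks,
        condition_ledger=ledger, timing=timing,
        rng_seed=config.get("rng_seed"))
    design.validate()
    return design
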