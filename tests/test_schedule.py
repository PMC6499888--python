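"""Schedule generation: combinatorics, timing, invariants, persistence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from repstream.schedule import (
    ParseError, PracticeConfig, ScheduleError, SpacingCondition, TimingConfig,
    build_session, build_stream, enumerate_irregular_orders,
    expected_practice_image_count, make_sequence, read_schedule,
    regular_conditions, write_schedule, SOA_MS,
)

# -- spacing conditions and sequence layout ---------------------------------

def test_irregular_orders_enumeration():
    orders = enumerate_irregular_orders()
    assert len(orders) == 120
    assert orders[0].order == (1, 2, 3, 4, 5)
    assert len({c.order for c in orders}) == 120
    assert all(c.n_distractors == 15 for c in orders)
    # lexicographic ordering
    assert [c.order for c in orders] == sorted(c.order for c in orders)


@pytest.mark.parametrize("condition, expected_length", [
    (SpacingCondition.regular(1), 11),
    (SpacingCondition.regular(3), 21),
    (SpacingCondition.regular(5), 31),
    (SpacingCondition.irregular((5, 4, 3, 2, 1)), 21),
])
def test_make_sequence_lengths(condition, expected_length):
    target = 1000
    distractors = list(range(condition.n_distractors))
    layout = make_sequence(condition, target, distractors)
    assert len(layout) == expected_length
    assert layout[0] == target and layout[-1] == target
    assert layout.count(target) == 6


def test_make_sequence_d1_pattern():
    layout = make_sequence(SpacingCondition.regular(1), 9, [1, 2, 3, 4, 5])
    assert layout == [9, 1, 9, 2, 9, 3, 9, 4, 9, 5, 9]


def test_make_sequence_gap_contents():
    cond = SpacingCondition.irregular((5, 4, 3, 2, 1))
    layout = make_sequence(cond, 99, list(range(15)))
    gaps = "".join("T" if x == 99 else "D" for x in layout).split("T")
    assert [len(g) for g in gaps if g or True][1:-1] == [5, 4, 3, 2, 1]


def test_make_sequence_input_errors():
    cond = SpacingCondition.regular(2)
    with pytest.raises(ScheduleError):
        make_sequence(cond, 0, list(range(1, 10)))     # wrong count
    with pytest.raises(ScheduleError):
        make_sequence(cond, 5, [1, 2, 3, 4, 5, 6, 7, 8, 9, 5][:10])
    with pytest.raises(ScheduleError):
        make_sequence(cond, 0, [1, 2, 3, 4, 5, 6, 7, 8, 8, 9])  # duplicate


@given(st.one_of(
    st.integers(1, 5).map(SpacingCondition.regular),
    st.permutations([1, 2, 3, 4, 5]).map(SpacingCondition.irregular)))
def test_make_sequence_properties(condition):
    target = 10 ** 6
    distractors = list(range(condition.n_distractors))
    layout = make_sequence(condition, target, distractors)
    assert layout[0] == target and layout[-1] == target
    assert layout.count(target) == 6
    assert len(layout) == 6 + condition.n_distractors
    positions = [i for i, x in enumerate(layout) if x == target]
    assert tuple(np.diff(positions) - 1) == condition.intervals


def test_condition_validation():
    with pytest.raises(ScheduleError):
        SpacingCondition.regular(6)
    with pytest.raises(ScheduleError):
        SpacingCondition.irregular((1, 2, 3, 4, 4))
    with pytest.raises(ScheduleError):
        SpacingCondition(kind="regular", regular_d=3, order=(1, 2, 3, 4, 5))


def test_timing_config_invariants():
    cfg = TimingConfig()
    assert cfg.soa_ms == pytest.approx(1000.0 / 15.0)
    with pytest.raises(ScheduleError):
        TimingConfig(image_duration_ms=50.0)   # breaks rate identity
    with pytest.raises(ScheduleError):
        TimingConfig(gap_min_images=53)


# -- session combinatorics ---------------------------------------------------

def test_session_condition_counts(session_design):
    ledger = session_design.condition_ledger
    assert len(ledger) == 240
    regular = [c for c in ledger if c.kind == "regular"]
    irregular = [c for c in ledger if c.kind == "irregular"]
    assert len(regular) == 120 and len(irregular) == 120
    for d in range(1, 6):
        assert sum(c.regular_d == d for c in regular) == 24
    assert {c.order for c in irregular} == {
        c.order for c in enumerate_irregular_orders()}
    assert len(session_design.blocks) == 12
    assert all(len(b.sequences) == 20 for b in session_design.blocks)
    session_design.validate()


def test_session_determinism():
    a = build_session(3, seed=77)
    b = build_session(3, seed=77)
    assert a.condition_ledger == b.condition_ledger
    assert all(x == y for x, y in zip(a.blocks, b.blocks))
    c = build_session(3, seed=78)
    assert a.condition_ledger != c.condition_ledger


def test_session_image_uniqueness(session_design):
    ids = np.concatenate([b.image_ids for b in session_design.blocks])
    targets = {seq.target_image
               for b in session_design.blocks for seq in b.sequences}
    unique, counts = np.unique(ids, return_counts=True)
    is_target = np.isin(unique, sorted(targets))
    assert np.all(counts[is_target] == 6)
    assert np.all(counts[~is_target] == 1)
    assert len(targets) == 240


# -- stream structure --------------------------------------------------------

def test_stream_gaps_and_tail(session_design):
    for block in session_design.blocks:
        starts = [s.event_indices[0] for s in block.sequences]
        ends = [s.event_indices[-1] for s in block.sequences]
        gaps = [starts[0]] + [starts[i + 1] - ends[i] - 1
                              for i in range(19)]
        assert all(37 <= g <= 52 for g in gaps)
        assert block.n_events - 1 - ends[-1] == 22


def test_stream_onsets_constant_soa(session_design):
    block = session_design.blocks[0]
    onsets = block.onsets_ms
    assert np.allclose(np.diff(onsets), SOA_MS)
    assert onsets[0] == 0.0
    # every onset is an integer multiple of the SOA
    assert np.allclose(onsets / SOA_MS, np.round(onsets / SOA_MS))


def test_regular_target_rate(session_design):
    """Consecutive target onsets in a regular-d sequence differ by (d+1)*SOA."""
    for block in session_design.blocks:
        for seq in block.sequences:
            if seq.condition.kind != "regular":
                continue
            d = seq.condition.regular_d
            diffs = np.diff(seq.onset_times)
            assert np.allclose(diffs, (d + 1) * SOA_MS)


def test_stream_mean_event_count():
    """Mean stream length approximates the design expectation of 1332."""
    rng = np.random.default_rng(5)
    counts = []
    for i in range(5):
        design = build_session(i, seed=int(rng.integers(2 ** 31)))
        counts.extend(b.n_events for b in design.blocks)
    assert abs(np.mean(counts) - 1332) < 15


def test_distinct_images_near_sixteen_thousand(session_design):
    main_only = session_design.distinct_image_count()
    with_practice = session_design.distinct_image_count(include_practice=True)
    assert with_practice - main_only == expected_practice_image_count()
    assert 0.95 * 16000 <= with_practice <= 1.05 * 16000


def test_practice_count_is_deterministic():
    assert expected_practice_image_count() == \
        expected_practice_image_count(PracticeConfig())


def test_build_stream_needs_twenty_conditions():
    with pytest.raises(ScheduleError):
        build_stream(regular_conditions(), seed=0)  # only 5 conditions


# -- persistence -------------------------------------------------------------

def test_schedule_roundtrip(tmp_path, session_design):
    block = session_design.blocks[1]
    path = tmp_path / "block.csv"
    write_schedule(block, path)
    back = read_schedule(path)
    assert back == block


def test_read_schedule_missing_column(tmp_path, session_design):
    path = tmp_path / "block.csv"
    write_schedule(session_design.blocks[0], path)
    pruned = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            pruned.append(line)
        else:  # drop the image_id column everywhere
            fields = line.split(",")
            del fields[4]
            pruned.append(",".join(fields))
    bad = tmp_path / "bad.csv"
    bad.write_text("\n".join(pruned))
    with pytest.raises(ParseError, match="image_id"):
        read_schedule(bad)


def test_read_schedule_malformed_value_reports_line(tmp_path, session_design):
    path = tmp_path / "block.csv"
    write_schedule(session_design.blocks[0], path)
    lines = path.read_text().splitlines()
    fields = lines[10].split(",")
    fields[4] = "not-a-number"
    lines[10] = ",".join(fields)
    path.write_text("\n".join(lines))
    with pytest.raises(ParseError, match="line 11"):
        read_schedule(path)


def test_read_schedule_rejects_empty_events(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(
        "block,index,onset_ms,duration_ms,image_id,role,sequence_id,"
        "cond_kind,cond_spec\n")
    with pytest.raises(ScheduleError):
        read_schedule(path)
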