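"""Detection scoring: window rule, scrambled null, condition contrasts."""

import numpy as np
import pytest

from repstream.detect import (
    ConditionSummary, DetectionWindow, ScoringError, chance_level,
    chance_level_session, contrast_all_regular_vs_all_irregular,
    contrast_r3_vs_irregular, group_condition, score_block, scores_frame,
    scramble_log, scramble_horizon_ms, summarize_conditions,
)
from repstream.observer import ButtonPressLog, CONDITION_GROUPS
from repstream.schedule import RepetitionSequence, SpacingCondition, SOA_MS


def make_toy_sequence(seq_id, start_index, condition=None, soa=SOA_MS):
    """A sequence whose first presentation sits at start_index."""
    condition = condition or SpacingCondition.regular(3)
    indices = [start_index]
    for gap in condition.intervals:
        indices.append(indices[-1] + gap + 1)
    return RepetitionSequence(
        sequence_id=seq_id, target_image=10_000 + seq_id,
        condition=condition,
        event_indices=tuple(indices),
        onset_times=tuple(i * soa for i in indices))


def brute_force_score(sequences, times, window):
    """Independent double-loop implementation of the window rule."""
    times = list(times)
    taken = [False] * len(times)
    result = {}
    for seq in sorted(sequences, key=lambda s: s.second_onset_ms):
        t2 = seq.second_onset_ms
        hits = [i for i, t in enumerate(times)
                if not taken[i]
                and t2 + window.start_offset_ms < t < t2 + window.end_offset_ms]
        for i in hits:
            taken[i] = True
        result[seq.sequence_id] = (len(hits) == 1,
                                   times[hits[0]] - t2 if len(hits) == 1
                                   else None, len(hits))
    return result


# -- window rule -------------------------------------------------------------

def test_single_press_in_window_is_detected():
    seq = make_toy_sequence(0, start_index=150)
    t2 = seq.second_onset_ms
    [score] = score_block([seq], np.array([t2 + 500.0]))
    assert score.detected and score.rt_ms == pytest.approx(500.0)
    assert score.n_presses_in_window == 1


def test_two_presses_in_window_cancel_detection():
    seq = make_toy_sequence(0, start_index=150)
    t2 = seq.second_onset_ms
    [score] = score_block([seq], np.array([t2 + 500.0, t2 + 1000.0]))
    assert not score.detected and score.n_presses_in_window == 2
    assert score.rt_ms is None


@pytest.mark.parametrize("offset", [100.0, 199.9, 2500.1, 3000.0])
def test_press_outside_window_not_counted(offset):
    seq = make_toy_sequence(0, start_index=150)
    [score] = score_block([seq], np.array([seq.second_onset_ms + offset]))
    assert not score.detected and score.n_presses_in_window == 0


def test_unsorted_log_rejected():
    seq = make_toy_sequence(0, start_index=150)
    with pytest.raises(ScoringError):
        score_block([seq], np.array([5000.0, 4000.0]))


def test_overlapping_windows_assign_press_to_earlier_sequence():
    a = make_toy_sequence(0, start_index=0)
    b = make_toy_sequence(1, start_index=30)   # windows overlap
    t = b.second_onset_ms + 300.0              # inside both windows
    assert t < a.second_onset_ms + 2500.0
    scores = {s.sequence_id: s for s in score_block([a, b], np.array([t]))}
    assert scores[0].n_presses_in_window == 1
    assert scores[1].n_presses_in_window == 0


def test_score_block_matches_brute_force():
    """Vectorised scorer equals the double-loop oracle on random instances."""
    rng = np.random.default_rng(2024)
    window = DetectionWindow()
    for _ in range(200):
        n_seq = int(rng.integers(2, 8))
        starts = np.cumsum(rng.integers(5, 60, size=n_seq))
        sequences = [make_toy_sequence(i, int(s))
                     for i, s in enumerate(starts)]
        times = np.sort(rng.uniform(0, starts[-1] * SOA_MS + 4000,
                                    size=rng.integers(0, 12)))
        expected = brute_force_score(sequences, times, window)
        for score in score_block(sequences, times, window):
            det, rt, n = expected[score.sequence_id]
            assert score.detected == det
            assert score.n_presses_in_window == n
            if det:
                assert score.rt_ms == pytest.approx(rt)


def test_reported_rts_stay_inside_window(simulated_session):
    df = simulated_session["scores_df"]
    rts = df.loc[df.detected, "rt_ms"]
    assert ((rts > 200) & (rts < 2500)).all()


def test_group_condition_labels():
    assert group_condition(make_toy_sequence(
        0, 10, SpacingCondition.regular(4))) == "R4"
    assert group_condition(make_toy_sequence(
        0, 10, SpacingCondition.irregular((3, 1, 5, 2, 4)))) == "I3"
    assert group_condition(make_toy_sequence(
        0, 10, SpacingCondition.irregular((5, 4, 3, 2, 1)))) == "I5"


# -- scrambling and chance level --------------------------------------------

def test_scramble_preserves_count_and_sorting():
    log = ButtonPressLog(0, 0, np.sort(np.random.default_rng(0)
                                       .uniform(0, 9e4, 13)))
    out = scramble_log(log, t_max=9e4, seed=1)
    assert len(out) == 13
    assert np.all(np.diff(out.press_times) >= 0)
    assert np.all((out.press_times >= 0) & (out.press_times <= 9e4))
    empty = scramble_log(ButtonPressLog(0, 0, []), t_max=9e4, seed=1)
    assert len(empty) == 0
    again = scramble_log(log, t_max=9e4, seed=1)
    assert np.array_equal(out.press_times, again.press_times)


def analytic_chance(k, w, T):
    """P(exactly one of k uniform presses lands in a width-w window)."""
    return k * (w / T) * (1 - w / T) ** (k - 1)


def test_chance_level_matches_analytic_oracle(session_design):
    """Monte-Carlo scrambled rate agrees with the closed-form binomial."""
    block = session_design.blocks[0]
    window = DetectionWindow()
    T = scramble_horizon_ms(block, window)
    k = 13
    presses = np.linspace(1000, 80000, k)
    rates = chance_level(block, presses, window, n_scrambles=4000, seed=8)
    observed = np.mean(list(rates.values()))
    expected = analytic_chance(k, window.width_ms, T)
    se = np.sqrt(expected * (1 - expected) / (4000 * 20))
    assert abs(observed - expected) < 3 * se + 1e-9


def test_chance_level_empty_log(session_design):
    rates = chance_level(session_design.blocks[0], np.array([]),
                         n_scrambles=5, seed=0)
    assert all(v == 0.0 for v in rates.values())


def test_chance_below_real_rate_for_clean_observer(session_design,
                                                   observer_params):
    from repstream.observer import simulate_presses
    from repstream.detect import score_session
    clean = observer_params.with_(
        hit_prob={g: 1.0 for g in CONDITION_GROUPS},
        extra_press_prob=0.0, fa_rate_hz=0.0)
    logs = [simulate_presses(b, clean, seed=b.block_id)
            for b in session_design.blocks]
    df = scores_frame(score_session(session_design, logs))
    chance = chance_level_session(session_design, logs, n_scrambles=50,
                                  seed=1)
    for summary in summarize_conditions(df, chance):
        assert summary.chance_rate < summary.detection_rate
        assert summary.pp_difference == pytest.approx(
            100 * (summary.detection_rate - summary.chance_rate))


def test_chance_variance_shrinks_with_more_scrambles(session_design):
    block = session_design.blocks[2]
    presses = np.linspace(500, 85000, 14)
    few, many = [], []
    for seed in range(12):
        few.append(np.mean(list(chance_level(
            block, presses, n_scrambles=1, seed=seed).values())))
        many.append(np.mean(list(chance_level(
            block, presses, n_scrambles=200, seed=seed).values())))
    assert np.var(many) < np.var(few)


# -- contrasts ---------------------------------------------------------------

def test_contrast_subsample_sizes_and_determinism(simulated_session):
    df = simulated_session["scores_df"]
    a = contrast_r3_vs_irregular(df, seed=4)
    b = contrast_r3_vs_irregular(df, seed=4)
    assert a.equals(b)
    assert len(a) == 1
    reg_n = (df.cond_group == "R3").sum()
    assert reg_n == 24  # 24 regular-3 trials per session


def test_contrast_all_counts(simulated_session):
    df = simulated_session["scores_df"]
    reg = df.cond_group.str.startswith("R").sum()
    irr = df.cond_group.str.startswith("I").sum()
    assert reg == 120 and irr == 120
    out = contrast_all_regular_vs_all_irregular(df)
    assert set(out.columns) == {"detection_diff", "rt_diff_ms"}


def test_contrast_requires_enough_irregular_trials(simulated_session):
    df = simulated_session["scores_df"]
    crippled = df[~df.cond_group.str.startswith("I") |
                  (df.index < 10)]
    with pytest.raises(ScoringError):
        contrast_r3_vs_irregular(crippled, seed=0)


def test_all_detected_observer_gives_zero_difference(session_design,
                                                     observer_params):
    from repstream.observer import simulate_presses
    from repstream.detect import score_session
    clean = observer_params.with_(
        hit_prob={g: 1.0 for g in CONDITION_GROUPS},
        extra_press_prob=0.0, fa_rate_hz=0.0)
    logs = [simulate_presses(b, clean, seed=b.block_id)
            for b in session_design.blocks]
    df = scores_frame(score_session(session_design, logs))
    out = contrast_all_regular_vs_all_irregular(df)
    assert out["detection_diff"].iloc[0] == 0.0


def test_exchangeable_groups_give_near_zero_mean_difference():
    """With one shared hit probability the contrast is centred on zero."""
    from tests_helpers import simulate_flat_sessions
    diffs = simulate_flat_sessions(n_participants=12, hit=0.6, seed=31)
    assert abs(diffs["detection_diff"].mean()) < 0.05
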