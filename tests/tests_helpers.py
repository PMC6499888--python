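"""Shared simulation helpers for the test suite."""

import numpy as np
import pandas as pd

from repstream import build_session, default_params, simulate_session
from repstream.detect import (contrast_all_regular_vs_all_irregular,
                              score_session, scores_frame)
from repstream.observer import CONDITION_GROUPS


def flat_params(hit=0.6, acc=0.6, **kwargs):
    """Defaults with one shared hit/memory probability for every group."""
    return default_params().with_(
        hit_prob={g: hit for g in CONDITION_GROUPS},
        mem_acc={g: acc for g in CONDITION_GROUPS}, **kwargs)


def simulate_dataset(n_participants, params, seed):
    """Simulate per-participant sessions; returns (designs, logs, responses)."""
    root = np.random.SeedSequence(seed)
    designs, all_logs, all_responses = [], [], []
    for pid, child in enumerate(root.spawn(n_participants)):
        s1, s2 = (int(x) for x in child.generate_state(2) % (2 ** 31))
        design = build_session(pid, seed=s1)
        logs, responses = simulate_session(design, params, seed=s2)
        designs.append(design)
        all_logs.append(logs)
        all_responses.append(responses)
    return designs, all_logs, all_responses


def score_dataset(designs, all_logs) -> pd.DataFrame:
    scores = []
    for design, logs in zip(designs, all_logs):
        scores.extend(score_session(design, logs))
    return scores_frame(scores)


def simulate_flat_sessions(n_participants, hit, seed) -> pd.DataFrame:
    """All-regular-vs-all-irregular differences under exchangeable groups."""
    params = flat_params(hit=hit)
    designs, all_logs, _ = simulate_dataset(n_participants, params, seed)
    return contrast_all_regular_vs_all_irregular(score_dataset(designs,
                                                               all_logs))
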