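"""Assemble the full analysis report for one or more simulated sessions.

Combines per-condition detection and memory summaries, the one-way ANOVA
with Tukey-Kramer post-hoc tests over the regular conditions, both
regular-vs-irregular contrasts (with BCa CIs and JZS Bayes factors), and the
short-vs-long delay split into one JSON-serialisable dictionary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import detect, memory, stats
from .observer import ButtonPressLog, MemoryResponseSet
from .schedule import SessionDesign


def _ci_dict(ci: stats.BootstrapCI | None) -> dict | None:
    if ci is None:
        return None
    return {"point": ci.point, "lower": ci.lower, "upper": ci.upper,
            "n_boot": ci.n_boot, "method": ci.method}


def _contrast_block(diffs: pd.Series, n_boot: int, seed: int) -> dict:
    """CI + Bayes factor for one column of per-participant differences."""
    values = diffs.dropna().to_numpy()
    out: dict = {"mean_difference": float(np.mean(values)),
                 "n_participants": int(len(values))}
    if len(values) >= 2:
        out["ci"] = _ci_dict(stats.bca_bootstrap(values, n_boot=n_boot,
                                                 seed=seed))
        if values.std(ddof=1) > 0:
            bf = stats.jzs_bf(values)
            out["bf10"] = bf.bf10
            out["bf_label"] = "%s evidence for the %s" % stats.bf_label(bf.bf10)
    return out


def _anova_block(frame: pd.DataFrame, value: str) -> dict:
    """One-way ANOVA + Tukey over the five regular groups' participant means."""
    reg = frame[frame["cond_group"].str.startswith("R")]
    per = reg.groupby(["cond_group", "participant"])[value].mean()
    groups = [per.loc[f"R{d}"].to_numpy() for d in range(1, 6)]
    if any(len(g) < 2 for g in groups):
        return {"note": "too few participants for ANOVA"}
    result = stats.oneway_anova(groups)
    tukey = stats.tukey_kramer(groups)
    return {
        "F": result.F, "df": [result.df_between, result.df_within],
        "p": result.p, "group_means": list(result.group_means),
        "tukey": [{"pair": [f"R{int(r.group_i) + 1}", f"R{int(r.group_j) + 1}"],
                   "mean_diff": r.mean_diff, "p_adj": r.p_adj}
                  for r in tukey.itertuples()],
    }


def build_report(designs: Sequence[SessionDesign],
                 press_logs: Sequence[Sequence[ButtonPressLog]],
                 responses: Sequence[Sequence[MemoryResponseSet]],
                 window: detect.DetectionWindow | None = None,
                 n_scrambles: int = 1,
                 n_boot: int = 2000,
                 seed: int | None = None) -> dict:
    """Run the complete analysis for matched (design, presses, memory) sets."""
    window = window or detect.DetectionWindow()
    seeds = np.random.SeedSequence(seed).spawn(8)

    def child(i: int) -> int:
        return int(seeds[i].generate_state(1)[0] % (2 ** 31))

    scores = []
    chance_sums: dict[str, float] = {}
    for i, (design, logs) in enumerate(zip(designs, press_logs)):
        scores.extend(detect.score_session(design, logs, window))
        rates = detect.chance_level_session(
            design, logs, window, n_scrambles,
            seed=child(0) + i)
        for g, r in rates.items():
            chance_sums[g] = chance_sums.get(g, 0.0) + r / len(designs)
    score_df = detect.scores_frame(scores)
    design_map = {d.participant_id: d for d in designs}
    all_responses = [rs for session in responses for rs in session]

    detection = {
        "condition_summaries": [
            {"cond_group": s.cond_group, "detection_rate": s.detection_rate,
             "mean_rt_ms": s.mean_rt_ms, "n_trials": s.n_trials,
             "chance_rate": s.chance_rate, "pp_difference": s.pp_difference}
            for s in detect.summarize_conditions(score_df, chance_sums)],
        "anova_regular": _anova_block(
            score_df.assign(detected=score_df["detected"].astype(float)),
            "detected"),
    }
    r3 = detect.contrast_r3_vs_irregular(score_df, seed=child(1))
    allc = detect.contrast_all_regular_vs_all_irregular(score_df)
    detection["contrast_r3_vs_irregular"] = {
        "detection": _contrast_block(r3["detection_diff"], n_boot, child(2)),
        "rt_ms": _contrast_block(r3["rt_diff_ms"], n_boot, child(2) + 1)}
    detection["contrast_all_regular_vs_all_irregular"] = {
        "detection": _contrast_block(allc["detection_diff"], n_boot, child(3)),
        "rt_ms": _contrast_block(allc["rt_diff_ms"], n_boot, child(3) + 1)}

    mem_frame = memory.memory_frame(all_responses, design_map)
    mem = {
        "condition_summaries": [
            {"cond_group": s.cond_group, "accuracy": s.accuracy,
             "mean_rt_ms": s.mean_rt_ms,
             "mean_confidence": s.mean_confidence, "n_trials": s.n_trials,
             "chance_accuracy": 0.25}
            for s in memory.score_memory(all_responses, design_map)],
        "anova_regular": _anova_block(
            mem_frame.assign(correct=mem_frame["correct"].astype(float)),
            "correct"),
    }
    mem_r3 = memory.memory_contrast_r3_vs_irregular(
        all_responses, design_map, seed=child(4))
    mem_all = memory.memory_contrast_all_regular_vs_all_irregular(
        all_responses, design_map)
    mem["contrast_r3_vs_irregular"] = {
        key: _contrast_block(mem_r3[col], n_boot, child(5) + k)
        for k, (key, col) in enumerate([
            ("accuracy", "accuracy_diff"), ("rt_ms", "rt_diff_ms"),
            ("confidence", "confidence_diff")])}
    mem["contrast_all_regular_vs_all_irregular"] = {
        key: _contrast_block(mem_all[col], n_boot, child(6) + k)
        for k, (key, col) in enumerate([
            ("accuracy", "accuracy_diff"), ("rt_ms", "rt_diff_ms"),
            ("confidence", "confidence_diff")])}

    split = memory.delay_split(all_responses, design_map, n_boot=n_boot,
                               seed=child(7))
    delay = {"n_participants": split["n_participants"]}
    for measure in ("accuracy", "rt_ms", "confidence"):
        block = split[measure]
        delay[measure] = {
            "short_mean": block["short_mean"],
            "long_mean": block["long_mean"],
            "difference_short_minus_long": block["difference"],
            "ci": _ci_dict(block["ci"])}

    return {"n_sessions": len(designs), "window_ms": [window.start_offset_ms,
                                                      window.end_offset_ms],
            "n_scrambles": n_scrambles, "seed": seed,
            "detection": detection, "memory": mem, "delay_split": delay}


def save_report(report: dict, path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
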