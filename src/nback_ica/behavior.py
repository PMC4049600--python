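"""Behavioral trial filtering, summaries, cost indices, exclusions.

Responses faster than 200 ms or slower than 1500 ms count as incorrect
(the bounds themselves are valid); missing responses are incorrect.
Per subject and load condition the summary reports accuracy (correct /
total trials) and the median RT over correct in-range trials.  Working
memory performance is indexed by two relative costs from the baseline
(0-back) to the complex (2-back) condition:

    speed_cost    = (RT_2back - RT_0back) / RT_0back
    accuracy_cost = (acc_0back - acc_2back) / acc_0back

Higher values mean less efficient performance.  Subjects performing
below chance (accuracy < .50) in the 1-back or 2-back condition are
excluded (the conjunctive "and" reading is available via ``rule``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import CONDITIONS

RT_MIN_MS = 200.0
RT_MAX_MS = 1500.0

REQUIRED_COLUMNS = ("subject", "condition", "rt_ms", "correct")


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Mark out-of-range RTs as incorrect.

    Adds ``rt_valid`` (RT within [200, 1500] ms, bounds inclusive) and
    ``correct_valid`` (response correct AND RT in range).  Trial counts
    are never changed — filtered trials stay in every denominator.
    Missing RTs (non-responses) are invalid; negative RTs raise.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise KeyError(f"trial table missing columns: {missing}")
    rt = trials["rt_ms"].astype(float)
    if (rt.dropna() < 0).any():
        raise ValueError("negative RT in trial table")
    out = trials.copy()
    out["rt_valid"] = rt.notna() & (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)
    out["correct_valid"] = out["correct"].astype(bool) & out["rt_valid"]
    return out


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-subject x condition summaries plus per-subject cost indices."""
    per_condition: pd.DataFrame   # subject, group, condition, accuracy,
                                  # median_rt_ms, n_trials, n_correct
    per_subject: pd.DataFrame     # subject, group, speed_cost, accuracy_cost,
                                  # included, reason


def summarize(trials: pd.DataFrame, *, on_empty: str = "flag") -> pd.DataFrame:
    """Accuracy and median RT per subject and condition.

    Accuracy counts a trial as correct only when the response was
    correct and the RT in range, over all trials of that condition.
    The RT summary is the median over correct in-range trials; when a
    subject has none in some condition the median is undefined — the
    row is flagged (``on_empty="flag"``, default) or an error is raised
    (``on_empty="raise"``).
    """
    f = (trials if "correct_valid" in trials.columns
         else filter_trials(trials))
    has_group = "group" in f.columns
    rows = []
    for (subj, cond), g in f.groupby(["subject", "condition"], sort=True):
        n = len(g)
        if n == 0:
            continue
        n_correct = int(g["correct_valid"].sum())
        accuracy = n_correct / n
        ok = g.loc[g["correct_valid"], "rt_ms"]
        if len(ok) == 0:
            if on_empty == "raise":
                raise ValueError(f"subject {subj!r} has no correct valid "
                                 f"trials in {cond}; median RT undefined")
            median = np.nan
        else:
            median = float(ok.median())
        group = g["group"].iloc[0] if has_group else ""
        rows.append((subj, group, cond, accuracy, median, n, n_correct))
    return pd.DataFrame(rows, columns=["subject", "group", "condition",
                                       "accuracy", "median_rt_ms",
                                       "n_trials", "n_correct"])


def cost_indices(rt_0back: float, rt_2back: float,
                 acc_0back: float, acc_2back: float) -> tuple[float, float]:
    """(speed_cost, accuracy_cost) from 0-back/2-back summaries.

    Invariant to the RT unit; requires positive 0-back denominators.
    """
    if rt_0back <= 0:
        raise ZeroDivisionError("0-back RT must be positive")
    if acc_0back <= 0:
        raise ZeroDivisionError("0-back accuracy must be positive")
    speed_cost = (rt_2back - rt_0back) / rt_0back
    accuracy_cost = (acc_0back - acc_2back) / acc_0back
    return speed_cost, accuracy_cost


def summarize_subjects(per_condition: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject table with cost indices (NaN when undefined)."""
    rows = []
    for subj, g in per_condition.groupby("subject", sort=True):
        rec = {"subject": subj,
               "group": g["group"].iloc[0] if "group" in g.columns else ""}
        for cond in CONDITIONS:
            sel = g[g["condition"] == cond]
            rec[f"accuracy_{cond}"] = (float(sel["accuracy"].iloc[0])
                                       if len(sel) else np.nan)
            rec[f"median_rt_{cond}"] = (float(sel["median_rt_ms"].iloc[0])
                                        if len(sel) else np.nan)
        try:
            sc, ac = cost_indices(rec["median_rt_0back"],
                                  rec["median_rt_2back"],
                                  rec["accuracy_0back"],
                                  rec["accuracy_2back"])
        except (ZeroDivisionError, ValueError):
            sc = ac = np.nan
        if np.isnan(rec["median_rt_0back"]) or np.isnan(rec["median_rt_2back"]):
            sc = np.nan
        rec["speed_cost"], rec["accuracy_cost"] = sc, ac
        rows.append(rec)
    return pd.DataFrame(rows)


def apply_exclusions(per_subject: pd.DataFrame, *, rule: str = "either",
                     threshold: float = 0.5,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag below-chance subjects; returns (annotated table, exclusion log).

    ``rule="either"`` (default) excludes a subject whose accuracy is
    strictly below ``threshold`` in the 1-back OR the 2-back condition;
    ``rule="both"`` requires below-chance performance in both.  Subjects
    with undefined summaries (no correct valid trials) are excluded too.
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    out = per_subject.copy()
    included, reasons, log = [], [], []
    for _, rec in out.iterrows():
        low1 = rec["accuracy_1back"] < threshold
        low2 = rec["accuracy_2back"] < threshold
        below = (low1 or low2) if rule == "either" else (low1 and low2)
        undefined = bool(np.isnan(rec["speed_cost"])
                         or np.isnan(rec["accuracy_cost"]))
        if below:
            which = [c for c, low in (("1back", low1), ("2back", low2)) if low]
            reason = f"below_chance:{'+'.join(which)}"
        elif undefined:
            reason = "undefined_summary"
        else:
            reason = ""
        included.append(not (below or undefined))
        reasons.append(reason)
        if reason:
            log.append((rec["subject"], reason))
    out["included"] = included
    out["reason"] = reasons
    log_df = pd.DataFrame(log, columns=["subject", "rule"])
    return out, log_df


def analyze_behavior(trials: pd.DataFrame, *, rule: str = "either",
                     ) -> tuple[BehaviorSummary, pd.DataFrame]:
    """Filter -> summarize -> cost indices -> exclusions, in one call."""
    filtered = filter_trials(trials)
    per_condition = summarize(filtered)
    per_subject = summarize_subjects(per_condition)
    per_subject, log = apply_exclusions(per_subject, rule=rule)
    return BehaviorSummary(per_condition=per_condition,
                           per_subject=per_subject), log
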