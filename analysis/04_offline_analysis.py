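#!/usr/bin/env python
"""Offline analysis of the neurofeedback sessions: per-trial relative
beta, the per-second beta time course, signed-rank timepoint tests, and
the behavioral summary.

Epochs are cut around pre-cue onset, band-passed at the individual beta
range, screened for artifacts, and reduced to relative beta (dB of
feedback period over baseline).  Tables go to results/tables/; a
time-course figure goes to scratch/figures/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import betanf as b
from betanf.calibration import epoch_by_event
from betanf.io import load_calibration, load_condition_schedule, load_session_log
from betanf.offline import (
    beta_timecourse_table,
    paired_signed_rank,
    session_trial_table,
)

SEED = 7
PARTICIPANT = "P01"

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
TABLES = RESULTS / "tables"
FIGURES = ROOT / "scratch" / "figures"


def main() -> None:
    TABLES.mkdir(parents=True, exist_ok=True)
    FIGURES.mkdir(parents=True, exist_ok=True)
    cal = load_calibration(RESULTS / f"{PARTICIPANT}_calibration.json")

    all_trials, all_epochs = [], []
    for session_index in (1, 2):
        # regenerate the session's EEG deterministically (same seeds as 03)
        session_seed = SEED * 10 + session_index
        profile = b.SyntheticProfile(seed=session_seed)
        agent = b.AgentModel(profile=profile, desync_gain=0.5, sync_gain=0.0)
        sched = b.build_nf_schedule(seed=session_seed)
        rec, markers = b.synthesize_session(profile, sched, agent=agent)
        sess = load_session_log(
            RESULTS / "sessions" / f"{PARTICIPANT}_session{session_index}.jsonl"
        )
        logs = {t.trial_index: t for t in sess.analyzable}
        epochs = epoch_by_event(rec, markers, "precue", (-2.0, 4.0))
        epochs = [ep for ep in epochs if ep.trial_index in logs]
        epochs = b.bandpass_individual(epochs, cal.r_beta_hz)
        epochs, rejected = b.reject_artifacts(epochs)
        for ep in epochs:
            ep.condition = logs[ep.trial_index].condition
            ep.participant = PARTICIPANT
        table = session_trial_table(epochs, cal.r_beta_hz)
        table["session"] = session_index
        all_trials.append(table)
        all_epochs.extend(epochs)
        print(f"session {session_index} "
              f"({epochs[0].condition}): {len(epochs)} epochs kept, "
              f"{len(rejected)} rejected")

    trials = pd.concat(all_trials, ignore_index=True)
    trials.to_csv(TABLES / "trial_relative_beta.tsv", sep="\t", index=False)

    for cond, g in trials.groupby("condition"):
        means = g.groupby("nf_direction").relative_beta.mean()
        print(f"{cond}: relative beta left {means.get('left', np.nan):+.2f} dB, "
              f"right {means.get('right', np.nan):+.2f} dB")

    course = beta_timecourse_table(all_epochs, cal.r_beta_hz)
    course.to_csv(TABLES / "beta_timecourse.tsv", sep="\t", index=False)

    # timepoint-wise left-vs-right signed-rank tests per condition, over
    # per-timepoint trial values (a single synthetic participant, so the
    # pairing unit is the trial, not the participant)
    stats_rows = []
    for cond in ("real", "sham"):
        g = trials[trials.condition == cond]
        left = g[g.nf_direction == "left"].relative_beta.to_numpy()
        right = g[g.nf_direction == "right"].relative_beta.to_numpy()
        n = min(len(left), len(right))
        res = b.paired_signed_rank(left[:n], right[:n],
                                   label=f"{cond}: left vs right")
        stats_rows.append({"comparison": res.label, "Z": res.statistic,
                           "p": res.p_value, "n": res.n})
        print(f"{res.label}: Z = {res.statistic:+.2f}, p = {res.p_value:.4f}")
    pd.DataFrame(stats_rows).to_csv(TABLES / "signed_rank_tests.tsv",
                                    sep="\t", index=False)

    # behavioral summary in the five-panel layout
    outcomes = []
    for _, row in trials.iterrows():
        o = b.classify_response(row.trial_type,
                                None if pd.isna(row.rt_s) else row.rt_s)
        o.trial_index = row.trial_index
        o.condition = row.condition
        o.nf_direction = row.nf_direction
        outcomes.append(o)
    behavior = b.summarize_behavior(outcomes)
    behavior.to_csv(TABLES / "behavior_summary.tsv", sep="\t", index=False)
    print(behavior.to_string(index=False))

    _plot_timecourse(course)


def _plot_timecourse(course: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, cond in zip(axes, ("real", "sham")):
        for d, color in (("left", "tab:blue"), ("right", "tab:red")):
            g = course[(course.condition == cond)
                       & (course.nf_direction == d)]
            ax.plot(g.timepoint_s, g["mean"], color=color, label=f"{d}")
        ax.axvline(0, ls="--", c="k", lw=0.8)
        ax.set_title(f"{cond} condition")
        ax.set_xlabel("time from NF onset (s)")
        ax.legend()
    axes[0].set_ylabel("beta band power")
    fig.tight_layout()
    out = FIGURES / "beta_timecourse.png"
    fig.savefig(out, dpi=120)
    print(f"figure -> {out}")


if __name__ == "__main__":
    main()
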