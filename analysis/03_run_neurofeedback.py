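#!/usr/bin/env python
"""Run both neurofeedback sessions (one real, one sham, order blinded)
through the closed-loop engine.

The session EEG is regenerated deterministically from the same profile,
schedule and agent as in 01; the sham session replays the calibration
beta stream through the identical bar algorithm.  Per-trial logs go to
results/sessions/.
"""

import warnings
from pathlib import Path

import numpy as np

import betanf as b
from betanf.io import (
    load_calibration,
    load_recording,
    save_condition_schedule,
    save_session_log,
)

SEED = 7
PARTICIPANT = "P01"

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SESSIONS = RESULTS / "sessions"


def main() -> None:
    SESSIONS.mkdir(parents=True, exist_ok=True)
    cal = load_calibration(RESULTS / f"{PARTICIPANT}_calibration.json")
    cal_rec = load_recording(DATA / f"{PARTICIPANT}_calibration.tsv")

    conds = b.make_condition_schedule([PARTICIPANT], seed=SEED)
    save_condition_schedule(RESULTS / "condition_schedule.json", conds)

    replay = b.make_replay_buffer(cal_rec, cal.r_beta_hz)
    for session_index in (1, 2):
        # each session is a separate visit: fresh EEG and trial jitter
        session_seed = SEED * 10 + session_index
        profile = b.SyntheticProfile(seed=session_seed)
        agent = b.AgentModel(profile=profile, desync_gain=0.5, sync_gain=0.0)
        sched = b.build_nf_schedule(seed=session_seed)
        rec, markers = b.synthesize_session(profile, sched, agent=agent)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # replay wrap notices
            sess = b.run_session(rec, markers, cal, sched, conds,
                                 PARTICIPANT, session_index,
                                 replay_buffer=replay)
        out = SESSIONS / f"{PARTICIPANT}_session{session_index}.jsonl"
        save_session_log(out, sess)
        # report only the blinded summary here; conditions are revealed
        # by the offline analysis, not by the session runner
        print(f"session {session_index}: {sess.summary()['n_analyzable']} "
              f"analyzable trials -> {out}")

    # unblinded engineering check (would not be printed during a study)
    for session_index in (1, 2):
        sess_cond = conds.condition_for(PARTICIPANT, session_index)
        print(f"  [post hoc] session {session_index} was {sess_cond}")


if __name__ == "__main__":
    main()
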