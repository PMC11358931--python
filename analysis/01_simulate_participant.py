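#!/usr/bin/env python
"""Simulate one participant's raw data: a 32-trial calibration run and
the EEG stream for the neurofeedback sessions.

The participant is a synthetic profile with a 21 Hz beta peak, 40% MRBD
suppression and a 1.4x PMBR, plus a closed-loop agent that can suppress
beta on demand (desync_gain 0.5) but cannot raise it (sync_gain 0).
Raw recordings go to scratch/data/ (large); schedules go to
results/tables/.
"""

from pathlib import Path

import betanf as b
from betanf.io import save_markers, save_recording, save_schedule

SEED = 7
PARTICIPANT = "P01"

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
TABLES = ROOT / "results" / "tables"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)

    profile = b.SyntheticProfile(seed=SEED)
    cal_sched = b.build_calibration_schedule(seed=SEED)
    nf_sched = b.build_nf_schedule(seed=SEED)

    cal_rec, cal_markers = b.synthesize_session(profile, cal_sched)
    save_recording(DATA / f"{PARTICIPANT}_calibration.tsv", cal_rec)
    save_markers(DATA / f"{PARTICIPANT}_calibration_events.tsv", cal_markers)
    save_schedule(TABLES / "calibration_schedule.tsv", cal_sched)
    save_schedule(TABLES / "nf_schedule.tsv", nf_sched)

    print(f"participant {PARTICIPANT}: beta peak {profile.peak_beta_hz} Hz, "
          f"MRBD depth {profile.mrbd_depth}, PMBR gain {profile.pmbr_gain}")
    print(f"calibration run: {len(cal_sched)} trials, "
          f"{cal_rec.duration_s:.0f} s of EEG -> {DATA}")
    print(f"NF schedule: {len(nf_sched.analyzable)} analyzable trials "
          f"(+{sum(t.practice for t in nf_sched)} practice) -> {TABLES}")


if __name__ == "__main__":
    main()
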