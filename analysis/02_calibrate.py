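#!/usr/bin/env python
"""Calibrate the participant: individual beta peak, band, and feedback
thresholds from the saved calibration run.

Reads the raw recording written by 01, runs the calibration pipeline,
checks the biphasic MRBD/PMBR signature, and writes the calibration
result consumed by the neurofeedback engine.
"""

from pathlib import Path

import betanf as b
from betanf.io import load_markers, load_recording, save_calibration

SEED = 7
PARTICIPANT = "P01"

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    rec = load_recording(DATA / f"{PARTICIPANT}_calibration.tsv")
    markers = load_markers(DATA / f"{PARTICIPANT}_calibration_events.tsv")
    cal = b.calibrate(rec, markers, provenance={"seed": SEED,
                                                "participant": PARTICIPANT})
    out = RESULTS / f"{PARTICIPANT}_calibration.json"
    save_calibration(out, cal)

    lo, hi = cal.r_beta_hz
    print(f"fmax_beta = {cal.fmax_beta_hz:.0f} Hz, "
          f"R_beta = [{lo:.0f}, {hi:.0f}] Hz "
          f"({cal.n_trials} correct Go trials)")
    print(f"thresholds: th_desync = {cal.th_desync:.1f}, "
          f"th_sync = {cal.th_sync:.1f} (baselined power units)")
    print(f"beta signature (MRBD then PMBR) confirmed: {cal.signature_ok}")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
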