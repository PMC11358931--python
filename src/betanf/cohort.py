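"""Statistical cohort model for the group-level analyses.

Simulating 17 participants' full EEG sessions is wasteful when the group
statistics only consume per-trial (reaction time, relative beta) pairs,
so this module generates those pairs directly.  Each participant
contributes correct-Go trials in the four (condition x direction) cells;
relative beta is drawn negative on average (beta is suppressed during
feedback regardless of instruction), and reaction time is coupled to
relative beta — faster responses with deeper suppression — only in the
cell where a planted effect is requested.  The default plants the
coupling in the real-left cell, the pattern the protocol is designed to
detect.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["simulate_cohort"]

CELLS = (("real", "left"), ("real", "right"), ("sham", "left"), ("sham", "right"))


def simulate_cohort(
    n_participants: int = 17,
    trials_per_cell: int = 21,
    planted_r: float = 0.4,
    planted_cell: tuple = ("real", "left"),
    rt_mean_s: float = 0.49,
    rt_sd_s: float = 0.08,
    beta_mean_db: float = -1.5,
    beta_sd_db: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Trialwise (RT, relative beta) cohort with one planted coupling.

    In the planted cell RT and relative beta are bivariate normal with
    population correlation ``planted_r`` (positive: lower beta goes with
    faster responses); all other cells are uncorrelated.  21 trials per
    cell reflects 84 correct Go trials split over two directions and two
    sessions.  Returns a long DataFrame with columns participant,
    condition, nf_direction, rt_s, relative_beta.
    """
    if not -1.0 < planted_r < 1.0:
        raise ValueError("planted_r must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for cond, d in CELLS:
            z_beta = rng.standard_normal(trials_per_cell)
            z_noise = rng.standard_normal(trials_per_cell)
            rho = planted_r if (cond, d) == planted_cell else 0.0
            z_rt = rho * z_beta + np.sqrt(1.0 - rho**2) * z_noise
            beta = beta_mean_db + beta_sd_db * z_beta
            rt = np.clip(rt_mean_s + rt_sd_s * z_rt, 0.1, 0.8)
            for b, r in zip(beta, rt):
                rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "nf_direction": d,
                        "rt_s": float(r),
                        "relative_beta": float(b),
                    }
                )
    return pd.DataFrame(rows)
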