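"""Eyeblink conditioning: acquisition curves for two genotypes.

Emulates ten daily sessions for a fast-learning "control" group and a
slow-starting "knockout" group by ramping the per-trial CR probability,
then pushes every session through the full trial pipeline (7x IQR
validity rule, full-blink normalization, CR criteria, session metrics).
The sessions here are scaled down to 40 paired trials (with the full 20 CS-only and
10 US-only trials) to keep the driver fast; the generator default is the
full 200/20/20 protocol.

Writes results/eyeblink_learning.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pcphys import BlinkGenSpec, analyze_session, gen_blink_session

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_SESSIONS = 10


def acquisition(p_final: float, rate: float) -> np.ndarray:
    """Saturating-exponential CR-probability schedule over sessions."""
    day = np.arange(N_SESSIONS)
    return p_final * (1.0 - np.exp(-rate * day))


def main() -> None:
    schedules = {"control": acquisition(0.85, 0.45),
                 "knockout": acquisition(0.85, 0.18)}
    rows = []
    for g_idx, (genotype, probs) in enumerate(schedules.items()):
        for day, p in enumerate(probs):
            spec = BlinkGenSpec(n_paired=40, n_cs_only=20, n_us_only=10,
                                cr_probability=float(p),
                                invalid_fraction=0.05,
                                seed=SEED + 100 * day + 17 * g_idx)
            res = analyze_session(gen_blink_session(spec))
            rows.append({"genotype": genotype, "session": day + 1,
                         "true_cr_prob": p,
                         "cr_percentage": res.cr_percentage,
                         "cr_amplitude": res.cr_amplitude,
                         "n_valid": res.n_valid,
                         "n_invalid": res.n_trials - res.n_valid})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "eyeblink_learning.csv", index=False, float_format="%.3f")

    print("CR% by session (pipeline estimate vs generator schedule):")
    for g in schedules:
        sub = df[df.genotype == g]
        print(f"  {g:9s} day1 {sub.cr_percentage.iloc[0]:5.1f}%  "
              f"day5 {sub.cr_percentage.iloc[4]:5.1f}%  "
              f"day10 {sub.cr_percentage.iloc[-1]:5.1f}%")
    invalid_rate = df.n_invalid.sum() / (df.n_invalid.sum() + df.n_valid.sum())
    print(f"overall invalid-trial rate: {invalid_rate:.1%} "
          f"(generator ground truth 5%)")


if __name__ == "__main__":
    main()
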