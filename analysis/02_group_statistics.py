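"""Group comparisons: printed-summary t table, cohort t test, power sizes.

Part 1 reconstructs the pooled t statistics of the four headline group
comparisons directly from their printed mean ± SD (n) summaries — these
are exact arithmetic, no simulation.  Part 2 applies the same test to
the per-cell rates simulated by 01_simulate_cohorts.py.  Part 3 runs the
noncentral-t sample-size search at the reported planning parameters.

Writes results/printed_t_table.csv and results/power_sizes.csv.
"""

from pathlib import Path

import pandas as pd

from pcphys import GroupSummary, PowerSpec, sample_size_t, t_from_raw, \
    t_from_summary

OUT = Path(__file__).resolve().parents[1] / "results"

PRINTED = [
    ("slice_rate_KO_Zneg", (55.4, 21.8, 43), (44.1, 15.6, 40)),
    ("slice_rate_GoF_Zneg", (58.4, 19.6, 15), (84.5, 36.2, 15)),
    ("targeted_rate_KO_Zneg", (72.7, 26.5, 14), (36.5, 23.2, 16)),
    ("inducible_rate_KO_Zneg", (86.5, 10.9, 25), (72.9, 9.1, 30)),
    ("slice_rate_KO_Zpos", (30.8, 11.7, 35), (28.5, 9.3, 36)),
    ("invivo_rate_KO_Zpos", (50.0, 12.9, 24), (50.2, 15.5, 32)),
]

POWER = [
    ("in_vivo_rate", 35.3, 17.8),
    ("in_vitro_rate", 18.1, 14.0),
]


def main() -> None:
    rows = []
    for name, ctrl, mut in PRINTED:
        res = t_from_summary(GroupSummary(*ctrl, label="control"),
                             GroupSummary(*mut, label="mutant"))
        rows.append({"comparison": name, "t": res.t, "df": res.df,
                     "p": res.p, "method": res.method})
    t_table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    t_table.to_csv(OUT / "printed_t_table.csv", index=False,
                   float_format="%.4f")
    print("t statistics from printed summaries:")
    print(t_table.round(3).to_string(index=False))

    cohort_file = OUT / "cohort_cells.csv"
    if cohort_file.exists():
        df = pd.read_csv(cohort_file)
        a = df.loc[df.group == "Zneg_control", "rate"]
        b = df.loc[df.group == "Zneg_knockout", "rate"]
        res = t_from_raw(a, b)
        print(f"\nsimulated Z- cohort: t_{res.df:.0f} = {res.t:.2f}, "
              f"p = {res.p:.4f}")

    power_rows = [{"experiment": name, "delta": d, "sd": sd,
                   "n_per_group": sample_size_t(PowerSpec(delta=d, sd=sd))}
                  for name, d, sd in POWER]
    power = pd.DataFrame(power_rows)
    power.to_csv(OUT / "power_sizes.csv", index=False)
    print("\na priori sample sizes (alpha 0.05, power 0.80):")
    print(power.to_string(index=False))


if __name__ == "__main__":
    main()
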