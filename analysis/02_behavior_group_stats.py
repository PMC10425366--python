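#!/usr/bin/env python
"""Group statistics on the scored behavioral tables.

Reads the tidy trial table written by 01_score_behavior_cohort.py and
re-runs the inference layer explicitly: per-phenotype mixed ANOVAs of CS
freezing (treatment x trial), the one-way ANOVA of extinction-day
baseline freezing (the contextual-generalization readout) and Dunnett
post hocs against vehicle.  Writes results/behavior/group_stats.csv.

Run after 01:  python analysis/02_behavior_group_stats.py
"""

from pathlib import Path

import pandas as pd

from fearframe import group_stats

IN = Path("results/behavior")
OUT = IN / "group_stats.csv"


def main() -> None:
    trial = pd.read_csv(IN / "trial_table.csv")
    animals = pd.read_csv(IN / "animals.csv")
    df = trial.merge(animals[["animal_id", "phenotype"]], on="animal_id")
    rows = []

    cohorts = {
        "female Non-darters": (df["sex"] == "female")
        & (df["phenotype"] == "Non-darter"),
        "female Darters": (df["sex"] == "female") & (df["phenotype"] == "Darter"),
        "males": df["sex"] == "male",
    }
    for name, sel in cohorts.items():
        sub = df[sel]
        if sub["animal_id"].nunique() < 8:
            print(f"{name}: too few animals, skipped")
            continue
        for session in ("conditioning", "extinction"):
            data = sub[
                (sub["session"] == session)
                & (sub["measure"] == "percent_freezing_cs")
                & (sub["trial_index"] >= 1)
            ]
            if (data.groupby("treatment")["animal_id"].nunique() < 2).any():
                continue
            for r in group_stats.mixed_anova(
                data, dv="value", between="treatment",
                within="trial_index", subject="animal_id",
            ):
                print(
                    f"{name} / {session} CS freezing: {r.test} "
                    f"F({r.df[0]:.3g},{r.df[1]:.4g}) = {r.statistic:.2f}, "
                    f"p = {r.p_value:.3g} [{r.correction}]"
                )
                rows.append(
                    {"cohort": name, "session": session, **r.as_dict()}
                )

    # contextual generalization: extinction baseline freezing, Non-darter females
    base = df[
        (df["session"] == "extinction")
        & (df["measure"] == "baseline_percent_freezing")
        & (df["sex"] == "female")
        & (df["phenotype"] == "Non-darter")
    ]
    samples = {
        t: g["value"].to_numpy() for t, g in base.groupby("treatment")
    }
    if len(samples) >= 2:
        r = group_stats.oneway_anova(samples, "extinction baseline freezing")
        print(
            f"female Non-darters / extinction baseline freezing: one-way "
            f"F({r.df[0]:.0f},{r.df[1]:.0f}) = {r.statistic:.2f}, p = {r.p_value:.3g}"
        )
        rows.append({"cohort": "female Non-darters", "session": "extinction",
                     **r.as_dict()})
        if "VEH" in samples and len(samples) > 2:
            for d in group_stats.dunnett_posthoc(samples, control="VEH", seed=1):
                print(f"  Dunnett {d.comparison}: p = {d.p_value:.3g}")
                rows.append({"cohort": "female Non-darters",
                             "session": "extinction", **d.as_dict()})

    pd.DataFrame(rows).to_csv(OUT, index=False)
    print(f"written {OUT}")


if __name__ == "__main__":
    main()
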