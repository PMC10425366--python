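#!/usr/bin/env python
"""Simulate and score the behavioral cohort.

Simulates a full drug-study cohort (4 treatments x 2 sexes, 12 rats per
group) through conditioning and extinction sessions, scores darting,
freezing and shock responsivity from the velocity traces, classifies the
Darter phenotype, and writes the tidy trial table, the animal manifest and
the behavioral statistics bundle under results/behavior/.

Run from the repository root:  python analysis/01_score_behavior_cohort.py
"""

from pathlib import Path

import pandas as pd

from fearframe.pipeline import BehaviorConfig, RunConfig, run_behavior_pipeline

OUT = Path("results/behavior")
SEED = 20260101


def main() -> None:
    cfg = RunConfig(
        seed=SEED,
        behavior=BehaviorConfig(n_per_group=12),
        out_dir=str(OUT),
    )
    res = run_behavior_pipeline(cfg)
    animals = res.animals
    print(f"scored {len(animals)} animals (seed {SEED})")
    for sex in ("female", "male"):
        sub = animals[animals["sex"] == sex]
        n_dart = int((sub["phenotype"] == "Darter").sum())
        print(f"  {sex}: {n_dart}/{len(sub)} Darters "
              f"({100 * n_dart / len(sub):.1f}%)")
    match = (animals["phenotype"] == "Darter") == (
        animals["planted_phenotype"] == "Darter-like"
    )
    print(f"  classification matches planted phenotype for {match.sum()}"
          f"/{len(animals)} animals")
    if res.darter_chi_square is not None:
        c = res.darter_chi_square
        print(
            "  Darter proportion homogeneity across treatments (females): "
            f"chi-square = {c.statistic:.2f}, df = {c.df[0]:.0f}, "
            f"p = {c.p_value:.2f}"
        )
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
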