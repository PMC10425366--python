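# fearframe

Quantification machinery for rodent cued-fear-conditioning studies that
score *multiple* defensive behaviors — not just freezing — together with
the microscopy and statistics layers such studies rely on. The package
covers three arms:

1. **Behavioral scoring from velocity traces.** Video-tracking software
   exports a per-animal speed series (cm/s). From it, fearframe scores:
   - **Darting** — a discrete locomotor movement reaching ≥ 20 cm/s during
     a conditioned-stimulus (CS) presentation;
   - the **Darter phenotype** — any animal with at least one dart,
     excluding darts on conditioning trials 1–2;
   - **Freezing** — velocity below a small threshold for ≥ 1 s, reported
     as percent of each 30-s CS (and of the pre-CS baseline, the
     contextual-generalization readout);
   - **Shock responsivity** — maximum velocity within 5 s of shock
     delivery, inclusive of the delivery itself.
2. **Microscopy quantification.** Watershed/particle counting of
   retrogradely labeled somata inside a traced region (cells/mm², averaged
   across sections per animal), and perisomatic "donut" fluorescence: a
   5-µm shell grown around each soma in a confocal z-stack
   (0.111 × 0.111 × 0.33 µm voxels), binarized, expressed as the
   positive-voxel fraction, and background-corrected as
   `normalized = raw − background` with the background measured by an
   identically shaped shell in a paired reference stack. Per-animal values
   are means of section means (never pooled counts).
3. **Group statistics.** Chi-square homogeneity (Darter proportions),
   Welch's *t* (Satterthwaite df), mixed-design repeated-measures ANOVA
   with Greenhouse–Geisser correction applied when Mauchly's test rejects
   sphericity (yielding fractional df), and two-sided Dunnett many-to-one
   post hocs computed from the equicorrelated multivariate-*t* reference
   distribution by seeded Monte Carlo.

Because raw animal data of such studies are rarely deposited, fearframe
ships **synthetic generators** for both arms — velocity traces with
planted darts/freezing bouts/shock peaks and cohorts with a 29 %
Darter-like mixture in females (0 % in males), and section images /
two-channel z-stacks with planted cell counts and a 2:1
labeled:unlabeled punctum density — so every stage of the pipeline is
verifiable end to end against logged ground truth.

Intended users: behavioral neuroscientists processing tracking exports,
and anyone needing a tested reference implementation of dart/freeze
scoring, donut quantification, or the accompanying statistics.

## Worked example

Simulate one Darter-like female through the standard conditioning session
(7 CS–US pairings, 30-s CS, 1-s shock, 180-s ITIs) and score it:

```python
from fearframe import (build_session_design, epoch_trace, detect_darts,
                       detect_freezing, classify_darter, summarize_session)
from fearframe.behavior_scoring import shock_response
from fearframe.synthetic_behavior import darter_like, simulate_animal

design = build_session_design("conditioning")
trace, truth = simulate_animal(darter_like(), design, seed=1)
epoched = epoch_trace(trace, design)
darts = detect_darts(epoched)
bouts = detect_freezing(trace, epoched)
summary = summarize_session(trace, epoched, darts, bouts)

print(f"phenotype: {classify_darter(darts)}")
for d in darts:
    print(f"dart on trial {d.trial_index}: peak {d.peak_velocity:.1f} cm/s "
          f"at {d.onset:.1f}-{d.offset:.1f} s")
print(f"baseline freezing: {summary[0].baseline_percent_freezing:.1f}%")
print("CS freezing by trial:",
      " ".join(f"{s.percent_freezing_cs:.0f}%" for s in summary[1:]))
print("shock response by trial:",
      " ".join(f"{r:.0f}" for r in shock_response(epoched)), "cm/s")
```

prints

```
phenotype: Darter
dart on trial 6: peak 25.5 cm/s at 1236.9-1237.1 s
baseline freezing: 4.4%
CS freezing by trial: 10% 20% 8% 0% 0% 19% 17%
shock response by trial: 63 76 60 65 70 68 66 cm/s
```

The single dart lands on trial 6 (darting concentrates in later trials),
so the animal meets the Darter criterion; the seven shock-response values
are the 5-s post-shock velocity maxima, which here equal the planted shock
peaks exactly.

## Analysis drivers

Numbered scripts under `analysis/` run the full arms and write tidy
tables under `results/`:

- `01_score_behavior_cohort.py` — simulate and score a 4-treatment ×
  2-sex cohort (conditioning + extinction), classify Darters, chi-square
  of Darter proportions across treatments.
- `02_behavior_group_stats.py` — per-phenotype mixed ANOVAs of CS
  freezing, baseline-freezing one-way ANOVA with Dunnett post hocs.
- `03_imaging_quantification.py` — synthetic sections and z-stacks;
  donut density ratio, cell-density Welch's *t*, circuit × sex mixed
  ANOVA.
- `04_shell_geometry_check.py` — voxel-counted 5-µm shell volumes vs
  closed-form annulus stacks.

A thin CLI wraps the same pipeline: `fearframe simulate|score|quantify|analyze`.

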