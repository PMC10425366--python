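# Methods

This note documents the models, conventions and numerical choices behind
fearframe, what the synthetic generators do and do not emulate, and the
problem sizes used by the validation battery.

## Behavioral data model

A session is a timed layout of baseline, CS, shock and inter-trial
windows (`SessionDesign`). The standard protocol builds 7 CS–US
conditioning, 20-CS extinction and 5-CS retrieval sessions from a 30-s
CS, 1-s shock coterminating with the CS, and 180-s ITIs; habituation is
a 600-s CS-free session. Two protocol details are not fixed by
convention and are therefore explicit parameters with documented
defaults: the tracking export's sampling rate (default 30 Hz, a typical
video-tracking rate) and the lead-in before the first CS (default one
ITI, 180 s). The baseline window is session start to first CS onset.

All intervals are half-open `[on, off)`; seconds are mapped to 0-based
sample indices by `floor(t * rate)`. Detectors operate in seconds, never
raw samples, so scored quantities are invariant to resampling up to one
sample period.

The reader (`read_velocity_trace`) expects a delimited text file with
header columns `time_s` and `velocity_cm_s` (comma or tab). Tracking
dropouts up to 0.5 s are repaired by linear interpolation and logged;
longer gaps are data-quality errors. Negative velocities and
non-monotonic time stamps are rejected outright.

## Scoring conventions

**Darting.** A dart is a maximal run of samples at or above the dart
threshold (default 20 cm/s) whose onset falls inside a CS window. Two
conventions sharpen the bare definition:

- *Gap merging* (default 0.3 s): sub-threshold gaps shorter than the
  merge gap fuse adjacent runs, so one lunge interrupted by a single
  noisy sample is not double-counted. A consequence worth knowing: dart
  *count* is only guaranteed monotone in the threshold for
  well-separated unimodal excursions (the biological regime); on
  arbitrary noise, raising the threshold can split a merged run in two.
- *Shock exclusion* (default on): in trials with a shock, the dart
  search window ends at shock onset. The shock coterminates with the
  CS, so a shock-evoked velocity burst starts inside the CS's final
  second and would otherwise be scored as a conditioned dart — making
  every shock-responsive animal a "Darter". Darting and shock
  responsivity are distinct constructs; the flag
  `exclude_shock_period_from_darts=False` restores the literal reading.

An excursion straddling the CS offset counts if its onset is inside the
CS and is clipped to the window. Events shorter than
`dart_min_duration` (default: one sample) are discarded.

**Darter classification.** An animal is a Darter iff it has at least one
dart on a conditioning trial outside the excluded set {1, 2}. Early-trial
excursions are treated as shock-reactivity carryover rather than
conditioned darting. Classification uses the conditioning session only;
whether extinction darts should confer status is an open convention and
is configurable (`classification_session`).

**Freezing.** A bout is a maximal run with velocity below
`freeze_velocity_threshold` lasting at least 1 s. The velocity cut-off is
*not* part of the behavioral definition (cessation of all movement except
breathing) — it is a scoring convention that must be calibrated to the
rig; the default 0.5 cm/s suits traces whose active baseline sits a few
cm/s above zero. The 1-s minimum applies to whole bouts; bouts are then
split at epoch boundaries, so a bout spanning a CS offset contributes
only its in-CS portion to that trial's percent. Hand-corrections (e.g.
sleeping animals scored as frozen) are supported by excluding intervals
upstream, not automated.

**Shock responsivity.** Max velocity over `[shock_onset, shock_onset +
5 s)`, inclusive of delivery. An instantaneous variant (velocity at the
shock-onset sample) exists behind `shock_instantaneous` for comparison
with reports that use that phrasing.

**Block averaging.** Per-trial CS-freezing percentages can be averaged
into consecutive blocks (e.g. 20 extinction trials → 10 two-trial
blocks) for repeated-measures analysis; block size is an analysis
choice, not a scoring one.

## Behavioral generator

`simulate_animal` builds a trace as: truncated-normal baseline noise
(mean 3, SD 1.2 cm/s, clipped at zero to honor the non-negativity
invariant — a censoring, acceptable because the mass below zero is
< 1 %), planted freezing bouts (velocity drawn uniformly below
0.2 cm/s), half-sine dart pulses inside CS windows, and half-sine shock
pulses at shock onsets (peaks 50–80 cm/s). Half-sines were chosen
because their threshold-crossing width is analytically computable and the
discretized pulse maximum can be logged exactly, so recovery checks are
sharp. Planted darts end ≥ 0.5 s before shock onset so the gap-merge
rule can never fuse a dart with the shock burst.

Dart probability rises linearly across trials (slope 0.15 per trial
around the session midpoint) so darting concentrates in later trials.
Darter-like animals (per-trial dart probability 0.6, amplitudes
25–40 cm/s) are guaranteed at least one dart on a classification-eligible
trial: if the Bernoulli draws produce none, one is planted on a random
eligible trial. This makes the planted phenotype label and the
classification rule coincide by construction, which is what the
mixture-consistency checks require.

Cohorts draw each animal's parameters from a per-sex mixture — 29 %
Darter-like in females, 0 % in males by default — with per-animal seeds
spawned from the cohort seed (`numpy.random.SeedSequence`), so cohorts
are bit-reproducible and assignment is independent of how many sessions
are later simulated. Default baseline freezing is modest (mean 15 s of a
180-s baseline, ≈ 8 %); contextual-generalization effects are planted by
raising `baseline_freeze_time` for a treatment group.

What the generator does **not** emulate: autocorrelated locomotion,
posture-dependent tracking noise, sleep (hand-scored in real studies),
within-session habituation of baseline speed, or trial-to-trial freezing
dynamics. Passing recovery tests therefore demonstrates correctness of
the scoring conventions, not robustness to every artifact of real video
tracking.

## Imaging quantification

**Cell counting.** Pipeline: restrict to the traced ROI polygon →
binarize (Otsu on ROI pixels by default, or a fixed absolute threshold)
→ fill holes → distance-transform watershed seeded at EDT peaks
(minimum peak separation 6 µm by default) → connected components → keep
components with area in [30, 700] µm² (soma scale at low magnification;
the bracket is configurable and is a default, not a claim about any
particular study's inclusion criteria) → count; density = count / ROI
polygon area (mm², shoelace formula). Two guards make degenerate inputs
explicit: a constant ROI yields zero cells with a warning, and an
auto-threshold that keeps more than 35 % of the ROI (Otsu bisecting a
cells-free noise image) also yields zero cells with a warning.
Animal-level density is the unweighted mean of per-section densities — a
mean of means, so each section contributes equally regardless of traced
area.

**Perisomatic shell.** The donut of width *w* (default 5 µm) is grown
in-plane: each z-slice containing soma is dilated by a true Euclidean
disk of `round(w / xy_voxel)` pixels (45 px at 0.111 µm; numpy's
round-half-even) and the soma is subtracted. In-plane construction was
chosen because the axial voxel (0.33 µm) is anisotropic and slice-wise
processing matches how such stacks are acquired and inspected; a 3-D
ball mode (`mode="ball3d"`, physical distance threshold) is available.
Shell voxels falling outside the image are clipped; the clipped fraction
is recorded and > 25 % is an error. Voxel-counted shell volumes agree
with closed-form annulus stacks to ≈ 0.5 % for spherical somata of
radius 3–6 µm, and the EDT construction matches a brute-force per-voxel
distance oracle exactly.

**Density and normalization.** Fluorescence within the shell is
binarized and reported as the positive-voxel fraction — dimensionless,
scale-free, robust to punctum merging, and cleanly subtractable. An
alternative punctum-count-per-volume metric was considered and rejected
as sensitive to merging at realistic punctum densities. The default
threshold is Otsu *on the shell voxels of the signal stack*, and the
same absolute threshold is then applied to an identically shaped shell
placed at the centre of the paired background stack; deriving a second
Otsu threshold from the (unimodal) background would bisect its noise and
produce a meaningless ~0.5 density. With sparse puncta Otsu can still
slide into the noise, so pipelines over synthetic data use the
generator's known fixed threshold (background + half punctum amplitude),
recorded per cell in the output. Normalized density = raw − background,
negatives retained (clipping would bias group means upward). Per-animal,
per-label values average cells within sections, then sections within
animals.

**Densitometry.** Band quantification is the plain ratio of target to
loading-control optical density, with duplicate lanes averaged before
the ratio.

## Imaging generator

Sections: Gaussian-profile somata (radius 5–8 µm, σ = half the radius,
peak 150–220 over a background of 10 with SD-3 noise) placed by
rejection sampling with a minimum centre separation inside a rectangular
ROI; counts are Poisson at the requested density or exact when
`n_cells` is given. Stacks: an ellipsoidal soma mask, puncta as
diffraction-scale 3-D Gaussians (σ ≈ 0.3 µm in-plane) centred on voxels
drawn uniformly from the true shell, with the punctum count set
deterministically to `round(density × shell volume)` so the planted
2:1 labeled:unlabeled contrast is exact rather than Poisson-blurred;
the paired background stack shares the background level and noise SD so
subtraction is meaningful. Not emulated: optical PSF anisotropy beyond
the punctum σ, photobleaching, chromatic registration error, tissue
autofluorescence gradients.

## Statistics

Wrappers delegate the sums-of-squares machinery to pingouin/scipy and
standardize the output (`StatResult`: statistic, df pair — possibly
fractional — p, correction applied):

- *Chi-square homogeneity*: Pearson statistic, no continuity correction;
  zero margins are errors.
- *Welch's t*: Satterthwaite df, reported fractionally.
- *Mixed ANOVA*: one between × one within factor; subjects with missing
  cells are dropped listwise and logged. Sphericity is tested with
  Mauchly's W; when rejected at α = 0.05, both df of the within and
  interaction terms are multiplied by the Greenhouse–Geisser epsilon and
  p recomputed — the GG-on-violation policy that produces fractional df.
  Constant data short-circuits to F = 0, p = 1 (the SS machinery would
  return 0/0).
- *Dunnett post hocs*: pooled-variance many-to-one t statistics; the
  familywise-adjusted p of comparison *i* is `P(max_j |T_j| ≥ |t_i|)`
  under the joint null, estimated from seeded Monte Carlo draws of the
  equicorrelated multivariate-t maximum (default 10⁵ draws; control-mean
  and variance sharing induce the correlation analytically, so unequal
  group sizes need no tables). Adjusted p is clamped to be at least the
  unadjusted t p — exact in the reference distribution, removing Monte
  Carlo violations — and zero pooled variance degenerates to p = 1 for
  identical data.

Null calibration (2000 replicates each; tolerance 3 Monte Carlo σ
≈ ±0.015): chi-square on 4 × binomial(50, 0.29) Darter tables, Welch on
unequal-variance normals (n = 15 vs 20), mixed ANOVA between/within on
iid normals (2 groups × 12 subjects × 6 trials), and Dunnett familywise
error via the 95 % quantile of 4 × 10⁵ max-|T| draws against 2000
simulated 4-group experiments.

## Problem sizes used by the validation battery

Chosen so the full suite runs in a few minutes on one core: 500 random
traces (≤ 10⁴ samples) for detector-oracle equivalence; 200 simulated
animals for planted-event recovery (dart sensitivity = precision = 1.0,
CS freezing within ±2 points, shock peaks exact); 500 females + 500
males for mixture consistency (binomial 95 % CI around the planted 29 %);
20 cells per label for the 2:1 donut ratio (±10 %); 16 sections per sex
for the 2:1 cell-density ratio (±10 %); 25-cell sections counted
exactly; 64³ stacks for the brute-force shell oracle.

## Known limitations

- The freezing velocity threshold is a convention; real deployments must
  calibrate it (and hand-score sleep) before trusting absolute percents.
- Otsu binarization is unreliable when the structure of interest
  occupies ≲ 2 % of the thresholded region (sparse puncta, cells-free
  ROIs); the fixed-threshold path and the foreground-fraction guard are
  the supported answers, and thresholds are always recorded in outputs.
- The mixed ANOVA handles one between and one within factor — the
  designs used here — not general factorial models.
- Dunnett adjusted p-values carry Monte Carlo error ~(p(1−p)/draws)^½;
  raise `n_draws` where the 3rd decimal matters.
- The generators are specification instruments: they make planted truth
  recoverable, they do not simulate rat biomechanics or microscope
  optics.
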