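"""Synthetic velocity traces and cohorts with planted, logged ground truth.

The generator emulates the signal structure of a tracked fear-conditioning
session: non-negative baseline locomotor noise, freezing bouts of
near-zero velocity, CS-locked dart excursions (half-sine pulses whose
threshold-crossing width is analytically computable), and shock-evoked
velocity peaks at shock onsets.  Every planted event is recorded in a
:class:`GroundTruthLog` so detector sensitivity/precision and freezing
recovery can be measured exactly.

Cohort-level defaults mirror the study population the scoring layer was
built for: 29% of females carry a Darter-like phenotype (conditioned
darting concentrated in later trials) while males are uniformly
Non-darter-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .behavior_io import AnimalRecord, SessionDesign, VelocityTrace
from .errors import SimulationError

__all__ = [
    "AnimalSimParams",
    "PlantedDart",
    "PlantedFreeze",
    "GroundTruthLog",
    "GroupSpec",
    "Cohort",
    "darter_like",
    "non_darter_like",
    "default_mixture",
    "simulate_animal",
    "simulate_cohort",
    "DARTER_RATE_FEMALE",
]

#: Default fraction of females carrying the Darter-like phenotype.
DARTER_RATE_FEMALE = 0.29


@dataclass(frozen=True)
class AnimalSimParams:
    """Per-animal generative parameters.

    Attributes
    ----------
    baseline_speed_mean, baseline_speed_sd
        Gaussian locomotor noise (cm/s), truncated at zero.
    p_freeze_per_cs
        Probability of planting one freezing bout in each CS.
    freeze_bout_duration
        (mean, sd) of planted bout durations in seconds.
    p_dart_per_cs
        Base per-trial dart probability; scaled across trials by
        ``dart_trial_slope`` so darting is most prevalent in later trials.
    dart_amplitude, dart_duration
        Uniform ranges for the half-sine dart pulse peak (cm/s) and width (s).
    dart_trial_slope
        Linear per-trial weighting of dart probability (0 = uniform).
    shock_peak
        Uniform range for the shock-evoked velocity peak (cm/s).
    shock_pulse_duration
        Width (s) of the half-sine shock response pulse.
    baseline_freeze_time
        (mean, sd) seconds of freezing planted in the pre-CS baseline
        window.  The default plants modest contextual freezing (~8% of a
        180-s baseline); raise it to emulate contextual fear
        generalization.
    phenotype_label
        Intended phenotype, ``"Darter-like"`` or ``"Non-darter-like"``.
        Darter-like animals are guaranteed at least one dart on a trial
        beyond the classification-excluded trials 1-2.
    """

    baseline_speed_mean: float = 3.0
    baseline_speed_sd: float = 1.2
    p_freeze_per_cs: float = 0.7
    freeze_bout_duration: tuple[float, float] = (5.0, 1.5)
    p_dart_per_cs: float = 0.0
    dart_amplitude: tuple[float, float] = (25.0, 40.0)
    dart_duration: tuple[float, float] = (0.4, 0.8)
    dart_trial_slope: float = 0.15
    shock_peak: tuple[float, float] = (50.0, 80.0)
    shock_pulse_duration: float = 0.8
    freeze_speed_max: float = 0.2
    baseline_freeze_time: tuple[float, float] = (15.0, 8.0)
    phenotype_label: str = "Non-darter-like"

    def __post_init__(self) -> None:
        for p in (self.p_freeze_per_cs, self.p_dart_per_cs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.phenotype_label not in ("Darter-like", "Non-darter-like"):
            raise ValueError("phenotype_label must be Darter-like or Non-darter-like")


def darter_like(**overrides) -> AnimalSimParams:
    """Parameters of a Darter-like animal (darts in most later trials)."""
    base = AnimalSimParams(p_dart_per_cs=0.6, phenotype_label="Darter-like")
    return replace(base, **overrides) if overrides else base


def non_darter_like(**overrides) -> AnimalSimParams:
    """Parameters of a Non-darter-like animal (never crosses dart threshold)."""
    base = AnimalSimParams(p_dart_per_cs=0.0, phenotype_label="Non-darter-like")
    return replace(base, **overrides) if overrides else base


def default_mixture(sex: str) -> list[tuple[float, AnimalSimParams]]:
    """Default phenotype mixture per sex: 29% Darter-like females, 0% males."""
    if sex == "female":
        return [
            (DARTER_RATE_FEMALE, darter_like()),
            (1.0 - DARTER_RATE_FEMALE, non_darter_like()),
        ]
    if sex == "male":
        return [(1.0, non_darter_like())]
    raise ValueError(f"unknown sex {sex!r}")


@dataclass(frozen=True)
class PlantedDart:
    trial_index: int
    onset: float
    offset: float
    peak: float  # max of the discretized pulse, hence exactly recoverable


@dataclass(frozen=True)
class PlantedFreeze:
    epoch: str
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class GroundTruthLog:
    """Everything the generator planted, for exact recovery checks."""

    phenotype_label: str
    darts: list[PlantedDart] = field(default_factory=list)
    freezes: list[PlantedFreeze] = field(default_factory=list)
    shock_peaks: list[tuple[int, float]] = field(default_factory=list)

    def cs_freeze_seconds(self, trial_index: int) -> float:
        return sum(
            f.duration for f in self.freezes if f.epoch == f"CS {trial_index}"
        )

    def baseline_freeze_seconds(self) -> float:
        return sum(f.duration for f in self.freezes if f.epoch == "baseline")

    @property
    def is_darter_like(self) -> bool:
        return self.phenotype_label == "Darter-like"


def _half_sine(n: int, amplitude: float) -> np.ndarray:
    # strictly interior sample phases: every sample is > 0, the center
    # sample(s) reach amplitude * sin(pi * k / (n + 1)) <= amplitude.
    k = np.arange(1, n + 1)
    return amplitude * np.sin(np.pi * k / (n + 1))


def _place_interval(
    rng: np.random.Generator,
    lo: float,
    hi: float,
    duration: float,
    occupied: list[tuple[float, float]],
    pad: float = 0.2,
    attempts: int = 100,
) -> float:
    """Uniformly place ``[onset, onset + duration)`` in [lo, hi] avoiding overlaps."""
    if hi - lo < duration:
        raise SimulationError(
            f"event of {duration:.2f} s cannot fit a {hi - lo:.2f} s window"
        )
    for _ in range(attempts):
        onset = rng.uniform(lo, hi - duration)
        if all(
            onset >= b + pad or onset + duration <= a - pad for a, b in occupied
        ):
            return onset
    raise SimulationError("could not place event after 100 attempts")


def simulate_animal(
    params: AnimalSimParams,
    design: SessionDesign,
    seed: int | np.random.SeedSequence,
    *,
    sampling_rate: float = 30.0,
    animal_id: str = "sim",
    session_label: str | None = None,
) -> tuple[VelocityTrace, GroundTruthLog]:
    """Simulate one animal-session; fully deterministic under ``seed``.

    The trace is baseline noise with planted freezing bouts (velocity
    drawn below ``freeze_speed_max``), half-sine dart pulses inside CS
    windows (ending well before shock onset so dart and shock excursions
    never merge), and half-sine shock pulses at shock onsets.  Ground
    truth records the discretized peak of every pulse, so a correct
    detector recovers the planted values exactly.
    """
    rng = np.random.default_rng(seed)
    n = int(round(design.total_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    v = np.clip(
        rng.normal(params.baseline_speed_mean, params.baseline_speed_sd, n), 0.0, None
    )
    truth = GroundTruthLog(phenotype_label=params.phenotype_label)

    shock_by_trial = dict(zip(design.shock_trial_indices(), design.shock_onsets))

    def seconds_to_slice(onset: float, duration: float) -> tuple[int, int]:
        i0 = int(np.floor(onset * sampling_rate + 1e-9))
        m = int(round(duration * sampling_rate))
        return i0, min(i0 + m, n)

    # -- freezing ------------------------------------------------------
    def plant_freeze(lo: float, hi: float, duration: float, epoch: str) -> None:
        onset = _place_interval(rng, lo, hi, duration, occupied=[])
        i0, i1 = seconds_to_slice(onset, duration)
        v[i0:i1] = rng.uniform(0.02, params.freeze_speed_max, i1 - i0)
        truth.freezes.append(
            PlantedFreeze(
                epoch=epoch,
                onset=i0 / sampling_rate,
                offset=i1 / sampling_rate,
            )
        )

    base_mean, base_sd = params.baseline_freeze_time
    if base_mean > 0:
        b0, b1 = design.baseline_window
        dur = float(np.clip(rng.normal(base_mean, base_sd), 0.0, (b1 - b0) - 2.0))
        if dur >= 1.5:
            plant_freeze(b0 + 0.5, b1 - 0.5, dur, "baseline")

    cs_windows = design.cs_windows()
    freeze_by_trial: dict[int, tuple[float, float]] = {}
    for k, (cs0, cs1) in enumerate(cs_windows, start=1):
        # keep clear of the shock pulse so planted bouts are not overwritten
        usable_end = min(cs1, shock_by_trial.get(k, cs1)) - 0.3
        if rng.random() < params.p_freeze_per_cs:
            mean, sd = params.freeze_bout_duration
            max_dur = (usable_end - cs0) - 2.5  # leave room for a dart pulse
            dur = float(np.clip(rng.normal(mean, sd), 1.5, max_dur))
            onset = _place_interval(rng, cs0 + 0.1, usable_end, dur, occupied=[])
            i0, i1 = seconds_to_slice(onset, dur)
            v[i0:i1] = rng.uniform(0.02, params.freeze_speed_max, i1 - i0)
            freeze_by_trial[k] = (i0 / sampling_rate, i1 / sampling_rate)
            truth.freezes.append(
                PlantedFreeze(
                    epoch=f"CS {k}",
                    onset=i0 / sampling_rate,
                    offset=i1 / sampling_rate,
                )
            )

    # -- darts ---------------------------------------------------------
    n_trials = design.n_trials
    dart_trials: list[int] = []
    if params.p_dart_per_cs > 0 and n_trials:
        mid = (n_trials + 1) / 2.0
        for k in range(1, n_trials + 1):
            p_k = params.p_dart_per_cs * (1.0 + params.dart_trial_slope * (k - mid))
            if rng.random() < float(np.clip(p_k, 0.0, 1.0)):
                dart_trials.append(k)
    eligible = [k for k in range(1, n_trials + 1) if k not in (1, 2)]
    if (
        params.phenotype_label == "Darter-like"
        and eligible
        and not any(k in eligible for k in dart_trials)
    ):
        dart_trials.append(int(rng.choice(eligible)))

    for k in sorted(set(dart_trials)):
        cs0, cs1 = cs_windows[k - 1]
        # end at least 0.5 s before shock onset so the dart run can never
        # merge (gap rule) with the shock-evoked excursion
        hi = min(cs1 - 0.2, shock_by_trial.get(k, np.inf) - 0.5)
        dur = rng.uniform(*params.dart_duration)
        amp = rng.uniform(*params.dart_amplitude)
        occupied = [freeze_by_trial[k]] if k in freeze_by_trial else []
        try:
            onset = _place_interval(rng, cs0 + 0.1, hi, dur, occupied)
        except SimulationError:
            continue  # pathological custom window; skip rather than abort
        i0, i1 = seconds_to_slice(onset, dur)
        pulse = _half_sine(i1 - i0, amp)
        v[i0:i1] = np.maximum(v[i0:i1], pulse)
        truth.darts.append(
            PlantedDart(
                trial_index=k,
                onset=i0 / sampling_rate,
                offset=i1 / sampling_rate,
                peak=float(pulse.max()),
            )
        )

    # -- shock responses ----------------------------------------------
    for trial, onset in zip(design.shock_trial_indices(), design.shock_onsets):
        amp = rng.uniform(*params.shock_peak)
        i0, i1 = seconds_to_slice(onset, params.shock_pulse_duration)
        pulse = _half_sine(i1 - i0, amp)
        v[i0:i1] = np.maximum(v[i0:i1], pulse)
        truth.shock_peaks.append((trial, float(pulse.max())))

    trace = VelocityTrace(
        animal_id=animal_id,
        sampling_rate=sampling_rate,
        time=t,
        velocity=v,
        session_label=session_label
        if session_label is not None
        else design.session_type,
    )
    return trace, truth


@dataclass(frozen=True)
class GroupSpec:
    """One simulated group: sex, treatment, size and phenotype mixture."""

    sex: str
    treatment: str
    n: int
    mixture: Sequence[tuple[float, AnimalSimParams]] | None = None

    def resolved_mixture(self) -> list[tuple[float, AnimalSimParams]]:
        mix = list(self.mixture) if self.mixture is not None else default_mixture(self.sex)
        total = sum(w for w, _ in mix)
        if not np.isclose(total, 1.0):
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        return mix


@dataclass
class Cohort:
    """A simulated cohort: records, traces and per-animal ground truth."""

    design: SessionDesign
    records: list[AnimalRecord]
    traces: dict[str, VelocityTrace]
    truths: dict[str, GroundTruthLog]

    def __len__(self) -> int:
        return len(self.records)


def assign_cohort_params(
    group_specs: Sequence[GroupSpec], seed: int
) -> list[tuple[AnimalRecord, AnimalSimParams]]:
    """Draw per-animal phenotype parameters from each group's mixture.

    The assignment is deterministic under ``seed`` and independent of how
    many sessions are later simulated, so the same animal keeps the same
    phenotype across sessions.
    """
    if not group_specs:
        raise ValueError("group_specs must contain at least one group")
    for spec in group_specs:
        if spec.n < 1:
            raise ValueError("each group must have n >= 1")
    assign_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    out: list[tuple[AnimalRecord, AnimalSimParams]] = []
    for spec in group_specs:
        mix = spec.resolved_mixture()
        weights = np.array([w for w, _ in mix])
        for i in range(spec.n):
            animal_id = f"{spec.sex}_{spec.treatment}_{i:03d}".replace("+", "")
            params = mix[assign_rng.choice(len(mix), p=weights)][1]
            out.append(
                (
                    AnimalRecord(
                        animal_id=animal_id, sex=spec.sex, treatment=spec.treatment
                    ),
                    params,
                )
            )
    return out


def simulate_cohort(
    group_specs: Sequence[GroupSpec],
    design: SessionDesign,
    seed: int,
    *,
    sampling_rate: float = 30.0,
    assignments: Sequence[tuple[AnimalRecord, AnimalSimParams]] | None = None,
) -> Cohort:
    """Simulate a full cohort; per-animal seeds derive from the cohort seed.

    Phenotype parameters are drawn per animal from the group's mixture
    (defaulting to 29% Darter-like for females, 0% for males) unless a
    precomputed ``assignments`` list (from :func:`assign_cohort_params`)
    is supplied, in which case those identities are reused.
    """
    if assignments is None:
        assignments = assign_cohort_params(group_specs, seed)
    root = np.random.SeedSequence(seed)
    records: list[AnimalRecord] = []
    traces: dict[str, VelocityTrace] = {}
    truths: dict[str, GroundTruthLog] = {}
    child_seeds = iter(root.spawn(1 + len(assignments))[1:])
    for record, params in assignments:
        trace, truth = simulate_animal(
            params,
            design,
            next(child_seeds),
            sampling_rate=sampling_rate,
            animal_id=record.animal_id,
        )
        records.append(record)
        traces[record.animal_id] = trace
        truths[record.animal_id] = truth
    return Cohort(design=design, records=records, traces=traces, truths=truths)
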