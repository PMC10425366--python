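"""Event detection and phenotype classification from epoched velocity traces.

Three defensive behaviors are scored from the speed series:

* **Darting** — a discrete locomotor movement reaching at least 20 cm/s
  during a CS presentation.  An animal showing at least one dart outside
  trials 1-2 of the conditioning session is classified a **Darter**.
* **Freezing** — cessation of movement, operationalized as velocity below a
  small threshold for at least 1 s.
* **Shock response** — the maximum velocity within 5 s of shock delivery,
  inclusive of the delivery itself.

A "discrete movement" is operationalized as a maximal supra-threshold run
of samples; runs separated by less than a short merge gap are fused so a
single lunge interrupted by one noisy sample is not double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .behavior_io import EpochedSession, VelocityTrace
from .errors import DesignError

__all__ = [
    "ScoringParams",
    "DartEvent",
    "FreezingBout",
    "TrialSummary",
    "detect_darts",
    "classify_darter",
    "shock_response",
    "detect_freezing",
    "summarize_session",
    "block_average",
]


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds and conventions for behavioral scoring.

    Attributes
    ----------
    dart_threshold
        Minimum velocity (cm/s) for a dart; 20 cm/s in the standard
        operational definition.
    dart_merge_gap
        Sub-threshold gaps shorter than this (s) are merged into one event.
    dart_min_duration
        Events shorter than this (s) are discarded.  The default of 0
        keeps every supra-threshold run down to a single sample.
    freeze_velocity_threshold
        Velocity (cm/s) below which the animal counts as immobile.  The
        operational definition of freezing is behavioral; this numeric
        cut-off is a scoring convention and should be calibrated to the
        tracking setup.
    freeze_min_bout
        Minimum immobility duration (s) for a freezing bout (1 s standard).
    shock_response_window
        Window length (s) after shock onset over which the response
        maximum is taken (5 s standard).
    shock_instantaneous
        If True, report velocity at the shock-onset sample instead of the
        5-s window maximum.
    darter_excluded_trials
        1-based conditioning trials whose darts do not confer Darter
        status (trials 1-2 standard: early-trial excursions are treated
        as shock-reactivity carryover, not conditioned darting).
    classification_session
        Session type whose darts drive the Darter/Non-darter call.
    exclude_shock_period_from_darts
        If True (default), the dart search window of a trial ends at shock
        onset so the shock-evoked burst is never scored as a dart.
    """

    dart_threshold: float = 20.0
    dart_merge_gap: float = 0.3
    dart_min_duration: float = 0.0
    freeze_velocity_threshold: float = 0.5
    freeze_min_bout: float = 1.0
    shock_response_window: float = 5.0
    shock_instantaneous: bool = False
    darter_excluded_trials: frozenset[int] = frozenset({1, 2})
    classification_session: str = "conditioning"
    exclude_shock_period_from_darts: bool = True

    def __post_init__(self) -> None:
        for name in (
            "dart_threshold",
            "dart_merge_gap",
            "freeze_velocity_threshold",
            "freeze_min_bout",
            "shock_response_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dart_min_duration < 0:
            raise ValueError("dart_min_duration must be >= 0")
        object.__setattr__(
            self, "darter_excluded_trials", frozenset(self.darter_excluded_trials)
        )


@dataclass(frozen=True)
class DartEvent:
    """One detected dart, attributed to a 1-based CS trial."""

    trial_index: int
    onset: float
    offset: float
    peak_velocity: float


@dataclass(frozen=True)
class FreezingBout:
    """One detected immobility bout (or the piece of one inside an epoch)."""

    onset: float
    offset: float
    epoch: str

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial scored measures; the trial-0 row carries session-level values."""

    trial_index: int
    percent_freezing_cs: float | None = None
    dart_count: int | None = None
    shock_response: float | None = None
    baseline_percent_freezing: float | None = None


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as half-open index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _merged_runs(
    mask: np.ndarray, max_gap_samples: float
) -> list[tuple[int, int]]:
    """Maximal runs with sub-threshold gaps shorter than ``max_gap_samples`` fused."""
    runs = _runs(mask)
    if not runs:
        return []
    merged = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap_samples:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [(a, b) for a, b in merged]


def detect_darts(
    epoched: EpochedSession, params: ScoringParams = ScoringParams()
) -> list[DartEvent]:
    """Detect darts: supra-threshold excursions whose onset falls in a CS.

    Candidate events are maximal runs of samples with velocity at or above
    ``dart_threshold`` over the whole trace, with near-contiguous runs
    merged (gap < ``dart_merge_gap``) and runs shorter than
    ``dart_min_duration`` discarded.  A candidate becomes a
    :class:`DartEvent` only if its onset lies inside a CS window; an
    excursion straddling the CS offset is kept but clipped to the window.
    With ``exclude_shock_period_from_darts`` the per-trial search window
    ends at shock onset, so the shock-evoked velocity burst of a
    conditioning trial is never reported as a dart.
    """
    trace = epoched.trace
    rate = trace.sampling_rate
    v = trace.velocity
    mask = v >= params.dart_threshold
    gap_samples = params.dart_merge_gap * rate
    candidates = _merged_runs(mask, gap_samples)
    min_samples = params.dart_min_duration * rate
    candidates = [(a, b) for a, b in candidates if (b - a) >= min_samples]

    shock_by_trial: dict[int, int] = {}
    if params.exclude_shock_period_from_darts and epoched.shock_onset_idx:
        for trial, s_idx in zip(
            epoched.design.shock_trial_indices(), epoched.shock_onset_idx
        ):
            shock_by_trial[trial] = s_idx

    events: list[DartEvent] = []
    for start, stop in candidates:
        for trial, (cs0, cs1) in enumerate(epoched.cs, start=1):
            search_end = min(cs1, shock_by_trial.get(trial, cs1))
            if cs0 <= start < search_end:
                clipped_stop = min(stop, search_end)
                peak = float(np.max(v[start:clipped_stop]))
                events.append(
                    DartEvent(
                        trial_index=trial,
                        onset=start / rate,
                        offset=clipped_stop / rate,
                        peak_velocity=peak,
                    )
                )
                break
    return events


def classify_darter(
    darts: Iterable[DartEvent], params: ScoringParams = ScoringParams()
) -> str:
    """Classify Darter vs Non-darter from one session's dart events.

    An animal is a Darter iff it shows at least one dart on a trial not in
    ``darter_excluded_trials`` (trials 1-2 by default).
    """
    for d in darts:
        if d.trial_index not in params.darter_excluded_trials:
            return "Darter"
    return "Non-darter"


def shock_response(
    epoched: EpochedSession, params: ScoringParams = ScoringParams()
) -> np.ndarray:
    """Per-shock response: max velocity within the post-delivery window.

    Returns one value per shock (cm/s), ordered by shock onset.  The
    window is ``[shock_onset, shock_onset + shock_response_window)``,
    inclusive of the delivery itself.  With ``shock_instantaneous`` the
    value is instead the velocity at the shock-onset sample.
    """
    if len(epoched.shock_onset_idx) == 0:
        raise DesignError("shock_response called on a shock-free session design")
    v = epoched.trace.velocity
    rate = epoched.sampling_rate
    out = []
    win = int(np.floor(params.shock_response_window * rate + 1e-9))
    for s_idx in epoched.shock_onset_idx:
        if params.shock_instantaneous:
            out.append(float(v[s_idx]))
        else:
            out.append(float(np.max(v[s_idx : min(s_idx + win, len(v))])))
    return np.array(out)


def _epoch_windows(epoched: EpochedSession) -> list[tuple[str, int, int]]:
    wins: list[tuple[str, int, int]] = [("baseline", *epoched.baseline)]
    for k, (a, b) in enumerate(epoched.cs, start=1):
        wins.append((f"CS {k}", a, b))
    for k, (a, b) in enumerate(epoched.iti, start=1):
        wins.append((f"ITI {k}", a, b))
    return wins


def detect_freezing(
    trace: VelocityTrace,
    epoched: EpochedSession,
    params: ScoringParams = ScoringParams(),
) -> list[FreezingBout]:
    """Detect freezing bouts and attribute them to session epochs.

    A bout is a maximal run of samples with velocity below
    ``freeze_velocity_threshold`` lasting at least ``freeze_min_bout``.
    The minimum-duration rule applies to the whole bout; bouts are then
    split at epoch boundaries so per-epoch freezing times sum correctly,
    e.g. a bout spanning a CS offset contributes only its in-CS portion
    to that trial's CS freezing.
    """
    rate = trace.sampling_rate
    mask = trace.velocity < params.freeze_velocity_threshold
    min_samples = params.freeze_min_bout * rate
    bouts = [(a, b) for a, b in _runs(mask) if (b - a) >= min_samples - 1e-9]
    pieces: list[FreezingBout] = []
    windows = _epoch_windows(epoched)
    for a, b in bouts:
        for label, w0, w1 in windows:
            lo, hi = max(a, w0), min(b, w1)
            if hi > lo:
                pieces.append(
                    FreezingBout(onset=lo / rate, offset=hi / rate, epoch=label)
                )
    return pieces


def summarize_session(
    trace: VelocityTrace,
    epoched: EpochedSession,
    darts: Sequence[DartEvent],
    bouts: Sequence[FreezingBout],
    params: ScoringParams = ScoringParams(),
) -> list[TrialSummary]:
    """Summarize one animal-session into per-trial scored measures.

    Row 0 carries the session-level baseline freezing percent; rows 1..T
    carry CS freezing percent, dart count, and (for designs with shocks)
    the shock response of that trial.
    """
    design = epoched.design
    rate = trace.sampling_rate
    freeze_by_epoch: dict[str, float] = {}
    for b in bouts:
        freeze_by_epoch[b.epoch] = freeze_by_epoch.get(b.epoch, 0.0) + b.duration
    base_dur = (epoched.baseline[1] - epoched.baseline[0]) / rate
    baseline_pct = (
        100.0 * freeze_by_epoch.get("baseline", 0.0) / base_dur if base_dur > 0 else 0.0
    )
    summaries = [
        TrialSummary(trial_index=0, baseline_percent_freezing=baseline_pct)
    ]
    shocks = (
        shock_response(epoched, params) if len(epoched.shock_onset_idx) else None
    )
    shock_trials = design.shock_trial_indices() if shocks is not None else []
    dart_counts: dict[int, int] = {}
    for d in darts:
        dart_counts[d.trial_index] = dart_counts.get(d.trial_index, 0) + 1
    for k in range(1, design.n_trials + 1):
        cs_pct = 100.0 * freeze_by_epoch.get(f"CS {k}", 0.0) / design.cs_duration
        resp = None
        if shocks is not None and k in shock_trials:
            resp = float(shocks[shock_trials.index(k)])
        summaries.append(
            TrialSummary(
                trial_index=k,
                percent_freezing_cs=min(cs_pct, 100.0),
                dart_count=dart_counts.get(k, 0),
                shock_response=resp,
            )
        )
    return summaries


def block_average(
    summaries: Sequence[TrialSummary], block_size: int
) -> list[tuple[int, float]]:
    """Average per-trial CS freezing into consecutive blocks of ``block_size``.

    Returns ``(block_index, mean_percent)`` pairs (1-based blocks).  Used
    to reduce e.g. 20 extinction trials to 10 two-trial block means for
    repeated-measures analysis.
    """
    trials = [s for s in summaries if s.trial_index >= 1]
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    out = []
    for i in range(0, len(trials), block_size):
        chunk = [
            s.percent_freezing_cs
            for s in trials[i : i + block_size]
            if s.percent_freezing_cs is not None
        ]
        if chunk:
            out.append((i // block_size + 1, float(np.mean(chunk))))
    return out
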