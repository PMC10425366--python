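"""Session/trace data model and I/O for video-tracking velocity exports.

The behavioral unit of analysis is a per-animal velocity time series
(cm/s, uniformly sampled) recorded while the animal experiences a timed
session of tone (CS) presentations, optionally coterminating footshocks,
and inter-trial intervals.  This module holds the containers for those
two pieces of information (:class:`VelocityTrace`, :class:`SessionDesign`),
the mapping between them (:func:`epoch_trace`), and the flat-file readers
and writers used by every downstream stage.

All detectors downstream operate in seconds; sample indices appear only
inside :class:`EpochedSession`.  Intervals are half-open ``[on, off)``
with 0-based sample indexing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataQualityError,
    DesignError,
    EpochingError,
    TraceParseError,
    TraceValidationError,
)

logger = logging.getLogger(__name__)

#: Number of CS presentations per session type in the standard protocol.
SESSION_CS_COUNTS: Mapping[str, int] = {
    "habituation": 0,
    "conditioning": 7,
    "extinction": 20,
    "retrieval": 5,
}

SESSION_TYPES = tuple(SESSION_CS_COUNTS)

#: Required column names in velocity exports.
TIME_COLUMN = "time_s"
VELOCITY_COLUMN = "velocity_cm_s"

#: Largest tracking dropout (s) that is silently repaired by linear
#: interpolation; anything longer raises :class:`DataQualityError`.
MAX_INTERPOLATED_GAP_S = 0.5


@dataclass(frozen=True)
class VelocityTrace:
    """A uniformly sampled per-animal speed series.

    Parameters
    ----------
    animal_id
        Identifier of the animal the trace belongs to.
    sampling_rate
        Samples per second (Hz).
    time
        Sample times in seconds, strictly increasing and uniformly spaced.
    velocity
        Speed in cm/s, non-negative everywhere.
    session_label
        Free-text session tag (e.g. ``"conditioning"``).
    """

    animal_id: str
    sampling_rate: float
    time: np.ndarray
    velocity: np.ndarray
    session_label: str = ""

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        velocity = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "velocity", velocity)
        if time.ndim != 1 or velocity.ndim != 1 or len(time) != len(velocity):
            raise TraceValidationError(
                "time and velocity must be 1-D vectors of equal length"
            )
        if len(time) >= 2:
            dt = np.diff(time)
            if np.any(dt <= 0):
                raise TraceValidationError("time must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-6:
                raise TraceValidationError(
                    "time must be uniformly spaced at 1/sampling_rate to 1e-6 s"
                )
        if np.any(velocity < 0):
            raise TraceValidationError("velocity must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Trace duration in seconds (number of samples / rate)."""
        return len(self.time) / self.sampling_rate


@dataclass(frozen=True)
class SessionDesign:
    """Timed layout of baseline, CS, shock and ITI windows for one session.

    ``baseline_window`` spans session start to first CS onset; the standard
    protocol uses a lead-in of one ITI (180 s).
    """

    session_type: str
    cs_onsets: np.ndarray
    cs_duration: float
    shock_onsets: np.ndarray
    shock_duration: float
    iti: float
    baseline_window: tuple[float, float]
    total_duration: float

    def __post_init__(self) -> None:
        cs = np.asarray(self.cs_onsets, dtype=float)
        sh = np.asarray(self.shock_onsets, dtype=float)
        object.__setattr__(self, "cs_onsets", cs)
        object.__setattr__(self, "shock_onsets", sh)
        if self.session_type not in SESSION_TYPES:
            raise DesignError(f"unknown session_type {self.session_type!r}")
        if len(cs) >= 2:
            if np.any(np.diff(cs) <= 0):
                raise DesignError("CS onsets must be strictly increasing")
            if np.any(np.diff(cs) < self.cs_duration):
                raise DesignError("CS windows overlap")
        for onset in sh:
            inside = np.any(
                (cs <= onset) & (onset + self.shock_duration <= cs + self.cs_duration)
            )
            if not inside:
                raise DesignError(f"shock at {onset} s lies outside every CS window")
        if len(cs) and cs[-1] + self.cs_duration > self.total_duration:
            raise DesignError("total_duration shorter than last CS offset")

    @property
    def n_trials(self) -> int:
        return len(self.cs_onsets)

    def cs_windows(self) -> list[tuple[float, float]]:
        """Per-trial ``(onset, offset)`` in seconds, half-open."""
        return [(on, on + self.cs_duration) for on in self.cs_onsets]

    def iti_windows(self) -> list[tuple[float, float]]:
        """Window following each CS, up to the next CS onset (or session end)."""
        wins = []
        for k, (_, off) in enumerate(self.cs_windows()):
            nxt = (
                self.cs_onsets[k + 1]
                if k + 1 < self.n_trials
                else self.total_duration
            )
            wins.append((off, float(nxt)))
        return wins

    def shock_trial_indices(self) -> list[int]:
        """1-based CS trial index containing each shock."""
        idx = []
        for onset in self.shock_onsets:
            k = int(np.searchsorted(self.cs_onsets, onset, side="right"))
            idx.append(k)
        return idx

    def to_json(self, path: str | Path) -> None:
        payload = {
            "session_type": self.session_type,
            "cs_onsets": self.cs_onsets.tolist(),
            "cs_duration": self.cs_duration,
            "shock_onsets": self.shock_onsets.tolist(),
            "shock_duration": self.shock_duration,
            "iti": self.iti,
            "baseline_window": list(self.baseline_window),
            "total_duration": self.total_duration,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionDesign":
        payload = json.loads(Path(path).read_text())
        payload["baseline_window"] = tuple(payload["baseline_window"])
        return cls(**payload)


def build_session_design(
    session_type: str,
    *,
    cs_duration: float = 30.0,
    iti: float = 180.0,
    lead_in: float = 180.0,
    shock_duration: float = 1.0,
    n_cs: int | None = None,
    habituation_duration: float = 600.0,
) -> SessionDesign:
    """Construct the standard-protocol design for one session type.

    Defaults reproduce the published protocol: 30-s CS, 180-s ITIs, a
    lead-in of one ITI before the first CS, and (for conditioning) a 1-s
    shock coterminating with each CS.  CS *k* (1-based) therefore starts at
    ``lead_in + (k - 1) * (cs_duration + iti)`` seconds.

    Parameters may be overridden; overrides that produce overlapping CS
    windows raise :class:`DesignError`.
    """
    if session_type not in SESSION_TYPES:
        raise DesignError(f"unknown session_type {session_type!r}")
    count = SESSION_CS_COUNTS[session_type] if n_cs is None else int(n_cs)
    if count == 0:
        return SessionDesign(
            session_type=session_type,
            cs_onsets=np.array([]),
            cs_duration=cs_duration,
            shock_onsets=np.array([]),
            shock_duration=shock_duration,
            iti=iti,
            baseline_window=(0.0, habituation_duration),
            total_duration=habituation_duration,
        )
    onsets = lead_in + np.arange(count) * (cs_duration + iti)
    if session_type == "conditioning":
        # shock coterminates with the CS: it occupies the last shock_duration
        # seconds of each tone.
        shocks = onsets + cs_duration - shock_duration
    else:
        shocks = np.array([])
    total = float(onsets[-1] + cs_duration + iti)
    return SessionDesign(
        session_type=session_type,
        cs_onsets=onsets,
        cs_duration=cs_duration,
        shock_onsets=shocks,
        shock_duration=shock_duration,
        iti=iti,
        baseline_window=(0.0, float(onsets[0])),
        total_duration=total,
    )


@dataclass(frozen=True)
class EpochedSession:
    """Sample-index windows of one trace against one design.

    All windows are half-open ``[start, stop)`` sample-index pairs obtained
    as ``floor(onset * rate) .. floor(offset * rate)``.
    """

    trace: VelocityTrace
    design: SessionDesign
    baseline: tuple[int, int]
    cs: list[tuple[int, int]] = field(default_factory=list)
    iti: list[tuple[int, int]] = field(default_factory=list)
    shock_onset_idx: list[int] = field(default_factory=list)

    @property
    def sampling_rate(self) -> float:
        return self.trace.sampling_rate


def _to_idx(t: float, rate: float) -> int:
    # guard against float fuzz like 5400.0000000001 -> 5401
    return int(np.floor(t * rate + 1e-9))


def epoch_trace(trace: VelocityTrace, design: SessionDesign) -> EpochedSession:
    """Map a design's second-domain windows onto a trace's sample grid."""
    rate = trace.sampling_rate
    last_needed = (
        design.cs_onsets[-1] + design.cs_duration
        if design.n_trials
        else design.baseline_window[1]
    )
    if trace.duration + 1e-9 < last_needed:
        raise EpochingError(
            f"trace of {trace.duration:.1f} s shorter than design requiring "
            f"{last_needed:.1f} s"
        )
    n = len(trace)
    clamp = lambda i: min(i, n)
    baseline = (
        _to_idx(design.baseline_window[0], rate),
        clamp(_to_idx(design.baseline_window[1], rate)),
    )
    cs = [
        (_to_idx(on, rate), clamp(_to_idx(off, rate)))
        for on, off in design.cs_windows()
    ]
    iti = [
        (_to_idx(on, rate), clamp(_to_idx(off, rate)))
        for on, off in design.iti_windows()
    ]
    shock_idx = [_to_idx(on, rate) for on in design.shock_onsets]
    return EpochedSession(
        trace=trace,
        design=design,
        baseline=baseline,
        cs=cs,
        iti=iti,
        shock_onset_idx=shock_idx,
    )


@dataclass
class AnimalRecord:
    """Identity, group membership and (post-classification) phenotype."""

    animal_id: str
    sex: str
    treatment: str
    phenotype: str = "unassigned"

    VALID_SEX = ("male", "female")
    VALID_TREATMENT = ("VEH", "AM", "CPZ", "AM+CPZ")
    VALID_PHENOTYPE = ("Darter", "Non-darter", "unassigned")

    def __post_init__(self) -> None:
        if self.sex not in self.VALID_SEX:
            raise ValueError(f"sex must be one of {self.VALID_SEX}")
        if self.treatment not in self.VALID_TREATMENT:
            raise ValueError(f"treatment must be one of {self.VALID_TREATMENT}")
        if self.phenotype not in self.VALID_PHENOTYPE:
            raise ValueError(f"phenotype must be one of {self.VALID_PHENOTYPE}")


def read_velocity_trace(
    path: str | Path,
    sampling_rate: float = 30.0,
    *,
    animal_id: str | None = None,
    session_label: str = "",
) -> VelocityTrace:
    """Read a delimited velocity export into a validated trace.

    The file must contain a header naming columns ``time_s`` and
    ``velocity_cm_s``; the delimiter (comma or tab) is autodetected.
    Tracking dropouts (missing samples) are repaired by linear
    interpolation when the gap is at most 0.5 s and rejected otherwise.

    Raises
    ------
    TraceParseError
        Missing columns, non-monotonic time, or sampling inconsistent with
        ``sampling_rate``.
    TraceValidationError
        Negative velocity values.
    DataQualityError
        A dropout longer than 0.5 s.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceParseError(f"could not parse {path}: {exc}") from exc
    for col in (TIME_COLUMN, VELOCITY_COLUMN):
        if col not in df.columns:
            raise TraceParseError(
                f"{path} lacks required column {col!r} (found {list(df.columns)})"
            )
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    v = df[VELOCITY_COLUMN].to_numpy(dtype=float)
    if len(t) == 0:
        raise TraceParseError(f"{path} contains no samples")
    if np.any(np.diff(t) <= 0):
        raise TraceParseError(f"{path}: time column is not strictly increasing")
    if np.any(v < 0):
        raise TraceValidationError(f"{path}: negative velocity values present")
    dt = 1.0 / sampling_rate
    gaps = np.diff(t)
    if len(gaps) and abs(np.min(gaps) - dt) > 1e-3 * dt:
        raise TraceParseError(
            f"{path}: sample spacing {np.min(gaps):.6f} s inconsistent with "
            f"sampling_rate {sampling_rate} Hz"
        )
    worst = float(np.max(gaps)) if len(gaps) else dt
    if worst > MAX_INTERPOLATED_GAP_S + dt / 2:
        raise DataQualityError(
            f"{path}: dropout of {worst:.3f} s exceeds the "
            f"{MAX_INTERPOLATED_GAP_S} s interpolation limit"
        )
    n_expected = int(round((t[-1] - t[0]) / dt)) + 1
    if n_expected != len(t):
        grid = t[0] + np.arange(n_expected) * dt
        v = np.interp(grid, t, v)
        logger.warning(
            "%s: interpolated %d missing sample(s)", path, n_expected - len(t)
        )
        t = grid
    else:
        # snap to an exact uniform grid so the trace invariant holds
        t = t[0] + np.arange(len(t)) * dt
    return VelocityTrace(
        animal_id=animal_id if animal_id is not None else path.stem,
        sampling_rate=sampling_rate,
        time=t,
        velocity=v,
        session_label=session_label,
    )


def write_velocity_trace(trace: VelocityTrace, path: str | Path) -> None:
    """Write a trace in the same two-column delimited format the reader accepts."""
    pd.DataFrame({TIME_COLUMN: trace.time, VELOCITY_COLUMN: trace.velocity}).to_csv(
        path, index=False
    )


def write_trial_table(
    summaries: Mapping[str, Sequence],
    path: str | Path,
) -> None:
    """Write tidy long-format trial summaries: one row per animal x trial x measure.

    ``summaries`` maps animal id to a sequence of
    :class:`~fearframe.behavior_scoring.TrialSummary`.  The table
    round-trips losslessly through :func:`read_trial_table`.
    """
    rows = []
    for animal_id, trial_summaries in summaries.items():
        for s in trial_summaries:
            for measure in (
                "percent_freezing_cs",
                "dart_count",
                "shock_response",
                "baseline_percent_freezing",
            ):
                value = getattr(s, measure)
                if value is None:
                    continue
                rows.append(
                    {
                        "animal_id": animal_id,
                        "trial_index": s.trial_index,
                        "measure": measure,
                        "value": float(value),
                    }
                )
    df = pd.DataFrame(rows, columns=["animal_id", "trial_index", "measure", "value"])
    df.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy trial table written by :func:`write_trial_table`."""
    return pd.read_csv(
        path,
        dtype={"animal_id": str, "trial_index": int, "measure": str, "value": float},
    )
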