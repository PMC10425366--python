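"""End-to-end orchestration: simulate -> score -> classify -> aggregate -> test.

The two entry points mirror the study's two arms:

* :func:`run_behavior_pipeline` simulates (or accepts) a cohort, scores
  conditioning and extinction sessions per animal, classifies the Darter
  phenotype, and runs the group statistics: a chi-square of Darter
  proportions across treatments, per-phenotype mixed ANOVAs of shock
  response and CS freezing (treatment x trial), and a one-way ANOVA with
  Dunnett post hocs on extinction-day baseline freezing (the contextual
  generalization readout).
* :func:`run_imaging_pipeline` simulates per-animal section images and
  per-cell z-stacks, quantifies labeled-cell density and perisomatic
  donut density, and runs the corresponding tests: Welch's t of
  cell density by sex and a mixed ANOVA of normalized perisomatic
  density (sex between x circuit label within).

Stages communicate through plain files when an output directory is
given (tidy CSV + JSON manifest carrying the config hash and seed), so
each stage is independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior_io, behavior_scoring, group_stats, image_quant
from .behavior_scoring import ScoringParams
from .synthetic_behavior import (
    Cohort,
    GroupSpec,
    assign_cohort_params,
    simulate_cohort,
)
from .synthetic_imaging import (
    SectionSimParams,
    StackSimParams,
    simulate_cell_stack,
    simulate_section,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviorConfig",
    "ImagingConfig",
    "RunConfig",
    "BehaviorResults",
    "ImagingResults",
    "run_behavior_pipeline",
    "run_imaging_pipeline",
    "score_cohort",
]

TREATMENTS = ("VEH", "AM", "CPZ", "AM+CPZ")


@dataclass(frozen=True)
class BehaviorConfig:
    """Cohort layout and scoring configuration for the behavioral arm."""

    n_per_group: int = 12
    treatments: tuple[str, ...] = TREATMENTS
    sexes: tuple[str, ...] = ("female", "male")
    sessions: tuple[str, ...] = ("conditioning", "extinction")
    scoring: ScoringParams = ScoringParams()
    extinction_block_size: int = 2
    sampling_rate: float = 30.0
    #: optional per-(sex, treatment) mixture override
    mixtures: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ImagingConfig:
    """Cohort layout for the imaging arm."""

    n_animals_per_sex: int = 8
    sections_per_animal: int = 4
    cells_per_label: int = 4
    section_params: SectionSimParams = SectionSimParams()
    stack_params: StackSimParams = StackSimParams()
    #: multiplier on section cell density for females (sex dimorphism)
    female_density_factor: float = 2.0
    donut_width_um: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    behavior: BehaviorConfig = BehaviorConfig()
    imaging: ImagingConfig = ImagingConfig()
    out_dir: str | None = None


@dataclass
class BehaviorResults:
    animals: pd.DataFrame
    trial_table: pd.DataFrame
    darter_chi_square: group_stats.StatResult | None
    anovas: dict
    baseline_generalization: dict


@dataclass
class ImagingResults:
    per_cell: pd.DataFrame
    per_animal_density: pd.DataFrame
    per_animal_counts: pd.DataFrame
    circuit_anova: list
    density_welch: group_stats.StatResult


def _config_hash(config) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(map(str, o))
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def score_cohort(
    cohort: Cohort, scoring: ScoringParams = ScoringParams()
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Score every trace of a cohort; return the tidy trial table and events.

    Classification is applied when (and only when) the cohort's session
    matches ``scoring.classification_session``, updating the records'
    phenotype in place.
    """
    design = cohort.design
    rows = []
    events: dict[str, list] = {}
    classify = design.session_type == scoring.classification_session
    for rec in cohort.records:
        trace = cohort.traces[rec.animal_id]
        epoched = behavior_io.epoch_trace(trace, design)
        darts = behavior_scoring.detect_darts(epoched, scoring)
        bouts = behavior_scoring.detect_freezing(trace, epoched, scoring)
        summaries = behavior_scoring.summarize_session(
            trace, epoched, darts, bouts, scoring
        )
        events[rec.animal_id] = darts
        if classify:
            rec.phenotype = behavior_scoring.classify_darter(darts, scoring)
        for s in summaries:
            for measure in (
                "percent_freezing_cs",
                "dart_count",
                "shock_response",
                "baseline_percent_freezing",
            ):
                value = getattr(s, measure)
                if value is not None:
                    rows.append(
                        {
                            "animal_id": rec.animal_id,
                            "sex": rec.sex,
                            "treatment": rec.treatment,
                            "session": design.session_type,
                            "trial_index": s.trial_index,
                            "measure": measure,
                            "value": float(value),
                        }
                    )
    return pd.DataFrame(rows), events


def run_behavior_pipeline(config: RunConfig) -> BehaviorResults:
    """Simulate and analyze the behavioral arm end to end."""
    bc = config.behavior
    if not bc.treatments or not bc.sexes or bc.n_per_group < 1:
        raise ValueError("behavior config describes an empty cohort")
    root = np.random.SeedSequence(config.seed)
    session_seeds = dict(zip(bc.sessions, root.spawn(len(bc.sessions))))

    specs = []
    for sex in bc.sexes:
        for trt in bc.treatments:
            mixture = bc.mixtures.get((sex, trt))
            specs.append(GroupSpec(sex=sex, treatment=trt, n=bc.n_per_group, mixture=mixture))

    # one phenotype draw per animal, shared by every session
    assignments = assign_cohort_params(specs, config.seed)

    tables = []
    animals_df = None
    for session in bc.sessions:
        design = behavior_io.build_session_design(session)
        # fresh noise per session, same animal identities
        seed_int = int(session_seeds[session].generate_state(1)[0] % (2**31))
        cohort = simulate_cohort(
            specs,
            design,
            seed_int,
            sampling_rate=bc.sampling_rate,
            assignments=assignments,
        )
        table, _ = score_cohort(cohort, bc.scoring)
        tables.append(table)
        if session == bc.scoring.classification_session:
            animals_df = pd.DataFrame(
                [
                    {
                        "animal_id": r.animal_id,
                        "sex": r.sex,
                        "treatment": r.treatment,
                        "phenotype": r.phenotype,
                        "planted_phenotype": cohort.truths[r.animal_id].phenotype_label,
                    }
                    for r in cohort.records
                ]
            )
    trial_table = pd.concat(tables, ignore_index=True)
    if animals_df is None:
        raise ValueError(
            "classification session missing from config.behavior.sessions"
        )

    # --- Darter proportion homogeneity across treatments (females) -----
    females = animals_df[animals_df["sex"] == "female"]
    chi = None
    if len(bc.treatments) >= 2 and not females.empty:
        counts = []
        for trt in bc.treatments:
            grp = females[females["treatment"] == trt]
            n_dart = int((grp["phenotype"] == "Darter").sum())
            counts.append([n_dart, len(grp) - n_dart])
        table = np.array(counts).T  # 2 x treatments
        try:
            chi = group_stats.chi_square_homogeneity(table)
        except ValueError:
            logger.warning("degenerate Darter table; chi-square skipped")

    # --- per-phenotype ANOVAs ------------------------------------------
    merged = trial_table.merge(
        animals_df[["animal_id", "phenotype"]], on="animal_id"
    )
    cohorts = {
        "female Non-darters": (merged["sex"] == "female")
        & (merged["phenotype"] == "Non-darter"),
        "female Darters": (merged["sex"] == "female")
        & (merged["phenotype"] == "Darter"),
        "males": merged["sex"] == "male",
    }
    anovas: dict = {}
    for name, sel in cohorts.items():
        sub = merged[sel]
        if sub["animal_id"].nunique() < 4:
            continue
        entry = {}
        for session, measure in (
            ("conditioning", "shock_response"),
            ("conditioning", "percent_freezing_cs"),
            ("extinction", "percent_freezing_cs"),
        ):
            data = sub[
                (sub["session"] == session)
                & (sub["measure"] == measure)
                & (sub["trial_index"] >= 1)
            ]
            if data.empty:
                continue
            per_level = data.groupby("treatment")["animal_id"].nunique()
            if (per_level < 2).any() or len(per_level) < 2:
                continue
            try:
                entry[f"{session}:{measure}"] = group_stats.mixed_anova(
                    data,
                    dv="value",
                    between="treatment",
                    within="trial_index",
                    subject="animal_id",
                )
            except ValueError as exc:
                logger.warning("%s %s %s: %s", name, session, measure, exc)
        anovas[name] = entry

    # --- contextual generalization: extinction baseline freezing -------
    baseline = merged[
        (merged["session"] == "extinction")
        & (merged["measure"] == "baseline_percent_freezing")
    ]
    generalization: dict = {}
    for name, sel_name in (("female Non-darters", "female Non-darters"),):
        sub = baseline[
            (baseline["sex"] == "female") & (baseline["phenotype"] == "Non-darter")
        ]
        samples = {
            trt: sub[sub["treatment"] == trt]["value"].to_numpy()
            for trt in bc.treatments
        }
        samples = {k: v for k, v in samples.items() if len(v) >= 2}
        if len(samples) >= 2:
            generalization["anova"] = group_stats.oneway_anova(
                samples, comparison="extinction baseline freezing"
            )
            if "VEH" in samples and len(samples) > 2:
                generalization["dunnett"] = group_stats.dunnett_posthoc(
                    samples, control="VEH", seed=config.seed
                )
    results = BehaviorResults(
        animals=animals_df,
        trial_table=trial_table,
        darter_chi_square=chi,
        anovas=anovas,
        baseline_generalization=generalization,
    )
    if config.out_dir:
        _write_behavior(results, config)
    return results


def run_imaging_pipeline(config: RunConfig) -> ImagingResults:
    """Simulate and analyze the imaging arm end to end."""
    ic = config.imaging
    if ic.n_animals_per_sex < 2:
        raise ValueError("need at least 2 animals per sex")
    root = np.random.SeedSequence(config.seed + 1)
    rng_master = np.random.default_rng(root)

    count_results = []
    density_results = []
    for sex in ("female", "male"):
        factor = ic.female_density_factor if sex == "female" else 1.0
        sp = dataclasses.replace(
            ic.section_params, cell_density=ic.section_params.cell_density * factor
        )
        for a in range(ic.n_animals_per_sex):
            animal_id = f"{sex}_{a:02d}"
            for s in range(ic.sections_per_animal):
                section, _ = simulate_section(sp, rng_master.integers(2**31))
                res = image_quant.count_labeled_cells(section)
                count_results.append(
                    dataclasses.replace(
                        res, section_id=f"{animal_id}_s{s}", animal_id=animal_id
                    )
                )
            for s in range(ic.sections_per_animal):
                for label in ("retro-labeled", "unlabeled"):
                    for c in range(ic.cells_per_label):
                        stack, background, _ = simulate_cell_stack(
                            ic.stack_params, rng_master.integers(2**31), label
                        )
                        stack.animal_id = animal_id
                        stack.section_id = f"{animal_id}_s{s}"
                        stack.cell_id = f"{animal_id}_s{s}_{label}_{c}"
                        density_results.append(
                            image_quant.quantify_cell(
                                stack,
                                background,
                                ic.donut_width_um,
                                ic.stack_params.suggested_threshold,
                            )
                        )
    if not density_results:
        raise ValueError("imaging cohort produced no cells")

    per_cell = pd.DataFrame([dataclasses.asdict(d) for d in density_results])
    per_animal_density = image_quant.aggregate_perisomatic(density_results).reset_index()
    per_animal_density["sex"] = per_animal_density["animal_id"].str.split("_").str[0]
    per_animal_counts = image_quant.aggregate_cell_density(count_results).reset_index()
    per_animal_counts["sex"] = per_animal_counts["animal_id"].str.split("_").str[0]

    circuit_anova = group_stats.mixed_anova(
        per_animal_density,
        dv="normalized_density",
        between="sex",
        within="cell_label",
        subject="animal_id",
    )
    density_welch = group_stats.welch_t(
        per_animal_counts.loc[per_animal_counts["sex"] == "female", "density"],
        per_animal_counts.loc[per_animal_counts["sex"] == "male", "density"],
        comparison="female vs male labeled-cell density",
    )
    results = ImagingResults(
        per_cell=per_cell,
        per_animal_density=per_animal_density,
        per_animal_counts=per_animal_counts,
        circuit_anova=circuit_anova,
        density_welch=density_welch,
    )
    if config.out_dir:
        _write_imaging(results, config)
    return results


def _manifest(config: RunConfig) -> dict:
    return {"seed": config.seed, "config_hash": _config_hash(config)}


def _write_behavior(results: BehaviorResults, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.animals.to_csv(out / "animals.csv", index=False)
    results.trial_table.to_csv(out / "trial_table.csv", index=False)
    stats_payload = {
        "darter_chi_square": results.darter_chi_square.as_dict()
        if results.darter_chi_square
        else None,
        "anovas": {
            name: {key: [r.as_dict() for r in rs] for key, rs in entry.items()}
            for name, entry in results.anovas.items()
        },
        "baseline_generalization": {
            k: (v.as_dict() if hasattr(v, "as_dict") else [r.as_dict() for r in v])
            for k, v in results.baseline_generalization.items()
        },
        "manifest": _manifest(config),
    }
    (out / "behavior_stats.json").write_text(json.dumps(stats_payload, indent=2))


def _write_imaging(results: ImagingResults, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.per_cell.to_csv(out / "per_cell_density.csv", index=False)
    results.per_animal_density.to_csv(out / "per_animal_density.csv", index=False)
    results.per_animal_counts.to_csv(out / "per_animal_counts.csv", index=False)
    payload = {
        "circuit_anova": [r.as_dict() for r in results.circuit_anova],
        "density_welch": results.density_welch.as_dict(),
        "manifest": _manifest(config),
    }
    (out / "imaging_stats.json").write_text(json.dumps(payload, indent=2))
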