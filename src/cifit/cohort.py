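"""Synthetic trial cohort: anatomy, insertions, schedules, diaries, outcomes.

Generates subjects with the statistical structure the analysis pipeline
assumes, so the whole pipeline runs end-to-end without any patient data:

* anatomy — cochlear duct length ~ N(35, 2) mm truncated to [28, 42]; the
  most apical contact's insertion depth ~ N(22, 2) mm truncated to
  [12, CDL - 1]; 16 contacts at fixed 0.95 mm spacing toward the base;
* wearing schedule and a daily diary that mis-reports each day's fitting
  with a small error probability;
* longitudinal outcomes per fitting arm following a saturating-exponential
  learning model S(t) = asymptote + (baseline - asymptote) * exp(-t / tau),
  observed at the scheduled visit weeks with Gaussian noise, clipped to each
  measure's scale, and dropped (missing) independently per visit.  The SRT
  trajectory improves downward (lower dB SNR is better) from a baseline at
  the assignment ceiling.  Substitution/gating rules are *not* applied here;
  that is the scoring module's job on the raw table.

Subject-level streams are spawned independently from the master seed, so a
cohort is reproducible bit-for-bit and any one subject can be regenerated
without touching the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .tonotopy import ElectrodeGeometry, GreenwoodParams, place_frequencies
from .fat import RuleSet, build_tonotopic_fat, standard_fat
from .randomize import (
    CONTROL,
    TEST,
    Diary,
    WearingSchedule,
    generate_schedule,
)
from .outcomes import (
    FLAG_MEASURED,
    FLAG_MISSING,
    FLAG_TOO_DIFFICULT,
    MEASURE_SCALES,
    VISIT_WEEKS,
)
from . import io as cifit_io

__all__ = [
    "ArmModel",
    "CohortConfig",
    "SyntheticSubject",
    "sample_geometry",
    "simulate_outcomes",
    "simulate_diary",
    "make_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class ArmModel:
    """Saturating learning model for one measure in one arm."""

    asymptote: float
    tau_days: float  # time constant of the exponential approach
    baseline: float = 0.0
    noise_sd: float = 0.0

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return self.asymptote + (self.baseline - self.asymptote) * np.exp(
            -t / self.tau_days
        )


def _default_learning_models() -> dict[str, dict[str, ArmModel]]:
    """Arm-level medians emulating the trial's group trajectories.

    Control (standard fitting) saturates higher on speech measures than test
    (imaging-based fitting); SRT starts at the 15 dB SNR assignment ceiling
    and improves downward.
    """
    return {
        "cnc": {
            CONTROL: ArmModel(asymptote=68.0, tau_days=21.0, baseline=16.0, noise_sd=5.0),
            TEST: ArmModel(asymptote=47.0, tau_days=21.0, baseline=2.0, noise_sd=5.0),
        },
        "quiet": {
            CONTROL: ArmModel(asymptote=90.0, tau_days=18.0, baseline=20.0, noise_sd=6.0),
            TEST: ArmModel(asymptote=80.0, tau_days=18.0, baseline=10.0, noise_sd=6.0),
        },
        "srt": {
            CONTROL: ArmModel(asymptote=0.3, tau_days=25.0, baseline=15.0, noise_sd=3.0),
            TEST: ArmModel(asymptote=1.9, tau_days=25.0, baseline=15.0, noise_sd=3.0),
        },
        "vas_speech": {
            CONTROL: ArmModel(asymptote=7.0, tau_days=21.0, baseline=3.0, noise_sd=1.0),
            TEST: ArmModel(asymptote=4.7, tau_days=21.0, baseline=1.2, noise_sd=1.0),
        },
        "vas_quality": {
            CONTROL: ArmModel(asymptote=6.9, tau_days=21.0, baseline=3.9, noise_sd=1.0),
            TEST: ArmModel(asymptote=4.5, tau_days=21.0, baseline=3.5, noise_sd=1.0),
        },
    }


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 14
    cdl_mean: float = 35.0  # mm
    cdl_sd: float = 2.0
    cdl_bounds: tuple[float, float] = (28.0, 42.0)
    apical_depth_mean: float = 22.0  # mm from round window
    apical_depth_sd: float = 2.0
    apical_depth_min: float = 12.0
    contact_spacing: float = 0.95  # mm between adjacent contacts
    contact_count: int = 16
    subject_asymptote_sd: float = 8.0  # between-subject spread, shared across arms
    arm_asymptote_sd: float = 6.0  # subject x arm spread (drives paired variance)
    missingness: float = 0.11  # per-visit drop probability
    diary_error: float = 0.05  # per-day mis-report probability
    period_days: int = 84
    master_seed: int = 0
    learning_models: dict = field(default_factory=_default_learning_models)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("cdl_sd", "apical_depth_sd", "subject_asymptote_sd",
                     "arm_asymptote_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missingness", "diary_error"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.contact_spacing <= 0:
            raise ValueError("contact_spacing must be positive")


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    geometry: ElectrodeGeometry
    schedule: WearingSchedule
    diary: Diary
    visits: pd.DataFrame  # raw (pre-scoring) visit table
    seed: int


def _truncated_normal(rng, mean, sd, lo, hi, max_tries: int = 1000) -> float:
    if lo > hi:
        raise ValueError(f"infeasible truncation [{lo}, {hi}]")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError(f"mean {mean} outside truncation [{lo}, {hi}]")
        return float(mean)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(f"truncation [{lo}, {hi}] too tight around N({mean}, {sd})")


def sample_geometry(
    config: CohortConfig, rng: np.random.Generator, subject_id: str = ""
) -> ElectrodeGeometry:
    """Draw one ear's duct length and contact insertion depths."""
    cdl = _truncated_normal(rng, config.cdl_mean, config.cdl_sd, *config.cdl_bounds)
    apical = _truncated_normal(
        rng, config.apical_depth_mean, config.apical_depth_sd,
        config.apical_depth_min, cdl - 1.0,
    )
    depths = apical - config.contact_spacing * np.arange(config.contact_count)
    if depths[-1] < 0:
        raise ValueError("basal contacts extend beyond the round window")
    return ElectrodeGeometry(
        insertion_depths=depths,
        cochlear_duct_length=cdl,
        contact_count=config.contact_count,
        subject_id=subject_id,
    )


def simulate_outcomes(
    subject_id: str, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw visit table for one subject, both arms, all modelled measures.

    CNC is emitted as two rows per visit (test and retest lists).  The
    sentence-in-quiet measurement is flagged "not measured, too difficult"
    when the same visit's (noise-free) CNC expectation is below 10%.  SRT
    rows carry the presented-level range so downstream validity checks run.
    """
    subj_shift = rng.normal(0.0, config.subject_asymptote_sd)
    days = np.array([w * 7 for w in VISIT_WEEKS], float)
    rows = []
    for measure, arms in config.learning_models.items():
        lo, hi = MEASURE_SCALES[measure]
        for fitting, model in arms.items():
            arm_shift = rng.normal(0.0, config.arm_asymptote_sd)
            shift = subj_shift + arm_shift
            if measure == "srt":  # lower is better: shift sign flips, damped scale
                shift = -shift * 0.15
            elif measure.startswith("vas"):
                shift = shift * 0.1
            truth = ArmModel(
                asymptote=float(np.clip(model.asymptote + shift, lo, hi)),
                tau_days=model.tau_days,
                baseline=model.baseline,
            ).value(days)
            cnc_truth = config.learning_models["cnc"][fitting]
            for week, t, mu in zip(VISIT_WEEKS, days, truth):
                missing = rng.random() < config.missingness
                if measure == "quiet":
                    cnc_mu = cnc_truth.value(t) + (subj_shift + arm_shift)
                    if cnc_mu < 10.0 and not missing:
                        rows.append(
                            dict(subject_id=subject_id, fitting=fitting,
                                 measure=measure, visit_week=week, value=np.nan,
                                 flag=FLAG_TOO_DIFFICULT)
                        )
                        continue
                n_rep = 2 if measure == "cnc" else 1
                for _ in range(n_rep):
                    value = float(np.clip(rng.normal(mu, model.noise_sd), lo, hi))
                    row = dict(
                        subject_id=subject_id, fitting=fitting, measure=measure,
                        visit_week=week,
                        value=np.nan if missing else value,
                        flag=FLAG_MISSING if missing else FLAG_MEASURED,
                    )
                    if measure == "srt":
                        row["level_min"], row["level_max"] = -20.0, 20.0
                    rows.append(row)
    return pd.DataFrame(rows)


def simulate_diary(
    schedule: WearingSchedule, config: CohortConfig, rng: np.random.Generator
) -> Diary:
    """Self-report that flips each day's fitting with the diary error rate."""
    other = {TEST: CONTROL, CONTROL: TEST}
    worn = tuple(
        other[a] if rng.random() < config.diary_error else a
        for a in schedule.assignments
    )
    return Diary(worn=worn, subject_id=schedule.subject_id)


def make_subject(
    subject_id: str, config: CohortConfig, seed: int
) -> SyntheticSubject:
    """Build one fully simulated subject from its own seed."""
    rng = np.random.default_rng(seed)
    geometry = sample_geometry(config, rng, subject_id)
    schedule = generate_schedule(config.period_days, rng, subject_id=subject_id)
    diary = simulate_diary(schedule, config, rng)
    visits = simulate_outcomes(subject_id, config, rng)
    return SyntheticSubject(subject_id, geometry, schedule, diary, visits, seed)


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    greenwood: GreenwoodParams = GreenwoodParams(),
    rules: RuleSet | None = None,
) -> dict:
    """Simulate a cohort; optionally write every pipeline input table.

    Returns a dict with subjects, per-subject place frequencies and FATs, and
    the manifest (master seed + per-subject seeds).  With ``out_dir`` set,
    writes geometry/FAT/schedule/diary/visit CSVs and ``manifest.json``.
    """
    ss = np.random.SeedSequence(config.master_seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_subjects)]
    subjects = [
        make_subject(f"S{i + 1:02d}", config, seed)
        for i, seed in enumerate(child_seeds)
    ]
    place = {
        s.subject_id: place_frequencies(s.geometry, greenwood) for s in subjects
    }
    fats = {
        s.subject_id: build_tonotopic_fat(
            place[s.subject_id], rules, subject_id=s.subject_id
        )
        for s in subjects
    }
    manifest = {
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "subject_seeds": dict(zip([s.subject_id for s in subjects], child_seeds)),
    }
    result = {
        "subjects": subjects,
        "place_frequencies": place,
        "tonotopic_fats": fats,
        "standard_fat": standard_fat(),
        "manifest": manifest,
    }
    if out_dir is not None:
        cifit_io.write_cohort(result, Path(out_dir))
    return result
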