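"""Bit-stable CSV/JSON readers and writers for every pipeline table.

No standard bioinformatics container covers CI fitting tables, so everything
is plain CSV with explicit column schemas (frequencies in Hz, octaves as
signed decimals, contact index 1 = most apical).  Floats are written with
`repr` round-trip precision, so write-then-read is the identity to better
than 1e-9 relative.  Schema violations raise :class:`SchemaError` naming the
file, column, and offending subject or row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import pandas as pd

from .fat import Channel, FrequencyAllocationTable, GLOBAL_MAX_HZ, GLOBAL_MIN_HZ
from .randomize import Diary, WearingSchedule
from .tonotopy import ElectrodeGeometry

__all__ = [
    "SchemaError",
    "read_geometries",
    "write_geometries",
    "read_fats",
    "write_fats",
    "read_schedules",
    "write_schedules",
    "read_diaries",
    "write_diaries",
    "read_visits",
    "write_visits",
    "write_report",
    "write_cohort",
    "run_pipeline",
]

GEOMETRY_COLUMNS = ["subject_id", "contact_index", "insertion_depth_mm", "cdl_mm"]
FAT_COLUMNS = ["subject_id", "channel_index", "lower_bound_hz", "upper_bound_hz", "enabled"]
SCHEDULE_COLUMNS = ["subject_id", "day_index", "date_offset", "assigned_fitting"]
DIARY_COLUMNS = ["subject_id", "day_index", "worn_fitting"]
VISIT_COLUMNS = ["subject_id", "fitting", "measure", "visit_week", "value", "flag"]


class SchemaError(ValueError):
    """A table failed schema validation; message names file, row, and column."""


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    # round_trip float parsing keeps write->read exact to the last ulp
    return pd.read_csv(path, float_precision="round_trip")


# -- electrode geometry -------------------------------------------------------

def write_geometries(geometries, path) -> None:
    rows = []
    for g in geometries:
        for i, d in enumerate(g.insertion_depths, start=1):
            rows.append(
                dict(subject_id=g.subject_id, contact_index=i,
                     insertion_depth_mm=float(d), cdl_mm=g.cochlear_duct_length)
            )
    pd.DataFrame(rows, columns=GEOMETRY_COLUMNS).to_csv(path, index=False)


def read_geometries(path) -> dict[str, ElectrodeGeometry]:
    df = _read_csv(path)
    _require_columns(df, GEOMETRY_COLUMNS, path)
    out: dict[str, ElectrodeGeometry] = {}
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("contact_index")
        n = len(g)
        if list(g["contact_index"]) != list(range(1, n + 1)):
            raise SchemaError(
                f"{path}: subject {sid}: contact_index must be 1..{n} with no gaps"
            )
        if g["cdl_mm"].nunique() != 1:
            raise SchemaError(f"{path}: subject {sid}: cdl_mm must be constant")
        try:
            out[str(sid)] = ElectrodeGeometry(
                insertion_depths=g["insertion_depth_mm"].to_numpy(),
                cochlear_duct_length=float(g["cdl_mm"].iloc[0]),
                contact_count=n,
                subject_id=str(sid),
            )
        except ValueError as e:
            raise SchemaError(f"{path}: subject {sid}: {e}") from e
    return out


# -- frequency allocation tables ----------------------------------------------

def write_fats(fats: dict[str, FrequencyAllocationTable], path) -> None:
    rows = [
        dict(subject_id=sid, channel_index=c.channel_index,
             lower_bound_hz=c.lower_bound, upper_bound_hz=c.upper_bound,
             enabled=bool(c.enabled))
        for sid, fat in fats.items()
        for c in fat.channels
    ]
    pd.DataFrame(rows, columns=FAT_COLUMNS).to_csv(path, index=False)


def read_fats(path) -> dict[str, FrequencyAllocationTable]:
    df = _read_csv(path)
    _require_columns(df, FAT_COLUMNS, path)
    out = {}
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("channel_index")
        try:
            channels = tuple(
                Channel(int(r.channel_index), float(r.lower_bound_hz),
                        float(r.upper_bound_hz), bool(r.enabled))
                for r in g.itertuples()
            )
            out[str(sid)] = FrequencyAllocationTable(
                channels,
                global_min=GLOBAL_MIN_HZ,
                global_max=GLOBAL_MAX_HZ,
                has_virtual_channel=channels[0].channel_index == 0,
                subject_id=str(sid),
            )
        except (ValueError, KeyError) as e:
            raise SchemaError(f"{path}: subject {sid}: {e}") from e
    return out


def fats_to_json(fats: dict[str, FrequencyAllocationTable]) -> str:
    """JSON export mirroring the FAT CSV."""
    payload = {
        sid: [dataclasses.asdict(c) for c in fat.channels]
        for sid, fat in fats.items()
    }
    return json.dumps(payload, indent=1)


# -- schedules and diaries ----------------------------------------------------

def write_schedules(schedules, path) -> None:
    rows = [
        dict(subject_id=s.subject_id, day_index=i, date_offset=i - 1,
             assigned_fitting=a)
        for s in schedules
        for i, a in enumerate(s.assignments, start=1)
    ]
    pd.DataFrame(rows, columns=SCHEDULE_COLUMNS).to_csv(path, index=False)


def read_schedules(path) -> dict[str, WearingSchedule]:
    df = _read_csv(path)
    _require_columns(df, SCHEDULE_COLUMNS, path)
    out = {}
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("day_index")
        if list(g["day_index"]) != list(range(1, len(g) + 1)):
            raise SchemaError(f"{path}: subject {sid}: day_index must be 1..n")
        try:
            out[str(sid)] = WearingSchedule(
                tuple(g["assigned_fitting"]), subject_id=str(sid)
            )
        except ValueError as e:
            raise SchemaError(f"{path}: subject {sid}: {e}") from e
    return out


def write_diaries(diaries, path) -> None:
    rows = [
        dict(subject_id=d.subject_id, day_index=i,
             worn_fitting="" if w is None else w)
        for d in diaries
        for i, w in enumerate(d.worn, start=1)
    ]
    pd.DataFrame(rows, columns=DIARY_COLUMNS).to_csv(path, index=False)


def read_diaries(path) -> dict[str, Diary]:
    df = _read_csv(path)
    _require_columns(df, DIARY_COLUMNS, path)
    out = {}
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("day_index")
        worn = tuple(
            None if (isinstance(w, float) and np.isnan(w)) or w == "" else str(w)
            for w in g["worn_fitting"]
        )
        out[str(sid)] = Diary(worn=worn, subject_id=str(sid))
    return out


# -- visits and reports -------------------------------------------------------

def write_visits(visits: pd.DataFrame, path) -> None:
    _require_columns(visits, VISIT_COLUMNS, path)
    visits.to_csv(path, index=False)


def read_visits(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, VISIT_COLUMNS, path)
    return df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))


# -- cohort bundle and pipeline ----------------------------------------------

def write_cohort(cohort: dict, out_dir: Path) -> None:
    """Write every input table a simulated cohort provides."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = cohort["subjects"]
    write_geometries([s.geometry for s in subjects], out_dir / "geometry.csv")
    write_fats(cohort["tonotopic_fats"], out_dir / "fat_tonotopic.csv")
    write_fats({"standard": cohort["standard_fat"]}, out_dir / "fat_standard.csv")
    write_schedules([s.schedule for s in subjects], out_dir / "schedules.csv")
    write_diaries([s.diary for s in subjects], out_dir / "diaries.csv")
    visits = pd.concat([s.visits for s in subjects], ignore_index=True)
    write_visits(visits, out_dir / "visits_raw.csv")
    (out_dir / "manifest.json").write_text(
        json.dumps(_jsonable(cohort["manifest"]), indent=1, sort_keys=True)
    )


def run_pipeline(config, out_dir) -> dict:
    """Simulate -> map -> build FATs -> audit schedules -> analyze.

    ``config`` is a :class:`cifit.config.PipelineConfig`.  Emits the cohort
    tables, per-contact and pooled mismatch summaries for both FATs, and the
    analysis report under ``out_dir``; returns the report dict.
    """
    from .config import PipelineConfig  # local import to avoid a cycle

    assert isinstance(config, PipelineConfig)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    from .cohort import generate_cohort
    from .fat import cohort_mismatch_summary, mismatch_profile
    from .outcomes import analyze_visits, apply_score_rules
    from .randomize import compliance_deviation

    cohort = generate_cohort(
        config.cohort, out_dir=out_dir, greenwood=config.greenwood,
        rules=config.rules,
    )
    std = cohort["standard_fat"]
    profiles = {"tonotopic": [], "standard": []}
    for sid, place in cohort["place_frequencies"].items():
        profiles["tonotopic"].append(
            mismatch_profile(cohort["tonotopic_fats"][sid], place,
                             config.mismatch_representative)
        )
        profiles["standard"].append(
            mismatch_profile(std, place, config.mismatch_representative)
        )
    mismatch = {}
    for kind, profs in profiles.items():
        per_contact, pooled = cohort_mismatch_summary(profs)
        mismatch[kind] = {
            "per_contact": {
                str(i): dict(median=m, iqr=q, n=n) for i, (m, q, n) in per_contact.items()
            },
            "pooled": dict(median=pooled[0], iqr=pooled[1], n=pooled[2]),
        }

    compliance = {
        s.subject_id: compliance_deviation(s.schedule, s.diary)
        for s in cohort["subjects"]
    }
    visits = pd.concat([s.visits for s in cohort["subjects"]], ignore_index=True)
    cleaned = apply_score_rules(visits)
    write_visits(cleaned, out_dir / "visits_clean.csv")
    analysis = analyze_visits(
        cleaned, n_boot=config.n_boot, seed=config.analysis_seed, alpha=config.alpha
    )
    report = {
        "config": config.to_dict(),
        "mismatch_octaves": mismatch,
        "compliance_deviation_pct": {
            "per_subject": compliance,
            "median": float(np.median(list(compliance.values()))),
        },
        "analysis": analysis,
    }
    write_report(report, out_dir / "report.json")
    return report
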