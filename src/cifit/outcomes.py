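"""Scoring rules, learning curves, and paired nonparametric statistics.

The longitudinal analysis of the two-fitting crossover works on visit-level
outcome tables (one row per subject, fitting, measure and visit week).  The
pieces, in pipeline order:

* :func:`apply_score_rules` — clinical substitution/exclusion rules: word
  recognition (CNC) is the mean of test and retest lists; a sentence-in-quiet
  visit skipped as too difficult scores 20% (guessing correction); sentence
  reception threshold (SRT) in noise is only valid when quiet >= 50%,
  otherwise 15 dB SNR is assigned; measured SRTs above 15 dB SNR or outside
  the presented level range are excluded as invalid.
* :func:`learning_curve` / :func:`curve_params` — daily piecewise-linear
  interpolation between visits over the 84-day randomization period, and the
  four summary parameters Begin (day 0), End (day 84), AUC (trapezoidal area
  over the period) and learning rate ((day 28 - day 0) / 28).
* :func:`paired_compare` — Wilcoxon signed-rank (exact for n <= 25, normal
  approximation above), medians/IQRs, and a seeded percentile bootstrap 95%
  CI of the median paired difference.
* :func:`holm_bonferroni` — step-down multiplicity correction.
* psychoacoustics: listening-effort presentation levels around the
  individual SRT, categorical-loudness (ACALOS) growth AUCs, and the
  1-up/1-down spectral-ripple (SMRT) staircase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MEASURE_SCALES",
    "VISIT_WEEKS",
    "VisitSeries",
    "CurveParams",
    "PairedComparison",
    "LoudnessSurface",
    "apply_score_rules",
    "learning_curve",
    "curve_params",
    "paired_compare",
    "holm_bonferroni",
    "effort_levels",
    "acalos_auc",
    "smrt_staircase",
    "preference_proportion",
    "series_from_frame",
]

# value scale (lo, hi) per measure; SRT in dB SNR is open-ended downward
MEASURE_SCALES: dict[str, tuple[float, float]] = {
    "cnc": (0.0, 100.0),  # % phonemes correct
    "quiet": (0.0, 100.0),  # % words correct, sentences in quiet
    "srt": (-20.0, 20.0),  # dB SNR presented range, lower is better
    "vas_speech": (0.0, 10.0),
    "vas_quality": (0.0, 10.0),
    "effort": (0.0, 12.0),
}

# weeks after activation at which primary outcomes are measured
VISIT_WEEKS: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8, 10, 12)

PERIOD_DAYS = 84
LEARNING_RATE_DAY = 28

QUIET_GUESS_SCORE = 20.0  # % substituted when quiet judged too difficult
QUIET_SRT_GATE = 50.0  # % in quiet required before SRT is measured
SRT_ASSIGNED = 15.0  # dB SNR assigned when the gate fails
SRT_INVALID_ABOVE = 15.0  # measured SRTs above this are excluded

FLAG_MEASURED = "measured"
FLAG_MISSING = "missing"
FLAG_TOO_DIFFICULT = "not_measured_too_difficult"
FLAG_ASSIGNED = "assigned"
FLAG_INVALID = "invalid"

VISIT_COLUMNS = ["subject_id", "fitting", "measure", "visit_week", "value", "flag"]


@dataclass(frozen=True)
class VisitSeries:
    """One subject x fitting x measure trajectory; NaN marks missing visits."""

    subject_id: str
    fitting: str
    measure: str
    days: tuple[int, ...]
    values: tuple[float, ...]

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.asarray(self.days, float)
        v = np.asarray(self.values, float)
        ok = np.isfinite(v)
        return d[ok], v[ok]


@dataclass(frozen=True)
class CurveParams:
    begin: float
    end: float
    auc: float  # units x days
    learning_rate: float  # units / day


@dataclass(frozen=True)
class PairedComparison:
    median_test: float
    median_control: float
    iqr_test: float
    iqr_control: float
    median_difference: float  # median of paired (test - control) differences
    p_value: float
    ci95_low: float
    ci95_high: float
    n: int


@dataclass(frozen=True)
class LoudnessSurface:
    """Loudness-growth samples per center frequency: level dB HL -> loudness CU."""

    samples: Mapping[float, tuple[np.ndarray, np.ndarray]]

    def frequencies(self) -> list[float]:
        return sorted(self.samples)


def apply_score_rules(visits: pd.DataFrame) -> pd.DataFrame:
    """Apply the clinical scoring/substitution rules to a raw visit table.

    Expects columns ``subject_id, fitting, measure, visit_week, value, flag``
    (optional ``level_min, level_max`` carry the SRT presented range).  Raw
    CNC may hold several rows per visit (test-retest lists); the cleaned
    table holds exactly one row per subject x fitting x measure x week.
    The operation is idempotent.
    """
    missing = [c for c in VISIT_COLUMNS if c not in visits.columns]
    if missing:
        raise ValueError(f"visit table missing columns {missing}")
    unknown = set(visits["measure"]) - set(MEASURE_SCALES)
    if unknown:
        raise ValueError(f"unknown measure type(s): {sorted(unknown)}")

    df = visits.copy()
    has_range = {"level_min", "level_max"}.issubset(df.columns)

    # CNC: mean of the test and retest lists at each visit
    def _mean_cnc(group: pd.DataFrame) -> pd.Series:
        vals = group.loc[group["flag"] == FLAG_MEASURED, "value"]
        if len(vals):
            return pd.Series({"value": float(vals.mean()), "flag": FLAG_MEASURED})
        return pd.Series({"value": np.nan, "flag": group["flag"].iloc[0]})

    cnc = df[df["measure"] == "cnc"]
    if len(cnc):
        cnc = (
            cnc.groupby(["subject_id", "fitting", "visit_week"], sort=False)[
                ["value", "flag"]
            ]
            .apply(_mean_cnc)
            .reset_index()
        )
        cnc["measure"] = "cnc"
    rest = df[df["measure"] != "cnc"].copy()

    # quiet: too-difficult visits score the guessing floor
    too_hard = (rest["measure"] == "quiet") & (rest["flag"] == FLAG_TOO_DIFFICULT)
    rest.loc[too_hard, "value"] = QUIET_GUESS_SCORE

    # SRT gating against the same visit's quiet score
    quiet = rest[rest["measure"] == "quiet"].set_index(
        ["subject_id", "fitting", "visit_week"]
    )["value"]
    srt_mask = rest["measure"] == "srt"
    for i in rest.index[srt_mask]:
        row = rest.loc[i]
        key = (row["subject_id"], row["fitting"], row["visit_week"])
        q = quiet.get(key, np.nan)
        if np.isfinite(q) and q < QUIET_SRT_GATE:
            rest.loc[i, "value"] = SRT_ASSIGNED
            rest.loc[i, "flag"] = FLAG_ASSIGNED
        elif row["flag"] == FLAG_MEASURED and np.isfinite(row["value"]):
            out_of_range = False
            if has_range and np.isfinite(row["level_min"]):
                out_of_range = not (row["level_min"] <= row["value"] <= row["level_max"])
            if row["value"] > SRT_INVALID_ABOVE or out_of_range:
                rest.loc[i, "flag"] = FLAG_INVALID

    out = pd.concat([cnc, rest], ignore_index=True) if len(cnc) else rest
    order = {m: k for k, m in enumerate(MEASURE_SCALES)}
    return (
        out.sort_values(
            ["subject_id", "fitting", "measure", "visit_week"],
            key=lambda s: s.map(order) if s.name == "measure" else s,
            kind="stable",
        )
        .reset_index(drop=True)
    )


def series_from_frame(
    cleaned: pd.DataFrame, subject_id: str, fitting: str, measure: str
) -> VisitSeries:
    """Extract one trajectory from a cleaned visit table (invalid -> missing)."""
    rows = cleaned[
        (cleaned["subject_id"] == subject_id)
        & (cleaned["fitting"] == fitting)
        & (cleaned["measure"] == measure)
    ].sort_values("visit_week")
    values = np.where(
        rows["flag"].isin([FLAG_MEASURED, FLAG_ASSIGNED]), rows["value"], np.nan
    )
    return VisitSeries(
        subject_id=subject_id,
        fitting=fitting,
        measure=measure,
        days=tuple(int(w) * 7 for w in rows["visit_week"]),
        values=tuple(float(v) for v in values),
    )


def learning_curve(series: VisitSeries, span: tuple[int, int] = (0, PERIOD_DAYS)) -> np.ndarray:
    """Daily piecewise-linear curve over ``span`` (inclusive, 1-day steps).

    Interior missing visits are bridged linearly between flanking non-missing
    visits; missing boundary visits are handled by carrying the nearest
    observed value outward (flat extrapolation).
    """
    days, values = series.observed()
    if len(days) < 2:
        raise ValueError(
            f"{series.subject_id}/{series.fitting}/{series.measure}: "
            f"need >= 2 non-missing visits, got {len(days)}"
        )
    grid = np.arange(span[0], span[1] + 1, dtype=float)
    return np.interp(grid, days, values)


def curve_params(curve: np.ndarray, span: tuple[int, int] = (0, PERIOD_DAYS)) -> CurveParams:
    """Begin / End / AUC / learning rate of a daily curve over ``span``."""
    curve = np.asarray(curve, float)
    if len(curve) != span[1] - span[0] + 1:
        raise ValueError("curve length does not match span")
    rate_day = min(LEARNING_RATE_DAY, span[1]) - span[0]
    return CurveParams(
        begin=float(curve[0]),
        end=float(curve[-1]),
        auc=float(np.trapezoid(curve, dx=1.0)),
        learning_rate=float((curve[rate_day] - curve[0]) / rate_day),
    )


def paired_compare(
    values_test: Sequence[float],
    values_control: Sequence[float],
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> PairedComparison:
    """Wilcoxon signed-rank comparison of paired per-subject values.

    Zero differences are dropped before ranking; the exact signed-rank
    distribution is used for n <= 25 remaining pairs (normal approximation
    above, and whenever ties make the exact distribution unavailable).  The
    95% CI is a seeded percentile bootstrap of the median paired difference.
    """
    a = np.asarray(values_test, float)
    b = np.asarray(values_control, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        p = 1.0
    else:
        if len(nz) < 5:
            warnings.warn(
                f"only {len(nz)} nonzero differences; signed-rank p is coarse",
                stacklevel=2,
            )
        ties = len(np.unique(np.abs(nz))) < len(nz)
        method = "exact" if (len(nz) <= 25 and not ties) else "approx"
        p = float(
            stats.wilcoxon(
                nz, zero_method="wilcox", alternative="two-sided", method=method
            ).pvalue
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    boot_medians = np.median(d[idx], axis=1)
    lo, hi = np.percentile(boot_medians, [2.5, 97.5])
    return PairedComparison(
        median_test=float(np.median(a)),
        median_control=float(np.median(b)),
        iqr_test=float(stats.iqr(a)),
        iqr_control=float(stats.iqr(b)),
        median_difference=float(np.median(d)),
        p_value=p,
        ci95_low=float(lo),
        ci95_high=float(hi),
        n=len(d),
    )


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05):
    """Step-down Holm correction: (adjusted p-values, reject decisions)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return np.array([]), np.array([], bool)
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return adjusted, reject


def effort_levels(srt: float) -> np.ndarray:
    """Six listening-effort presentation SNRs around the individual SRT."""
    if not np.isfinite(srt):
        raise ValueError("SRT must be finite")
    return srt + np.array([-6.0, -3.0, 0.0, 3.0, 6.0, 9.0])


def acalos_auc(
    surface: LoudnessSurface,
    level_range: tuple[float, float] = (0.0, 105.0),
    freq_range: tuple[float, float] = (250.0, 4000.0),
    n_freq_grid: int = 17,
) -> tuple[float, dict[float, float]]:
    """Loudness-growth areas under the curve, overall and per frequency.

    Per measured frequency: trapezoidal integral of loudness (CU) over the
    stimulus-level range (flat extrapolation beyond the sampled levels).
    Overall: the loudness surface is linearly interpolated (in log2
    frequency) onto a log-spaced grid over ``freq_range`` and the per-grid
    integrals are summed.
    """
    freqs = surface.frequencies()
    per_freq: dict[float, float] = {}
    level_grid = np.linspace(*level_range, 512)
    grid_curves = []
    for f in freqs:
        levels, loudness = (np.asarray(x, float) for x in surface.samples[f])
        if len(levels) < 2:
            raise ValueError(f"{f} Hz: need >= 2 level samples")
        if np.any(np.diff(levels) <= 0):
            raise ValueError(f"{f} Hz: stimulus levels must strictly increase")
        curve = np.interp(level_grid, levels, loudness)
        grid_curves.append(curve)
        per_freq[f] = float(np.trapezoid(curve, level_grid))

    from scipy.interpolate import interp1d

    fgrid = np.geomspace(*freq_range, n_freq_grid)
    curves = np.array(grid_curves)  # (n_meas_freqs, n_levels)
    logf = np.log2(freqs)
    on_grid = interp1d(
        logf, curves, axis=0, bounds_error=False,
        fill_value=(curves[0], curves[-1]),
    )(np.log2(fgrid))  # (n_freq_grid, n_levels)
    overall = float(np.trapezoid(on_grid, level_grid, axis=1).sum())
    return overall, per_freq


def smrt_staircase(
    respond: Callable[[float, np.random.Generator], bool],
    seed: int | np.random.Generator | None = None,
    start: float = 0.5,
    step: float = 0.2,
    floor: float = 0.5,
    n_reversals: int = 10,
    n_average: int = 6,
    max_trials: int = 150,
) -> float:
    """1-up/1-down spectral-ripple staircase; threshold in ripples per octave.

    The target starts at ``start`` rpo and moves up ``step`` after a correct
    discrimination (harder) and down after an incorrect one, floored at
    ``floor``.  The track stops after ``n_reversals`` reversals and returns
    the mean of the last ``n_average`` reversal values; a guard at
    ``max_trials`` returns the mean of whatever reversals occurred (or the
    current value if none, e.g. a track pinned at the floor).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    value = start
    reversals: list[float] = []
    prev_direction = 0
    for _ in range(max_trials):
        correct = bool(respond(value, rng))
        direction = 1 if correct else -1
        if prev_direction and direction != prev_direction:
            reversals.append(value)
            if len(reversals) >= n_reversals:
                return float(np.mean(reversals[-n_average:]))
        prev_direction = direction
        value = max(floor, value + direction * step)
    if reversals:
        return float(np.mean(reversals[-n_average:]))
    return float(value)


def analyze_visits(
    cleaned: pd.DataFrame,
    measures: Sequence[str] | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Learning-curve parameters per arm plus paired comparisons per measure.

    For every measure present (or requested), each subject x arm trajectory
    is interpolated into a daily curve and summarised as Begin / End / AUC
    (learning rate additionally for CNC); arms are then compared per
    parameter with the signed-rank test, and within each measure the Begin
    and End p-values are Holm-corrected.  Subjects lacking two non-missing
    visits in either arm are dropped from that measure (their ids are
    reported under ``excluded``).
    """
    rng = np.random.default_rng(seed)
    if measures is None:
        measures = [m for m in MEASURE_SCALES if m in set(cleaned["measure"])]
    subjects = sorted(cleaned["subject_id"].unique())
    report: dict = {"alpha": alpha, "measures": {}}
    for measure in measures:
        params_by_arm: dict[str, dict[str, CurveParams]] = {"test": {}, "control": {}}
        excluded = []
        for sid in subjects:
            try:
                per_arm = {
                    arm: curve_params(
                        learning_curve(series_from_frame(cleaned, sid, arm, measure))
                    )
                    for arm in ("test", "control")
                }
            except ValueError:
                excluded.append(sid)
                continue
            for arm, cp in per_arm.items():
                params_by_arm[arm][sid] = cp
        kept = sorted(params_by_arm["test"])
        names = ["begin", "end", "auc"] + (["learning_rate"] if measure == "cnc" else [])
        entry: dict = {"n": len(kept), "excluded": excluded, "params": {}}
        for name in names:
            t = [getattr(params_by_arm["test"][s], name) for s in kept]
            c = [getattr(params_by_arm["control"][s], name) for s in kept]
            entry["params"][name] = paired_compare(t, c, n_boot=n_boot, seed=rng)
        adj, rej = holm_bonferroni(
            [entry["params"]["begin"].p_value, entry["params"]["end"].p_value], alpha
        )
        entry["holm_begin_end"] = {
            "begin": {"p_adjusted": float(adj[0]), "reject": bool(rej[0])},
            "end": {"p_adjusted": float(adj[1]), "reject": bool(rej[1])},
        }
        report["measures"][measure] = entry
    return report


def preference_proportion(n_prefer: int, n_total: int) -> tuple[float, float, float]:
    """Share (%) of subjects preferring a fitting, with exact binomial 95% CI."""
    if not 0 <= n_prefer <= n_total or n_total < 1:
        raise ValueError("need 0 <= n_prefer <= n_total, n_total >= 1")
    ci = stats.binomtest(n_prefer, n_total).proportion_ci(0.95, method="exact")
    return 100.0 * n_prefer / n_total, float(ci.low), float(ci.high)
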