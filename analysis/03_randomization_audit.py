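#!/usr/bin/env python
"""Audit the daily randomization: constraints at scale, cohort compliance.

Verifies the run-length caps (<= 2 consecutive days in weeks 1-4, <= 4
afterwards) and the exact 42:42 ratio over many freshly drawn 84-day
schedules, then scores each simulated subject's diary against their
schedule, writing per-subject deviations to results/compliance.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cifit import io as cifit_io
from cifit.randomize import compliance_deviation, generate_schedule

ROOT = Path(__file__).resolve().parents[1]


def main(n_schedules: int = 10_000) -> None:
    worst_early = worst_late = 0
    for seed in range(n_schedules):
        s = generate_schedule(84, seed=seed)
        assert s.n_test() == 42
        worst_early = max(worst_early, s.max_run(1, 28))
        worst_late = max(worst_late, s.max_run(29, 84))
    print(f"{n_schedules} schedules drawn: worst run {worst_early} (days 1-28), "
          f"{worst_late} (days 29-84); every draw split 42:42")

    schedules = cifit_io.read_schedules(ROOT / "scratch" / "cohort" / "schedules.csv")
    diaries = cifit_io.read_diaries(ROOT / "scratch" / "cohort" / "diaries.csv")
    devs = {
        sid: compliance_deviation(schedules[sid], diaries[sid]) for sid in schedules
    }
    pd.DataFrame(
        [dict(subject_id=k, deviation_pct=v) for k, v in devs.items()]
    ).to_csv(ROOT / "results" / "compliance.csv", index=False)
    vals = np.array(list(devs.values()))
    q1, q3 = np.percentile(vals, [25, 75])
    print(f"cohort compliance deviation: median {np.median(vals):.1f}% "
          f"(IQR {q3 - q1:.1f}%), max {vals.max():.1f}%")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--n-schedules", type=int, default=10_000, dest="n_schedules")
    main(**vars(p.parse_args()))
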