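#!/usr/bin/env python
"""Psychoacoustic endpoints: effort levels, loudness growth AUC, ripple test.

Demonstrates the secondary-outcome machinery on synthetic inputs: the six
listening-effort presentation levels derived from each arm's final SRT, a
synthetic categorical-loudness surface per fitting (the standard fitting
grows louder in the low frequencies, mirroring the expected effect of the
wide virtual-channel band), and the 1-up/1-down spectral-ripple staircase
for a simulated listener, writing results/psychoacoustics.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from cifit.outcomes import LoudnessSurface, acalos_auc, effort_levels, smrt_staircase

ROOT = Path(__file__).resolve().parents[1]

ACALOS_FREQS = (250.0, 500.0, 1000.0, 2000.0, 4000.0)


def synthetic_loudness_surface(low_freq_gain: float) -> LoudnessSurface:
    """Synthetic loudness growth: 0 CU at threshold rising to 50 CU.

    ``low_freq_gain`` shifts the 250/500 Hz growth curves toward lower
    thresholds (louder percept), emulating a fitting with stronger
    low-frequency representation.
    """
    levels = np.linspace(0.0, 105.0, 8)
    samples = {}
    for f in ACALOS_FREQS:
        threshold = 35.0 - (low_freq_gain if f <= 500.0 else 0.0)
        growth = np.clip((levels - threshold) / (100.0 - threshold), 0.0, 1.0) * 50.0
        samples[f] = (levels, growth)
    return LoudnessSurface(samples)


def main(seed: int = 1) -> None:
    results = {}

    # effort presentation levels around each arm's final simulated SRT
    end_srt = {"test": 1.9, "control": 0.3}
    results["effort_levels_db_snr"] = {
        arm: list(effort_levels(srt)) for arm, srt in end_srt.items()
    }
    for arm, levels in results["effort_levels_db_snr"].items():
        print(f"effort levels ({arm}, SRT {end_srt[arm]:+.1f} dB SNR): "
              + ", ".join(f"{x:+.1f}" for x in levels))

    # loudness growth: standard fitting louder below 500 Hz
    results["acalos_auc"] = {}
    for arm, gain in (("test", 0.0), ("control", 10.0)):
        overall, per = acalos_auc(synthetic_loudness_surface(gain))
        results["acalos_auc"][arm] = {
            "overall": overall, **{f"{int(f)}_hz": v for f, v in per.items()}
        }
        print(f"ACALOS AUC ({arm}): overall {overall:.0f} CU*dB, "
              f"250 Hz {per[250.0]:.0f}, 4000 Hz {per[4000.0]:.0f}")

    # spectral ripple discrimination for a listener with a 2.6 rpo limit
    def listener(target_rpo, rng):
        p_correct = 0.98 if target_rpo < 2.6 else 0.02
        return rng.random() < p_correct

    thr = smrt_staircase(listener, seed=seed)
    results["smrt_threshold_rpo"] = thr
    print(f"SMRT staircase threshold: {thr:.2f} ripples per octave")

    out = ROOT / "results" / "psychoacoustics.json"
    out.write_text(json.dumps(results, indent=1))
    print(f"wrote {out}")


if __name__ == "__main__":
    p = argparse.ArgumentParser()
    p.add_argument("--seed", type=int, default=1)
    main(**vars(p.parse_args()))
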