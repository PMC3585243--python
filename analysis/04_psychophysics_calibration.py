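"""Calibration of the adaptive procedures against analytic observers.

QUEST (4AFC, 82.5% criterion, 40-trial runs) is run against an observer
whose analytic 82.5%-correct point is 1.00 arcmin; the 3-down/1-up contrast
staircase (0.1 log steps) is run against a 2IFC observer and compared with
its analytic 79.4%-correct convergence point.  Writes
results/psychophysics.json.
"""

import json
import math
from pathlib import Path

import numpy as np

from foveal_limits import psychophys, synthgen


def main() -> None:
    estimates = [
        psychophys.quest_run(
            synthgen.make_observer(synthgen.spec_for_criterion(1.0, seed=s)),
            n_trials=40,
        ).threshold
        for s in range(200)
    ]
    quest_mean = float(np.mean(estimates))
    quest_sd = float(np.std(estimates))
    print(f"QUEST, 200 x 40 trials vs a 1.00-arcmin observer: "
          f"mean {quest_mean:.3f} arcmin (SD {quest_sd:.3f})")

    logs = []
    for seed in range(500):
        obs = synthgen.make_observer(
            synthgen.ObserverSpec(limit=0.05, slope=3.0, guess_rate=0.5,
                                  lapse_rate=0.01, seed=seed)
        )
        logs.append(math.log10(psychophys.staircase_run(obs, 0.05, n_trials=60)))
    target = math.log10(
        synthgen.make_observer(
            synthgen.ObserverSpec(limit=0.05, slope=3.0, guess_rate=0.5,
                                  lapse_rate=0.01)
        ).criterion_size(0.5 ** (1.0 / 3.0))
    )
    stair_mean = float(np.mean(logs))
    print(f"staircase, 500 seeds: mean log10 contrast {stair_mean:.3f} "
          f"(analytic 79.4% point {target:.3f})")

    Path("results").mkdir(exist_ok=True)
    Path("results/psychophysics.json").write_text(json.dumps({
        "quest_mean_arcmin": quest_mean,
        "quest_sd_arcmin": quest_sd,
        "quest_true_point_arcmin": 1.0,
        "staircase_mean_log10": stair_mean,
        "staircase_target_log10": target,
    }, indent=1))


if __name__ == "__main__":
    main()
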