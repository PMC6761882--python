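#!/usr/bin/env python
"""New-encounter statistics and the collision-theory rate bridge.

Counts, per focal molecule, the distinct partners that ever come within
the 1.5 nm encounter radius, fits the growth law N_enc ~ t^m, derives the
encounter-frequency exponent m - 1, and converts the encounter count to a
surface reaction rate via rate = f * T*^2 with 15% triplets.  Writes
results/encounters.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tta2d.simulate import SimulationConfig, simulate_brownian, simulate_fbm  # noqa: E402
from tta2d.trajectories import (  # noqa: E402
    count_new_encounters, encounter_rate_to_reaction_rate,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main():
    OUT.mkdir(exist_ok=True)
    frames = {}
    for label, motion, hurst in [("brownian", "brownian", 0.5),
                                 ("fbm_H0.4", "fbm", 0.4)]:
        dt = 2e-11
        D = 2e-9 * dt ** (1 - 2 * hurst)  # same RMS frame step
        cfg = SimulationConfig(seed=SEED, n_particles=50, n_steps=2000,
                               D=D, dt=dt, L=30e-9, motion=motion,
                               hurst=hurst)
        sim = simulate_brownian if motion == "brownian" else simulate_fbm
        traj = sim(cfg)
        enc = count_new_encounters(traj, 1.5e-9)
        frames[label] = enc
        rate = encounter_rate_to_reaction_rate(
            enc, triplet_fraction=0.15, area=cfg.L**2,
            duration=traj.times[-1])
        print(f"{label}: N_enc ~ t^{enc.exponent:.2f} -> encounter "
              f"frequency ~ t^{enc.frequency_exponent:+.2f}; "
              f"{enc.initial_neighbors:.1f} initial neighbours; "
              f"rate(15% triplets) = {rate:.2e} mol m^-2 s^-1")

    df = pd.DataFrame({
        "time_s": frames["brownian"].times,
        "n_enc_brownian": frames["brownian"].counts,
        "n_enc_fbm": frames["fbm_H0.4"].counts,
    })
    df.to_csv(OUT / "encounters.csv", index=False)
    print("sublinear growth in both cases: 2D exploration is compact, so "
          "walkers revisit old neighbours instead of finding new ones")


if __name__ == "__main__":
    main()
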