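#!/usr/bin/env python
"""The time-dependent 2D rate coefficient and its certification.

Evaluates the cylindrical-Smoluchowski coefficient k(t) for the dilute-
interface mobility (D = 1.1e-9 m^2 s^-1, R = 1.5 nm), cross-checks it
against the independent finite-difference PDE absorbing-flux oracle, and
shows the defining 2D behaviour: 1/k grows like ln t, so k never reaches
an asymptote.  Writes results/rate_coefficient.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from tta2d.kinetics import (  # noqa: E402
    DiffusionKineticsParams, rate_coefficient_2d,
)
from tta2d.validation import rate_coefficient_pde  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    D, R = 1.1e-9, 1.5e-9
    params = DiffusionKineticsParams(D=D, R=R, T0=1e-7)

    t = np.geomspace(1e-8, 1e-6, 25)
    curve = rate_coefficient_2d(params, t)
    k_pde = rate_coefficient_pde(D, R, t)
    dev = np.abs(curve.k_of_t / k_pde - 1)

    df = pd.DataFrame({"time_s": t, "k_m2_mol_s": curve.k_of_t,
                       "k_pde_oracle": k_pde, "rel_dev": dev})
    df.to_csv(OUT / "rate_coefficient.csv", index=False)

    print(f"k(20 ns) = {curve.k_of_t[np.searchsorted(t, 2e-8)]:.3e} "
          f"m^2 mol^-1 s^-1 at D = {D:.1e} m^2 s^-1, R = 1.5 nm")
    print(f"Bessel-integral evaluator vs PDE flux oracle: "
          f"max deviation {dev.max() * 100:.3f}% over 2 decades of t")

    # long-time form: 1/k is linear in ln t (no plateau, ever)
    t_long = np.geomspace(1e-4, 1e-3, 30)
    k_long = rate_coefficient_2d(params, t_long).k_of_t
    slope, _ = np.polyfit(np.log(t_long), 1 / k_long, 1)
    r = np.corrcoef(np.log(t_long), 1 / k_long)[0, 1]
    print(f"late-time 1/k vs ln t: R^2 = {r**2:.5f} (slope {slope:.3e}) -- "
          "the coefficient decays logarithmically forever")


if __name__ == "__main__":
    main()
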