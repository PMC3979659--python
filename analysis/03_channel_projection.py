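#!/usr/bin/env python
"""Monomer -> dimer projection and clamshell/channel correlation.

Projects the reference dimer onto a synthetic monomer trajectory whose
linker residue drifts toward its chain-B partner, reporting the P632-P632
linker series (the ion-channel opening proxy).  Then quantifies how well the squared Pearson
correlation recovers planted population values on paired series of the sizes
the analysis layer works with (r^2 = 0.916: strongly coupled clamshell and
channel; r^2 = 0.11: decoupled).
"""

import sys
from pathlib import Path

import numpy as np

from azogate.cli import write_table
from azogate.switch_dynamics import Trajectory
from azogate.synthetic_data import (DOMAIN1_RANGE, ScaffoldSpec,
                                    make_correlated_series, make_toy_dimer,
                                    make_toy_lbd)
from azogate.traj_metrics import pearson_r2, project_dimer

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 11


def main():
    RESULTS.mkdir(exist_ok=True)
    spec = ScaffoldSpec(seed=SEED)
    mono = make_toy_lbd(spec)
    dimer = make_toy_dimer(spec)

    # monomer trajectory: residue 632 drifts away from its reference position
    idx = [i for i, a in enumerate(mono.atoms) if a.res_number == 632]
    frames = []
    for step in range(50):
        c = mono.coordinates.copy()
        c[idx] += np.array([0.0, 0.01, 0.0]) * step
        frames.append(c)
    n = len(frames)
    traj = Trajectory(np.arange(n, dtype=float), np.array(frames),
                      np.zeros(n), np.zeros(n))
    linker = project_dimer(traj, dimer, DOMAIN1_RANGE, mono)
    write_table(RESULTS / "linker_series.tsv", ["time_ps", "value_nm"],
                [{"time_ps": float(t), "value_nm": float(v)}
                 for t, v in zip(linker.times, linker.values)])
    print(f"projected linker distance: {linker.values[0]:.3f} nm at rest, "
          f"{linker.values[-1]:.3f} nm after the planted drift")

    rows = []
    for r2_planted in (0.916, 0.11):
        a, b = make_correlated_series(float(np.sqrt(r2_planted)), 10_000,
                                      seed=SEED)
        r2 = pearson_r2(a, b)
        rows.append({"r2_planted": r2_planted, "r2_measured": r2, "n": 10_000})
        print(f"planted r^2 = {r2_planted}: measured {r2:.4f} (n = 10^4)")
    write_table(RESULTS / "correlations.tsv",
                ["r2_planted", "r2_measured", "n"], rows)

    ok = (abs(rows[0]["r2_measured"] - 0.916) < 0.01
          and abs(rows[1]["r2_measured"] - 0.11) < 0.02)
    print("conclusion: correlation estimates recover the planted couplings."
          if ok else "warning: correlation recovery outside tolerance.")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
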