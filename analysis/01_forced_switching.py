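#!/usr/bin/env python
"""Forced trans->cis photo-isomerization of the toy azobenzene.

Nine Langevin replicates: thermalize in trans, activate the harmonic dihedral
switching potential (k = 320, minimum at cis) for 500 fs, then 50 ps of
unbiased follow-up.  Then the reverse process (cis -> trans) from a cis-basin
start.  Writes per-replicate tables and prints the success counts and
first-passage statistics.
"""

import sys
from pathlib import Path

import numpy as np

from azogate.cli import _cis_geometry, write_table
from azogate.switch_dynamics import (IntegratorConfig, SwitchPotential,
                                     run_switch_experiment)
from azogate.toy_system import build_azobenzene, minimize

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def report(tag, summary):
    times = [t for t in summary.isomerization_times if t is not None]
    print(f"{tag}: {summary.success_count}/{summary.n_replicates} replicates "
          f"switched and held the target isomer through the follow-up; "
          f"median first passage {np.median(times):.1f} fs "
          f"(min {min(times):.1f}, max {max(times):.1f})")
    write_table(RESULTS / f"switching_{tag}.tsv",
                ["replicate", "seed", "success", "time_fs"],
                [{**r, "time_fs": r["time_fs"] if r["time_fs"] is not None
                  else "none"} for r in summary.as_rows()])


def main():
    RESULTS.mkdir(exist_ok=True)
    model = build_azobenzene("minimal")
    cfg = IntegratorConfig()

    forward = run_switch_experiment(
        model, cfg, SwitchPotential(target_angle=0.0),
        n_replicates=9, seeds=[SEED + i for i in range(9)], follow_up=50.0)
    report("forward", forward)

    cis_model = minimize(model.with_coordinates(_cis_geometry(model)))
    reverse = run_switch_experiment(
        cis_model, cfg, SwitchPotential(target_angle=180.0),
        n_replicates=9, seeds=[SEED + 100 + i for i in range(9)],
        follow_up=50.0)
    report("reverse", reverse)

    ok = (forward.success_count == forward.n_replicates
          and reverse.success_count == reverse.n_replicates)
    print("conclusion: the 500 fs switching window is sufficient in both "
          "directions and the new isomer persists unbiased."
          if ok else "warning: some replicates failed to hold the target isomer.")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
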