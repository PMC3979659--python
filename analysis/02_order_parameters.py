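#!/usr/bin/env python
"""Order-parameter analysis of a synthetic trajectory with planted events.

Builds the toy LBD scaffold in the bound/closed regime (clamshell 0.70 nm,
gate 0.55 nm, ligand in position 1 at 0.45 nm), plants a gate-opening event
(0.55 -> 0.80 nm) and a pose transition (0.45 -> 1.05 nm) with coordinate
noise, and runs the series/classifier/transition analysis over the result.
"""

import sys
from pathlib import Path

from azogate.cli import write_table
from azogate.synthetic_data import (EventSpec, ScaffoldSpec,
                                    make_event_trajectory, make_toy_lbd)
from azogate.traj_metrics import (detect_transitions, gate_state,
                                  order_parameter_series, pose_state)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7
GATE_EVENT_FRAME = 400
POSE_EVENT_FRAME = 700


def main():
    RESULTS.mkdir(exist_ok=True)
    scaffold = make_toy_lbd(ScaffoldSpec(seed=SEED))
    traj = make_event_trajectory(scaffold, [
        EventSpec("gate", 0.55, GATE_EVENT_FRAME, 0.80, sigma=0.01,
                  n_frames=1000, seed=SEED),
        EventSpec("pocket", 0.45, POSE_EVENT_FRAME, 1.05, sigma=0.01,
                  n_frames=1000, seed=SEED),
    ])

    found = {}
    for name, classifier in (("gate", gate_state), ("pocket", pose_state)):
        ser = order_parameter_series(scaffold, traj, name)
        write_table(RESULTS / f"series_{name}.tsv",
                    ["time_ps", "value_nm", "state"],
                    [{"time_ps": float(t), "value_nm": float(v), "state": s}
                     for t, v, s in zip(ser.times, ser.values, ser.states)])
        found[name] = detect_transitions(ser, classifier, min_dwell=10)
        for frame, s_from, s_to in found[name]:
            print(f"{name}: {s_from} -> {s_to} at frame {frame}")

    write_table(RESULTS / "transitions.tsv",
                ["series", "frame", "from", "to"],
                [{"series": n, "frame": f, "from": a, "to": b}
                 for n, trs in found.items() for f, a, b in trs])

    ok = (len(found["gate"]) == 1
          and abs(found["gate"][0][0] - GATE_EVENT_FRAME) <= 5
          and len(found["pocket"]) == 1
          and abs(found["pocket"][0][0] - POSE_EVENT_FRAME) <= 5)
    print("conclusion: both planted events recovered at the planted frames."
          if ok else "warning: planted events not recovered as expected.")
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
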