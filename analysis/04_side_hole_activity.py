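#!/usr/bin/env python
"""Per-side-hole mass flows and the active/inactive classification.

For cases 1, 2, 8 and 9: writes results/side_holes_case<N>.csv (hole
index, signed mass flow into the lumen, share of the total, active flag
at the 1% threshold) and prints the active sets.
"""

from pathlib import Path

import pandas as pd

from stentflow.analysis import solve_scenario
from stentflow.config_io import write_csv
from stentflow.geometry import make_scenario
from stentflow.network import classify_active_holes, side_hole_flows

OUT = Path(__file__).resolve().parent.parent / "results"
CASES = (1, 2, 8, 9)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for cid in CASES:
        sol = solve_scenario(make_scenario(cid))
        flows = side_hole_flows(sol)
        active = classify_active_holes(flows, sol.total_flow)
        table = pd.DataFrame([
            {"hole_index": idx, "m_dot": q,
             "share_pct": abs(q) / abs(sol.total_flow) * 100.0,
             "active": idx in active}
            for idx, q in flows
        ])
        write_csv(table, OUT / f"side_holes_case{cid}.csv",
                  {"hole_index": "-", "m_dot": "kg/s", "share_pct": "%",
                   "active": "-"})
        peak = max(flows, key=lambda t: abs(t[1]))
        print(f"case {cid}: {len(active)}/{len(flows)} holes active; "
              f"largest |m_dot| at hole {peak[0]} ({peak[1]:+.3e} kg/s)")


if __name__ == "__main__":
    main()
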