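#!/usr/bin/env python
"""Solve the nine named cases and tabulate their average total flows.

Writes results/case_matrix.csv: one row per case with permeability,
side-hole count, occlusion flag, average total mass flow, change versus
the unporous baseline (case 1) and the maximum edge Reynolds number.
"""

from pathlib import Path

import pandas as pd

from stentflow.analysis import average_total_flow, max_reynolds, solve_scenario
from stentflow.config_io import write_csv
from stentflow.geometry import CASE_MATRIX, make_scenario

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    baseline = None
    for cid in range(1, 10):
        sol = solve_scenario(make_scenario(cid))
        q = average_total_flow(sol)
        if cid == 1:
            baseline = q
        alpha, n_holes, occluded = CASE_MATRIX[cid]
        rows.append({
            "case": cid,
            "permeability_m2": alpha,
            "n_side_holes": n_holes,
            "occluded": occluded,
            "avg_total_kg_s": q,
            "delta_vs_case1_pct": (q - baseline) / baseline * 100.0,
            "max_reynolds": max_reynolds(sol),
        })
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    write_csv(table, OUT / "case_matrix.csv",
              {"case": "-", "permeability_m2": "m^2", "n_side_holes": "-",
               "occluded": "-", "avg_total_kg_s": "kg/s",
               "delta_vs_case1_pct": "%", "max_reynolds": "-"})
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
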