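"""Build the calibration grid and pick a D-optimal validation set.

Generates the five-level 25-mixture calibration design over the default
working ranges (CFPM 1-17, TAZO 1-9 ug/mL), enumerates the 1 ug/mL
candidate lattice with calibration points excluded, and runs the Fedorov
exchange to select 13 validation mixtures maximizing det(X'X) of a
quadratic response-surface model.
"""

import numpy as np

import chemocal as cc
from chemocal.design import InformationModel, leverage_diagnostics

calib = cc.generate_brereton()
print(f"calibration grid: {calib.n_points} mixtures")
print("  CFPM levels:", sorted({float(v) for v in calib.points[:, 0]}), "ug/mL")
print("  TAZO levels:", sorted({float(v) for v in calib.points[:, 1]}), "ug/mL")

cands = cc.enumerate_candidates(cc.DEFAULT_DOMAIN, 1.0, exclude=calib)
print(f"candidate pool after excluding calibration points: {len(cands)}")

model = InformationModel("quadratic", cc.DEFAULT_DOMAIN)
valid, trace = cc.fedorov_select(cands, 13, model, seed=42, restarts=20)
print(f"selected {valid.n_points} validation mixtures, "
      f"log det(X'X) = {trace.final_log_det:.4f} "
      f"({len(trace.swaps)} exchange swaps in the winning restart)")
for c, t in valid.points:
    print(f"  CFPM {c:5.1f}  TAZO {t:4.1f}  ug/mL")

lev = leverage_diagnostics(valid, model)
print(f"leverages sum to {lev['leverage_sum']:.2f} (= number of model terms); "
      f"pairwise distances {lev['min_pairwise_distance']:.2f}-"
      f"{lev['max_pairwise_distance']:.2f} ug/mL show the spread over "
      "peripheral, intermediate and central regions")
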