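"""Full pipeline on a synthetic array scene with planted viruses.

Simulates a 10 x 10 split-ring array with six viruses anchored at known
gaps, renders the ten-angle polarization stack with camera noise,
demodulates it, registers the lattice, applies the extended Laplace
background subtraction, scores every interior unit for longitudinal
asymmetry and calls virus-positive units at |As| > 7.
"""

import tempfile
from pathlib import Path

import pandas as pd

from pimidetect import RunConfig, SceneSpec, VirusPlacement, run_pipeline

placements = (
    VirusPlacement(2, 3, "top"),
    VirusPlacement(3, 8, "bottom"),
    VirusPlacement(4, 6, "bottom"),
    VirusPlacement(5, 2, "top"),
    VirusPlacement(6, 7, "bottom"),
    VirusPlacement(7, 4, "top"),
)

out = Path(tempfile.mkdtemp(prefix="pimidetect_"))
scene = SceneSpec(virus_placements=placements, seed=1)
summary = run_pipeline(RunConfig(mode="all", out_dir=str(out), scene=scene, seed=1))

records = pd.read_csv(out / "records.csv")
called = records[records.call]

print(f"artifacts in {out}")
print(f"valid interior units: {summary['n_valid']}   called: {summary['n_called']}")
print(f"sensitivity: {summary['sensitivity']:.3f}   specificity: {summary['specificity']:.3f}")
print(f"empirical misdetection fraction (P2 estimate): {summary['p_mis_hat']:.3f}")
print()
print(called[["i", "j", "score", "signed_score", "direction"]].to_string(index=False))
print()
print("Each called unit is one split-ring; |As| far above the clean-unit")
print("envelope (~0.001 here) flags a virus, and the sign of the directional")
print("score says which longitudinal gap it occupies (+top / -bottom).")
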