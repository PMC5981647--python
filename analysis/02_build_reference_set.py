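#!/usr/bin/env python
"""Build the full-factorial calibration corpus from the single spectra.

Scales the six 100 ppm singles by {0, 0.3, 0.7, 1} in all 4^6 = 4096
combinations ("generated" levels 0/30/70/100 ppm per component) and adds
10% independent per-row Gaussian noise.  The full X matrix is bulky, so it
goes to scratch/; results/ gets the design summary.

Reads:  results/singles.csv (run 01 first)
Writes: scratch/reference/{X.csv,Y.csv,meta.json}, results/reference_summary.csv
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pamix import AugmentationConfig, build_reference_set
from pamix.io import read_spectra_csv, save_reference_set

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"

grid, spectra = read_spectra_csv(OUT / "singles.csv")
cfg = AugmentationConfig(noise_fraction=0.10, noise_placement="per_reference", seed=SEED)
ref = build_reference_set(list(spectra.values()), cfg, list(spectra))
save_reference_set(ROOT / "scratch" / "reference", ref, cfg)

levels, counts = np.unique(ref.Y, return_counts=True)
summary = pd.DataFrame(
    {
        "n_reference_spectra": [ref.n_samples],
        "n_wavelengths": [ref.X.shape[1]],
        "n_components": [ref.n_components],
        "concentration_levels_ppm": [" ".join(map(str, levels))],
        "noise_fraction": [cfg.noise_fraction],
        "noise_placement": [cfg.noise_placement],
        "seed": [SEED],
    }
)
summary.to_csv(OUT / "reference_summary.csv", index=False)
print(summary.to_string(index=False))
print(f"-> {ref.n_samples} spectra = 4 factor levels ^ {ref.n_components} components;")
print("   the balanced factorial design gives the regression every level of every")
print("   component in every context of the others.")
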