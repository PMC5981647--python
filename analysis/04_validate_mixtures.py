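#!/usr/bin/env python
"""Two-component validation mixtures, the study's prediction scenario.

Trains a six-factor SIMPLS model on the noisy factorial corpus, then
predicts 2-butanone/1-propanol mixtures at 30/70, 50/50 and 70/30 ppm
whose spectra carry fresh measurement noise.  Reports raw and clamped
predictions and the pooled summary metrics.

Writes: results/mixture_predictions.csv, results/mixture_metrics.csv
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pamix import (
    AugmentationConfig,
    add_noise,
    build_reference_set,
    clamp_nonnegative,
    fit_simpls,
    predict,
)
from pamix.io import read_spectra_csv
from pamix.metrics import ValidationReport

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results"

grid, spectra = read_spectra_csv(OUT / "singles.csv")
singles, names = list(spectra.values()), list(spectra)

cfg = AugmentationConfig(noise_fraction=0.10, seed=SEED)
ref = build_reference_set(singles, cfg, names)
model = fit_simpls(ref.X, ref.Y, n_factors=6, component_names=names)

ratios = [(30.0, 70.0), (50.0, 50.0), (70.0, 30.0)]
a, b = names[0], names[1]
truths, preds = [], []
records = []
for i, (ca, cb) in enumerate(ratios):
    clean = (ca / 100.0) * spectra[a].signal + (cb / 100.0) * spectra[b].signal
    noisy = add_noise(
        type(singles[0])(grid=grid, signal=clean, normalized=True), 0.10, seed=SEED + 500 + i
    )
    res = predict(model, noisy.signal)
    truth = np.array([ca, cb] + [0.0] * (len(names) - 2))
    truths.append(truth)
    preds.append(res.raw)
    for j, n in enumerate(names):
        records.append(
            {
                "mixture": f"{int(ca)}/{int(cb)}",
                "component": n,
                "true_ppm": truth[j],
                "raw_ppm": res.raw[j],
                "clamped_ppm": res.clamped[j],
            }
        )

table = pd.DataFrame(records)
table.to_csv(OUT / "mixture_predictions.csv", index=False, float_format="%.3f")
truths, preds = np.array(truths), np.array(preds)
raw = ValidationReport.from_predictions(truths, preds, "raw")
clamped = ValidationReport.from_predictions(truths, clamp_nonnegative(preds), "clamped")
metrics = pd.DataFrame([raw.to_dict(), clamped.to_dict()])
metrics.to_csv(OUT / "mixture_metrics.csv", index=False, float_format="%.4f")

print(table.round(2).to_string(index=False))
print(metrics.round(3).to_string(index=False))
print(f"-> the model separates the two mixed VOCs and reports near-zero amounts of")
print("   the four absent ones; clamping negative excursions tightens the summary,")
print("   mirroring the raw-vs-clamped comparison on the published mixtures.")
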