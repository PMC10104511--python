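#!/usr/bin/env python
"""Protrusion morphometry benchmark over seeded synthetic cells.

Generates 20 cells (0–6 slender protrusions, lengths 3R–5R) and measures
how well the inscribed-sphere / 2R protrusion census recovers the ground
truth: exact-count rate, inscribed-radius error, per-protrusion length
error, and sphericity vs protrusion count.  Writes the per-cell table to
results/morphometry.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fibremech.morphology import cell_metrics
from fibremech.synth import SceneParams, generate_cell_mask

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for seed in range(20):
    rng = np.random.default_rng(seed + 1000)
    n_prot = int(rng.integers(0, 7))
    R = 7.0
    length = float(rng.uniform(3 * R, 5 * R))
    params = SceneParams(
        grid_shape=(160, 160, 160), cell_radius_um=R, n_protrusions=n_prot,
        protrusion_length_um=length, protrusion_radius_um=1.5, seed=seed,
    )
    cell, _, truth_lengths = generate_cell_mask(params)
    m = cell_metrics(cell)
    len_err = (
        float(np.mean([
            abs(a - b) / b
            for a, b in zip(sorted(m.protrusion_lengths_um), sorted(truth_lengths))
        ]))
        if m.protrusion_count == n_prot and n_prot
        else np.nan
    )
    rows.append({
        "seed": seed,
        "true_count": n_prot,
        "recovered_count": m.protrusion_count,
        "true_length_um": length,
        "inscribed_R_um": m.inscribed_radius_R_um,
        "sphericity_pct": m.sphericity_pct,
        "volume_um3": m.volume_um3,
        "mean_length_rel_err": len_err,
    })

df = pd.DataFrame(rows)
df.to_csv(OUT / "morphometry.csv", index=False)

exact = (df.true_count == df.recovered_count).mean()
print(f"exact protrusion-count recovery: {100 * exact:.0f}% of {len(df)} cells")
print(f"inscribed R: {df.inscribed_R_um.mean():.2f} um (truth 7.00 um)")
print(f"mean length error: {100 * df.mean_length_rel_err.mean():.1f}%")
print("sphericity drops with protrusion count:")
print(df.groupby("true_count").sphericity_pct.mean().round(1).to_string())
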