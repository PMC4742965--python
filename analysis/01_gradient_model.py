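#!/usr/bin/env python
"""Characterise the dSi bead source: loading, profile, timing, release.

Writes results/gradient/{loadings,profile,summary}.csv and prints the
headline numbers: a 1.40-nmol bead releases ~5% of its load over a
600-s assay, the gradient is established within ~452 s, and the
flat-chamber profile falls from ~14 uM at the bead surface (r = 50 um)
to ~5 uM at the observation-field edge (r = 336 um).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import taxikit as tk

OUT = Path(__file__).resolve().parent.parent / "results" / "gradient"
OUT.mkdir(parents=True, exist_ok=True)

# per-particle loadings from the three evaporation recipes
recipes = pd.DataFrame(
    {"stock_volume_ul": [50.0, 800.0, 1270.0]},
).assign(
    stock_conc_mol_l=0.440, alox_mass_mg=100.0, particles_per_mg=2640.0
)
recipes["loading_nmol"] = [
    tk.bead_loading(r.stock_volume_ul, r.stock_conc_mol_l, r.alox_mass_mg,
                    r.particles_per_mg) * 1e9
    for r in recipes.itertuples()
]
recipes.to_csv(OUT / "loadings.csv", index=False)

gradient = tk.PointSourceGradient()  # measured flux 1.21e-13 mol/s, 1.40 nmol

radii_um = np.arange(50.0, 337.0, 2.0)
profile = tk.gradient_profile(gradient, radii_um * 1e-4)
profile.to_csv(OUT / "profile.csv", index=False)

t_steady = tk.time_to_steady_state(gradient, 0.0672)
released = tk.fraction_released(gradient, 600.0)
edge = tk.steady_state_concentration(gradient, 0.0336)
surface = tk.steady_state_concentration(gradient, 50e-4)

summary = pd.DataFrame(
    [
        {"quantity": "time_to_steady_state_s", "value": t_steady},
        {"quantity": "fraction_released_600s", "value": released},
        {"quantity": "edge_conc_uM_literal", "value": edge},
        {"quantity": "surface_conc_uM_literal", "value": surface},
    ]
)
summary.to_csv(OUT / "summary.csv", index=False)

print(f"per-particle loadings (nmol): "
      f"{', '.join(f'{v:.3f}' for v in recipes['loading_nmol'])}")
print(f"time to steady state over 672-um field: {t_steady:.1f} s")
print(f"fraction of load released in 600 s: {released * 100:.1f}%")
print(f"flat-chamber concentration: {surface:.1f} uM at the bead surface "
      f"(r = 50 um) -> {edge:.2f} uM at the field edge (r = 336 um)")
print(f"tables written to {OUT}")
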