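#!/usr/bin/env python
"""Per-bin chemotaxis readouts of the simulated assay arms.

Reads the tracks written by 02_simulate_assays.py (control, attractant,
repellent), computes the four readouts — normalized cell counts (60 s),
mean sine angle (60 s), sum distance (60 s) and mean gliding speed
(30 s, raw and log1p) — per concentric ring, plus OLS trend slopes of
the sum-distance and normalized-count series. The attractant arm shows
falling sum distance and rising inner-ring counts; the repellent arm
the reverse; the control neither.
"""

from pathlib import Path

import pandas as pd

import taxikit as tk
from taxikit.metrics import binseries_to_frame

BASE = Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "simulations"
OUT = BASE / "metrics"
OUT.mkdir(parents=True, exist_ok=True)

geometry = tk.BeadAssayGeometry()
trend_rows = []

for scenario in ("control", "attractant", "repellent"):
    path = SIM / f"{scenario}_tracks.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run 02_simulate_assays.py first")
    ts = tk.read_tracks_table(path)

    counts = tk.frame_bin_counts(ts, geometry, 60.0)
    norm = tk.normalize_counts(counts, tk.NormalizationSpec())
    sine = tk.binned_mean_sine(ts, geometry, 60.0)
    sumdist = tk.sum_distance_series(ts, geometry, 60.0)
    total = tk.total_sum_distance(ts, geometry, 60.0, include_outside=True)
    speed_raw, speed_log = tk.binned_mean_speed(ts, geometry, 30.0)

    tidy = binseries_to_frame(
        counts + norm + sine + list(sumdist) + [total] + speed_raw + speed_log
    )
    tidy.insert(0, "scenario", scenario)
    tidy.to_csv(OUT / f"{scenario}_metrics.csv", index=False)

    for series in list(sumdist) + [total] + norm:
        res = tk.trend_slope(series)
        trend_rows.append({
            "scenario": scenario, "metric": series.metric, "bin": series.label,
            "slope": res.slope, "stderr": res.stderr,
            "tvalue": res.tvalue, "pvalue": res.pvalue,
        })

trends = pd.DataFrame(trend_rows)
trends.to_csv(OUT / "trend_slopes.csv", index=False)

show = trends[trends.bin == "ALL_CELLS"][["scenario", "slope", "tvalue"]]
print("total sum-distance trends (all cells, um per s):")
print(show.to_string(index=False))
print(f"tables written to {OUT}")
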