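"""Calibration curves and detection limits from a simulated ladder.

Simulates the nine-level 1:2 dilution series (20 -> 0.08 uM), extracts
every panel compound, selects each compound's linear range (r^2 > 0.95,
>= 5 contiguous levels) and calls the LOD as the lowest continuously
detected level.
"""

import pandas as pd

from ccmscan import (RunSpec, call_lod, extract_peaks, fit_linear_range,
                     load_default_panel, make_ladder, simulate_ladder)

panel = load_default_panel()
ladder = make_ladder()
print("ladder labels (uM):", ladder.labels)

spec = RunSpec(seed=7)
ft = simulate_ladder(panel, ladder, spec, polarity="-")
peaks = extract_peaks(ft, panel)
nominal = ft.samples["nominal_uM"]

rows = []
for entry, grp in peaks.groupby("entry"):
    det = grp[grp["status"] == "matched"]
    pts = [(float(nominal[s]), a) for s, a in zip(det["sample_id"], det["area"])]
    model = fit_linear_range(pts, entry)
    lod = call_lod(
        [(float(nominal[s]), st == "matched")
         for s, st in zip(grp["sample_id"], grp["status"])]
    )
    rows.append({"entry": entry, "status": model.status, "r2": model.r2,
                 "n_selected": len(model.selected), "lod_uM": lod})
df = pd.DataFrame(rows)
ok = df[df["status"] == "ok"]
print(f"\ncurves fit: {len(ok)}/{len(df)} compounds linear "
      f"(median r^2 {ok['r2'].median():.4f})")
no_curve = sorted(e for e in df.loc[df["status"] != "ok", "entry"]
                  if not panel[e].is_internal_standard)
print("analytes without a curve (unresolved isomer pairs):", no_curve)
print("\nfirst five calibrated compounds:")
print(ok.head(5).to_string(index=False))
# In this noise regime most compounds are detected down to the lowest
# level, so the called LOD sits at the 0.08 uM floor.
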