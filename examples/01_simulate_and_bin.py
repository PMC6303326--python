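"""Generate a synthetic continental forest-inventory table and bin it into
climatic units.

The generator emulates FIA-like plot data: correlated MAT/TAP climate,
ecoregion structure, Poisson species richness and lognormal productivity,
with the richness effect on productivity switching from linear-positive in
dry climates to hump-shaped in mesic climates.
"""

import forestbpr as fb

params = fb.default_params("continental", n_plots=10_000, seed=42)
table = fb.simulate(params=params)
table = fb.derive_productivity(table)
table, report = fb.filter_complete(table)

print(f"simulated plots: {report.n_input}, complete cases kept: {report.n_kept}")
print(f"MAT range: {table.df['mat'].min():.1f} .. {table.df['mat'].max():.1f} degC")
print(f"TAP range: {table.df['tap'].min():.0f} .. {table.df['tap'].max():.0f} mm")
print(f"richness: 1 .. {int(table.df['richness'].max())} species per plot")

grid = fb.build_grid(table, k=10)
units = fb.summarize_units(table, grid)
print(f"\npopulated climatic units: {len(units)} of {grid.k_mat * grid.k_tap}")
print("units per aridity class:")
for cls, count in units["aridity_class"].value_counts().items():
    print(f"  {cls:14s} {count}")
# Each unit is one cell of the 10x10 MAT x TAP quantile grid; the aridity
# class of a unit decides which BPR regime the analysis expects there.
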