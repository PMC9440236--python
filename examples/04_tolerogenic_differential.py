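"""Donor-blocked differential markers: tolerogenic vs control precursors.

Simulates control and vitamin-D3-treated 24 h precursors for three donors,
summarises each donor/arm as arcsinh medians of the control well, and runs
the donor-blocked differential test with Benjamini-Hochberg adjustment.
"""

import numpy as np

import scenmep as sm

archs = [a for a in sm.builtin_archetypes()
         if a.stage == "mono_24h" and a.condition in ("ctrl", "vitd3")]
events = sm.generate_scenith_dataset(
    archs, n_cells_per_well=1500, donor_model=sm.DonorModel(3, 0.1), seed=7)

markers = ["CD14", "HLA-DR", "CD86", "ILT3", "CD141", "p-mTOR", "p-AMPK"]
c_well = events[events["inhibitor"] == "C"]
rows = []
for (donor, condition), group in c_well.groupby(["donor_id", "condition"],
                                                observed=True):
    row = {"donor_id": donor, "group": condition}
    for m in markers:
        row[m] = float(np.median(sm.arcsinh_transform(group[m])))
    rows.append(row)

import pandas as pd
result = sm.differential_markers(pd.DataFrame(rows), ("ctrl", "vitd3"),
                                 markers=markers)
print(result.to_string(index=False,
                       float_format=lambda v: f"{v:.4f}"))

print("\nEffect is the donor-adjusted arcsinh-median difference"
      "\n(vitd3 - ctrl): positive for the tolerogenic signature (CD14,"
      "\nILT3, CD141, p-mTOR up), negative for costimulation (CD86 down).")
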