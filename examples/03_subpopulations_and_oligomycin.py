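"""Metabolic subpopulations: quantile strata and oligomycin classes.

Immature DC carry CD86-high (more mitochondrial) and CD1c-high (more
glycolytic) subsets. This script stratifies simulated iDC by CD86
expression, recomputes SCENITH per stratum, then classifies single
oligomycin-well cells as glycolytic vs mitochondrial and reports the
p-mTOR:p-AMPK ratio per puromycin tertile.
"""

import scenmep as sm

(arch,) = [a for a in sm.builtin_archetypes()
           if a.key == ("ctrl", "iDC")]
events = sm.generate_scenith_dataset(
    [arch], n_cells_per_well=4000, donor_model=sm.DonorModel(1, 0.0),
    seed=7)

# Top vs bottom CD86 quartile: recovered mitochondrial dependence
bins = sm.quantile_stratify(events, "CD86", k=4)
print("CD86 quartile -> mitochondrial dependence (%)")
for q in (1, 4):
    (p,) = sm.profiles_from_events(events[bins == q],
                                   by=("condition", "stage"), min_cells=100)
    print(f"  Q{q}: {p.clamped['mitochondrial_dependence']:.1f}")
print(f"  (generator truth: CD86hi subset "
      f"{arch.subpopulation_truth('CD86hi')['mitochondrial_dependence']:.0f},"
      f" CD1chi subset "
      f"{arch.subpopulation_truth('CD1chi')['mitochondrial_dependence']:.0f})")

# Single-cell oligomycin classification
group = events
o = group[group["inhibitor"] == "O"]
labels = sm.classify_oligomycin_cells(
    o, c_puromycin=group.loc[group["inhibitor"] == "C", "puromycin"],
    dgo_puromycin=group.loc[group["inhibitor"] == "DGO", "puromycin"])
frac = (labels["metabolic_class"] == "glycolytic").mean()
print(f"\nglycolytic fraction in the oligomycin well: {frac:.2f}")

merged = o.merge(labels, on="cell_id")
print("puromycin tertile -> p-mTOR:p-AMPK gMFI ratio")
for tertile in ("low", "mid", "high"):
    cells = merged[merged["puromycin_tertile"] == tertile]
    ratio = sm.phospho_ratio(sm.geometric_mfi(cells["p-mTOR"]),
                             sm.geometric_mfi(cells["p-AMPK"]))
    print(f"  {tertile}: {ratio:.3f}")

print("\nCells translating through an ATP-synthase block are running on"
      "\nglycolysis; quartile/tertile cuts expose that heterogeneity that a"
      "\nwhole-well gMFI hides.")
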