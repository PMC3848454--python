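"""Population structure: modified Rogers' distances, PCoA, and the
family-vs-diversity summaries used to interpret prediction accuracy.
"""

import numpy as np

import beetgs as b

# smaller study so the distance matrix is easy to eyeball
design = b.PopulationDesign(
    n_diversity=200,
    families=tuple(b.FamilySpec(f"Family{i}", 40) for i in range(1, 5)),
)
study = b.simulate_study(seed=42, design=design, n_markers=300, n_qtl=20)
pop = study.population

dm = b.modified_rogers_distance(study.marker_matrix())
res = b.pcoa(dm, n_axes=2)
print("PCoA of modified Rogers' distances:")
print(f"  axis 1 explains {res.explained[0]:.1%}, axis 2 {res.explained[1]:.1%}")

div_ids = pop.membership.index[pop.membership == "diversity"]
print(f"\nmean within-diversity-set distance: "
      f"{b.within_family_variation(dm, div_ids):.3f}")
print(f"{'family':>8} {'within':>7} {'to set':>7} {'monomorphic':>12}")
mm = study.marker_matrix()
for i in range(1, 5):
    fam = f"Family{i}"
    ids = pop.membership.index[pop.membership == fam]
    within = b.within_family_variation(dm, ids)
    to_set = b.mean_distance_to_set(dm, ids, div_ids)
    mono = b.count_monomorphic(mm, ids)
    print(f"{fam:>8} {within:7.3f} {to_set:7.3f} {mono:12d}")

print("\nBiparental families are tighter than the diversity set (all progeny")
print("segregate from one F1), and carry more monomorphic markers - markers")
print("whose QTL regions the family cannot see, one driver of poor")
print("across-population prediction.")
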