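"""Simulate a complete breeding-population study and inspect its layout.

Builds the default study geometry — 676 diverse inbred lines plus four
62-progeny biparental families sharing one common parent, genotyped with
677 SNPs on a 698 cM nine-chromosome map and testcross-phenotyped for six
traits at 1-7 locations — and prints what was generated.
"""

import beetgs as b

study = b.simulate_study(seed=42)
pop = study.population
mm = study.marker_matrix()

print(f"lines: {pop.n_lines} "
      f"({(pop.membership == 'diversity').sum()} diversity + "
      f"{(pop.membership != 'diversity').sum()} in families)")
print(f"markers: {mm.n_markers} on {len(pop.marker_map.chromosome_ids)} chromosomes, "
      f"map length {pop.marker_map.total_length:.0f} cM, "
      f"max gap {pop.marker_map.adjacent_gaps().max():.1f} cM")
print(f"hidden QTL: {study.qtl.n_qtl}")
print(f"mean per-line heterozygosity: {pop.heterozygosity().mean():.3f} "
      "(S1-S3 inbreds: expect ~0.09-0.12)")
for trait, rec in study.phenotypes.items():
    counts = rec.locations_per_line()
    print(f"trait {trait:>3}: {rec.n_records} entry means, "
          f"locations per line {counts.min()}-{counts.max()}")
print("\nEach trait is a per-location adjusted entry mean y_ij = mu + l_j + g_i + e_ij;")
print("the marker matrix is the 0/1/2 dosage input of the prediction model.")
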