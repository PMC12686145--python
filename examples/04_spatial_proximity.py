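"""Spatial proximity: which cell types sit closest to the reference type?

Per section, the k-distance of every reference cell to each target type is
summarized and ranked; robust rank aggregation integrates the per-section
rankings, separately for responder and non-responder sections.
"""

import cafsig as cs

spec = cs.SpatialSimSpec(seed=4)  # effector T cells near iCAFs in responders,
table, truth = cs.simulate_sections(spec)  # exhausted T cells in non-responders

ktable = cs.build_kdistance_table(table, spec.reference_type, k=10)
for group in ("R", "NR"):
    rm = cs.rank_matrix(ktable[ktable["group"] == group])
    rra = cs.rra_aggregate(rm)
    label = "responders" if group == "R" else "non-responders"
    print(f"\n{label}: RRA aggregate (position 1 = nearest to iCAF)")
    print(rra.to_string(index=False))

res = cs.compare_groups(ktable, "CD8_Tex")
print(f"\nCD8_Tex distance to iCAF: median R = {res['median_responder']:.1f}, "
      f"median NR = {res['median_nonresponder']:.1f}, p = {res['p_value']:.2e}")
# A small rho marks a type consistently ranked nearest across sections; the
# rank-sum test confirms exhausted T cells sit closer to iCAFs in
# non-responders, matching the planted dispersions.
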