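"""Normalize counts and test differential expression for one contrast.

Simulates the reference design, normalizes miRNA counts to reads per
million, and tests heat stress vs control in the tolerant genotype at 5 DPA
with the default moderated t-test on log2 abundances. Features whose
planted effect sits in this very contrast should surface as significant.
"""

from trio_mirnet import SimulationPlan, normalize_rpm, simulate_all, test_differential

plan = SimulationPlan(seed=11)
sim = simulate_all(plan)
rpm = normalize_rpm(sim["mirna_matrix"])

groups = {
    "HS": rpm.libraries_where(genotype="TG", treatment="HS", timepoint_dpa=5),
    "CG": rpm.libraries_where(genotype="TG", treatment="CG", timepoint_dpa=5),
}
table = test_differential(rpm, groups, contrast="TG:HS_vs_CG@5")

n_sig = (table["p_value"] < 0.05).sum()
print(f"{n_sig} of {len(table)} miRNAs at p < 0.05 in TG: HS vs CG at 5 DPA")

planted_here = {
    m for m, _, c, _ in sim["truth"].planted_antagonistic_pairs
    if c == "TG:HS_vs_CG@5"
}
top = table.sort_values("p_value").head(8)
for _, row in top.iterrows():
    mark = "*planted*" if row["feature_id"] in planted_here else ""
    print(f"  {row['feature_id']}  log2FC {row['log2fc']:+.2f}  "
          f"p {row['p_value']:.2e}  q {row['q_value']:.2e}  {mark}")
# The top of the list is dominated by the miRNAs whose ~4-fold effect was
# planted in this cell; the remaining significant calls reflect the 5%
# false-positive rate the raw-p filter accepts.
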