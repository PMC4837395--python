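"""Simulate three cell-line methylomes and call differentially methylated regions.

Generates a small synthetic study (one chemosensitive line WT, two resistant
lines R1/R2 with planted promoter/gene-body methylation shifts), filters CpG
sites to those covered at >=4x in all three lines, and tests each
feature-anchored region for a methylation shift (|median beta difference| >
0.20 and Wilcoxon signed-rank p < 0.01).
"""

from chemosig import annotate, differential
from chemosig.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(
    n_genes=60, n_mirnas=15, cpgs_min=10, cpgs_max=20,
    n_double=6, n_bg_de_genes=6, n_regulator_mirnas=6,
    n_bg_de_mirnas=2, n_meth_mirnas=3, n_neutral_true_pairs=15,
)
ds = simulate_dataset(cfg, seed=42)

shared = differential.filter_sites(list(ds.profiles.values()), min_depth=4)
print(f"CpG sites covered >=4x in all three lines: {len(shared)}")

regions = annotate.derive_promoters(ds.genes) + annotate.gene_feature_regions(ds.genes)
annotate.assign_cpgs(regions, ds.profiles["WT"])
res = differential.call_dmrs(ds.profiles["WT"], ds.profiles["R1"], regions, shared_sites=shared)
print(f"regions tested: {len(res)}, significant DMRs (R1 vs WT): {len(res.significant)}")

planted = {rid for rid, v in ds.truth.dmr_regions.items() if "R1" in v["lines"]}
called = {r.region_id for r in res.significant}
print(f"planted regions recovered: {len(called & planted)}/{len(planted & {r.region_id for r in res})}")
print(differential.dmr_location_summary(res.significant).to_string(index=False))
# The location table shows where the methylation changes fall (promoter,
# CDS, intron, UTR); the recovery line shows the planted shifts are found.
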