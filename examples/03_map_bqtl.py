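"""Map binding QTL by local association across the F1 panel.

For every site the binding frequency across lines is regressed on the
genotype code and on the allelic methylation differences (CG, CHG,
CHH), separately and jointly; sites significant at 5% FDR are
classified as genotype-driven, methylation-driven or both, and clumped
into 65-bp linkage groups.
"""

from pancistrome import SimConfig, binding_frequency, map_bqtl, simulate_dataset
from pancistrome.bqtl import assemble_predictors
from pancistrome.footprints import pool_replicates

cfg = SimConfig(n_sites=1_500, read_depth_mean=100, seed=7)
data = simulate_dataset(cfg)

pooled = pool_replicates(data.coverage["WW"])
pooled["binding_frequency"] = binding_frequency(
    pooled["rpgc_ref"].to_numpy(), pooled["rpgc_pat"].to_numpy()
)
predictors = assemble_predictors(pooled, data.genotypes, data.methylomes)
records = map_bqtl(predictors, data.sites.set_index("site_id")["pos"], fdr=0.05)

sig = records[records["sig_class"] != "none"]
print("significant bQTL:", len(sig), "of", len(records), "sites tested")
print("attribution:", sig["sig_class"].value_counts().to_dict())
print("linkage groups:", sig["group_id"].nunique(),
      "| lead sites:", int(sig["is_lead"].sum()))

truth = data.truth.classes.reindex(sig["site_id"])
print("planted classes among the selected sites:",
      truth.value_counts().to_dict())
print()
print("geno_only/meth_only/both mirror the planted causal structure: the")
print("few 'null' entries among selected sites are the FDR-controlled")
print("false discoveries.")
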