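"""Classify allele-specific sites across well-watered vs drought.

Sites with an AMP call in at least one condition fall into four groups:
(I) detected in only one condition, (II) >=60% bias toward the same
allele in both, (III) bias flipping allele between conditions, and
(IV) significant bias in one condition, near-balanced in the other.
"""

from pancistrome import SimConfig, call_amps, call_mps, simulate_dataset
from pancistrome.drought import classify_condition_amps_table, condition_pairs_from_records
from pancistrome.footprints import pool_replicates

cfg = SimConfig(n_sites=1_500, drought_effect_frac=0.3, seed=15)
data = simulate_dataset(cfg)

in_peak = data.sites.set_index("site_id")["in_peak"]
records = {}
for cond in ("WW", "DS"):
    pooled = pool_replicates(data.coverage[cond])
    records[cond] = call_amps(call_mps(pooled, in_peak))

pairs = condition_pairs_from_records(records["WW"], records["DS"])
groups = classify_condition_amps_table(pairs)
counts = groups.value_counts()
print("eligible condition pairs:", len(pairs))
for g in ("I", "II", "III", "IV", "unclassified"):
    print(f"  group {g:>12}: {counts.get(g, 0)}")
print()
print("Drought in this simulation rescales total occupancy but preserves")
print("allelic bias, so consistent-bias sites (II) dominate while bias")
print("flips (III) are rare -- occupancy changes, allele preference does not.")
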